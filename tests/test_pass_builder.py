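"""Cluster filtering, masking, homology screens and dataset assembly."""

import numpy as np
import pytest

from passforge import (
    Cluster,
    ScreenConfig,
    build_pass_dataset,
    filter_clusters,
    homology_screen,
    mask_low_complexity,
    purge_by_annotation,
)
from passforge.structio import CANONICAL_AA


def _cluster(family, rep_len, n_unique, rng):
    rep = "".join(rng.choice(list(CANONICAL_AA), size=rep_len))
    members = [rep]
    while len(set(members)) < n_unique:
        m = list(rep)
        i = int(rng.integers(rep_len))
        m[i] = CANONICAL_AA[int(rng.integers(20))]
        members.append("".join(m))
    return Cluster(family, rep, members)


class TestFilterClusters:
    def test_short_representative_dropped(self, rng):
        c = _cluster("short", 19, 12, rng)
        kept, rejected = filter_clusters([c])
        assert not kept and rejected == [("short", "length")]

    def test_shallow_cluster_dropped(self, rng):
        c = _cluster("shallow", 50, 9, rng)
        kept, rejected = filter_clusters([c])
        assert not kept and rejected == [("shallow", "depth")]

    def test_boundary_retained(self, rng):
        # strict "less than": length 20 with 10 unique members stays
        c = _cluster("edge", 20, 10, rng)
        kept, rejected = filter_clusters([c])
        assert kept == [c] and not rejected

    def test_duplicate_members_not_counted(self, rng):
        c = _cluster("dup", 30, 5, rng)
        c.members = c.members + c.members  # duplicates add no redundancy
        kept, _ = filter_clusters([c])
        assert not kept

    def test_200_cluster_fixture_matches_brute_force(self):
        rng = np.random.default_rng(2024)
        clusters = []
        for i in range(200):
            if i < 37:  # planted violations
                if i % 2 == 0:
                    clusters.append(_cluster(f"c{i}", int(rng.integers(5, 20)), 12, rng))
                else:
                    clusters.append(_cluster(f"c{i}", int(rng.integers(20, 60)),
                                             int(rng.integers(1, 10)), rng))
            else:
                clusters.append(_cluster(f"c{i}", int(rng.integers(20, 60)),
                                         int(rng.integers(10, 15)), rng))
        rng.shuffle(clusters)
        kept, rejected = filter_clusters(clusters)
        # independent exhaustive scan
        expect_kept = [c for c in clusters
                       if len(c.representative) >= 20 and len(c.unique_members()) >= 10]
        assert len(kept) == len(expect_kept) == 163
        assert len(kept) + len(rejected) == 200


class TestMaskLowComplexity:
    def test_homopolymer_fully_masked(self):
        assert mask_low_complexity("A" * 12) == "X" * 12

    def test_random_sequence_mostly_unmasked(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_AA), size=200))
        masked = mask_low_complexity(seq)
        assert masked.count("X") / len(seq) < 0.05

    def test_permutation_invariance(self):
        # entropy depends only on counts: relabelling residues preserves the mask
        seq = "AAAAABBBBBCCCCC" + "ACDEFGHIKLMNPQRSTVWY"
        perm = str.maketrans("ABC", "WYV")
        m1 = mask_low_complexity(seq)
        m2 = mask_low_complexity(seq.translate(perm))
        assert [c == "X" for c in m1] == [c == "X" for c in m2]

    def test_short_sequence_whole_entropy(self):
        assert mask_low_complexity("AAAA", window=11) == "XXXX"
        assert mask_low_complexity("ACDEFGHIK", window=11) == "ACDEFGHIK"

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            mask_low_complexity("ACDEF", window=4)

    def test_length_unchanged(self, rng):
        seq = "".join(rng.choice(list("AG"), size=60))
        assert len(mask_low_complexity(seq)) == 60


class TestHomologyScreen:
    def test_exact_copy_flagged_at_stage1(self, universe):
        ref = universe.labelled_test[0].sequence
        bait = Cluster("bait", ref, [ref])
        flags, evidence = homology_screen([bait], [ref], ScreenConfig(), "test")
        assert flags == {"bait"}
        assert "stage1" in evidence["bait"]

    def test_planted_baits_all_recalled(self, universe):
        baits = [c for c in universe.unlabelled_clusters
                 if c.family in universe.bait_families]
        refs = [e.sequence for e in universe.labelled_test]
        flags, _ = homology_screen(baits, refs, ScreenConfig(), "test")
        assert flags == universe.bait_families

    def test_background_false_flag_rate_below_5_percent(self, universe):
        background = [c for c in universe.unlabelled_clusters
                      if c.family not in universe.bait_families]
        refs = [e.sequence for e in universe.labelled_test]
        flags, _ = homology_screen(background, refs, ScreenConfig(), "test")
        assert len(flags) / len(background) < 0.05

    def test_test_stage_flags_contain_validation_stage_flags(self, universe):
        refs = [e.sequence for e in universe.labelled_test]
        clusters = universe.unlabelled_clusters
        ft, _ = homology_screen(clusters, refs, ScreenConfig(), "test")
        fv, _ = homology_screen(clusters, refs, ScreenConfig(), "validation")
        assert fv <= ft

    def test_empty_reference_set_rejected(self, universe):
        with pytest.raises(ValueError):
            homology_screen(universe.unlabelled_clusters[:1], [], ScreenConfig(), "test")

    def test_threshold_asymmetry_enforced(self):
        with pytest.raises(ValueError):
            ScreenConfig(stage1_identity_threshold=0.7, stage1_identity_threshold_val=0.5)


class TestAnnotationPurge:
    def test_matching_annotation_flagged(self):
        c = Cluster("c1", "ACDEFGHIKLMNPQRSTVWY", ["ACDEFGHIKLMNPQRSTVWY"])
        assert purge_by_annotation([c], {"c1": "A"}, {"A", "B"}) == {"c1"}

    def test_unannotated_cluster_never_flagged(self):
        c = Cluster("c1", "ACDEFGHIKLMNPQRSTVWY", ["ACDEFGHIKLMNPQRSTVWY"])
        assert purge_by_annotation([c], {}, {"A"}) == set()

    def test_annotated_baits_caught_even_if_sequence_screens_miss(self, rng):
        # three clusters unrelated in sequence but sharing test annotations
        clusters = [_cluster(f"b{i}", 40, 11, rng) for i in range(3)]
        ann = {f"b{i}": f"pf_test{i}" for i in range(3)}
        refs_ann = {"pf_test0", "pf_test1", "pf_test2"}
        flags, _ = homology_screen(clusters,
                                   ["".join(rng.choice(list(CANONICAL_AA), size=50))],
                                   ScreenConfig(), "test")
        assert not flags  # sequence screens see nothing
        assert purge_by_annotation(clusters, ann, refs_ann) == {"b0", "b1", "b2"}


class TestBuildPassDataset:
    @pytest.fixture(scope="class")
    def dataset(self, universe, teacher):
        test_ann = {universe.family_annotations[e.family] for e in universe.labelled_test}
        return build_pass_dataset(
            universe.unlabelled_clusters, teacher,
            universe.labelled_val, universe.labelled_test,
            ScreenConfig(), annotation_map=universe.family_annotations,
            reference_annotations=test_ann,
        )

    def test_no_bait_in_output(self, universe, dataset):
        out_fams = {e.family for e in dataset.examples}
        assert not (out_fams & universe.bait_families)

    def test_label_length_equals_sequence_length(self, dataset):
        for e in dataset.examples:
            assert len(e.labels) == len(e.sequence)

    def test_attrition_conserves_counts(self, dataset):
        a = dataset.attrition
        assert a["input"] == a["output"] + a["filter"] + a["screen_test"] \
            + a["screen_val"] + a["annotation"]

    def test_manifest_accounts_for_every_cluster(self, universe, dataset):
        fams = [m[0] for m in dataset.manifest]
        assert sorted(fams) == sorted(c.family for c in universe.unlabelled_clusters)

    def test_zero_survivors_raises_with_attrition(self, universe, teacher):
        with pytest.raises(RuntimeError, match="attrition"):
            build_pass_dataset(
                universe.unlabelled_clusters[:3], teacher,
                universe.labelled_val, universe.labelled_test,
                ScreenConfig(), min_members=10_000,
            )
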