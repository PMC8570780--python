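"""Pseudo-labelled dataset construction with leakage-safe screening.

The pipeline turns a pool of unlabelled sequence clusters into a
single-sequence training set:

1. **filter** — drop clusters whose representative is shorter than 20
   residues or that hold fewer than 10 non-redundant members;
2. **test screen (aggressive)** — flag clusters sharing detectable
   homology with any test-set sequence, using a coarse k-mer-anchored
   identity pass plus a profile-vs-sequence local alignment scan against
   complexity-masked references;
3. **validation screen (default stringency)** — k-mer identity pass only,
   at a stricter identity threshold (the validation set only steers
   early stopping, so the sweep need not be as wide);
4. **annotation purge** — drop clusters whose family annotation matches
   any test-set annotation (catching homologues the sequence screens
   missed);
5. **pseudo-label** — run the profile teacher on every survivor, keep
   the representative sequence plus its hard 3-class predictions, and
   discard the alignment.

Every input cluster is accounted for exactly once in the manifest,
either as retained or as removed with the stage that removed it.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .structio import AA_ALPHABET, Cluster, DEFAULT_ENCODING, LabelledExample, encode_sequence
from .teacher_profiler import Profile, TeacherModel, build_profile, teacher_predict

DEFAULT_MIN_LEN = 20
DEFAULT_MIN_MEMBERS = 10


@dataclass
class ScreenConfig:
    """Thresholds for the leakage screens.

    The test-set identity threshold must not exceed the validation one:
    the test pass is the aggressive sweep, trading false flags for
    recall, while the validation pass runs at default stringency.
    """

    stage1_kmer: int = 4
    stage1_identity_threshold: float = 0.45      # test pass (aggressive)
    stage1_identity_threshold_val: float = 0.55  # validation pass (default)
    stage1_min_overlap: int = 20
    stage2_score_threshold: float = 25.0         # profile-vs-sequence log-odds
    mask_window: int = 11
    mask_entropy_threshold: float = 2.0          # bits

    def __post_init__(self) -> None:
        if self.stage1_identity_threshold > self.stage1_identity_threshold_val:
            raise ValueError("test-stage identity threshold must be <= validation threshold")
        if self.mask_window < 3 or self.mask_window % 2 == 0:
            raise ValueError("mask_window must be odd and >= 3")


@dataclass
class PseudoLabelledSet:
    """Pseudo-labelled single-sequence examples plus full provenance."""

    examples: list[LabelledExample]
    probabilities: dict[str, np.ndarray] = field(default_factory=dict)
    manifest: list[tuple[str, str, str]] = field(default_factory=list)  # family, decision, reason
    attrition: dict[str, int] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Stage 0: cluster filters
# --------------------------------------------------------------------------

def filter_clusters(
    clusters: list[Cluster],
    min_len: int = DEFAULT_MIN_LEN,
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> tuple[list[Cluster], list[tuple[str, str]]]:
    """Drop short or shallow clusters; boundaries are inclusive.

    A cluster is removed when the representative length is strictly
    below ``min_len`` or the number of non-redundant member strings
    (unique after gap removal and uppercasing) is strictly below
    ``min_members``. Returns (retained, rejection log) where the log
    holds (family, reason) pairs.
    """
    kept, rejected = [], []
    for c in clusters:
        if len(c.representative) < min_len:
            rejected.append((c.family, "length"))
        elif len(c.unique_members()) < min_members:
            rejected.append((c.family, "depth"))
        else:
            kept.append(c)
    return kept, rejected


# --------------------------------------------------------------------------
# Low-complexity masking (windowed Shannon entropy)
# --------------------------------------------------------------------------

def mask_low_complexity(
    sequence: str,
    window: int = 11,
    entropy_threshold: float = 2.0,
) -> str:
    """Mask compositionally biased regions with 'X'.

    A residue is masked when the Shannon entropy (bits) of the residue
    counts in the length-``window`` window centred on it falls below
    ``entropy_threshold``. Entropy depends only on the count multiset,
    so masking is invariant to residue-identity permutations. Sequences
    shorter than the window are scored by whole-sequence entropy.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    L = len(sequence)
    if L == 0:
        return ""
    if L < window:
        ent = _entropy_bits(Counter(sequence))
        return "X" * L if ent < entropy_threshold else sequence
    half = window // 2
    masked = list(sequence)
    mask = np.zeros(L, dtype=bool)
    counts = Counter(sequence[:window])
    for i in range(half, L - half):
        if i > half:
            counts[sequence[i - half - 1]] -= 1
            if counts[sequence[i - half - 1]] == 0:
                del counts[sequence[i - half - 1]]
            counts[sequence[i + half]] += 1
        if _entropy_bits(counts) < entropy_threshold:
            mask[max(0, i - half):i + half + 1] = True
    for i in np.flatnonzero(mask):
        masked[i] = "X"
    return "".join(masked)


def _entropy_bits(counts: Counter) -> float:
    n = sum(counts.values())
    return -sum((k / n) * math.log2(k / n) for k in counts.values() if k)


# --------------------------------------------------------------------------
# Stage 1: k-mer-anchored identity screen
# --------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def best_anchored_identity(
    query: str,
    reference: str,
    ref_index: dict[str, list[int]],
    k: int,
    min_overlap: int,
) -> float:
    """Best ungapped identity over diagonals anchored by a shared k-mer.

    For every shared k-mer the implied diagonal offset is evaluated by
    counting matches over the full ungapped overlap; overlaps shorter
    than ``min_overlap`` are ignored. Returns 0.0 when no anchored
    diagonal qualifies.
    """
    offsets = set()
    for i in range(len(query) - k + 1):
        for j in ref_index.get(query[i:i + k], ()):
            offsets.add(j - i)
    best = 0.0
    Lq, Lr = len(query), len(reference)
    for off in offsets:
        q0 = max(0, -off)
        r0 = q0 + off
        n = min(Lq - q0, Lr - r0)
        if n < min_overlap:
            continue
        matches = sum(1 for a, b in zip(query[q0:q0 + n], reference[r0:r0 + n]) if a == b)
        best = max(best, matches / n)
    return best


# --------------------------------------------------------------------------
# Stage 2: profile-vs-sequence local alignment scan
# --------------------------------------------------------------------------

def profile_sequence_score(profile: Profile, reference: str) -> float:
    """Best gapless local alignment score of a profile against a sequence.

    Position *i* of the profile aligned to residue *j* of the reference
    scores ``log(p_i(aa_j) / (1/20))``; masked ('X') reference residues
    score 0. The best score is the maximum-sum contiguous segment over
    any diagonal (a gapless Smith-Waterman scan, which is exact for
    indel-free homology).
    """
    Lp = len(profile)
    ref_idx = encode_sequence(reference, DEFAULT_ENCODING)
    logmat = np.log(np.maximum(profile.matrix, 1e-12)) - math.log(1.0 / 20.0)
    # score[i, j] for profile position i vs reference residue j
    S = logmat[:, ref_idx]
    S[:, ref_idx == DEFAULT_ENCODING.x_index] = 0.0
    Lr = len(reference)
    best = 0.0
    for off in range(-(Lp - 1), Lr):
        i0 = max(0, -off)
        j0 = i0 + off
        n = min(Lp - i0, Lr - j0)
        diag = S[np.arange(i0, i0 + n), np.arange(j0, j0 + n)]
        cum = np.concatenate([[0.0], np.cumsum(diag)])
        running_min = np.minimum.accumulate(cum[:-1])
        best = max(best, float(np.max(cum[1:] - running_min)))
    return best


# --------------------------------------------------------------------------
# Homology screen (union of stages)
# --------------------------------------------------------------------------

def homology_screen(
    clusters: list[Cluster],
    reference_seqs: list[str],
    config: ScreenConfig,
    stage: str = "test",
) -> tuple[set[str], dict[str, str]]:
    """Flag clusters sharing detectable homology with the references.

    ``stage`` selects the sweep: ``"test"`` uses the aggressive stage-1
    identity threshold and additionally runs the stage-2
    profile-vs-sequence scan against complexity-masked references;
    ``"validation"`` runs stage 1 only at the stricter threshold.
    Returns (flagged family ids, evidence strings). Deterministic.
    """
    if stage not in ("test", "validation"):
        raise ValueError("stage must be 'test' or 'validation'")
    if not reference_seqs:
        raise ValueError("reference set is empty")
    thr = (config.stage1_identity_threshold if stage == "test"
           else config.stage1_identity_threshold_val)
    k = config.stage1_kmer
    ref_indices = [(r, _kmer_index(r, k)) for r in reference_seqs]
    flagged: set[str] = set()
    evidence: dict[str, str] = {}

    for c in clusters:
        hit = None
        for m, member in enumerate(c.members):
            seq = member.replace("-", "")
            for ri, (ref, ridx) in enumerate(ref_indices):
                ident = best_anchored_identity(seq, ref, ridx, k, config.stage1_min_overlap)
                if ident >= thr:
                    hit = f"stage1 member={m} ref={ri} identity={ident:.3f}"
                    break
            if hit:
                break
        if hit:
            flagged.add(c.family)
            evidence[c.family] = hit

    if stage == "test":
        masked_refs = [mask_low_complexity(r, config.mask_window,
                                           config.mask_entropy_threshold)
                       for r in reference_seqs]
        for c in clusters:
            if c.family in flagged:
                continue
            profile = build_profile(c)
            for ri, ref in enumerate(masked_refs):
                score = profile_sequence_score(profile, ref)
                if score >= config.stage2_score_threshold:
                    flagged.add(c.family)
                    evidence[c.family] = f"stage2 ref={ri} score={score:.2f}"
                    break
    return flagged, evidence


def purge_by_annotation(
    clusters: list[Cluster],
    annotation_map: dict[str, str],
    reference_annotations: set[str],
) -> set[str]:
    """Flag clusters whose family annotation matches a reference annotation.

    ``annotation_map`` may be partial; unannotated clusters are never
    flagged by this pass, and unannotated references contribute nothing
    (they simply are not in ``reference_annotations``).
    """
    flagged = set()
    for c in clusters:
        ann = annotation_map.get(c.family)
        if ann is not None and ann in reference_annotations:
            flagged.add(c.family)
    return flagged


# --------------------------------------------------------------------------
# Full dataset build
# --------------------------------------------------------------------------

def build_pass_dataset(
    clusters: list[Cluster],
    teacher: TeacherModel,
    labelled_val: list[LabelledExample],
    labelled_test: list[LabelledExample],
    screen_config: ScreenConfig | None = None,
    annotation_map: dict[str, str] | None = None,
    reference_annotations: set[str] | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    min_members: int = DEFAULT_MIN_MEMBERS,
    keep_probabilities: bool = False,
) -> PseudoLabelledSet:
    """Run the full pipeline: filter, screen, purge, pseudo-label.

    The builder sees test *sequences* only, never test labels. Raises
    with a stage-by-stage attrition report if no cluster survives.
    """
    screen_config = screen_config or ScreenConfig()
    manifest: list[tuple[str, str, str]] = []
    attrition = {"input": len(clusters)}

    kept, rejected = filter_clusters(clusters, min_len, min_members)
    for fam, reason in rejected:
        manifest.append((fam, "removed", f"filter:{reason}"))
    attrition["filter"] = len(rejected)

    test_refs = [e.sequence for e in labelled_test]
    flagged_test, ev_test = homology_screen(kept, test_refs, screen_config, stage="test")
    kept2 = [c for c in kept if c.family not in flagged_test]
    for c in kept:
        if c.family in flagged_test:
            manifest.append((c.family, "removed", f"screen_test:{ev_test[c.family]}"))
    attrition["screen_test"] = len(flagged_test)

    val_refs = [e.sequence for e in labelled_val]
    flagged_val, ev_val = homology_screen(kept2, val_refs, screen_config, stage="validation")
    kept3 = [c for c in kept2 if c.family not in flagged_val]
    for c in kept2:
        if c.family in flagged_val:
            manifest.append((c.family, "removed", f"screen_val:{ev_val[c.family]}"))
    attrition["screen_val"] = len(flagged_val)

    if annotation_map and reference_annotations:
        flagged_ann = purge_by_annotation(kept3, annotation_map, reference_annotations)
    else:
        flagged_ann = set()
    kept4 = [c for c in kept3 if c.family not in flagged_ann]
    for c in kept3:
        if c.family in flagged_ann:
            manifest.append((c.family, "removed", "annotation"))
    attrition["annotation"] = len(flagged_ann)

    examples: list[LabelledExample] = []
    probabilities: dict[str, np.ndarray] = {}
    for c in kept4:
        profile = build_profile(c)
        proba, labels = teacher_predict(teacher, profile)
        examples.append(LabelledExample(family=c.family, sequence=c.representative,
                                        labels=labels))
        if keep_probabilities:
            probabilities[c.family] = proba
        manifest.append((c.family, "retained", "pseudo-labelled"))
    attrition["output"] = len(examples)

    if not examples:
        raise RuntimeError(f"no clusters survived the pipeline; attrition: {attrition}")
    return PseudoLabelledSet(examples=examples, probabilities=probabilities,
                             manifest=manifest, attrition=attrition)
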