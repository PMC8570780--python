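"""Synthetic protein universe: homologous families with known 3-class structure.

The generator produces the statistical situation the pseudo-labelling
pipeline assumes: a small labelled training set, a small labelled
validation set, an orphan-like labelled test set, and a large pool of
unlabelled sequence clusters (aligned families). Ground truth for the
unlabelled clusters is retained off to the side so that the teacher can
be scored as an oracle diagnostic, but the pipeline itself never sees it.

Generative model
----------------
* A family's structure string is a first-order Markov chain over H/E/C
  with strong self-transitions (realistic segment lengths); the first
  state is drawn from the chain's stationary distribution.
* Residues are emitted per position from a class-conditional residue
  frequency row. The three emission rows deliberately overlap: a single
  residue carries weak class information, while an alignment column
  (many draws from the same row) identifies the class almost surely.
  This is the gap between single-sequence and profile-based prediction
  that the teacher-student scheme exploits, and it is controlled by a
  single ``difficulty`` scalar (0 = identical rows, 1 = disjoint rows).
* Homologues conserve the founder's structure exactly; each residue
  independently mutates with probability ``substitution_rate``, the
  replacement drawn from the emission row of the position's class.
  No indels are generated, so alignment coordinates are trivial.
* A configurable fraction of unlabelled families are "bait": true
  homologues of test-set families, planted to exercise the leakage
  screen. Baits inherit their source family's annotation.

Seeding uses a splittable hierarchy (one child stream per family, keyed
by split and index), so enlarging one split never reshuffles another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .structio import (
    CANONICAL_AA,
    Cluster,
    LabelledExample,
    SS3_CLASSES,
    read_cluster,
    read_fasta,
    read_labels,
    write_fasta,
    write_labels,
)

# streams of the seed hierarchy, one per family role
_STREAM = {"train": 0, "val": 1, "test": 2, "unlabelled": 3}

# residue preference groups used to build overlapping emission rows
_PREF = {
    "H": "AELMQKRH",
    "E": "VIYCWFT",
    "C": "GNPSD",
}

DEFAULT_TRANSITION = np.array(
    [
        [0.90, 0.04, 0.06],  # H
        [0.03, 0.90, 0.07],  # E
        [0.075, 0.075, 0.85],  # C
    ]
)


def default_emission(difficulty: float = 0.6) -> np.ndarray:
    """Class-conditional residue frequencies interpolating uniform -> disjoint.

    ``difficulty`` is the separation scalar: each class row is
    ``(1 - difficulty) * uniform + difficulty * uniform-over-preferred-set``.
    At 0 the rows coincide (single-sequence prediction impossible); at 1
    the preferred sets are disjoint and prediction is easy even from one
    residue.
    """
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must be in [0, 1]")
    rows = []
    for c in SS3_CLASSES:
        pref = np.zeros(20)
        for aa in _PREF[c]:
            pref[CANONICAL_AA.index(aa)] = 1.0 / len(_PREF[c])
        rows.append((1.0 - difficulty) / 20.0 + difficulty * pref)
    E = np.vstack(rows)
    return E / E.sum(axis=1, keepdims=True)


@dataclass
class UniverseConfig:
    """Everything that defines a synthetic universe draw."""

    n_labelled_families: int = 16
    n_val_families: int = 12
    n_test_families: int = 12
    n_unlabelled_families: int = 220
    length_range: tuple[int, int] = (40, 80)
    mean_depth: float = 18.0  # geometric member-count distribution, min 1
    structure_transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    emission: np.ndarray = field(default_factory=default_emission)
    substitution_rate: float = 0.3
    leak_fraction: float = 0.1
    bait_substitution_rate: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_labelled_families <= 0 or self.n_val_families <= 0 \
                or self.n_test_families <= 0 or self.n_unlabelled_families <= 0:
            raise ValueError("every split requires a positive family count")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length_range")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        _check_stochastic(self.structure_transition, (3, 3))
        _check_stochastic(self.emission, (3, 20))


def _check_stochastic(mat: np.ndarray, shape: tuple[int, int]) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != shape:
        raise ValueError(f"matrix must have shape {shape}")
    if np.any(mat < 0) or np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("matrix rows must be non-negative and sum to 1")


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution (leading left eigenvector) of a 3x3 chain."""
    _check_stochastic(np.asarray(transition, float), (3, 3))
    vals, vecs = np.linalg.eig(np.asarray(transition, float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# --------------------------------------------------------------------------
# Sampling primitives
# --------------------------------------------------------------------------

def sample_structure(length: int, transition: np.ndarray, rng: np.random.Generator) -> str:
    """Sample a 3-class structure string from the Markov chain.

    The first state comes from the stationary distribution so that state
    frequencies are length-independent.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    transition = np.asarray(transition, dtype=float)
    pi = stationary_distribution(transition)
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(3, p=pi)
    for i in range(1, length):
        states[i] = rng.choice(3, p=transition[states[i - 1]])
    return "".join(SS3_CLASSES[s] for s in states)


def sample_sequence(structure: str, emission: np.ndarray, rng: np.random.Generator) -> str:
    """Sample residues position-wise from the class-conditional emission rows."""
    emission = np.asarray(emission, dtype=float)
    _check_stochastic(emission, (3, 20))
    out = []
    for ch in structure:
        row = emission[SS3_CLASSES.index(ch)]
        out.append(CANONICAL_AA[rng.choice(20, p=row)])
    return "".join(out)


def spawn_family(
    founder_seq: str,
    founder_structure: str,
    depth: int,
    substitution_rate: float,
    emission: np.ndarray,
    rng: np.random.Generator,
    family: str = "fam",
) -> Cluster:
    """Generate a cluster of homologues of the founder.

    Structure is conserved; each founder residue independently mutates
    with probability ``substitution_rate``, the replacement drawn from
    the emission row of the (unchanged) structure class. ``depth``
    counts the representative, so depth 1 returns just the founder.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    emission = np.asarray(emission, dtype=float)
    L = len(founder_seq)
    cls = np.array([SS3_CLASSES.index(c) for c in founder_structure])
    members = [founder_seq]
    for _ in range(depth - 1):
        mutate = rng.random(L) < substitution_rate
        chars = list(founder_seq)
        for i in np.flatnonzero(mutate):
            chars[i] = CANONICAL_AA[rng.choice(20, p=emission[cls[i]])]
        members.append("".join(chars))
    return Cluster(family=family, representative=founder_seq, members=members)


# --------------------------------------------------------------------------
# Universe assembly
# --------------------------------------------------------------------------

@dataclass
class Universe:
    """A fully drawn synthetic universe.

    ``hidden_truth`` maps unlabelled family id -> ground-truth labels; it
    exists for oracle diagnostics and test assertions only and must not
    be consulted by the training pipeline.
    """

    config: UniverseConfig
    labelled_train: list[LabelledExample]
    labelled_val: list[LabelledExample]
    labelled_test: list[LabelledExample]
    unlabelled_clusters: list[Cluster]
    labelled_train_clusters: list[Cluster]
    labelled_val_clusters: list[Cluster]
    family_annotations: dict[str, str]
    hidden_truth: dict[str, str]
    bait_families: set[str]
    bait_source: dict[str, str]


def _family_rng(seed: int, stream: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM[stream], index))
    )


def _draw_depth(rng: np.random.Generator, mean_depth: float) -> int:
    # geometric on {1, 2, ...} with the configured mean
    p = min(1.0, 1.0 / max(mean_depth, 1.0))
    return int(rng.geometric(p))


def _make_founder(cfg: UniverseConfig, rng: np.random.Generator) -> tuple[str, str]:
    lo, hi = cfg.length_range
    L = int(rng.integers(lo, hi + 1))
    ss = sample_structure(L, cfg.structure_transition, rng)
    seq = sample_sequence(ss, cfg.emission, rng)
    return seq, ss


def build_universe(config: UniverseConfig) -> Universe:
    """Draw the full universe deterministically from ``config.seed``.

    Labelled families are emitted both as single labelled examples (the
    founder plus its true labels) and, for the train and validation
    splits, as alignments of homologues — the training input the profile
    teacher needs, and the evaluation input for the teacher-vs-student
    comparison. A ``leak_fraction`` of unlabelled families are planted
    homologues of test families (screen bait), recorded in
    ``bait_families``/``bait_source``.
    """
    config.validate()
    labelled: dict[str, list[LabelledExample]] = {"train": [], "val": [], "test": []}
    clusters_for: dict[str, list[Cluster]] = {"train": [], "val": []}
    annotations: dict[str, str] = {}
    counts = {
        "train": config.n_labelled_families,
        "val": config.n_val_families,
        "test": config.n_test_families,
    }
    test_founders: list[tuple[str, str, str]] = []  # (family, seq, ss)
    for split, n in counts.items():
        for i in range(n):
            fam = f"{split}{i:04d}"
            rng = _family_rng(config.seed, split, i)
            seq, ss = _make_founder(config, rng)
            labelled[split].append(LabelledExample(family=fam, sequence=seq, labels=ss))
            annotations[fam] = f"pf_{fam}"
            if split in clusters_for:
                depth = max(2, _draw_depth(rng, config.mean_depth))
                clusters_for[split].append(
                    spawn_family(seq, ss, depth, config.substitution_rate,
                                 config.emission, rng, family=fam)
                )
            if split == "test":
                test_founders.append((fam, seq, ss))

    n_bait = int(round(config.leak_fraction * config.n_unlabelled_families))
    bait_picker = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(9,))
    )
    bait_idx = set(
        bait_picker.choice(config.n_unlabelled_families, size=n_bait, replace=False).tolist()
    ) if n_bait else set()

    unlabelled: list[Cluster] = []
    hidden_truth: dict[str, str] = {}
    bait_families: set[str] = set()
    bait_source: dict[str, str] = {}
    for i in range(config.n_unlabelled_families):
        fam = f"u{i:05d}"
        rng = _family_rng(config.seed, "unlabelled", i)
        if i in bait_idx:
            src_fam, src_seq, src_ss = test_founders[int(rng.integers(len(test_founders)))]
            # bait founder: a diverged true homologue of the test founder
            bait = spawn_family(src_seq, src_ss, 2, config.bait_substitution_rate,
                                config.emission, rng).members[1]
            seq, ss = bait, src_ss
            annotations[fam] = annotations[src_fam]
            bait_families.add(fam)
            bait_source[fam] = src_fam
        else:
            seq, ss = _make_founder(config, rng)
            annotations[fam] = f"pf_{fam}"
        depth = _draw_depth(rng, config.mean_depth)
        cluster = spawn_family(seq, ss, depth, config.substitution_rate,
                               config.emission, rng, family=fam)
        unlabelled.append(cluster)
        hidden_truth[fam] = ss

    return Universe(
        config=config,
        labelled_train=labelled["train"],
        labelled_val=labelled["val"],
        labelled_test=labelled["test"],
        unlabelled_clusters=unlabelled,
        labelled_train_clusters=clusters_for["train"],
        labelled_val_clusters=clusters_for["val"],
        family_annotations=annotations,
        hidden_truth=hidden_truth,
        bait_families=bait_families,
        bait_source=bait_source,
    )


# --------------------------------------------------------------------------
# Serialization (plain-text directory layout)
# --------------------------------------------------------------------------

def save_universe(universe: Universe, outdir) -> None:
    """Write the universe as FASTA/label/cluster text files plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "clusters").mkdir(exist_ok=True)
    (out / "teacher_clusters").mkdir(exist_ok=True)
    (out / "val_clusters").mkdir(exist_ok=True)
    for split, examples in (("train", universe.labelled_train),
                            ("val", universe.labelled_val),
                            ("test", universe.labelled_test)):
        write_fasta([(e.family, e.sequence) for e in examples], out / f"{split}.fasta")
        write_labels([(e.family, e.labels) for e in examples], out / f"{split}.labels")
    for sub, clusters in (("clusters", universe.unlabelled_clusters),
                          ("teacher_clusters", universe.labelled_train_clusters),
                          ("val_clusters", universe.labelled_val_clusters)):
        for c in clusters:
            recs = [(c.family, c.members[0])]
            recs += [(f"{c.family}_m{j}", m) for j, m in enumerate(c.members[1:], 1)]
            write_fasta(recs, out / sub / f"{c.family}.afa")
    write_labels(sorted(universe.hidden_truth.items()), out / "hidden_truth.labels")
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("family\tsplit\tdepth\tbait\tbait_source\tannotation\n")
        for split, examples in (("train", universe.labelled_train),
                                ("val", universe.labelled_val),
                                ("test", universe.labelled_test)):
            for e in examples:
                fh.write(f"{e.family}\t{split}\t1\t0\t-\t{universe.family_annotations[e.family]}\n")
        for c in universe.unlabelled_clusters:
            bait = int(c.family in universe.bait_families)
            src = universe.bait_source.get(c.family, "-")
            fh.write(f"{c.family}\tunlabelled\t{c.depth}\t{bait}\t{src}\t"
                     f"{universe.family_annotations[c.family]}\n")
    cfg = dataclasses.asdict(universe.config)
    cfg["structure_transition"] = np.asarray(cfg["structure_transition"]).tolist()
    cfg["emission"] = np.asarray(cfg["emission"]).tolist()
    cfg["length_range"] = list(cfg["length_range"])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def load_universe(indir) -> Universe:
    """Inverse of :func:`save_universe`."""
    ind = Path(indir)
    with open(ind / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["structure_transition"] = np.array(raw["structure_transition"])
    raw["emission"] = np.array(raw["emission"])
    raw["length_range"] = tuple(raw["length_range"])
    config = UniverseConfig(**raw)

    def read_split(split: str) -> list[LabelledExample]:
        labs = dict(read_labels(ind / f"{split}.labels"))
        return [LabelledExample(family=f, sequence=s, labels=labs[f])
                for f, s in read_fasta(ind / f"{split}.fasta")]

    def read_cluster_dir(sub: str) -> list[Cluster]:
        return [read_cluster(p) for p in sorted((ind / sub).glob("*.afa"))]

    annotations: dict[str, str] = {}
    bait_families: set[str] = set()
    bait_source: dict[str, str] = {}
    with open(ind / "manifest.tsv") as fh:
        next(fh)
        for line in fh:
            fam, split, depth, bait, src, ann = line.rstrip("\n").split("\t")
            annotations[fam] = ann
            if bait == "1":
                bait_families.add(fam)
                bait_source[fam] = src
    return Universe(
        config=config,
        labelled_train=read_split("train"),
        labelled_val=read_split("val"),
        labelled_test=read_split("test"),
        unlabelled_clusters=read_cluster_dir("clusters"),
        labelled_train_clusters=read_cluster_dir("teacher_clusters"),
        labelled_val_clusters=read_cluster_dir("val_clusters"),
        family_annotations=annotations,
        hidden_truth=dict(read_labels(ind / "hidden_truth.labels")),
        bait_families=bait_families,
        bait_source=bait_source,
    )
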