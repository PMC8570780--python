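"""Sequence and secondary-structure I/O, alphabets and integer encodings.

The package works with three-class secondary structure (H = helix,
E = strand, C = coil) collapsed from the eight DSSP states, and with
amino-acid sequences encoded as integers over a 21-symbol alphabet
(20 canonical residues plus 'X' for anything unknown or non-canonical).

Formats handled here:

* plain FASTA (wrapped or unwrapped), via Biopython;
* aligned-FASTA / A3M cluster files (first record = representative,
  lowercase insertion states dropped);
* two-line label files (``>id`` then a label string over ``HEC.``,
  where ``.`` marks an unlabelled residue excluded from loss/metrics);
* a vertical per-residue prediction format compatible with PSIPRED's
  ss2 layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# --------------------------------------------------------------------------
# Alphabets
# --------------------------------------------------------------------------

#: Canonical amino acids in alphabetical one-letter order; 'X' is index 20.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = CANONICAL_AA + "X"
X_INDEX = 20

#: Three-class alphabet, fixed order used everywhere (confusions, reports).
SS3_CLASSES = "HEC"

#: Eight-state secondary-structure letters ('-' is "no assignment"/loop).
SS8_STATES = "HIGEBST-"

#: Mask symbol for unlabelled residues in label strings.
MASK_LABEL = "."

_SS8_TO_SS3 = {
    "H": "H", "G": "H",
    "E": "E", "B": "E",
    "I": "C", "S": "C", "T": "C", "-": "C",
}


class InvalidStateError(ValueError):
    """An out-of-alphabet secondary-structure state was encountered."""


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


@dataclass(frozen=True)
class ResidueEncoding:
    """Bijection between the 21-symbol residue alphabet and integers 0..20.

    Any letter outside the 20 canonical amino acids (B, Z, J, U, O, X, ...)
    resolves to the 'X' index.
    """

    alphabet: str = AA_ALPHABET
    index_of: dict = field(default_factory=lambda: {a: i for i, a in enumerate(AA_ALPHABET)})

    def __post_init__(self) -> None:
        if len(self.alphabet) != 21 or len(set(self.alphabet)) != 21:
            raise ValueError("residue alphabet must contain exactly 21 distinct symbols")

    @property
    def x_index(self) -> int:
        return self.index_of["X"]


DEFAULT_ENCODING = ResidueEncoding()


def map8to3(ss8: str) -> str:
    """Collapse an 8-state string to the 3 classes (E,B -> E; H,G -> H; rest -> C).

    'C' and ' ' are accepted as coil synonyms on input and normalized to '-'
    before mapping. Raises :class:`InvalidStateError` naming the first
    offending position for any other character.
    """
    out = []
    for i, ch in enumerate(ss8):
        c = ch.upper()
        if c in ("C", " "):
            c = "-"
        try:
            out.append(_SS8_TO_SS3[c])
        except KeyError:
            raise InvalidStateError(
                f"invalid 8-state character {ch!r} at position {i}"
            ) from None
    return "".join(out)


def encode_sequence(seq: str, enc: ResidueEncoding = DEFAULT_ENCODING) -> np.ndarray:
    """Encode an amino-acid string as integer indices in [0, 20].

    Canonical residues map to their fixed index; every other letter maps to
    the 'X' index. Non-alphabetic characters raise ``ValueError``.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    idx = np.empty(len(seq), dtype=np.int64)
    x = enc.x_index
    for i, ch in enumerate(seq):
        if not ch.isalpha():
            raise ValueError(f"non-alphabetic character {ch!r} at position {i}")
        idx[i] = enc.index_of.get(ch.upper(), x)
    return idx


def decode_sequence(indices: Sequence[int], enc: ResidueEncoding = DEFAULT_ENCODING) -> str:
    """Inverse of :func:`encode_sequence` (non-canonical letters come back as 'X')."""
    return "".join(enc.alphabet[i] for i in indices)


# --------------------------------------------------------------------------
# Core record types
# --------------------------------------------------------------------------

@dataclass
class LabelledExample:
    """A single sequence with an aligned 3-class label string.

    ``labels`` may contain the mask symbol '.' for unlabelled residues.
    """

    family: str
    sequence: str
    labels: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.labels):
            raise ValueError(
                f"{self.family}: sequence length {len(self.sequence)} != "
                f"label length {len(self.labels)}"
            )


@dataclass
class Cluster:
    """An aligned family: representative plus member rows.

    Members are stored in the alignment coordinates of the representative,
    i.e. every member string has exactly ``len(representative)`` columns and
    column *c* of any member aligns to residue *c* of the representative.
    The representative itself appears as ``members[0]``.
    """

    family: str
    representative: str
    members: list[str]

    def __post_init__(self) -> None:
        L = len(self.representative)
        for m in self.members:
            if len(m) != L:
                raise ValueError(f"{self.family}: ragged member row")

    @property
    def depth(self) -> int:
        return len(self.members)

    def unique_members(self) -> set[str]:
        """Distinct member strings after gap removal and uppercasing."""
        return {m.replace("-", "").upper() for m in self.members}


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs, order preserved.

    Wrapped and unwrapped sequence lines are both fine. Duplicate ids are
    kept but renamed with ``_dupN`` suffixes (a warning is emitted).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or unparseable FASTA file")
    seen: dict[str, int] = {}
    out = []
    for rec in records:
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            warnings.warn(f"{path}: duplicate id {rid!r}; renaming")
            rid = f"{rid}_dup{seen[rec.id]}"
        else:
            seen[rid] = 0
        out.append((rid, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA with ``width``-column wrapping."""
    seqrecs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# --------------------------------------------------------------------------
# Aligned cluster files (aligned FASTA / A3M dialect)
# --------------------------------------------------------------------------

def read_cluster(path, family: str | None = None) -> Cluster:
    """Read an aligned-FASTA/A3M cluster file; first record = representative.

    Lowercase letters are A3M insertion states and are dropped before
    column mapping. After insertion removal all rows must have equal
    length; columns where the representative has a gap are removed from
    every row, so that the returned coordinates index representative
    residues directly.
    """
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise FormatError(f"{path}: empty cluster file")
    rows = []
    for rec in raw:
        s = str(rec.seq)
        s = "".join(ch for ch in s if not ch.islower())  # drop A3M insertions
        s = s.replace(".", "-").upper()
        rows.append(s)
    L = len(rows[0])
    for r in rows:
        if len(r) != L:
            raise FormatError(f"{path}: ragged alignment (row lengths differ)")
    keep = [c for c in range(L) if rows[0][c] != "-"]
    rows = ["".join(r[c] for c in keep) for r in rows]
    fam = family if family is not None else raw[0].id
    return Cluster(family=fam, representative=rows[0], members=rows)


def write_cluster(cluster: Cluster, path) -> None:
    """Write a cluster as aligned FASTA (representative first)."""
    recs = [(f"{cluster.family}", cluster.members[0])]
    recs += [(f"{cluster.family}_m{i}", m) for i, m in enumerate(cluster.members[1:], 1)]
    write_fasta(recs, path)


# --------------------------------------------------------------------------
# Label files: two-line records, ">id" then the label string
# --------------------------------------------------------------------------

def read_labels(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0]
            else:
                if header is None:
                    raise FormatError(f"{path}: label line before any header")
                out.append((header, line))
                header = None
    return out


def write_labels(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, lab in records:
            fh.write(f">{rid}\n{lab}\n")


# --------------------------------------------------------------------------
# Vertical prediction format (ss2-style)
# --------------------------------------------------------------------------

_SS2_HEADER = "# PSF VFORMAT (passforge)"
# column order follows the public ss2 convention: coil, helix, strand
_SS2_PROB_ORDER = "CHE"


def write_ss2(sequence: str, labels: str, probabilities: np.ndarray, path) -> None:
    """Write per-residue predictions in a PSIPRED-ss2-compatible layout.

    ``probabilities`` is (L, 3) in H, E, C class order; columns are emitted
    in the conventional coil/helix/strand order with 3 decimals.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if not (len(sequence) == len(labels) == probabilities.shape[0]):
        raise ValueError("sequence, labels and probabilities must have equal length")
    if probabilities.ndim != 2 or probabilities.shape[1] != 3:
        raise ValueError("probabilities must be (L, 3)")
    sums = probabilities.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    order = [SS3_CLASSES.index(c) for c in _SS2_PROB_ORDER]
    with open(path, "w") as fh:
        fh.write(_SS2_HEADER + "\n\n")
        for i, (aa, ss) in enumerate(zip(sequence, labels), start=1):
            pc, ph, pe = probabilities[i - 1, order]
            fh.write(f"{i:4d} {aa} {ss}   {pc:.3f} {ph:.3f} {pe:.3f}\n")


def read_ss2(path) -> tuple[str, str, np.ndarray]:
    """Parse a file written by :func:`write_ss2` back into (seq, labels, probs)."""
    seq, labels, probs = [], [], []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _SS2_HEADER:
            raise FormatError(f"{path}: unexpected header {first!r}")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            _, aa, ss, pc, ph, pe = parts
            seq.append(aa)
            labels.append(ss)
            row = np.zeros(3)
            row[SS3_CLASSES.index("C")] = float(pc)
            row[SS3_CLASSES.index("H")] = float(ph)
            row[SS3_CLASSES.index("E")] = float(pe)
            probs.append(row)
    return "".join(seq), "".join(labels), np.array(probs)


def labels_to_indices(labels: str) -> np.ndarray:
    """Map an 'HEC.' label string to indices 0/1/2 with -1 at masked positions."""
    lut = {c: i for i, c in enumerate(SS3_CLASSES)}
    lut[MASK_LABEL] = -1
    try:
        return np.array([lut[c] for c in labels], dtype=np.int64)
    except KeyError as e:
        raise InvalidStateError(f"invalid 3-class label {e.args[0]!r}") from None
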