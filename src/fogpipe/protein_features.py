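"""Physicochemical profiling and pairwise global sequence similarity.

Composition uses a fixed four-way partition of the 20 standard residues;
the isoelectric point is the bisection root of the Henderson-Hasselbalch
net charge with EMBOSS pKa defaults; similarity is identity over the
optimal Needleman-Wunsch global alignment (affine gaps, BLOSUM62), with
gaps counted in the alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .io_formats import ProteinSequence

HYDROPHOBIC = frozenset("GAVLIPF")
AMPHIPATHIC = frozenset("WYM")
POLAR = frozenset("STCNQ")
CHARGED = frozenset("DEKRH")

GROUPS = {
    "hydrophobic": HYDROPHOBIC,
    "amphipathic": AMPHIPATHIC,
    "polar": POLAR,
    "charged": CHARGED,
}


@dataclass
class CompositionProfile:
    hydrophobic: float
    amphipathic: float
    polar: float
    charged: float

    def as_dict(self) -> dict[str, float]:
        return {
            "hydrophobic": self.hydrophobic,
            "amphipathic": self.amphipathic,
            "polar": self.polar,
            "charged": self.charged,
        }


def aa_composition(seq: ProteinSequence) -> CompositionProfile:
    """Fraction of residues in each of the four physicochemical groups."""
    n = len(seq.residues)
    fractions = {
        name: sum(1 for c in seq.residues if c in members) / n
        for name, members in GROUPS.items()
    }
    return CompositionProfile(**fractions)


# ---------------------------------------------------------------------------
# isoelectric point
# ---------------------------------------------------------------------------

@dataclass
class PkaSet:
    """Ionizable-group pKa values (EMBOSS defaults)."""

    n_terminus: float = 8.6
    c_terminus: float = 3.6
    side_chains: dict[str, float] = field(
        default_factory=lambda: {
            "D": 3.9,
            "E": 4.1,
            "C": 8.5,
            "Y": 10.1,
            "H": 6.5,
            "K": 10.8,
            "R": 12.5,
        }
    )

    ACIDIC = frozenset("DECY")
    BASIC = frozenset("HKR")

    def __post_init__(self) -> None:
        values = [self.n_terminus, self.c_terminus, *self.side_chains.values()]
        if not all(0 < v < 14 for v in values):
            raise ValidationError("pKa values must lie in (0, 14)")


def net_charge(seq: ProteinSequence, ph: float, pka: PkaSet | None = None) -> float:
    """Henderson-Hasselbalch net charge at the given pH, termini included."""
    pka = pka or PkaSet()
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - ph))
    for residue in seq.residues:
        if residue in PkaSet.BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka.side_chains[residue]))
        elif residue in PkaSet.ACIDIC:
            charge -= 1.0 / (1.0 + 10.0 ** (pka.side_chains[residue] - ph))
    return charge


def isoelectric_point(
    seq: ProteinSequence, pka: PkaSet | None = None, tol: float = 1e-6
) -> float:
    """pH where the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH (termini guarantee at least one
    acid and one base), so the root exists and is unique.
    """
    pka = pka or PkaSet()
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka)
        if abs(q) < tol and hi - lo < 1e-9:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


# ---------------------------------------------------------------------------
# global alignment similarity
# ---------------------------------------------------------------------------

def _make_aligner(substitution_matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    if substitution_matrix is None:
        substitution_matrix = substitution_matrices.load("BLOSUM62")
    elif isinstance(substitution_matrix, str):
        substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrix
    # a gap of length k costs gap_open + (k - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass
class AlignmentResult:
    """A pairwise global alignment as two gapped rows."""

    aligned_a: str
    aligned_b: str
    score: float

    def __getitem__(self, index: int) -> str:
        return (self.aligned_a, self.aligned_b)[index]

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def global_similarity(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    substitution_matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
):
    """Optimal global alignment and its identity-based similarity.

    Returns ``(alignment, similarity)`` where similarity = identical aligned
    positions / alignment length (gaps included in the length), in [0, 1].
    Co-optimal alignments are broken deterministically on the
    lexicographically smaller sequence, so the similarity is exactly
    symmetric in its arguments.
    """
    seq_a = a.residues if isinstance(a, ProteinSequence) else a
    seq_b = b.residues if isinstance(b, ProteinSequence) else b
    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    swap = seq_b < seq_a
    first, second = (seq_b, seq_a) if swap else (seq_a, seq_b)
    raw = aligner.align(first, second)[0]
    row_first, row_second = raw[0], raw[1]
    if swap:
        row_a, row_b = row_second, row_first
    else:
        row_a, row_b = row_first, row_second
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    similarity = identical / len(row_a)
    return AlignmentResult(row_a, row_b, float(raw.score)), similarity


def alignment_score(
    a: str, b: str, substitution_matrix=None, gap_open: float = 10.0, gap_extend: float = 1.0
) -> float:
    """Optimal global alignment score (for oracle comparisons)."""
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    return float(aligner.score(a, b))


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray  # square, symmetric, unit diagonal, in [0, 1] (or NaN)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SimilarityMatrix":
        return cls(list(frame.index), frame.to_numpy(dtype=float))


def sequence_similarity_matrix(
    family: list[ProteinSequence],
    substitution_matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> SimilarityMatrix:
    """All-pairs global-alignment similarity; symmetric with unit diagonal."""
    if len(family) < 2:
        raise ValidationError("need at least 2 sequences")
    n = len(family)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            _, sim = global_similarity(
                family[i], family[j], substitution_matrix, gap_open, gap_extend
            )
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix([s.seq_id for s in family], values)


def feature_table(family: list[ProteinSequence], pka: PkaSet | None = None) -> pd.DataFrame:
    """Per-sequence composition fractions, pI, and length."""
    rows = []
    for seq in family:
        profile = aa_composition(seq)
        rows.append(
            {
                "seq_id": seq.seq_id,
                "species_id": seq.species_id,
                "length": len(seq),
                **profile.as_dict(),
                "pI": isoelectric_point(seq, pka),
            }
        )
    return pd.DataFrame(rows)
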