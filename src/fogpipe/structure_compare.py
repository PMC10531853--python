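"""Rigid superposition, TM-score, and sequence/structure concordance.

The TM-score here is sequence-dependent: the residue correspondence between
two CA traces comes from the global alignment of their sequences (or an
explicit pair list), and the score is maximized over rigid superpositions
via the usual seed-fragment + distance-cutoff refinement. Matrix entries
average the two normalizations (by either chain length) to stay symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io_formats import ProteinSequence, Structure
from .protein_features import SimilarityMatrix, global_similarity


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    p: np.ndarray, q: np.ndarray, correspondence: list[tuple[int, int]] | None = None
) -> Superposition:
    """Least-squares optimal rigid motion mapping *p* onto *q*.

    With a correspondence list, only the listed (i_p, j_q) pairs enter the
    fit. Raises on <3 pairs or a collinear configuration.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if correspondence is not None:
        idx_p = [i for i, _ in correspondence]
        idx_q = [j for _, j in correspondence]
        p = p[idx_p]
        q = q[idx_q]
    if len(p) != len(q):
        raise ValidationError("coordinate sets must have equal length")
    if len(p) < 3:
        raise ValidationError("superposition needs >=3 corresponding pairs")

    p_mean = p.mean(axis=0)
    q_mean = q.mean(axis=0)
    p_c = p - p_mean
    q_c = q - q_mean
    if _is_collinear(p_c) or _is_collinear(q_c):
        raise ValidationError("degenerate (collinear) configuration")

    h = p_c.T @ q_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = q_mean - rotation @ p_mean
    residual = p @ rotation.T + translation - q
    rmsd = float(np.sqrt((residual**2).sum() / len(p)))
    return Superposition(rotation, translation, rmsd)


def _is_collinear(centered: np.ndarray, rtol: float = 1e-9) -> bool:
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= rtol * max(s[0], 1.0)


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

@dataclass
class TMScoreParams:
    """Scale parameter and search settings of the TM-score."""

    l_norm: str = "reference"  # or "shorter"
    max_refine_iters: int = 20
    seed_min_len: int = 4
    d0_floor: float = 0.5

    def d0(self, length: int) -> float:
        if length > 15:
            value = 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8
        else:
            value = 0.0
        return max(value, self.d0_floor)


def _tm_from_distances(d: np.ndarray, d0: float, l_norm: int) -> float:
    return float((1.0 / l_norm) * (1.0 / (1.0 + (d / d0) ** 2)).sum())


def tm_score(
    query: Structure | np.ndarray,
    ref: Structure | np.ndarray,
    correspondence: list[tuple[int, int]] | None = None,
    params: TMScoreParams | None = None,
    l_norm: int | None = None,
    superposition: Superposition | None = None,
    search: bool = True,
) -> float:
    """TM-score of *query* against *ref* under a residue correspondence.

    TM = max over rigid superpositions of (1/L_norm) * sum 1/(1+(d_i/d0)^2).
    The search seeds Kabsch fits on contiguous fragments (whole, halves,
    quarters; minimum length 4) and refines each by re-superposing on the
    pairs within d0 of each other, up to ``max_refine_iters`` rounds. With
    *search* False a fixed *superposition* is scored as-is.
    """
    params = params or TMScoreParams()
    p = query.coords if isinstance(query, Structure) else np.asarray(query, dtype=float)
    q = ref.coords if isinstance(ref, Structure) else np.asarray(ref, dtype=float)
    if correspondence is None:
        if len(p) != len(q):
            raise ValidationError("identity correspondence needs equal lengths")
        correspondence = [(i, i) for i in range(len(p))]
    if not correspondence:
        raise ValidationError("empty correspondence")
    idx_p = np.array([i for i, _ in correspondence])
    idx_q = np.array([j for _, j in correspondence])
    pc = p[idx_p]
    qc = q[idx_q]
    n_pairs = len(pc)

    if l_norm is None:
        if params.l_norm == "reference":
            l_norm = len(q)
        elif params.l_norm == "shorter":
            l_norm = min(len(p), len(q))
        else:
            raise ValidationError(f"unknown l_norm choice {params.l_norm!r}")
    d0 = params.d0(l_norm)

    if not search:
        if superposition is None:
            raise ValidationError("search disabled but no superposition given")
        d = np.linalg.norm(superposition.apply(pc) - qc, axis=1)
        return _tm_from_distances(d, d0, l_norm)

    best = 0.0
    for start, length in _seed_fragments(n_pairs, params.seed_min_len):
        window = np.arange(start, start + length)
        try:
            sup = kabsch_superpose(pc[window], qc[window])
        except ValidationError:
            continue
        selected = window
        for _ in range(params.max_refine_iters):
            d = np.linalg.norm(sup.apply(pc) - qc, axis=1)
            best = max(best, _tm_from_distances(d, d0, l_norm))
            cutoff = d0
            new_sel = np.flatnonzero(d < cutoff)
            while len(new_sel) < 3:
                cutoff += 0.5
                new_sel = np.flatnonzero(d < cutoff)
            if len(new_sel) == len(selected) and (new_sel == selected).all():
                break
            selected = new_sel
            try:
                sup = kabsch_superpose(pc[selected], qc[selected])
            except ValidationError:
                break
    return best


def _seed_fragments(n: int, min_len: int):
    """Contiguous seed windows: whole chain, then halves and quarters."""
    yield 0, n
    for divisor in (2, 4):
        length = max(n // divisor, min_len)
        if length >= n:
            continue
        step = max(length // 2, 1)
        for start in range(0, n - length + 1, step):
            yield start, length


# ---------------------------------------------------------------------------
# similarity matrix and concordance
# ---------------------------------------------------------------------------

def alignment_correspondence(
    a: ProteinSequence, b: ProteinSequence, **align_kwargs
) -> list[tuple[int, int]]:
    """Residue pairs from the non-gap columns of the global alignment."""
    alignment, _ = global_similarity(a, b, **align_kwargs)
    row_a, row_b = alignment[0], alignment[1]
    pairs = []
    i = j = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            pairs.append((i, j))
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    return pairs


def structure_similarity_matrix(
    structures: list[Structure],
    sequences: list[ProteinSequence],
    params: TMScoreParams | None = None,
    **align_kwargs,
) -> SimilarityMatrix:
    """Symmetric all-pairs TM-score matrix.

    Entry (A, B) is the mean of the TM-score normalized by each chain
    length. Correspondences come from the pairwise global sequence
    alignments; pairs aligning <3 residues get NaN.
    """
    if len(structures) != len(sequences):
        raise ValidationError("need exactly one structure per sequence")
    for structure, seq in zip(structures, sequences):
        if len(structure) != len(seq):
            raise ValidationError(
                f"structure {structure.struct_id!r} and sequence {seq.seq_id!r} "
                f"have different lengths ({len(structure)} vs {len(seq)})"
            )
    params = params or TMScoreParams()
    n = len(structures)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pairs = alignment_correspondence(sequences[i], sequences[j], **align_kwargs)
            if len(pairs) < 3:
                values[i, j] = values[j, i] = np.nan
                continue
            tm_i = tm_score(
                structures[i], structures[j], pairs, params, l_norm=len(structures[i])
            )
            tm_j = tm_score(
                structures[i], structures[j], pairs, params, l_norm=len(structures[j])
            )
            values[i, j] = values[j, i] = 0.5 * (tm_i + tm_j)
    return SimilarityMatrix([s.struct_id for s in structures], values)


@dataclass
class ConcordanceReport:
    seq_matrix: SimilarityMatrix
    struct_matrix: SimilarityMatrix
    spearman_rho: float | None
    discordant_pairs: list[tuple[str, str, float, float]]  # (idA, idB, seq, tm)

    def to_dict(self) -> dict:
        return {
            "labels": self.seq_matrix.labels,
            "spearman_rho": self.spearman_rho,
            "discordant_pairs": [
                {"id_a": a, "id_b": b, "seq_similarity": s, "tm": t}
                for a, b, s, t in self.discordant_pairs
            ],
        }


def dual_similarity_concordance(
    seq_matrix: SimilarityMatrix,
    struct_matrix: SimilarityMatrix,
    s_hi: float = 0.7,
    tm_lo: float = 0.5,
) -> ConcordanceReport:
    """Compare paired similarity matrices and flag discordant pairs.

    Spearman rho (mid-rank ties) is computed over the upper-triangle
    off-diagonal entries; a pair is discordant when seq >= s_hi and
    tm < tm_lo. Rho is None with fewer than 3 off-diagonal pairs (flagging
    still runs).
    """
    if seq_matrix.labels != struct_matrix.labels:
        raise ValidationError("matrices must share the same labels in order")
    labels = seq_matrix.labels
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    seq_vals = seq_matrix.values[iu]
    struct_vals = struct_matrix.values[iu]

    ok = np.isfinite(seq_vals) & np.isfinite(struct_vals)
    rho = None
    if ok.sum() >= 3:
        rho = float(stats.spearmanr(seq_vals[ok], struct_vals[ok]).statistic)

    discordant = []
    for i, j, s, t in zip(iu[0], iu[1], seq_vals, struct_vals):
        if np.isfinite(s) and np.isfinite(t) and s >= s_hi and t < tm_lo:
            discordant.append((labels[i], labels[j], float(s), float(t)))
    return ConcordanceReport(seq_matrix, struct_matrix, rho, discordant)
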