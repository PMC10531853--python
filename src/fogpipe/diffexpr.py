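"""Replicate QC and bundle-sheath vs mesophyll differential expression.

The DE stage is a deliberately simple negative-binomial Wald test:
median-of-ratios size factors, method-of-moments gene-wise dispersion with a
floor, a log-link NB GLM (intercept + cell-type coefficient) fitted by IRLS
at fixed dispersion, a two-sided normal p-value on the coefficient, and
Benjamini-Hochberg adjustment. No shrinkage, no outlier handling, no
independent filtering. DEG calls use strict inequalities on both the
adjusted p and |log2FC| thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import CountMatrix, SampleSheet

LN2 = np.log(2.0)
ALPHA_MIN = 1e-8

DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "se", "wald_stat", "p_value", "p_adj", "is_deg"]


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def compute_size_factors(
    counts: CountMatrix | np.ndarray, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios size factors.

    Reference genes are rows with no zero count; each sample's factor is the
    median over reference genes of count / geometric-mean. With
    *pseudo_reference*, the geometric mean of each gene is taken over its
    positive counts only, so zero-containing genes can serve as reference
    (use when no gene is zero-free).
    """
    matrix = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    matrix = matrix.astype(float)
    if pseudo_reference:
        reference = (matrix > 0).any(axis=1)
        if not reference.any():
            raise ValidationError("all counts are zero; size factors undefined")
        logs = np.full_like(matrix, np.nan, dtype=float)
        positive = matrix > 0
        np.log(matrix, where=positive, out=logs)
        log_geomean = np.nanmean(logs[reference], axis=1)
        log_ratios = logs[reference] - log_geomean[:, None]
        factors = np.exp(np.nanmedian(log_ratios, axis=0))
    else:
        reference = (matrix > 0).all(axis=1)
        if not reference.any():
            raise ValidationError(
                "no zero-free gene to use as reference; rerun with "
                "pseudo_reference=True"
            )
        logs = np.log(matrix[reference])
        log_geomean = logs.mean(axis=1)
        factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    if not (factors > 0).all():
        raise ValidationError("non-positive size factor")
    return factors


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: CountMatrix | np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
    alpha_min: float = ALPHA_MIN,
) -> np.ndarray:
    """Method-of-moments NB dispersion on normalized counts.

    Pools the within-group variance across the two groups and solves
    var = mean + alpha * mean**2 for alpha, floored at *alpha_min*.
    Zero-mean genes get the floor.
    """
    matrix = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    normalized = matrix / np.asarray(size_factors)[None, :]
    groups = np.asarray(groups)
    labels = np.unique(groups)
    n_total = 0
    ss = np.zeros(matrix.shape[0])
    mean_sq = np.zeros(matrix.shape[0])  # sample-weighted E[mu_g^2]
    for label in labels:
        cols = groups == label
        if cols.sum() < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 samples")
        sub = normalized[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        mean_sq += cols.sum() * sub.mean(axis=1) ** 2
        n_total += cols.sum()
    pooled_var = ss / (n_total - len(labels))
    mean = normalized.mean(axis=1)
    mean_sq /= n_total
    # var = mu + alpha * mu^2 holds per group; use the within-group means in
    # the quadratic term so DE genes are not biased upward
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean_sq
    alpha = np.where(mean > 0, alpha, alpha_min)
    return np.maximum(alpha, alpha_min)


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def wald_test(
    counts: CountMatrix,
    size_factors: np.ndarray,
    dispersions: np.ndarray,
    groups: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """NB log-link GLM Wald test, BS relative to M, vectorized over genes.

    *groups* holds 'BS'/'M' per sample. Returns a frame with columns
    gene_id, base_mean, log2fc, se, wald_stat, p_value plus boolean
    null_flag (all-zero gene) and converged. All-zero and non-converged
    genes get p=1 and log2fc=0 (conservative).
    """
    matrix = counts.counts.astype(float)
    sf = np.asarray(size_factors, dtype=float)
    groups = np.asarray(groups)
    is_bs = groups == "BS"
    if is_bs.sum() < 2 or (~is_bs).sum() < 2:
        raise ValidationError("need >=2 samples in each of BS and M")

    n_genes, n_samples = matrix.shape
    alpha = np.asarray(dispersions, dtype=float)
    x = is_bs.astype(float)  # group indicator column of the design
    log_sf = np.log(sf)

    null_flag = (matrix == 0).all(axis=1)
    active = ~null_flag

    beta = np.zeros((n_genes, 2))
    with np.errstate(divide="ignore"):
        beta[:, 0] = np.where(
            active, np.log(np.maximum((matrix / sf).mean(axis=1), 1e-8)), 0.0
        )

    converged = np.zeros(n_genes, dtype=bool)
    y = matrix
    for _ in range(max_iter):
        todo = active & ~converged
        if not todo.any():
            break
        b = beta[todo]
        eta = np.clip(b[:, [0]] + b[:, [1]] * x[None, :], -50.0, 50.0)
        mu = np.maximum(np.exp(eta + log_sf[None, :]), 1e-10)
        w = mu / (1.0 + alpha[todo, None] * mu)
        z = eta + (y[todo] - mu) / mu
        # closed-form 2x2 weighted LS for design [1, x]
        s0 = w.sum(axis=1)
        s1 = (w * x).sum(axis=1)
        s2 = (w * x * x).sum(axis=1)
        t0 = (w * z).sum(axis=1)
        t1 = (w * x * z).sum(axis=1)
        det = s0 * s2 - s1 * s1
        det = np.where(det > 0, det, np.nan)
        new0 = (s2 * t0 - s1 * t1) / det
        new1 = (s0 * t1 - s1 * t0) / det
        new = np.column_stack([new0, new1])
        delta = np.max(np.abs(new - b), axis=1)
        bad = ~np.isfinite(delta)
        new[bad] = b[bad]
        beta[todo] = new
        just_converged = np.zeros(n_genes, dtype=bool)
        just_converged[todo] = np.isfinite(delta) & (delta < tol)
        converged |= just_converged

    # standard errors at the final fit
    eta = np.clip(beta[:, [0]] + beta[:, [1]] * x[None, :], -50.0, 50.0)
    mu = np.maximum(np.exp(eta + log_sf[None, :]), 1e-10)
    w = mu / (1.0 + alpha[:, None] * mu)
    s0 = w.sum(axis=1)
    s1 = (w * x).sum(axis=1)
    s2 = (w * x * x).sum(axis=1)
    det = s0 * s2 - s1 * s1
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = np.where(det > 0, s0 / det, np.inf)
    se = np.sqrt(var_b1)

    ok = active & converged & np.isfinite(se) & (se > 0)
    coef = np.where(ok, beta[:, 1], 0.0)
    wald = np.where(ok, coef / np.where(se > 0, se, np.inf), 0.0)
    p = np.where(ok, 2.0 * stats.norm.sf(np.abs(wald)), 1.0)

    base_mean = (matrix / sf).mean(axis=1)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "base_mean": base_mean,
            "log2fc": coef / LN2,
            "se": np.where(ok, se / LN2, np.nan),
            "wald_stat": wald,
            "p_value": p,
            "null_flag": null_flag,
            "converged": converged,
        }
    )


# ---------------------------------------------------------------------------
# multiple testing and DEG calls
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_degs(de: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0) -> set[str]:
    """Strict thresholds: p_adj < alpha and |log2fc| > lfc_min."""
    mask = (de["p_adj"] < alpha) & (de["log2fc"].abs() > lfc_min)
    return set(de.loc[mask, "gene_id"])


def run_de(
    counts: CountMatrix,
    sample_sheet: SampleSheet,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Full per-species DE: size factors -> dispersion -> Wald -> BH -> DEG flag."""
    sheet = sample_sheet.for_species(counts.species_id)
    sheet = sheet[sheet["sample_id"].isin(counts.sample_ids)]
    ordered = [s for s in counts.sample_ids if s in set(sheet["sample_id"])]
    if len(ordered) < len(counts.sample_ids):
        counts = counts.subset_samples(ordered)
    groups = (
        sheet.set_index("sample_id").loc[counts.sample_ids, "cell_type"].to_numpy()
    )
    sf = compute_size_factors(counts, pseudo_reference=pseudo_reference)
    alpha_hat = estimate_dispersion(counts, sf, groups)
    de = wald_test(counts, sf, alpha_hat, groups)
    de["p_adj"] = bh_adjust(de["p_value"].to_numpy())
    de["is_deg"] = (de["p_adj"] < alpha) & (de["log2fc"].abs() > lfc_min)
    return de


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    correlation: pd.DataFrame  # samples x samples Pearson r
    within_group: pd.DataFrame  # per sample: max/min r vs same-cell-type replicates
    removed_samples: list[str]
    kept_despite_low_r: list[str] = field(default_factory=list)


def replicate_qc(
    counts: CountMatrix,
    sample_sheet: SampleSheet,
    r_min: float = 0.85,
    pseudo_reference: bool = False,
) -> QCReport:
    """Flag replicates inconsistent with their same-cell-type peers.

    Correlations are Pearson on log2(normalized count + 1). A sample is
    removed when its best correlation with same-cell-type replicates falls
    below *r_min* — unless removal would leave that group with fewer than 2
    replicates, in which case it is kept and flagged.
    """
    sheet = sample_sheet.for_species(counts.species_id)
    cell_type = sheet.set_index("sample_id")["cell_type"]
    missing = [s for s in counts.sample_ids if s not in cell_type.index]
    if missing:
        raise ValidationError(f"samples missing from sheet: {missing}")

    sf = compute_size_factors(counts, pseudo_reference=pseudo_reference)
    logged = np.log2(counts.counts / sf[None, :] + 1.0)
    corr = pd.DataFrame(
        np.corrcoef(logged, rowvar=False),
        index=counts.sample_ids,
        columns=counts.sample_ids,
    )

    rows = []
    candidates = []
    for sample in counts.sample_ids:
        peers = [
            s
            for s in counts.sample_ids
            if s != sample and cell_type[s] == cell_type[sample]
        ]
        if not peers:
            rows.append((sample, np.nan, np.nan))
            continue
        values = corr.loc[sample, peers]
        rows.append((sample, values.max(), values.min()))
        if values.max() < r_min:
            candidates.append(sample)
    within = pd.DataFrame(rows, columns=["sample_id", "max_within_r", "min_within_r"])
    within = within.set_index("sample_id")

    removed: list[str] = []
    kept: list[str] = []
    for sample in candidates:
        group = [
            s
            for s in counts.sample_ids
            if cell_type[s] == cell_type[sample] and s not in removed
        ]
        if len(group) - 1 < 2:
            kept.append(sample)
        else:
            removed.append(sample)
    return QCReport(corr, within, removed, kept)
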