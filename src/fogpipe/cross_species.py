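"""Ortholog-aware DEG intersection, enrichment, and signature classification.

Classes per ortholog group, evaluated in this order:

1. ``not_common`` — not a DEG in every species (unmappable counts as not DEG)
2. ``dropped_null`` — a null-expression flag in any species
3. outside the optional pathway filter -> dropped (class ``not_common``
   is not used here; such groups are simply excluded from the output of the
   filtered run, mirroring a restriction to enriched pathways)
4. sign test on per-species log2FC: uniform sign everywhere ->
   ``conserved_signature``; uniform within each photosynthesis type but
   opposite between types -> ``flip_over``; anything else ``inconsistent``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .diffexpr import bh_adjust, compute_size_factors
from .io_formats import CountMatrix, GeneSetCollection, OrthologMap, SampleSheet, SpeciesSheet

CLASS_CONSERVED = "conserved_signature"
CLASS_FLIP_OVER = "flip_over"
CLASS_INCONSISTENT = "inconsistent"
CLASS_DROPPED_NULL = "dropped_null"
CLASS_NOT_COMMON = "not_common"


# ---------------------------------------------------------------------------
# DEG projection and Venn partition
# ---------------------------------------------------------------------------

def project_degs(
    deg_sets: dict[str, set[str]], ortholog_map: OrthologMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project per-species DEG sets onto ortholog groups.

    Returns ``(membership, mappable)``: boolean frames indexed by group_id
    with one column per species. A group is a DEG in species *s* iff its
    *s*-gene exists and is in that species' DEG set; *mappable* records
    gene existence. Raises if a gene maps to more than one group.
    """
    by_species = ortholog_map.genes_by_species()
    groups = ortholog_map.group_ids()
    species = list(deg_sets)
    membership = pd.DataFrame(False, index=groups, columns=species)
    mappable = pd.DataFrame(False, index=groups, columns=species)
    for sp in species:
        gene_to_group = by_species.get(sp)
        if gene_to_group is None:
            continue
        mappable.loc[gene_to_group.values, sp] = True
        hits = gene_to_group[gene_to_group.index.isin(deg_sets[sp])]
        membership.loc[hits.values, sp] = True
    return membership, mappable


@dataclass
class VennPartition:
    """Counts of ortholog groups per exact species subset of DEG membership."""

    subset_counts: dict[frozenset[str], int]
    common_all: set[str]
    c4_specific: set[str]

    def total(self) -> int:
        return sum(self.subset_counts.values())


def venn_partition(membership: pd.DataFrame, species_sheet: SpeciesSheet) -> VennPartition:
    """Partition groups by their exact DEG species subset.

    ``common_all`` = DEG in every species; ``c4_specific`` = DEG in every C4
    species and no C3 species.
    """
    species = list(membership.columns)
    unknown = set(species) - set(species_sheet.species())
    if unknown:
        raise ValidationError(f"species missing from sheet: {sorted(unknown)}")
    counts: dict[frozenset[str], int] = {}
    for _, row in membership.iterrows():
        subset = frozenset(sp for sp in species if row[sp])
        if subset:
            counts[subset] = counts.get(subset, 0) + 1

    all_set = membership.index[membership[species].all(axis=1)]
    c3 = [sp for sp in species if species_sheet.type_of(sp) == "C3"]
    c4 = [sp for sp in species if species_sheet.type_of(sp) == "C4"]
    in_all_c4 = membership[c4].all(axis=1) if c4 else pd.Series(False, index=membership.index)
    in_no_c3 = ~membership[c3].any(axis=1) if c3 else pd.Series(True, index=membership.index)
    c4_specific = membership.index[in_all_c4 & in_no_c3]
    return VennPartition(counts, set(all_set), set(c4_specific))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    p_max: float = 0.01,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of *query* against each set.

    p = P(X >= k) drawing n=|query| from N=|universe| with K set members in
    the universe; q is BH over all tested sets. ``enriched`` requires
    p < p_max and q < q_max (strict).
    """
    if not universe:
        raise ValidationError("universe is empty")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    n = len(query)
    big_n = len(universe)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        k_hit = len(in_universe & query)
        big_k = len(in_universe)
        p = float(stats.hypergeom.sf(k_hit - 1, big_n, big_k, n))
        rows.append((name, k_hit, big_k, n, big_n, min(p, 1.0)))
    frame = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "p_value"]
    )
    frame["q_value"] = bh_adjust(frame["p_value"].to_numpy())
    frame["enriched"] = (frame["p_value"] < p_max) & (frame["q_value"] < q_max)
    return frame


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def classify_patterns(
    de_results: dict[str, pd.DataFrame],
    ortholog_map: OrthologMap,
    species_sheet: SpeciesSheet,
    pathway_filter: set[str] | None = None,
) -> pd.DataFrame:
    """Classify each ortholog group from per-species DE results.

    *de_results* maps species_id to a frame with columns gene_id, log2fc,
    p_adj, is_deg and (optionally) null_flag. Returns one row per group
    with per-species stats, a sign vector string, and the class.
    """
    species = species_sheet.species()
    missing = [sp for sp in species if sp not in de_results]
    if missing:
        raise ValidationError(f"no DE results for species: {missing}")
    species_sheet.require_both_types()
    c3 = species_sheet.species("C3")
    c4 = species_sheet.species("C4")
    groups = ortholog_map.group_ids()
    ortholog_map.genes_by_species()  # raises on gene mapped to >1 group

    lfc = pd.DataFrame(np.nan, index=groups, columns=species)
    padj = pd.DataFrame(np.nan, index=groups, columns=species)
    deg = pd.DataFrame(False, index=groups, columns=species)
    null = pd.DataFrame(False, index=groups, columns=species)
    omap = ortholog_map.frame
    for sp in species:
        de = de_results[sp]
        cols = ["gene_id", "log2fc", "p_adj", "is_deg"]
        stats_frame = de[cols + (["null_flag"] if "null_flag" in de.columns else [])].copy()
        if "null_flag" not in stats_frame.columns:
            stats_frame["null_flag"] = False
        sub = omap[omap["species_id"] == sp].merge(stats_frame, on="gene_id", how="inner")
        idx = sub["group_id"].values
        lfc.loc[idx, sp] = sub["log2fc"].values
        padj.loc[idx, sp] = sub["p_adj"].values
        deg.loc[idx, sp] = sub["is_deg"].values.astype(bool)
        null.loc[idx, sp] = sub["null_flag"].values.astype(bool)

    deg_all = deg.all(axis=1)
    any_null = null.any(axis=1)
    signs = np.sign(lfc.to_numpy())
    c3_cols = [species.index(sp) for sp in c3]
    c4_cols = [species.index(sp) for sp in c4]
    c3_uniform = np.abs(signs[:, c3_cols].sum(axis=1)) == len(c3_cols)
    c4_uniform = np.abs(signs[:, c4_cols].sum(axis=1)) == len(c4_cols)
    with np.errstate(invalid="ignore"):
        c3_sign = np.sign(signs[:, c3_cols].sum(axis=1))
        c4_sign = np.sign(signs[:, c4_cols].sum(axis=1))

    classes = np.full(len(groups), CLASS_INCONSISTENT, dtype=object)
    both_uniform = c3_uniform & c4_uniform
    classes[both_uniform & (c3_sign == c4_sign)] = CLASS_CONSERVED
    classes[both_uniform & (c3_sign == -c4_sign)] = CLASS_FLIP_OVER
    classes[any_null.to_numpy()] = CLASS_DROPPED_NULL
    classes[~deg_all.to_numpy()] = CLASS_NOT_COMMON

    sign_chars = np.full(signs.shape, ".", dtype=object)
    sign_chars[signs > 0] = "+"
    sign_chars[signs < 0] = "-"
    sign_chars[signs == 0] = "0"
    sign_vectors = ["".join(row) for row in sign_chars]

    out = pd.DataFrame({"group_id": groups, "class": classes, "sign_vector": sign_vectors})
    for sp in species:
        out[f"log2fc_{sp}"] = lfc[sp].values
        out[f"p_adj_{sp}"] = padj[sp].values
        out[f"deg_{sp}"] = deg[sp].values
        out[f"null_{sp}"] = null[sp].values
    if pathway_filter is not None:
        keep_anyway = out["class"].isin([CLASS_NOT_COMMON, CLASS_DROPPED_NULL])
        out = out[keep_anyway | out["group_id"].isin(pathway_filter)]
        out = out.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# photosynthesis-type correlation
# ---------------------------------------------------------------------------

def per_replicate_log2fc(
    counts: CountMatrix,
    sample_sheet: SampleSheet,
    gene_id: str,
    size_factors: np.ndarray | None = None,
) -> list[float]:
    """log2((BS_i + 1) / (M_i + 1)) on normalized counts, paired by replicate index."""
    if gene_id not in counts.gene_ids:
        raise ValidationError(f"gene {gene_id!r} not in count matrix")
    sheet = sample_sheet.for_species(counts.species_id)
    sheet = sheet[sheet["sample_id"].isin(counts.sample_ids)]
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    g = counts.gene_ids.index(gene_id)
    normalized = counts.counts[g, :] / np.asarray(size_factors)
    by_sample = dict(zip(counts.sample_ids, normalized))

    bs = sheet[sheet["cell_type"] == "BS"].set_index("replicate")["sample_id"]
    m = sheet[sheet["cell_type"] == "M"].set_index("replicate")["sample_id"]
    shared = sorted(set(bs.index) & set(m.index))
    return [
        float(np.log2((by_sample[bs[r]] + 1.0) / (by_sample[m[r]] + 1.0)))
        for r in shared
    ]


def type_correlation(
    values_by_species: dict[str, list[float]], species_sheet: SpeciesSheet
) -> float:
    """Pearson r between per-replicate log2FC values and the C3/C4 type code.

    Types are coded C3=0, C4=1. Returns NaN (reported as undefined) when
    either vector is constant; raises with fewer than 3 pairs.
    """
    xs: list[float] = []
    ys: list[float] = []
    for sp, values in values_by_species.items():
        code = 0.0 if species_sheet.type_of(sp) == "C3" else 1.0
        for v in values:
            xs.append(float(v))
            ys.append(code)
    if len(xs) < 3:
        raise ValidationError("type correlation needs >=3 (value, type) pairs")
    x = np.asarray(xs)
    y = np.asarray(ys)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
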