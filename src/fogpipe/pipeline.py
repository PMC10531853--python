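"""End-to-end orchestration: QC -> DE -> intersection -> enrichment ->
classification -> correlation -> protein features -> structure comparison
-> concordance, driven by a flat YAML config. Every stage's output is
persisted as TSV/JSON; optional stages are skipped with a logged notice
when their inputs are absent."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ValidationError
from . import cross_species, diffexpr, protein_features, structure_compare
from .io_formats import (
    read_counts,
    read_fasta,
    read_gene_sets,
    read_ortholog_map,
    read_pdb_ca,
    read_sheets,
)

logger = logging.getLogger("fogpipe")

DE_OUTPUT_COLUMNS = ["gene_id", "base_mean", "log2fc", "se", "p_value", "p_adj", "is_deg"]


@dataclass
class PipelineConfig:
    counts: dict[str, str]  # species_id -> counts TSV path
    samples: str
    species: str
    orthologs: str
    gene_sets: str | None = None
    fasta: str | None = None
    pdb_dir: str | None = None
    alpha: float = 0.05
    lfc_min: float = 1.0
    r_min: float = 0.85
    p_max: float = 0.01
    q_max: float = 0.05
    s_hi: float = 0.7
    tm_lo: float = 0.5
    seed: int = 0
    outdir: str = "fogpipe_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as handle:
                raw = yaml.safe_load(handle)
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a key-value document")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"counts", "samples", "species", "orthologs"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        config = cls(**raw)
        config.validate(base=Path(path).parent)
        return config

    def validate(self, base: Path | None = None) -> None:
        if not isinstance(self.counts, dict) or not self.counts:
            raise ConfigError("'counts' must map species ids to TSV paths")
        base = base or Path(".")
        self.counts = {sp: str(self._resolve(base, p)) for sp, p in self.counts.items()}
        for attr in ("samples", "species", "orthologs", "gene_sets", "fasta"):
            value = getattr(self, attr)
            if value is not None:
                setattr(self, attr, str(self._resolve(base, value)))
        if self.pdb_dir is not None:
            self.pdb_dir = str(self._resolve(base, self.pdb_dir, directory=True))
        for name, value, lo, hi in [
            ("alpha", self.alpha, 0, 1),
            ("p_max", self.p_max, 0, 1),
            ("q_max", self.q_max, 0, 1),
            ("s_hi", self.s_hi, 0, 1),
            ("tm_lo", self.tm_lo, 0, 1),
        ]:
            if not 0 < value <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {value}")
        if self.lfc_min < 0:
            raise ConfigError("lfc_min must be >= 0")

    @staticmethod
    def _resolve(base: Path, value: str, directory: bool = False) -> Path:
        path = Path(value)
        if not path.is_absolute():
            path = base / path
        if directory and not path.is_dir():
            raise ConfigError(f"directory not found: {path}")
        if not directory and not path.is_file():
            raise ConfigError(f"file not found: {path}")
        return path

    def digest(self) -> str:
        # outdir excluded: it does not affect the computation
        payload = {
            k: getattr(self, k)
            for k in sorted(self.__dataclass_fields__)
            if k != "outdir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class RunReport:
    deg_counts: dict[str, int]
    deg_proportions: dict[str, float]
    gene_counts: dict[str, int]
    removed_samples: dict[str, list[str]]
    venn: dict[str, int]
    n_common: int
    n_c4_specific: int
    class_counts: dict[str, int]
    flip_over_groups: list[str]
    conserved_groups: list[str]
    type_correlations: dict[str, float | None]
    enrichment: list[dict] | None
    concordance: dict | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "deg_counts": self.deg_counts,
            "deg_proportions": self.deg_proportions,
            "gene_counts": self.gene_counts,
            "removed_samples": self.removed_samples,
            "venn": self.venn,
            "n_common": self.n_common,
            "n_c4_specific": self.n_c4_specific,
            "class_counts": self.class_counts,
            "flip_over_groups": self.flip_over_groups,
            "conserved_groups": self.conserved_groups,
            "type_correlations": self.type_correlations,
            "enrichment": self.enrichment,
            "concordance": self.concordance,
            "provenance": self.provenance,
        }


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sample_sheet, species_sheet = read_sheets(config.samples, config.species)
    ortholog_map = read_ortholog_map(config.orthologs)
    counts = {
        sp: read_counts(path, sp) for sp, path in sorted(config.counts.items())
    }
    missing = set(counts) - set(species_sheet.species())
    if missing:
        raise ValidationError(f"count matrices for unknown species: {sorted(missing)}")

    # QC + DE per species
    de_results: dict[str, pd.DataFrame] = {}
    deg_sets: dict[str, set[str]] = {}
    removed: dict[str, list[str]] = {}
    size_factors: dict[str, np.ndarray] = {}
    for sp, matrix in counts.items():
        qc = diffexpr.replicate_qc(matrix, sample_sheet, r_min=config.r_min)
        removed[sp] = qc.removed_samples
        if qc.removed_samples:
            logger.info("QC removed samples for %s: %s", sp, qc.removed_samples)
            kept = [s for s in matrix.sample_ids if s not in set(qc.removed_samples)]
            matrix = matrix.subset_samples(kept)
            counts[sp] = matrix
        qc.correlation.to_csv(outdir / f"qc_corr_{sp}.tsv", sep="\t")
        de = diffexpr.run_de(matrix, sample_sheet, alpha=config.alpha, lfc_min=config.lfc_min)
        de_results[sp] = de
        deg_sets[sp] = diffexpr.call_degs(de, config.alpha, config.lfc_min)
        size_factors[sp] = diffexpr.compute_size_factors(matrix)
        de[DE_OUTPUT_COLUMNS].to_csv(outdir / f"de_{sp}.tsv", sep="\t", index=False)

    # intersection
    membership, _ = cross_species.project_degs(deg_sets, ortholog_map)
    venn = cross_species.venn_partition(membership, species_sheet)
    venn_rows = [
        {"species_subset": ",".join(sorted(k)), "n_groups": v}
        for k, v in sorted(venn.subset_counts.items(), key=lambda kv: sorted(kv[0]))
    ]
    pd.DataFrame(venn_rows, columns=["species_subset", "n_groups"]).to_csv(
        outdir / "venn.tsv", sep="\t", index=False
    )

    # enrichment (optional)
    enrichment_records = None
    pathway_filter = None
    if config.gene_sets is not None:
        collection = read_gene_sets(config.gene_sets)
        universe = set(ortholog_map.group_ids())
        enrichment = cross_species.hypergeometric_enrichment(
            venn.common_all, universe, collection, config.p_max, config.q_max
        )
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        enrichment_records = enrichment.to_dict(orient="records")
        enriched_sets = enrichment.loc[enrichment["enriched"], "set_name"]
        pathway_filter = set().union(
            *(collection.sets[name] for name in enriched_sets), set()
        ) or None
        if pathway_filter is None:
            logger.info("no enriched gene sets; pathway filter not applied")
    else:
        logger.info("no gene sets supplied; skipping enrichment")

    # classification
    classes = cross_species.classify_patterns(
        de_results, ortholog_map, species_sheet, pathway_filter=pathway_filter
    )
    fog_groups = sorted(classes.loc[classes["class"] == "flip_over", "group_id"])
    conserved_groups = sorted(
        classes.loc[classes["class"] == "conserved_signature", "group_id"]
    )

    # per-group photosynthesis-type correlation for signature classes
    correlations: dict[str, float | None] = {}
    gene_lookup = {
        (row["group_id"], row["species_id"]): row["gene_id"]
        for _, row in ortholog_map.frame.iterrows()
    }
    for group in fog_groups + conserved_groups:
        values: dict[str, list[float]] = {}
        for sp, matrix in counts.items():
            gene = gene_lookup.get((group, sp))
            if gene is None or gene not in matrix.gene_ids:
                continue
            values[sp] = cross_species.per_replicate_log2fc(
                matrix, sample_sheet, gene, size_factors[sp]
            )
        try:
            r = cross_species.type_correlation(values, species_sheet)
        except ValidationError:
            r = float("nan")
        correlations[group] = None if np.isnan(r) else float(r)
    classes["type_correlation"] = [
        correlations.get(g, None) for g in classes["group_id"]
    ]
    classes.to_csv(outdir / "signatures.tsv", sep="\t", index=False)

    # optional protein / structure stages
    concordance_dict = None
    if config.fasta is not None:
        family = read_fasta(config.fasta)
        features = protein_features.feature_table(family)
        features.to_csv(outdir / "protein_features.tsv", sep="\t", index=False)
        seq_matrix = protein_features.sequence_similarity_matrix(family)
        seq_matrix.to_frame().to_csv(outdir / "seq_similarity.tsv", sep="\t")
        if config.pdb_dir is not None:
            structures = []
            for seq in family:
                pdb_path = Path(config.pdb_dir) / f"{seq.seq_id}.pdb"
                if not pdb_path.is_file():
                    raise ValidationError(f"no structure for {seq.seq_id!r}: {pdb_path}")
                structures.append(read_pdb_ca(pdb_path))
            struct_matrix = structure_compare.structure_similarity_matrix(
                structures, family
            )
            struct_matrix = structure_compare.SimilarityMatrix(
                seq_matrix.labels, struct_matrix.values
            )
            struct_matrix.to_frame().to_csv(outdir / "struct_similarity.tsv", sep="\t")
            report = structure_compare.dual_similarity_concordance(
                seq_matrix, struct_matrix, s_hi=config.s_hi, tm_lo=config.tm_lo
            )
            concordance_dict = report.to_dict()
            with open(outdir / "concordance.json", "w") as handle:
                json.dump(concordance_dict, handle, indent=2)
        else:
            logger.info("no PDB directory supplied; skipping structure comparison")
    else:
        logger.info("no FASTA supplied; skipping protein stages")

    gene_counts = {sp: len(m.gene_ids) for sp, m in counts.items()}
    deg_counts = {sp: len(deg_sets[sp]) for sp in counts}
    report = RunReport(
        deg_counts=deg_counts,
        deg_proportions={sp: deg_counts[sp] / gene_counts[sp] for sp in counts},
        gene_counts=gene_counts,
        removed_samples=removed,
        venn={",".join(sorted(k)): v for k, v in venn.subset_counts.items()},
        n_common=len(venn.common_all),
        n_c4_specific=len(venn.c4_specific),
        class_counts=classes["class"].value_counts().to_dict(),
        flip_over_groups=fog_groups,
        conserved_groups=conserved_groups,
        type_correlations=correlations,
        enrichment=enrichment_records,
        concordance=concordance_dict,
        provenance={
            "config_sha256": config.digest(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    with open(outdir / "report.json", "w") as handle:
        json.dump(report.to_dict(), handle, indent=2, sort_keys=True)
    return report
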