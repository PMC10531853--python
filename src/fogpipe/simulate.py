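"""Synthetic counts, protein families, and CA-trace structures.

Everything here is a pure function of (parameters, seed): identical inputs
give bit-identical outputs. The count simulator plants ortholog groups of
four kinds — flip_over (opposite cell-type preference between C3 and C4
species), conserved_signature (same preference in all species),
species_specific (perturbed in exactly one species), and null — and returns
the ground-truth labels alongside the data so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    CountMatrix,
    OrthologMap,
    ProteinSequence,
    SampleSheet,
    SpeciesSheet,
    Structure,
    write_counts,
    write_ortholog_map,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CLASS_FLIP_OVER = "flip_over"
CLASS_CONSERVED = "conserved_signature"
CLASS_SPECIES_SPECIFIC = "species_specific"
CLASS_NULL = "null"


@dataclass
class SimDesign:
    """Parameters of the two-cell-type negative-binomial count simulation."""

    n_species_c3: int = 2
    n_species_c4: int = 3
    n_replicates: int = 3
    n_groups: int = 2000
    n_fog: int = 10
    n_conserved: int = 20
    n_species_specific: int = 20
    lfc_planted: float = 2.0
    dispersion: float = 0.05
    lib_size_mean: float = 1.0
    lib_size_cv: float = 0.2
    base_mean_log_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_fog + self.n_conserved + self.n_species_specific
        if planted > self.n_groups:
            raise ValidationError(
                f"planted gene counts ({planted}) exceed n_groups ({self.n_groups})"
            )
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.lib_size_mean <= 0:
            raise ValidationError("lib_size_mean must be > 0")
        if self.n_species_c3 < 1 or self.n_species_c4 < 1:
            raise ValidationError("need at least one species of each type")
        if self.n_replicates < 2:
            raise ValidationError("need >=2 replicates per cell type")


@dataclass
class SimTruth:
    """Ground truth: per-group class and per-(group, species) true log2FC."""

    classes: pd.Series  # index group_id -> class label
    log2fc: pd.DataFrame  # index group_id, columns species_id, BS-vs-M log2FC

    def groups_of(self, label: str) -> list[str]:
        return list(self.classes[self.classes == label].index)


@dataclass
class SimulatedExperiment:
    counts: dict[str, CountMatrix]
    sample_sheet: SampleSheet
    species_sheet: SpeciesSheet
    ortholog_map: OrthologMap
    truth: SimTruth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mean + dispersion * mean^2; Poisson when dispersion=0."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(design: SimDesign) -> SimulatedExperiment:
    """Simulate per-species count matrices with planted signature structure.

    Counts are NB with mean ``s_j * mu_g * 2**(sign * lfc/2)`` where the
    sign is + in BS and - in M for up-in-BS genes; the +/- lfc/2 split keeps
    each gene's average abundance constant across the contrast.
    """
    rng = np.random.default_rng(design.seed)
    c3 = [f"c3_{i + 1}" for i in range(design.n_species_c3)]
    c4 = [f"c4_{i + 1}" for i in range(design.n_species_c4)]
    species = c3 + c4
    width = max(4, len(str(design.n_groups)))
    groups = [f"g{i + 1:0{width}d}" for i in range(design.n_groups)]

    # class assignment
    order = rng.permutation(design.n_groups)
    classes = pd.Series(CLASS_NULL, index=groups, name="class")
    fog_idx = order[: design.n_fog]
    cons_idx = order[design.n_fog : design.n_fog + design.n_conserved]
    spec_idx = order[
        design.n_fog
        + design.n_conserved : design.n_fog
        + design.n_conserved
        + design.n_species_specific
    ]
    classes.iloc[fog_idx] = CLASS_FLIP_OVER
    classes.iloc[cons_idx] = CLASS_CONSERVED
    classes.iloc[spec_idx] = CLASS_SPECIES_SPECIFIC

    # per-(group, species) sign of the BS-vs-M effect
    signs = pd.DataFrame(0.0, index=groups, columns=species)
    for i in fog_idx:
        c3_sign = rng.choice([-1.0, 1.0])
        signs.iloc[i, : len(c3)] = c3_sign
        signs.iloc[i, len(c3) :] = -c3_sign
    for i in cons_idx:
        signs.iloc[i, :] = rng.choice([-1.0, 1.0])
    for i in spec_idx:
        target = rng.integers(len(species))
        signs.iloc[i, target] = rng.choice([-1.0, 1.0])

    truth_lfc = signs * design.lfc_planted
    base_mean = 2.0 ** rng.uniform(*design.base_mean_log_range, size=design.n_groups)

    # lognormal library sizes with the requested mean and CV
    sigma2 = np.log1p(design.lib_size_cv**2)
    mu_ln = np.log(design.lib_size_mean) - sigma2 / 2

    n_rep = design.n_replicates
    sample_rows: list[tuple[str, str, str, int]] = []
    ortho_rows: list[tuple[str, str, str]] = []
    counts: dict[str, CountMatrix] = {}
    for sp in species:
        gene_ids = [f"{sp}_{g}" for g in groups]
        sample_ids = [f"{sp}_BS_{r + 1}" for r in range(n_rep)] + [
            f"{sp}_M_{r + 1}" for r in range(n_rep)
        ]
        for r in range(n_rep):
            sample_rows.append((f"{sp}_BS_{r + 1}", sp, "BS", r + 1))
        for r in range(n_rep):
            sample_rows.append((f"{sp}_M_{r + 1}", sp, "M", r + 1))
        ortho_rows.extend((g, sp, f"{sp}_{g}") for g in groups)

        lib = np.exp(rng.normal(mu_ln, np.sqrt(sigma2), size=2 * n_rep))
        half = signs[sp].to_numpy() * design.lfc_planted / 2.0
        # (genes, samples) mean: +lfc/2 in BS columns, -lfc/2 in M columns
        cell_sign = np.array([1.0] * n_rep + [-1.0] * n_rep)
        mean = (
            base_mean[:, None]
            * 2.0 ** (half[:, None] * cell_sign[None, :])
            * lib[None, :]
        )
        matrix = _nb_draw(rng, mean, design.dispersion)
        counts[sp] = CountMatrix(sp, gene_ids, sample_ids, matrix)

    sample_sheet = SampleSheet(
        pd.DataFrame(sample_rows, columns=["sample_id", "species_id", "cell_type", "replicate"])
    )
    species_sheet = SpeciesSheet(
        pd.DataFrame(
            [(sp, "C3") for sp in c3] + [(sp, "C4") for sp in c4],
            columns=["species_id", "photosynthesis_type"],
        )
    )
    ortholog_map = OrthologMap(
        pd.DataFrame(ortho_rows, columns=["group_id", "species_id", "gene_id"])
    )
    truth = SimTruth(classes=classes, log2fc=truth_lfc)
    return SimulatedExperiment(counts, sample_sheet, species_sheet, ortholog_map, truth)


def simulate_protein_family(
    ancestor_length: int,
    per_species_substitution_rate: dict[str, float],
    seed: int = 0,
) -> list[ProteinSequence]:
    """Ancestor plus one mutated copy per species.

    The ancestor is drawn uniformly over the 20 codes; each species copy
    substitutes each site independently with its rate, choosing uniformly
    among the other 19 codes. The returned list starts with the ancestor
    (species_id ``ancestor``).
    """
    for sp, rate in per_species_substitution_rate.items():
        if not 0 <= rate < 1:
            raise ValidationError(f"substitution rate for {sp!r} must be in [0, 1)")
    if ancestor_length < 1:
        raise ValidationError("ancestor_length must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AA_ALPHABET))
    ancestor = rng.integers(20, size=ancestor_length)
    out = [ProteinSequence("ancestor", "ancestor", "".join(alphabet[ancestor]))]
    for sp, rate in per_species_substitution_rate.items():
        mutate = rng.random(ancestor_length) < rate
        # offset 1..19 from the current code picks uniformly among the others
        offsets = rng.integers(1, 20, size=ancestor_length)
        derived = np.where(mutate, (ancestor + offsets) % 20, ancestor)
        out.append(ProteinSequence(f"{sp}_hom", sp, "".join(alphabet[derived])))
    return out


# ideal CA helix geometry (Angstroms / degrees per residue)
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0


def simulate_helix_structure(
    length: int,
    noise_sigma: float = 0.0,
    rigid_transform: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
    struct_id: str = "helix",
) -> Structure:
    """Ideal CA helix with optional Gaussian noise and rigid transform.

    *rigid_transform* is a ``(rotation, translation)`` pair applied after
    the noise.
    """
    if length < 3:
        raise ValidationError("length must be >= 3")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    i = np.arange(length)
    theta = np.deg2rad(HELIX_TURN_DEG) * i
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    if rigid_transform is not None:
        rotation, translation = rigid_transform
        coords = coords @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
    return Structure(struct_id, coords, i + 1)


def write_experiment(experiment: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Persist a simulated experiment as the pipeline's TSV inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sp, matrix in experiment.counts.items():
        path = outdir / f"counts_{sp}.tsv"
        write_counts(matrix, path)
        paths[f"counts_{sp}"] = path

    samples_path = outdir / "samples.tsv"
    experiment.sample_sheet.frame.to_csv(samples_path, sep="\t", index=False)
    paths["samples"] = samples_path

    species_path = outdir / "species.tsv"
    experiment.species_sheet.frame.to_csv(species_path, sep="\t", index=False)
    paths["species"] = species_path

    ortho_path = outdir / "orthologs.tsv"
    write_ortholog_map(experiment.ortholog_map, ortho_path)
    paths["orthologs"] = ortho_path

    truth = experiment.truth.log2fc.copy()
    truth.insert(0, "class", experiment.truth.classes)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index_label="group_id")
    paths["truth"] = truth_path
    return paths
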