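"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain TSV; ``#``-prefixed lines are treated as
comments in count tables. Readers validate aggressively and raise
:class:`~fogpipe.errors.FormatError` with file/line context on the first
violation they encounter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
CELL_TYPES = ("BS", "M")
PHOTO_TYPES = ("C3", "C4")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample counts for one species."""

    species_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n_genes, n_samples = self.counts.shape
        if n_genes < 1 or n_samples < 2:
            raise ValidationError(
                f"need >=1 gene and >=2 samples, got {n_genes} x {n_samples}"
            )
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise ValidationError("id lists do not match matrix shape")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            self.species_id,
            list(self.gene_ids),
            list(sample_ids),
            self.counts[:, idx].copy(),
        )


@dataclass
class SampleSheet:
    """(sample_id, species_id, cell_type, replicate_index) rows."""

    frame: pd.DataFrame  # columns: sample_id, species_id, cell_type, replicate

    def __post_init__(self) -> None:
        required = ["sample_id", "species_id", "cell_type", "replicate"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        _check_unique(list(self.frame["sample_id"]), "sample id")
        bad = set(self.frame["cell_type"]) - set(CELL_TYPES)
        if bad:
            raise ValidationError(f"cell_type must be one of {CELL_TYPES}, got {bad}")
        if (self.frame["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be positive")
        for sp, sub in self.frame.groupby("species_id"):
            types = set(sub["cell_type"])
            if not set(CELL_TYPES) <= types:
                raise ValidationError(
                    f"species {sp!r} lacks one of the cell types {CELL_TYPES}"
                )

    def for_species(self, species_id: str) -> pd.DataFrame:
        return self.frame[self.frame["species_id"] == species_id].reset_index(drop=True)

    def species_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["species_id"]))


@dataclass
class SpeciesSheet:
    """(species_id, photosynthesis_type) rows."""

    frame: pd.DataFrame  # columns: species_id, photosynthesis_type

    def __post_init__(self) -> None:
        required = ["species_id", "photosynthesis_type"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"species sheet missing columns: {missing}")
        _check_unique(list(self.frame["species_id"]), "species id")
        bad = set(self.frame["photosynthesis_type"]) - set(PHOTO_TYPES)
        if bad:
            raise ValidationError(
                f"photosynthesis_type must be one of {PHOTO_TYPES}, got {bad}"
            )

    def type_of(self, species_id: str) -> str:
        row = self.frame[self.frame["species_id"] == species_id]
        if row.empty:
            raise ValidationError(f"unknown species {species_id!r}")
        return row["photosynthesis_type"].iloc[0]

    def species(self, photosynthesis_type: str | None = None) -> list[str]:
        f = self.frame
        if photosynthesis_type is not None:
            f = f[f["photosynthesis_type"] == photosynthesis_type]
        return list(f["species_id"])

    def require_both_types(self) -> None:
        present = set(self.frame["photosynthesis_type"])
        if present != set(PHOTO_TYPES):
            raise ValidationError(
                f"cross-type analysis needs both C3 and C4 species, got {present}"
            )


@dataclass
class OrthologMap:
    """(group_id, species_id, gene_id) rows, at most one gene per pair."""

    frame: pd.DataFrame  # columns: group_id, species_id, gene_id

    def __post_init__(self) -> None:
        required = ["group_id", "species_id", "gene_id"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"ortholog map missing columns: {missing}")
        dup = self.frame.duplicated(subset=["group_id", "species_id"])
        if dup.any():
            row = self.frame[dup].iloc[0]
            raise ValidationError(
                "duplicate (group, species) pair: "
                f"({row['group_id']!r}, {row['species_id']!r})"
            )

    def group_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group_id"]))

    def gene_for(self, group_id: str, species_id: str) -> str | None:
        sub = self.frame[
            (self.frame["group_id"] == group_id)
            & (self.frame["species_id"] == species_id)
        ]
        return None if sub.empty else sub["gene_id"].iloc[0]

    def genes_by_species(self) -> dict[str, pd.Series]:
        """Per species: Series mapping gene_id -> group_id."""
        out: dict[str, pd.Series] = {}
        for sp, sub in self.frame.groupby("species_id"):
            dup = sub.duplicated(subset="gene_id")
            if dup.any():
                gid = sub[dup]["gene_id"].iloc[0]
                raise ValidationError(
                    f"gene {gid!r} in species {sp!r} mapped to more than one group"
                )
            out[sp] = pd.Series(sub["group_id"].values, index=sub["gene_id"].values)
        return out


@dataclass
class ProteinSequence:
    seq_id: str
    species_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.seq_id!r} is empty")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValidationError(
                f"sequence {self.seq_id!r} contains non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """Ordered CA trace: one coordinate per residue, in Angstroms."""

    struct_id: str
    coords: np.ndarray  # (n, 3) float
    residue_numbers: np.ndarray  # (n,) int, strictly increasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be (n, 3)")
        if len(self.coords) < 3:
            raise ValidationError("structure needs >=3 residues")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinate")
        if len(self.residue_numbers) != len(self.coords):
            raise ValidationError("residue_numbers length mismatch")
        if not (np.diff(self.residue_numbers) > 0).all():
            raise ValidationError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise ValidationError(f"duplicate {what}(s): {sorted(set(dups))}")


def _data_lines(path: str | Path):
    """Yield (line_number, raw_line) skipping blanks and '#' comments."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, species_id: str) -> CountMatrix:
    """Parse an htseq-count-style TSV: header of sample ids, gene id rows.

    The first header cell is arbitrary. Cells must be nonnegative integers.
    """
    path = Path(path)
    rows = _data_lines(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty count table") from None
    sample_ids = header.split("\t")[1:]
    if len(sample_ids) < 2:
        raise FormatError(f"{path}: need at least 2 sample columns")

    gene_ids: list[str] = []
    data: list[list[int]] = []
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                f"got {len(fields)}"
            )
        gene = fields[0]
        values: list[int] = []
        for sample, cell in zip(sample_ids, fields[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {cell!r} for gene "
                    f"{gene!r}, sample {sample!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative count for gene {gene!r}, "
                    f"sample {sample!r}"
                )
            values.append(value)
        gene_ids.append(gene)
        data.append(values)

    if not data:
        raise FormatError(f"{path}: no gene rows")
    try:
        return CountMatrix(species_id, gene_ids, sample_ids, np.array(data, dtype=np.int64))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write the canonical count TSV (inverse of :func:`read_counts`)."""
    with open(path, "w") as handle:
        handle.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.counts):
            handle.write(gene + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# sheets / ortholog map / gene sets
# ---------------------------------------------------------------------------

def _read_tsv_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    records: list[list[str]] = []
    lines = _data_lines(path)
    try:
        lineno, header = next(lines)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    names = header.split("\t")
    if names != columns:
        raise FormatError(
            f"{path}:{lineno}: expected header {columns}, got {names}"
        )
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise FormatError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
            )
        records.append(fields)
    return pd.DataFrame(records, columns=columns)


def read_sheets(
    sample_path: str | Path, species_path: str | Path
) -> tuple[SampleSheet, SpeciesSheet]:
    sample_frame = _read_tsv_table(
        sample_path, ["sample_id", "species_id", "cell_type", "replicate"]
    )
    try:
        sample_frame["replicate"] = sample_frame["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{sample_path}: non-integer replicate index: {exc}") from exc
    species_frame = _read_tsv_table(species_path, ["species_id", "photosynthesis_type"])
    try:
        return SampleSheet(sample_frame), SpeciesSheet(species_frame)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def read_ortholog_map(path: str | Path) -> OrthologMap:
    frame = _read_tsv_table(path, ["group_id", "species_id", "gene_id"])
    try:
        return OrthologMap(frame)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.frame.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then tab-separated members."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 member"
            )
        name, desc, *members = fields
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = set(members)
        descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    species_map: dict[str, str] | None = None,
    drop_nonstandard: bool = False,
) -> list[ProteinSequence]:
    """Read protein FASTA; headers parsed as ``seq_id|species_id``.

    Records without a ``|`` token fall back to *species_map* (seq_id ->
    species_id), or species_id ``""`` if no mapping is supplied. With
    *drop_nonstandard*, residues outside the 20 standard codes are removed
    with a warning instead of raising.
    """
    path = Path(path)
    out: list[ProteinSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        token = record.id
        if "|" in token:
            seq_id, species_id = token.split("|", 1)
        else:
            seq_id = token
            species_id = (species_map or {}).get(seq_id, "")
        residues = str(record.seq).upper()
        if drop_nonstandard:
            kept = "".join(c for c in residues if c in STANDARD_AA)
            if kept != residues:
                warnings.warn(
                    f"{path}: dropped {len(residues) - len(kept)} non-standard "
                    f"residue(s) from {seq_id!r}"
                )
            residues = kept
        try:
            out.append(ProteinSequence(seq_id, species_id, residues))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: Sequence[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as handle:
        for seq in sequences:
            header = seq.seq_id if not seq.species_id else f"{seq.seq_id}|{seq.species_id}"
            handle.write(f">{header}\n{seq.residues}\n")


# ---------------------------------------------------------------------------
# PDB CA traces
# ---------------------------------------------------------------------------

def read_pdb_ca(path: str | Path, chain: str | None = None) -> Structure:
    """Extract the CA trace from PDB ATOM records.

    Only atom name ``CA`` is kept; altloc other than blank/'A' and records
    with insertion codes are skipped (the latter with a warning). The first
    chain encountered is used unless *chain* is given.
    """
    path = Path(path)
    coords: list[tuple[float, float, float]] = []
    residue_numbers: list[int] = []
    selected_chain: str | None = chain
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith("ATOM"):
                continue
            atom_name = line[12:16].strip()
            if atom_name != "CA":
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            chain_id = line[21]
            if selected_chain is None:
                selected_chain = chain_id
            if chain_id != selected_chain:
                continue
            icode = line[26]
            if icode != " ":
                warnings.warn(f"{path}:{lineno}: skipping insertion-code residue")
                continue
            try:
                resseq = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed ATOM record") from None
            residue_numbers.append(resseq)
            coords.append(xyz)
    if not coords:
        raise FormatError(f"{path}: no CA atoms" + (f" in chain {chain!r}" if chain else ""))
    if not all(b > a for a, b in zip(residue_numbers, residue_numbers[1:])):
        raise FormatError(f"{path}: residue numbering is not strictly increasing")
    try:
        return Structure(path.stem, np.array(coords), np.array(residue_numbers))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_pdb_ca(structure: Structure, path: str | Path, chain: str = "A") -> None:
    """Write the CA trace as minimal PDB ATOM records."""
    with open(path, "w") as handle:
        for i, (num, (x, y, z)) in enumerate(
            zip(structure.residue_numbers, structure.coords), start=1
        ):
            handle.write(
                f"ATOM  {i:5d}  CA  ALA {chain}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        handle.write("END\n")
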