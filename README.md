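# fogpipe

Cross-species discovery of cell-specific transcriptome signature genes
between C3 and C4 grasses — including *flip-over genes* (ortholog groups
whose bundle-sheath/mesophyll preference is opposite in C3 vs C4 species) —
plus downstream protein-level analysis comparing pairwise sequence
similarity with pairwise structure similarity (TM-score) to flag
sequence/structure discordance.

The pipeline starts from per-species gene × sample count matrices and runs:

1. **Replicate QC** — Pearson correlation of log-normalized counts;
   replicates inconsistent with their same-cell-type peers are removed.
2. **Differential expression** — median-of-ratios size factors,
   method-of-moments NB dispersion, NB Wald test (log-link GLM via IRLS),
   Benjamini–Hochberg adjustment; DEGs require adjusted p < 0.05 and
   |log2FC| > 1 (both strict).
3. **Cross-species intersection** — ortholog-aware Venn partition
   (common-to-all and C4-specific sets), optional hypergeometric enrichment
   over user-supplied GMT gene sets (enriched ⇔ p < 0.01 and q < 0.05).
4. **Classification** — each ortholog group that is a DEG in every species
   is classified by the sign pattern of its log2FCs:
   `conserved_signature` (one sign everywhere), `flip_over` (uniform within
   each photosynthesis type, opposite between types), or `inconsistent`;
   groups with null expression are dropped, everything else is
   `not_common`.
5. **Type correlation** — Pearson r between per-replicate log2FC values and
   the C3/C4 type code per signature group.
6. **Protein features** (optional) — four-group amino-acid composition,
   isoelectric point (EMBOSS pKa set, bisection), pairwise global-alignment
   similarity (Needleman–Wunsch, BLOSUM62, affine gaps).
7. **Structure comparison** (optional) — Kabsch superposition, RMSD, and
   sequence-dependent TM-score over CA traces; symmetric similarity matrix;
   dual-similarity concordance flags pairs with high sequence but low
   structure similarity (defaults: seq ≥ 0.7, TM < 0.5).

A synthetic-data module generates NB count matrices with planted flip-over /
conserved / species-specific groups (with ground truth), protein families
with controlled divergence, and noisy/rigidly transformed CA helices, so the
whole pipeline is testable without any external data.

## CLI

```sh
# synthetic inputs (TSV counts/sheets/orthologs + truth labels)
fogpipe simulate --outdir data [--config sim.yaml] [--seed 3]

# per-species QC + DE
fogpipe de --counts data/counts_c3_1.tsv --samples data/samples.tsv \
  --species data/species.tsv --out de_c3_1.tsv

# classification from a directory of de_<species>.tsv files
fogpipe signatures --de-dir . --orthologs data/orthologs.tsv \
  --species data/species.tsv --out signatures.tsv

# protein features and similarity matrices
fogpipe protfeat --fasta family.fa --out features.tsv --pairs seq_sim.tsv
fogpipe structcomp --pdb-dir pdb/ --fasta family.fa --out struct_sim.tsv
fogpipe concordance --seq seq_sim.tsv --struct struct_sim.tsv --out report.json

# everything end to end
fogpipe run --config config.yaml
```

`config.yaml` is a flat document; required keys `counts` (mapping
species_id → counts TSV), `samples`, `species`, `orthologs`; optional
`gene_sets` (GMT), `fasta`, `pdb_dir`; thresholds `alpha`, `lfc_min`,
`r_min`, `p_max`, `q_max`, `s_hi`, `tm_lo`; plus `seed` and `outdir`.
Exit codes: 0 success, 2 config error, 3 data validation error.

## File formats

All inputs are plain text: counts TSV (header of sample ids, gene-id rows,
`#` comments allowed), sample sheet TSV (`sample_id species_id cell_type
replicate`), species sheet TSV (`species_id photosynthesis_type`), ortholog
TSV (`group_id species_id gene_id`, one gene per group and species), GMT,
protein FASTA (headers `seq_id|species_id`), and PDB ATOM records (CA
traces). Outputs are TSV/JSON.

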