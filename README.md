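# kranz

Analysis toolkit for plastic C3–C4 photosynthesis in allopolyploid plants,
built around single-nucleus transcriptomics and chromatin accessibility of
an amphibious sedge whose culms switch between a C4-like state on land and
a C3-like state under water.

The package is aimed at plant single-cell researchers who already have a
UMI count matrix with cell-type and condition labels, homeolog pair
assignments between the A and B subgenomes, a peak-to-gene link table with
motif-family annotations, promoter sequences, and cross-species similarity
scores — and who want the downstream statistics:

- **Cell QC and expression profiles** — cells with > 500 UMIs and > 200
  detected genes are retained, counts are scaled to 10,000 per cell
  (cp10k), and mean expression Exp(g, cell type, condition) is profiled
  per group.
- **Cellular subgenome dominance.** For each gene, the contrast between
  two cell types (inner mesophyll IMC vs Kranz cell KC) is summarized as
  `D = |Exp_imc − Exp_kc|`, and for a set of homeolog pairs the expression
  weight of subgenome B is

  ```
  Weight_B/AB = Σ D_B / (Σ D_A + Σ D_B)
  ```

  Weights above 0.5 indicate that the B subgenome dominates the cell-type
  contrast (e.g. carboxylation-side C4 families in IMC); below 0.5, the A
  subgenome (e.g. NAD-ME and RuBisCO small subunits in KC).
- **Marker screening** — a self-implemented two-sided Wilcoxon rank-sum
  test (exact for small tie-free samples, tie-corrected normal otherwise)
  with Bonferroni or Benjamini–Hochberg adjustment; genes pass at linear
  fold change > 1.5 (either direction) and adjusted p < 0.05.
- **Cis-regulatory motif-family profiles** — accessible elements linked to
  a gene set are counted per (family × cell type × condition) and each
  group column is normalized to sum to 1; predominant families (maximal
  rate per group) and environment-triggered families (rate ≥ 0.10 in one
  condition, ≤ 0.05 in the other) are called.
- **Promoter scanning** — overlapping IUPAC consensus matches on both
  strands, checked against closed-form background expectations.
- **Orthology and conservation** — reciprocal-best-hit ortholog calling
  with an e-value ceiling (default 1e-10), and the screen for genes
  cell-specialized exclusively in the C4 forms of two species.
- **Ks dating** — divergence time `T = K / 2r` and rate calibration
  `r = K / 2T` from mean synonymous substitution values.

A synthetic-data module generates every input with known ground truth
(planted dominance weights, DE effects, motif rate vectors, motif
occurrences, ortholog pairs), so the whole pipeline is testable without
any sequencing data.

## Worked example

Run the full pipeline on the default synthetic bundle (eight cell types ×
three conditions × 300 cells, ~1232 UMIs/cell, five homeolog families with
40 A/B pairs each):

```
$ kranz run-all --seed 1 --out demo_out
pipeline complete; summary at demo_out/summary.json
  NAD-ME: Weight_B/AB = 0.310 (A-dominant)
  PEPC: Weight_B/AB = 0.564 (B-dominant)
  PPDK: Weight_B/AB = 0.657 (B-dominant)
  RuBisCO-SSU: Weight_B/AB = 0.295 (A-dominant)
  betaCA: Weight_B/AB = 0.632 (B-dominant)
```

The generator plants weights 0.63/0.56/0.67 for the three IMC-enriched
families and 0.31/0.29 for the two KC-enriched families; the pipeline
recovers each weight to ~±0.02 and the dominance direction of every
family. `demo_out/` also contains the expression profile, marker tables
for the configured contrasts, motif frequency matrices whose columns sum
to 1, environment-triggered calls (Homeobox and MYB-related in IMC,
G2-like in KC — present under terrestrial growth, depleted under
submergence), the promoter scan and the recovered ortholog map.

Single stages are available as subcommands (`simulate`, `qc`, `profile`,
`markers`, `dominance`, `motif-freq`, `motif-calls`, `promoter-scan`,
`rbh`, `conserved`, `ks-time`), e.g.

```
$ kranz ks-time --k 0.2 --rate 5e-9
T = 2e+07 years (20 Mya)
```

Library use mirrors the CLI:

```python
from kranz import SimConfig, simulate_all, normalize_cp10k, qc_filter
from kranz import celltype_means, family_weights

bundle = simulate_all(SimConfig(), seed=1)
counts, cells = qc_filter(bundle.counts, bundle.cells)
profile = celltype_means(normalize_cp10k(counts), cells)
weights = family_weights(profile, bundle.homeologs, "IMC", "KC", "terrestrial")
```

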