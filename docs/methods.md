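# Methods

This note documents the models, defaults and numerical conventions behind
`kranz`, in the spirit of the methods documentation of established
scientific Python packages. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study system and scope

The package implements the downstream statistics of a single-nucleus study
of an amphibious allotetraploid sedge whose culms run a C4-like
photosynthetic state on land and a C3-like state under water. Its inputs
are already-processed objects: a genes × cells UMI count matrix with
cell-type/condition/replicate labels, homeolog A/B pair assignments with
enzyme-family labels, a peak-to-gene link table annotated with
transcription-factor motif families, promoter FASTA, and an all-vs-all
cross-species similarity table. Upstream steps — read alignment, UMI
counting, clustering, cell-type annotation, peak calling and peak-to-gene
linking, Ks computation from codon alignments — are out of scope; their
outputs are this package's inputs.

## Normalization and expression profiles

Counts are scaled to 10,000 per cell (cp10k) with a log1p companion
layer. This replaces the variance-stabilizing transform often used in
single-cell toolkits because it is fully specified, deterministic and
sufficient for the two downstream uses: rank-based testing (invariant to
monotone transforms within a cell) and group-mean profiles. Cell QC keeps
cells with strictly more than 500 UMIs and strictly more than 200 detected
genes (both configurable); there is no gene-level filter. Mean expression
`Exp(g, cell type, condition)` is the arithmetic mean of cp10k over the
cells of the group. The scale on which D-values are computed is
configurable (`layer=`); linear cp10k is the default.

## Subgenome dominance

For a contrast of two cell types under one condition, each gene's D-value
is `D = |Exp_a − Exp_b|`. For a homeolog set (by default one enzyme
family), `Weight_B/AB = ΣD_B / (ΣD_A + ΣD_B)`. The statistic is invariant
to a common rescaling of all expression values and maps to `1 − w` when
the A/B labels are swapped; sets whose D-values are all zero raise an
error rather than report 0.5, because a weight of 0.5 would assert balance
without evidence. No uncertainty is attached to the weight; pair counts
and the number of all-zero pairs are reported alongside. An optional
marker-set pre-filter can restrict the computation to genes differentially
expressed between the contrast cell types; it is off by default.

## Marker screening

The test is a self-implemented two-sided Wilcoxon rank-sum. Exact mode
enumerates all C(n+m, n) group labelings (selected automatically for
tie-free data with groups of at most 8); otherwise a normal approximation
with tie correction and a 0.5 continuity correction is used, vectorized
across genes for the screen. The approximation is a large-sample method:
against full permutation on heavily tied data with group sizes ≤ 6 its
absolute deviation stays below 0.5 (documented in the module; the extreme
occurs only when nearly all observations are tied), which is irrelevant at
the tens-to-hundreds of cells per group where the screen operates.

Fold change is computed on linear cp10k group means with an additive
pseudocount of 0.1 to stabilize zero means; "fold change > 1.5" is applied
two-sidedly as `max(fc, 1/fc) > 1.5`, and both directions are reported.
The multiplicity correction is Bonferroni by default, with
Benjamini–Hochberg available; both are self-implemented (BH as the step-up
with enforced monotonicity) and cross-checked against statsmodels in the
test suite. The choice is exposed because the upstream convention the
thresholds come from does not name the method.

## Motif-family profiles and calls

Elements of a link table restricted to a gene set are counted per (family
× group). The default counting unit is the element (`element` mode:
distinct (element_id, family) pairs per group), with `occurrence` mode
counting rows; element-mode counts never exceed occurrence-mode counts.
Frequencies divide each group column by its total; all-zero columns are
flagged degenerate and left at zero, never NaN. Predominant families are
the per-group maxima, reported when the rate is at least `tau_pred = 0.10`
(ties all reported, lexicographic order). Environment-triggered families
satisfy rate ≥ `tau_high = 0.10` in one condition and ≤ `tau_low = 0.05`
in the other. The thresholds are defaults motivated by the clearly
separated exemplar contrasts observed in the study system (≈20% vs 0%,
18% vs 5%, ≥10% vs 0%) and are fully configurable, since no formal rule is
fixed by convention.

## Promoter scanning

IUPAC consensus patterns are slid over every position; overlapping matches
count; `N` in the sequence never matches any symbol. In `both` mode the
reverse complement of the pattern is scanned as well and hits are counted
separately, so a palindrome on its own site yields two hits. This
convention is explicit and oracle-checkable; deduplication is left to the
caller. For a fixed k-mer on i.i.d. uniform ACGT background the expected
hits per promoter are `2(L − k + 1)/4^k`, which the acceptance script
verifies by Monte Carlo.

## Orthology and the conserved-gene screen

Reciprocal best hits: rows above the e-value ceiling (default 1e-10) are
removed; each gene's top-scoring partner is found in both directions;
mutual best pairs are returned. Score ties are broken by the
lexicographically smallest partner id — deterministically, rather than by
dropping tied genes — and logged. The conserved screen formalizes
"cell-specialized exclusively in the C4 form" as the set difference of a
species' C4-condition DE set against its C3-condition DE set within the
same cell class (mesophyll-type or bundle-sheath/Kranz-type), intersected
across species through the ortholog map.

## Ks dating

`T = K/(2r)` and `r = K/(2T)` with K in substitutions per synonymous site
and rates per site per year; helper conversions to Mya are provided. No
default rate is shipped: calibration rates are lineage-specific inputs.

## Synthetic data generator

The generator emulates the study's data shapes: eight culm cell types
(including IMC, OMC, KC) × three conditions (terrestrial, submerged,
submerged + ABA) × 300 cells per group; per-cell library sizes lognormal
around 1232 UMIs (the study's reported per-cell average) with σ = 0.35;
counts gamma-Poisson (negative binomial) with a single shared dispersion
of 0.5. The dispersion and cell-type proportions are not reported by the
study; the defaults are typical of droplet-style UMI data and uniform
group sizes, chosen once. Five homeolog families are planted with 40 A/B
pairs each and true weights 0.63/0.56/0.67 (enriched in IMC) and
0.31/0.29 (enriched in KC), mirroring the study system's reported family
biases; 200 pairs at 300 cells/group match the sizes at which weight
recovery is tested.

Dominance is planted at expectation level. Because cp10k normalizes each
cell, a gene's expected profile value is its mean divided by the group's
column sum, and the mass a family gains in its enriched cell type dilutes
every other gene there. A naive proportional split of each pair's extra
mass therefore biases the recovered weight. The generator instead solves
the A/B split on the normalized scale for a configured contrast
(`contrast_cell_types`, default IMC/KC): with pair baseline b, extra mass
d, and enriched/other column sums s*, s_o, the split solves
`D_B/(D_A + D_B) = w` for `D_X = |Δ_X/s* + b(1/s* − 1/s_o)|`, falling back
to the proportional split when the solution is infeasible or the enriched
cell type is outside the contrast. The remaining bias comes from folding
sampling noise through the absolute value (|·| of a noisy difference is
biased upward when the difference is small); at the default sizes it is
≈0.02–0.03, within the ±0.05 recovery tolerance the acceptance suite
checks.

Motif rate vectors per (gene set × cell type × condition) are sampled
multinomially over 1000 elements per group. The default vectors follow
the study system's contrasts (NAC/C2H2 dominant in IMC, bZIP in KC;
Homeobox, MYB-related and G2-like present under terrestrial growth and
depleted under submergence), with every rate placed at least ~3
multinomial standard deviations from the call thresholds at 1000 elements
so that the planted calls are identifiable by design — a benchmark whose
truth sits exactly on a decision boundary would measure sampling noise,
not the caller. Promoters are i.i.d. uniform ACGT (giving closed-form
background-hit expectations) with planted occurrences at recorded
non-overlapping positions; planted counts are lower bounds for the
scanner, since background hits can add. Ortholog tables give true pairs
the highest mutual scores, with decoys capped strictly below both genes'
true scores and occasional sub-threshold rows exercising the e-value
filter; e-values decrease monotonically with score.

All generators derive independent substreams from one master seed via
fixed labels (`SeedSequence([seed, crc32(label)])`), so identical (config,
seed) gives bit-identical outputs and adding one generator never perturbs
another.

### What the generator does not emulate

Ambient RNA, doublets, batch effects between replicates, gene–gene
correlation, varying cell-type proportions, mappability or peak-calling
artifacts, positional structure in promoters beyond the planted motifs,
and paralogy structure in the ortholog table. Passing tests therefore
demonstrate correctness of the statistics under a clean generative model,
not robustness to those real-data complications.

## Problem sizes and determinism

The test suite and acceptance script run everything at the sizes stated
above (50 simulation replicates for weight recovery, 20 for the null
marker calibration, 10 for motif recovery, 20 full pipeline runs for
end-to-end concordance), which complete in about a minute on one CPU.
Pipeline outputs are pure functions of config + seed: TSVs are written
with fixed column order, sorted rows and fixed float formatting, and the
summary JSON contains no timestamps, so reruns are byte-identical.

## Known limitations

- The weight statistic carries no confidence interval; seed-to-seed spread
  in the acceptance suite is its only calibration here.
- The exact rank-sum mode enumerates combinations and is limited to groups
  of ≤ 8; tied small samples fall back to the approximation, whose
  small-sample error is documented rather than eliminated.
- `conserved_exclusive_sets` takes the four DE sets as given and does not
  harmonize thresholds across studies/species.
- The element-vs-occurrence counting ambiguity for motif rates is resolved
  by a default (element mode), not by evidence; both modes are exposed.
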