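# Methods

## Overview

`comira` implements an integrative tumor-transcriptomics workflow over
paired mRNA/miRNA expression matrices: (1) preprocessing of FPKM values,
(2) a miRNA–mRNA anti-correlation screen, (3) chi-square association of a
dichotomized expression marker with categorical clinical features, (4)
construction of a thresholded gene coexpression network with hub calling,
and (5) Fisher-exact over-representation of each network against gene-set
collections. A synthetic-data generator with planted structure makes every
stage testable without any external download.

## Preprocessing

Input matrices are genes × samples FPKM values. Genes with zero FPKM in
every sample are discarded first; the survivors are transformed as
`log2(FPKM + c)` with pseudocount `c = 0.001` (so a zero maps to
log2(0.001) ≈ −9.966 and stays finite). The order matters and is fixed:
zero-filter, then pseudocount/log. The pseudocount is a uniform parameter,
not per-gene. No further normalization is applied; callers can insert
their own normalizer between the two steps since both are plain
matrix→matrix functions.

Sample alignment restricts two assays to their shared samples in
lexicographic order and refuses to proceed with fewer than three shared
samples, below which a correlation is meaningless.

## miRNA–mRNA screen

The full mRNA × miRNA Pearson matrix is computed as a single blocked
matrix product of row-standardized matrices; this is bit-equivalent (to
~1e−15) to per-pair computation and is tested against `scipy.stats.pearsonr`
as an independent route. Zero-variance profiles produce NaN (undefined)
correlations with a warning and can never pass the screen; they are not
coerced to 0.

Candidate regulations are pairs with r **strictly below −0.5**. The strict
inequality reflects that published pair tables in this style print values
like "−0.50" that are display roundings of values below the cutoff; our
own pair table therefore carries both a 2-decimal display column and a
full-precision column. Output ordering is deterministic: ascending r, then
(miRNA, gene) lexicographic.

Under the null at n = 255, P(r < −0.5) is below 1e−8 (Fisher-z bound), so
any screen hit at cohort scale is overwhelming evidence of dependence;
the acceptance checks verify zero false discoveries over 10^5 null pairs
and ≥ 95% sensitivity for planted ρ = −0.6.

## Coexpression network

The gene–gene adjacency is a power of the Pearson correlation:
`M(i,j) = |r(i,j)|^β` (unsigned, default) or `((1+r)/2)^β` (signed).
β defaults to 1: with a hard edge threshold the exponent does not change
the edge set when thresholding on correlation, and unsigned adjacency is
the default because strong negative coexpression is counted as
interaction too. Edges require `|r| ≥ 0.7` (**inclusive**). Isolated genes
are dropped. "Networks" are the connected components of the thresholded
graph, ordered by decreasing size with ties broken by the smallest
lexicographic member, which makes "network 1/2/3" reproducible. Hub genes
have **strictly more than** 20 neighbors (degree 21 is a hub, 20 is not).

A gene-subset option restricts the network to candidate genes, since at
transcriptome scale (~17,300 genes) the dense correlation matrix is large
and published analyses of this kind typically network a pre-selected
candidate list; the pipeline guards against accidentally requesting a
transcriptome-wide dense matrix (`max_network_genes`, default 4,000).

Edge lists export in Cytoscape-readable SIF (`geneA co geneB`) and TSV
(source, target, r, weight), one line per unordered edge with endpoints
in lexicographic order.

## Clinical association

The marker miRNA is dichotomized at the **median, ties to "low"**: the
split rule is median because the high/low group sizes in published tables
of this kind are near-equal but not forced-equal, which is consistent
with ties-low plus missingness. Overall survival is itself dichotomized
at the median of non-missing survival times (≤ median vs > median).
Missing clinical values are dropped pairwise per feature, never imputed —
this is why row totals legitimately differ across features.

Each feature × group contingency table is tested for independence with
the chi-square test: **Yates continuity correction for 2×2 tables**
(statistic `N·(max(|ad−bc|−N/2, 0))² / (r₁r₂c₁c₂)`), plain Pearson
chi-square with df = (r−1)(c−1) otherwise. The implementation delegates
to `scipy.stats.chi2_contingency`, whose clipped correction matches the
closed form above (asserted in the tests against an explicit oracle). The
corrected test reproduces the published miR-200c clinical p-values from
their printed counts: overall survival 0.0025, distant metastasis 1
(corrected statistic exactly 0), lymphatic invasion 0.10, neoplasm status
0.34, tumor stage 0.886 (4×2, df = 3); the uncorrected test does not
reproduce them, which is what pins down the correction choice. Two
caveats, encoded in `comira.datasets`: the published age table is
internally inconsistent (margin ≠ sum of cells) and is excluded; the
polyps table computes to p = 0.0456 against a printed "0.04", so only the
headline bound p < 0.05 is asserted for it.

The corrected test is conservative: under simulated independence at
clinical-scale margins its rejection rate at α = 0.05 is ≈ 0.035–0.04
(measured, 10,000 tables). Against the exact conditional (permutation)
null it agrees to ≈ 5e−3 on most bundled tables but deviates up to
≈ 2e−2 on margins where the continuity correction over-corrects
(lymphatic invasion) — a known property of Yates' correction, documented
rather than hidden.

## Enrichment

One-sided Fisher exact test per gene set (over-representation is the only
direction that means "enriched"): with universe U, query Q and set S (all
intersected with U), p is the hypergeometric upper tail
P(X ≥ |Q∩S|), computed via `scipy.stats.hypergeom.sf` and verified to
1e−10 against an exact rational tail-sum oracle for universes ≤ 60. A
term is called enriched iff **p < 0.05 (strict) and overlap ≥ 3 genes
(inclusive)**. No multiple-testing correction enters the filter — raw
Fisher p with the dual filter is the convention this workflow follows — 
but a Benjamini–Hochberg q column is emitted for information. The
background universe defaults to the zero-filter survivors and is
configurable; query genes outside the universe are dropped with a
warning. The `%` column is 100·count/|query| over the actual query
length.

## Synthetic data

The generator draws everything Gaussian on the log2 scale and maps to
FPKM by `2^x − 0.001` clipped at 0, so preprocessing inverts it exactly
(gene means ~N(5, 2), within-gene sd 1 keep values far from the clip).
A Gaussian log-scale model was chosen over negative-binomial counts
because every statistic in the pipeline operates on log-transformed
continuous values; count-level realism would add parameters without
exercising any additional code path.

* **Planted pairs**: the target gene is `μ_g + σ·(−|ρ|·z_mir + √(1−ρ²)·ε)`
  with `z_mir` the standardized miRNA profile, giving population
  correlation exactly ρ. Effects are specified as target correlations —
  the quantity the screen thresholds — so recovery criteria are
  self-calibrating.
* **Modules**: members share a latent factor with loading √ρ_m and
  idiosyncratic sd √(1−ρ_m), giving within-module pairwise correlation
  ρ_m.
* **Clinical**: binary features are drawn with group-conditional
  probabilities (an odds ratio between expression groups), survival is
  exponential with per-group medians, and missingness is injected per
  feature.

Defaults are the study conditions used throughout the tests: 255
patients; 1,200 mRNAs × 60 miRNAs (desk scale — the full cohort
dimensions 17,300 × 612 are available via `SimulationConfig.full_scale`
and change only the amount of null noise, not the planted structure);
five planted pairs at ρ = −0.65; modules of 25/15/8 genes at ρ_m = 0.8;
2% all-zero genes. With these defaults the pipeline recovers all five
pairs, exactly three components equal to the planted modules, and hubs
only inside the 25-gene module (the 15- and 8-gene modules cannot exceed
degree 20).

What the generator does **not** emulate: real covariance spectra, batch
effects, count noise, miRNA-family correlation structure, or any
sequence-level target relationship. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated model, not
biological validity on real cohorts.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] after the blocked product to absorb
  float drift; blocked vs per-pair agreement is asserted at 1e−12.
* Zero-variance profiles: NaN correlation + warning (screen), weight 0 +
  warning (adjacency); never silently zero in the screen.
* Degenerate contingency margins (all-zero row/column) are errors, as is
  a chi-square on them.
* An all-constant marker dichotomizes to all-"low" with a warning.
* Ties: expression ties at the median go "low"; survival at the median
  goes "≤ median"; component ordering and all output files have
  deterministic tie-breaks so reruns are byte-identical.

## Problem sizes

Simulated checks use: 1,000 replicate planted pairs and 10^5 null pairs
at n = 255 for screen operating characteristics; 10,000 multinomial 2×2
tables for type-I calibration; 10^5 hypergeometric draws for the
permutation-null comparison; universes ≤ 60 for the exact Fisher oracle
(exhaustive rational arithmetic). These sizes give Monte-Carlo standard
errors well below the asserted margins while keeping the full suite and
the acceptance script each under a minute on one CPU.

## Known limitations

* The chi-square/permutation-null gap of up to ~0.02 near p ≈ 0.05–0.1
  on some margins is inherent to the continuity correction.
* The published clinical tables carry their source's quirks (the
  inconsistent age row; an implausible "31 days" median overall survival,
  reproduced as printed; a truncated polyps p-value).
* Enrichment assumes an unstructured universe; no gene-length or
  expression-level bias correction.
* No survival regression (Cox/Kaplan–Meier); survival enters only via the
  median split, by design.
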