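# Methods

This note records the model, the numerical conventions, the design choices
made where the design was genuinely open, and what the synthetic cohorts do
and do not show.

## The typing model

EMT subtyping here is cohort-wise unsupervised clustering on a fixed marker
panel, not a trained classifier: a cohort is typed as a whole, and there is
no mechanism for assigning a new sample to an existing clustering. The
`EMTTypingModel.fit()` pipeline is

normalize → select panel → cluster (complete linkage, 1 − Pearson r, k=3)
→ score → label → verify,

deterministic given its inputs.

**Marker panel.** 22 epithelial genes (KRT18, KRT19, CDH1, EPCAM, F11R,
ESRP1, ESRP2, CLDN1, CLDN4, CLDN7, S100A14, PRSS8, PRSS22, ST14, ZNF165,
C1ORF116, KDF1, CRB3, ELF3, HNF4A, OVOL1, OVOL2) and 16 mesenchymal genes
(ZEB1, ZEB2, SNAI1, SNAI2, TWIST1, TWIST2, VIM, TGFB1, TGFB2, TGFB3, FN1,
SPARC, COL1A1, COL1A2, MMP2, TCF4). The symbol "EARP1" seen in some
printed versions of this panel matches no human gene and is read as ESRP1
(the ESRP splicing factors are canonical epithelial markers and the
companion gene ESRP2 is on the list); the substitution is shipped in the
gene-alias map and recorded in run metadata whenever the default panel is
used. Users can override the panel from JSON/YAML; sub-panel lists must be
disjoint and non-empty.

**Normalization.** `auto` mode applies log2(x+1) when the matrix maximum
exceeds 50 — z-scored or logged data never reaches that scale, counts and
FPKM always do — then z-scores each gene across samples. Z-scores use the
sample standard deviation (divide by n−1, the R `scale()` convention);
either convention is defensible and the choice only rescales all genes by
one common factor, leaving correlation distances and cluster partitions
unchanged, but it is fixed here for bit-reproducibility. Zero-variance
genes are dropped with a warning (they carry no clustering information and
make the z-score undefined).

**Panel coverage.** Typing proceeds only if at least 60% of each sub-panel
is measured (`min_coverage`, user-adjustable). The method is a panel
consensus; below ~60% the epithelial and mesenchymal axes are
under-determined and the labels would be dominated by a handful of genes.

**Clustering.** Distance between samples is 1 minus the Pearson
correlation of their panel z-score vectors (range [0, 2]); agglomeration
is complete linkage (scipy); the tree is cut into exactly k=3 clusters.
k is fixed at 3 because the method is defined as a three-state typing; no
data-driven k selection is attempted. Whether to cut the dendrogram at
k=3 or delineate clusters visually on a heatmap is a genuinely open point
in the method's description; cutting at k=3 is the reproducible choice.
Samples whose panel vector has zero variance have no defined correlation
and are reported by name as errors.

**Labeling.** Clusters are ranked by mean Δ = epithelial − mesenchymal
score: highest → EPC, middle → HPC, lowest → MPC. Ties break toward the
larger mean epithelial score, then the smaller cluster index, so the
cluster→subtype map is always a bijection.

**Verification.** The verification axis is a normalized mean-rank
enrichment score computed per sample: rank all G
measured genes within a sample (ascending, ties averaged); the score for a
set S is (mean rank of S − (G+1)/2) / ((G−1)/2), which lies in [−1, 1] and
depends on expression only through within-sample ranks — hence it is
invariant under any strictly monotone transform and insensitive to
per-sample normalization. The epithelial panel serves as the epithelial
verification set and the mesenchymal panel as the stromal set. Samples are
tertiled on each score (tertiles by sample count, ties to the lower
tertile, deterministic); EPC is concordant with (epi high ∧ stromal low),
MPC with (epi low ∧ stromal high), HPC with any non-extreme pattern.
Verification is a diagnostic: discordant samples keep their cluster label
and are flagged. With fewer than 3 samples tertiles are undefined and the
report says so.

## Downstream statistics

* **Association tests** are plain Pearson χ² with no continuity correction
  at any table size; expected counts are row·col/total and the p-value is
  the χ² upper tail (regularized upper incomplete gamma, via scipy).
  Zero-margin rows/columns are dropped first; a cell with expected count
  < 5 raises a flag but not an error. "Missing"/"Uncertain" categories are
  ordinary rows by default (`include_missing=True`) — that is how the
  published clinical tables tally, and their printed statistics are only
  reproducible with those rows included.
* **Percentages** print at 1 dp using round-half-to-even, the convention
  (R's `round`) under which the published percentages — including
  26/32 → 81.2 — are reproducible.
* **Mann–Whitney** is two-sided, exact when both groups are ≤ 8 untied
  observations and tie-corrected normal otherwise; the U statistic counts
  first-group wins.
* **Correlation blocks** summarize pairwise Pearson correlations of panel
  genes across samples as within-epithelial (E&E), within-mesenchymal
  (M&M) and cross-panel (E&M) means, diagonals excluded. In normal tissue
  E&M is strongly negative (the two programs are mutually exclusive);
  joint upregulation in tumors moves it toward zero — the decoupling
  signature.
* **Survival** is the standard product-limit estimator and the k-group
  log-rank test with df = k−1 (lifelines). Deaths are processed before
  censorings at tied times; censored subjects at an event time count as at
  risk for that time. Greenwood bands are omitted — no reported quantity
  uses them.

## The synthetic cohorts

The simulator generates, at the normalized-expression level, cohorts with
the structure the typing method targets. Gaussian expression (not
negative-binomial counts) is deliberate: the classifier consumes
normalized values, and the Gaussian model keeps every recovery expectation
closed-form. A count-level mode is out of scope.

* **Three latent states.** Panel genes carry fixed strength loadings
  w_g ~ U(0.7, 1.3). The epithelial state expresses epithelial markers at
  +a·w_g and mesenchymal markers at −a·w_g; the mesenchymal state is the
  mirror image; so the two sub-panels are anti-coupled in normal tissue.
  The hybrid state is a mosaic partial-EMT program: each marker is
  retained (+a·w_g) or lost (−a·w_g) with equal probability, fixed per
  simulation. Its panel-average scores are therefore intermediate (≈ 0,
  between +a and −a) while the state keeps full per-gene amplitude and its
  own direction in marker space. The full amplitude matters: under
  per-sample Pearson centering, any block-constant state pattern collapses
  onto the single epithelial-vs-mesenchymal contrast axis, and a
  sub-amplitude hybrid program leaves the hybrid centroid close to that
  axis (prevalence centering pushes it toward the mesenchymal pole), so
  three-state recovery becomes erratic. With the mosaic program the three
  state directions are mutually distinguishable at any noise level, and
  recovery degrades gracefully with σ.
* **Defaults** (`SimulationParams`): separation a = 1.0 and noise
  σ = 0.5 — i.e. adjacent states are 2 noise-sd apart; n = 300 samples;
  subtype prevalence (0.60, 0.10, 0.30) in normal tissue and
  (0.35, 0.43, 0.22) in tumors, echoing the epithelial-dominant normal /
  hybrid-dominant tumor shift the method is meant to expose; 200
  background genes.
* **Tumor decoupling.** Tumor samples add one shared offset
  u ~ N(b=1.0, τ=0.8) to *both* sub-panels: markers of both programs are
  jointly upregulated, and the shared per-sample variability injects
  positive cross-panel covariance that cancels much of the anti-coupling —
  reproducing the normal-vs-tumor E&M contrast. The offset is constant
  across genes within a sample, so it does not perturb the correlation
  distances used for clustering.
* **Paired designs** draw the normal state from the normal prevalence and
  the tumor state from a 3×3 row-stochastic transition matrix (default
  EPC row (0.2, 0.5, 0.3): most epithelial normal tissue converts to
  hybrid or mesenchymal tumors).
* **Survival** is exponential per subtype with default monthly hazards
  (0.00876, 0.01012, 0.01595), chosen to give roughly 59% / 55% / 38%
  survival at 60 months, with uniform censoring on [0, 120] months.
* **Cell-count tables** are per-sample multinomials (1000 cells) over
  {epithelial, fibroblast, endothelial, immune} with epithelial proportion
  0.45 in normal vs 0.20 in tumor samples (26 tumor / 10 normal samples by
  default, the shape of a typical single-cell gastric atlas).

All generators are pure functions of (params, seed).

**What passing tests show — and don't.** The simulator demonstrates
internal consistency: the pipeline recovers planted states, transition
matrices, prevalences and survival orderings under the stated conditions.
It does not emulate real-data pathologies — no batch effects, no
library-size or GC biases, no gene–gene covariance beyond the panel
blocks, no dropout — so recovery here says nothing about robustness to
those. Published cohort-scale quantities that require the original
accessions (per-cohort subtype counts, 5-year survival rates, single-cell
proportions, differential-expression lists) are out of scope and are not
claimed.

## Numerical conventions and degenerate inputs

* Correlation distances are clamped at 0 from below (floating-point can
  produce −1e-17 for near-identical samples); complete-linkage heights are
  then monotone.
* Duplicate gene rows (after symbol canonicalization) collapse by mean —
  deterministic and order-independent; duplicate sample ids are errors.
* Empty expression files, non-numeric cells (reported by row/column),
  missing values, negative values under log, metadata event flags outside
  {0, 1} and unknown tissue labels are all hard errors.
* E/M ratios with an empty EMT compartment are NaN (flagged), never 0.
  The CDH1/VIM ratio rule maps vim = 0 ∧ cdh1 > 0 to EPC (the r → ∞ limit)
  and both-zero to "indeterminate" rather than guessing.
* Problem sizes in tests and the acceptance script (n = 300 cohorts,
  500 pairs, 1000 log-rank null replicates) were chosen as the smallest
  sizes at which the binomial/χ² tolerances of the checks are informative.

## Known limitations

* Cohort-wise clustering means subtype labels are only comparable within
  one run; adding samples can relabel a cohort.
* The enrichment-score verification is a rank heuristic, not a calibrated
  deconvolution; its tertile concordance is a sanity diagnostic.
* The simulator's Gaussian panel model cannot probe count-level noise or
  normalization pipelines upstream of the typing.
* No batch correction or cross-cohort merging: cohorts are clustered
  individually by design.
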