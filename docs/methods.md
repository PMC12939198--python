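# Methods

This note documents the models, conventions and numerical choices behind
`trmspatial`, in the spirit of the model documentation of simulation and
statistics packages: what is computed, under which assumptions, which
defaults matter, and what the synthetic tests do and do not establish.

## Phenotype gating

Cells are labelled by **ordered hierarchical gating** of mean fluorescence
intensities. Positivity is `intensity >= threshold` (a cell exactly at the
cut counts as positive — a convention, documented here because some
implementations use a strict inequality). The default hierarchy evaluates
PanCK first, so tumor cells can never receive an immune label, then splits
CD8⁺ cells by CD103 and PD-1:

| order | label | requires | excludes |
|---|---|---|---|
| 1 | `tumor` | PanCK⁺ | — |
| 2 | `exhausted_trm` | CD8⁺ CD103⁺ PD-1⁺ | PanCK |
| 3 | `naive_trm` | CD8⁺ CD103⁺ | PanCK, PD-1 |
| 4 | `pd1_cd8` | CD8⁺ PD-1⁺ | PanCK, CD103 |
| 5 | `cd8` | CD8⁺ | PanCK, CD103, PD-1 |
| — | `other` | anything else | |

Whether a panel's analysis treats, say, CD69⁺CD8⁺ as its own class is a
reporting choice, not a biological fact; the gater therefore emits the
exclusive label *plus* boolean `<marker>_pos` columns, and
`select_phenotype` resolves aggregate names (`trm`, `cd8_any`, `cd69_cd8`,
`tcf1_cd8`, `pd1_cd8_any`) from them, so both exclusive and overlapping
readings are recoverable from one table.

Thresholds are **required inputs** — on real panels they are calibrated
against negative controls, and no defensible universal default exists.
`estimate_thresholds` offers a data-driven starting point: a two-component
Gaussian mixture on log intensities, cut at the midpoint of the component
means. Gating is deterministic, permutation-equivariant over rows, and
covariant under joint scaling of intensities and thresholds (all tested).

## Tumor region and compartments

Image-based workflows segment tumor vs stroma at the pixel level. From
point data this package uses a **disk-union proxy**: the tumor region is
the union of disks of `dilation_radius_um` (default 15 µm, about one cell
diameter beyond the membrane) centred on tumor cells; connected components
supported by fewer than `min_component` tumor cells (default 5) are
discarded as debris. Disks are polygonized with 64 segments, keeping the
area error below ~0.2%. The proxy is monotone in its radius (a larger
radius never shrinks the region) and has few degenerate cases, which is
why it was chosen over alpha-shapes; it is a *substitution* for image
segmentation, flagged for sensitivity analysis rather than asserted
equivalent.

Compartment assignment is inclusive on the boundary (on-boundary =
`intra_tumor`), and every cell receives a signed Euclidean distance to the
region boundary, negative inside. With no tumor cells the region is empty,
all cells are stromal, and the distance is a `+inf` sentinel — downstream
band profiles then report the documented empty value rather than failing.

## Spatial statistics

All coordinates are in µm; the default simulation window is 1000×1000 µm =
1 mm², so densities in cells/mm² equal raw counts there. Orientation is
fixed: **tumor cells are the reference type, the immune phenotype the
target** — G-cross is asymmetric and the package's reading is "probability
of an immune cell within r of a tumor cell".

* `density_and_fraction`: count/area per compartment; the fraction of the
  CD8⁺ population is undefined (NaN) where no CD8⁺ cells exist, rather
  than 0 — absence of the denominator is not evidence of absence of the
  subset.
* `infiltration_profile`: stromal cells of the phenotype with boundary
  distance in (0, 100] µm, binned into ten right-closed 10-µm bands,
  normalized to the zone total. The band width must divide the maximum
  distance exactly.
* `interaction_count`: per-tumor-cell count of target cells within 10 µm,
  computed with a k-d tree but contractually identical to the all-pairs
  result; radii are closed balls (d ≤ r) everywhere in the package.
* `gcross`: the uncorrected empirical CDF of reference-to-nearest-target
  distances on a uniform grid over [0, 30] µm with 0.5-µm spacing
  (n_r = 61). The AUC uses the trapezoid rule; the score is AUC/r_max so
  scores are comparable across r_max choices. A reduced-sample border
  correction (drop reference cells nearer than r_max to the window edge)
  is available via a flag and off by default: the uncorrected estimator
  matches the plain "probability within radius" reading, and its CSR bias
  is negligible for r_max = 30 µm on mm-scale cores. When the target
  phenotype is absent the score is **0, not missing** — a sample genuinely
  devoid of the subset is maximally non-proximal, and treating it as
  missing would silently drop the most informative samples.
* `sample_qc`: a sample enters spatial scoring only if tumor + CD8⁺ cells
  within tumor tissue reach 1500 (inclusive); failures are logged with the
  count, and the pipeline records them in `exclusions.csv`.
* G-cross within the intra-tumor compartment only vs the whole core is an
  open protocol choice; the whole core is the default here (all cells are
  candidates as targets), and callers can pre-filter the table to change
  that.

Survival dichotomization uses a **median split** by default (an explicit
numeric cutpoint is accepted; optimal-cutpoint searches are deliberately
not offered because they inflate type-I error). Ties go to the low group.

## Survival models

Backed by `lifelines` and `scipy.stats` behind the package's own
interfaces; hand-worked oracles in the tests pin the numerics regardless
of backend. Unpaired comparisons use the Wilcoxon rank-sum test — exact
enumeration for small tie-free samples, tie-corrected normal approximation
otherwise — reported as a standardized (antisymmetric) statistic; paired
comparisons use the paired t-test, where all-zero differences return
(0, 1) and constant non-zero differences raise a degenerate-variance
error. Cox models use Efron tie handling; age group (<65/≥65), sex, and
TNM stage enter as adjustment covariates, stage ordinally (I–IV → 1–4) by
default with a dummy-coding option. Non-convergence and separation
produce an explicit failure result, never silent numbers. Fewer than 10
events or a constant covariate is rejected up front.

## The synthetic cohort generator

The generator emulates the *structure* of a TMA-based mIHC study so that
every downstream contract is testable with known truth.

* **Tumor islets**: a Thomas (Neyman–Scott) cluster process with a fixed
  number of parents (default 8) uniform on the window, Poisson(250)
  Gaussian offspring per parent with 60 µm spread, restricted to the
  window (offspring falling outside are discarded). Fixing the parent
  count rather than drawing it Poisson trades a little realism for
  reproducible per-sample cell budgets; defaults are sized so a default
  sample comfortably passes the 1500-cell QC rule (~2000 tumor cells/mm²).
* **Immune placement**: each immune cell of phenotype p is, with
  probability ρ_p, *attracted*: placed at Exponential(mean 15 µm) distance
  and uniform angle from a uniformly chosen tumor cell, redrawn while
  outside the window; otherwise uniform. A single-parameter monotone
  kernel is all that is needed: the mean proximity score is strictly
  increasing in ρ (tested on the grid {0, .25, .5, .75, 1}).
* **Intensities**: per marker, a two-component log-normal mixture —
  log-intensity Normal(μ_neg or μ_pos, σ) with defaults μ_neg = 2.0,
  μ_pos = 4.4, σ = 0.4 — **truncated at ±2σ**. Truncation is a deliberate
  design choice: it models the clean bimodality of a well-unmixed panel
  and makes midpoint gating *exactly* correct whenever the separation
  μ_pos − μ_neg ≥ 4σ (the default separation is 6σ). With unbounded
  Gaussian tails no finite separation could guarantee exact label
  recovery, so perfect-recovery tests would be flaky by construction.
  CD69/TCF-1 positivity rides on CD8-lineage cells as independent
  Bernoulli marks (30%/20%) without affecting the primary label.
* **Survival linkage**: per patient, per-phenotype attraction strengths
  ρ ~ U(0,1) are drawn independently; the designated spatial covariate
  (default: the PD-1⁻ T_RM proximity score, gated with the generator's own
  midpoint thresholds) is standardized across the cohort; event times are
  Exponential with rate `baseline_hazard · exp(β·z)` (defaults 0.05/month,
  β = log 0.5) and censoring is Uniform(0, 60 months), giving ~65–70%
  events. Age/sex/stage are drawn independently of the hazard with the
  frequencies of a typical resection cohort, so they act as pure noise
  covariates in recovery experiments.
* **RNG**: one root seed; each sample uses `default_rng([seed, index])`
  so enlarging a cohort never reshuffles earlier samples; cohort-level
  draws use a fixed separate stream. Identical configs give byte-identical
  tables.
* **Expression matrices**: negative-binomial counts (mean 2, dispersion 5)
  over gene names that include an `MT-` set and HBA1/HBA2/HBB, with
  designated cells forced to violate exactly one named QC rule (feature
  count just past the bound; mito/erythroid share scaled to twice its
  threshold) while all other cells are adjusted to pass every rule with
  margin — so the QC filter's retained set is known by construction.
  "Features" means genes with count > 0; the erythroid gene list is
  configurable (hemoglobin defaults), since panels differ.

### What the simulator does *not* capture

Real mIHC data have segmentation errors, spillover between adjacent cells,
spatially varying staining intensity, holes and folds in tissue, necrotic
regions, and cores of irregular shape. Passing tests therefore establish
that the *statistical machinery* is correct (estimators match brute-force
and closed-form oracles; effects injected into the generative model are
recovered at the right rates), not that any particular biological effect
size from patient material will be reproduced. Published cohort-specific
numbers (hazard ratios, log-rank p-values, subset percentages) require the
original data and are out of scope; the package instead demonstrates
recovery of *known* parameters on synthetic cohorts.

## Problem sizes in the shipped checks

The test-suite's recovery experiments use compact cores (~120 tumor plus
~120 immune cells) and cohorts of 500 patients over 50 replicate seeds;
the Cox recovery being exercised depends on the score→hazard linkage, not
on per-core point density, so compact cores are a pure efficiency choice.
The CSR calibration uses 25 interior reference points on a 2000×2000 µm
window, 200 Poisson replicates at λ ∈ {1e-4, 5e-4} µm⁻², comparing mean
Ĝ(r) with 1 − exp(−λπr²) at r ∈ {5, 10, 20, 30} µm within three standard
errors. `scripts/acceptance.py` runs a 61-patient end-to-end cohort (the
size of a typical dual-core TMA study after exclusions) plus ten 300-patient
recovery cohorts.

## Known limitations

* The disk-union region is a proxy for image-based segmentation; boundary
  distances within ~1 polygon segment (<0.2 µm) of the true disk boundary
  inherit polygonization error.
* The uncorrected Ĝ is negatively biased for reference cells within r_max
  of the tissue edge; use the border-correction flag when cores are small
  relative to r_max.
* Cox models assume proportional hazards; no diagnostics are provided.
* No multiple-testing correction is applied across features by default
  (unadjusted p-values are the primary report); `adjust_pvalues` and the
  pipeline's `adjust_pvalues` flag apply Benjamini–Hochberg when asked.
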