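# trmspatial

Spatial proximity analysis of tissue-resident CD8⁺ T cells in multiplex
immunofluorescence (mIHC) cell tables, with survival association and a
fully synthetic, ground-truth-known cohort simulator.

## The problem

In solid tumors such as cholangiocarcinoma, the prognostic value of
CD103⁺CD8⁺ tissue-resident memory T cells (T_RM) depends not only on how
many of them infiltrate a sample but on *where they sit relative to tumor
cells*, and on their functional state (PD-1⁻ "naïve" vs PD-1⁺ "exhausted"
resident subsets). Quantifying that spatial relationship from segmented
mIHC images — per-cell coordinates plus mean fluorescence intensities for
PanCK, CD8, CD103, PD-1, CD69 and TCF-1 — takes a chain of steps that this
package implements as a tested, reusable pipeline:

1. **Phenotype gating** — hierarchical thresholding of marker intensities
   (PanCK⁺ tumor first, then the CD8/CD103/PD-1 splits), emitting an
   exclusive label plus per-marker positivity columns.
2. **Compartments** — the tumor region as the union of 15-µm disks around
   PanCK⁺ cells; each cell gets an intra-tumor/stroma label and a signed
   distance to the tumor boundary.
3. **Spatial statistics** — densities (cells/mm²), fractions of the CD8⁺
   population, 10-µm distance-band infiltration profiles out to 100 µm,
   counts of immune cells within 10 µm of each tumor cell, mean
   tumor-to-nearest-T-cell distances, and the G-cross function.
4. **Survival** — Kaplan–Meier curves with log-rank tests on median splits,
   and Cox proportional-hazards models adjusted for age, sex and TNM stage.

The core statistic is the **cross-type nearest-neighbour distance
distribution** ("G-cross"): with tumor cells as the reference type and an
immune phenotype as the target,

```
Ĝ(r) = (1/n_tumor) · #{ tumor cells whose nearest target cell lies within r }
```

its area under the curve over r ∈ [0, 30] µm, normalized by 30 µm, is the
**proximity score** in [0, 1]. Under complete spatial randomness of the
target at intensity λ, G(r) = 1 − exp(−λπr²), which the test-suite uses as
a closed-form calibration oracle.

Because real patient data cannot ship with the code, a simulator generates
mIHC-like samples with known truth: tumor islets as a Thomas cluster
process, immune cells attracted to tumor with a tunable probability ρ,
bimodal (truncated log-normal) marker intensities, and exponential
survival times whose hazard is exp(β·z) with z the standardized proximity
score — so gating accuracy, score monotonicity in ρ, and Cox recovery of β
are all checkable end to end.

## Worked example

```python
from trmspatial import (SimulationConfig, simulate_sample, gate_phenotypes,
                        TumorRegionBuilder, gcross, sample_qc, mean_nearest_distance)

cfg = SimulationConfig(seed=1)                      # 1 mm^2 core, 8 tumor islets
cells, truth = simulate_sample(cfg, sample_index=0)
gated = gate_phenotypes(cells, cfg.gating_config())
builder = TumorRegionBuilder(dilation_radius_um=15, min_component=5).fit(gated)
comp = builder.transform(gated)

print(f"{len(comp)} cells, {(comp.phenotype == 'tumor').sum()} tumor, "
      f"tumor region = {builder.region_.area / 1e6:.3f} mm^2")
print("sample QC (>=1500 combined tumor+CD8 in tumor tissue):", sample_qc(comp))
curve = gcross(comp, "naive_trm")                   # PD-1- resident subset
print(f"G-cross AUC(0-30 um) = {curve.auc:.2f} um, proximity score = {curve.score:.3f}")
print(f"mean tumor-to-naive-TRM distance = {mean_nearest_distance(comp, 'naive_trm'):.1f} um")
```

prints

```
2673 cells, 1823 tumor, tumor region = 0.321 mm^2
sample QC (>=1500 combined tumor+CD8 in tumor tissue): True
G-cross AUC(0-30 um) = 5.49 um, proximity score = 0.183
mean tumor-to-naive-TRM distance = 33.9 um
```

i.e. this simulated core passes the ≥1500-cell QC rule, and 18.3% of the
possible area under the 0–30 µm G-cross curve is realized — a moderately
infiltrated sample (a score near 1 means almost every tumor cell has a
PD-1⁻ T_RM within a few microns; near 0, the subset is absent or distant).

The same stages are available from the shell:

```
trmspatial simulate --seed 1 --out-dir sim
trmspatial run --cells sim/cells --cohort sim/cohort.csv \
               --gating-config sim/gating.yaml --out-dir run
trmspatial report --run-dir run
```

Single-cell RNA helpers (`qc_filter` with the 200–3000 feature, <10%
mitochondrial, <1% erythroid rules; `signature_score` as mean normalized
expression of a gene set) support the expression side of the analysis.

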