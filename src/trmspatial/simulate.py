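"""Synthetic mIHC-like cohort generator with known ground truth.

Emulates the study material downstream stages consume: per-cell tables
(coordinates + marker intensities) whose tumor cells form clustered
islets, immune subsets with a tunable attraction to the tumor, bimodal
marker intensities consistent with each cell's true phenotype, matched
proportional-hazards survival outcomes whose hazard depends on a chosen
spatial proximity score, and negative-binomial expression matrices with
designated QC violators.

Reproducibility: one root seed; each sample draws from an independent
stream keyed by (seed, sample_index), so enlarging a cohort never
reshuffles earlier samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .config import (
    MARKERS,
    PHENOTYPE_PROFILES,
    ConfigurationError,
    QCThresholds,
    SimulationConfig,
)
from .phenotyping import gate_phenotypes
from .spatial import gcross

_COHORT_STREAM = 0x5EED  # fixed offset separating cohort-level draws from per-sample streams


@dataclass
class GroundTruth:
    """Per-cell true labels (and positivity) plus per-patient hazard truth."""

    cell_truth: pd.DataFrame | None = None
    patient_truth: pd.DataFrame | None = None


def _truncated_normal(rng: np.random.Generator, n: int, trunc_sd: float) -> np.ndarray:
    """Standard normal draws conditioned on |z| <= trunc_sd (vectorized rejection)."""
    out = rng.standard_normal(n)
    bad = np.abs(out) > trunc_sd
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > trunc_sd
    return out


def _sample_rng(config: SimulationConfig, sample_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(sample_index)])


def _simulate_tumor(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = config.window
    if config.n_islets == 0:
        return np.empty((0, 2))
    parents = rng.uniform([0, 0], [w, h], size=(config.n_islets, 2))
    counts = rng.poisson(config.tumor_per_islet, size=config.n_islets)
    pts = []
    for p, n in zip(parents, counts):
        if n:
            pts.append(p + rng.normal(0.0, config.islet_sd_um, size=(n, 2)))
    if not pts:
        return np.empty((0, 2))
    xy = np.concatenate(pts)
    inside = (xy[:, 0] >= 0) & (xy[:, 0] <= w) & (xy[:, 1] >= 0) & (xy[:, 1] <= h)
    return xy[inside]


def _place_immune(
    n: int, rho: float, tumor_xy: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    w, h = config.window
    xy = rng.uniform([0, 0], [w, h], size=(n, 2))
    if n == 0 or len(tumor_xy) == 0:
        return xy
    attracted = np.flatnonzero(rng.random(n) < rho)
    todo = attracted
    for _ in range(1000):
        if len(todo) == 0:
            break
        anchors = tumor_xy[rng.integers(0, len(tumor_xy), size=len(todo))]
        d = rng.exponential(config.attract_scale_um, size=len(todo))
        theta = rng.uniform(0, 2 * np.pi, size=len(todo))
        cand = anchors + np.column_stack([d * np.cos(theta), d * np.sin(theta)])
        ok = (cand[:, 0] >= 0) & (cand[:, 0] <= w) & (cand[:, 1] >= 0) & (cand[:, 1] <= h)
        xy[todo[ok]] = cand[ok]
        todo = todo[~ok]  # redraw out-of-window placements
    return xy


def _draw_intensities(
    labels: np.ndarray, extra_pos: dict[str, np.ndarray], config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Intensity columns and true-positivity masks, marker by marker in fixed order."""
    n = len(labels)
    intensities: dict[str, np.ndarray] = {}
    positivity: dict[str, np.ndarray] = {}
    for m in MARKERS:
        mm = config.intensity_model[m]
        pos = np.array([m in PHENOTYPE_PROFILES[lab] for lab in labels])
        if m in extra_pos:
            pos |= extra_pos[m]
        z = _truncated_normal(rng, n, mm.trunc_sd)
        logi = np.where(pos, mm.mu_pos, mm.mu_neg) + mm.sigma * z
        intensities[m] = np.exp(logi)
        positivity[m] = pos
    return intensities, positivity


def simulate_sample(config: SimulationConfig, sample_index: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one mIHC-like sample (cell table + ground truth).

    Deterministic in (config.seed, sample_index); identical inputs yield
    byte-identical tables.
    """
    if config.n_islets * config.tumor_per_islet < 1:
        raise ConfigurationError("expected tumor cell count n_islets * tumor_per_islet must be >= 1")
    rng = _sample_rng(config, sample_index)
    tumor_xy = _simulate_tumor(config, rng)
    labels = ["tumor"] * len(tumor_xy)
    coords = [tumor_xy]
    for phen in sorted(config.immune_counts):
        n = config.immune_counts[phen]
        coords.append(_place_immune(n, config.rho_for(phen), tumor_xy, config, rng))
        labels.extend([phen] * n)
    xy = np.concatenate(coords) if coords else np.empty((0, 2))
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    # CD69/TCF-1 positivity rides on CD8-lineage cells without affecting the label
    cd8_lineage = np.array([("CD8" in PHENOTYPE_PROFILES[lab]) for lab in labels])
    extra = {
        "CD69": cd8_lineage & (rng.random(n) < config.p_cd69),
        "TCF1": cd8_lineage & (rng.random(n) < config.p_tcf1),
    }
    intensities, positivity = _draw_intensities(labels, extra, config, rng)
    sample_id = f"S{sample_index:04d}"
    cells = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": [f"{sample_id}_c{i}" for i in range(n)],
            "x_um": xy[:, 0] if n else np.array([], dtype=float),
            "y_um": xy[:, 1] if n else np.array([], dtype=float),
            **intensities,
            "true_label": labels,
        }
    )
    truth = pd.DataFrame({"cell_id": cells["cell_id"], "true_label": labels})
    for m in MARKERS:
        truth[f"true_{m}_pos"] = positivity[m]
    return cells, GroundTruth(cell_truth=truth)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Simulate a cohort: per-patient samples, clinical table, ground truth.

    Each patient draws independent per-phenotype attraction strengths
    rho ~ U(0,1); the spatial covariates named in ``config.survival.beta``
    (``"<phenotype>_gcross_score"``) are computed from the realized pattern
    with known-truth midpoint gating, standardized across the cohort, and
    drive exponential event times under a proportional-hazards model.
    Age/sex/stage covariates are drawn independently of the hazard.
    """
    surv = config.survival
    for feat in surv.beta:
        if not feat.endswith("_gcross_score"):
            raise ConfigurationError(
                f"survival beta key {feat!r} must be of the form '<phenotype>_gcross_score'"
            )
        phen = feat[: -len("_gcross_score")]
        if phen not in config.immune_counts:
            raise ConfigurationError(f"survival covariate phenotype {phen!r} not simulated")
    rng = np.random.default_rng([int(config.seed), _COHORT_STREAM])
    gate_cfg = config.gating_config()
    phenos = sorted(config.immune_counts)
    tables, cell_truths, scores = [], [], []
    for i in range(config.n_patients):
        rho_i = {p: float(r) for p, r in zip(phenos, rng.uniform(0, 1, size=len(phenos)))}
        cfg_i = replace(config, proximity_rho=rho_i)
        cells, gt = simulate_sample(cfg_i, sample_index=i)
        gated = gate_phenotypes(cells, gate_cfg)
        scores.append(
            {f"{p}_gcross_score": gcross(gated, p).score for p in phenos if p != "other"}
        )
        tables.append(cells)
        cell_truths.append(gt.cell_truth)
    feats = pd.DataFrame(scores)
    z = pd.DataFrame(index=feats.index)
    for feat in surv.beta:
        col = feats[feat]
        sd = col.std(ddof=0)
        z[feat + "_z"] = (col - col.mean()) / sd if sd > 0 else 0.0
    eta = np.zeros(config.n_patients)
    for feat, beta in surv.beta.items():
        eta += beta * z[feat + "_z"].to_numpy()
    rate = surv.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, surv.censor_time_max, size=config.n_patients)
    event = (t_event <= t_censor).astype(int)
    os_time = np.maximum(np.minimum(t_event, t_censor), 1e-9)
    age_group = np.where(rng.random(config.n_patients) < 0.4, ">=65", "<65")
    sex = np.where(rng.random(config.n_patients) < 0.57, "M", "F")
    stage = rng.choice(["I", "II", "III", "IV"], size=config.n_patients, p=[16 / 67, 23 / 67, 13 / 67, 15 / 67])
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(config.n_patients)],
            "sample_id": [t["sample_id"].iloc[0] if len(t) else f"S{i:04d}" for i, t in enumerate(tables)],
            "os_time": os_time,
            "event": event,
            "age_group": age_group,
            "sex": sex,
            "tnm_stage": stage,
        }
    )
    cohort = pd.concat([cohort, feats, z], axis=1)
    patient_truth = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "linear_predictor": eta,
            **{f + "_z": z[f + "_z"] for f in surv.beta},
        }
    )
    truth = GroundTruth(
        cell_truth=pd.concat(cell_truths, ignore_index=True), patient_truth=patient_truth
    )
    return tables, cohort, truth


_QC_RULES = ("features_low", "features_high", "mito", "erythroid")


def simulate_expression(
    n_cells: int,
    n_genes: int,
    qc_violation_spec: dict | None = None,
    seed: int = 0,
    thresholds: QCThresholds = QCThresholds(),
    mean_count: float = 2.0,
    nb_dispersion: float = 5.0,
) -> tuple[sparse.csr_matrix, list[str], list[str], pd.DataFrame]:
    """Negative-binomial expression counts with designated QC violators.

    ``qc_violation_spec`` maps a rule name (``features_low``,
    ``features_high``, ``mito``, ``erythroid``) to an iterable of cell
    indices forced to violate exactly that rule; all other cells are
    adjusted to pass every rule comfortably. Gene names include an ``MT-``
    set and hemoglobin genes so the fractions are computable. Returns
    (matrix genes x cells, gene names, cell names, per-cell truth flags).
    """
    if n_cells < 0 or n_genes < 0:
        raise ConfigurationError("n_cells and n_genes must be >= 0")
    spec = {k: sorted(set(v)) for k, v in (qc_violation_spec or {}).items()}
    for rule in spec:
        if rule not in _QC_RULES:
            raise ConfigurationError(f"unknown QC violation rule {rule!r}; known: {_QC_RULES}")
    for rule, idx in spec.items():
        if idx and (min(idx) < 0 or max(idx) >= n_cells):
            raise ConfigurationError(f"violation indices for {rule!r} out of range")
    n_mito = min(13, max(0, n_genes - 3))
    mito_genes = [f"MT-G{i}" for i in range(n_mito)]
    ery_genes = ["HBA1", "HBA2", "HBB"][: max(0, n_genes - n_mito)]
    other_genes = [f"GENE{i}" for i in range(n_genes - n_mito - len(ery_genes))]
    genes = mito_genes + ery_genes + other_genes
    cells = [f"cell{i}" for i in range(n_cells)]
    rng = np.random.default_rng(seed)
    p = nb_dispersion / (nb_dispersion + mean_count)
    m = rng.negative_binomial(nb_dispersion, p, size=(n_genes, n_cells)).astype(np.int64)
    mito_rows = np.arange(len(mito_genes))
    ery_rows = np.arange(len(mito_genes), len(mito_genes) + len(ery_genes))
    flags = {r: np.zeros(n_cells, dtype=bool) for r in _QC_RULES}
    for rule, idx in spec.items():
        flags[rule][idx] = True
    if spec.get("features_high") and n_genes <= thresholds.max_features:
        raise ConfigurationError("features_high violators need n_genes > max_features")
    target_lo = min(thresholds.min_features + 20, n_genes)
    target_hi = max(thresholds.min_features, thresholds.max_features - 2)
    for j in range(n_cells):
        col = m[:, j]
        # feature-count compliance (or designed violation); fractions handled after
        _force_feature_count(
            col,
            thresholds.max_features + 1 if flags["features_high"][j]
            else thresholds.min_features - 1 if flags["features_low"][j]
            else int(np.clip((col > 0).sum(), target_lo, target_hi)),
            rng,
        )
        # cells not designated as fraction violators carry zero mito/erythroid
        # UMIs (their counts are swapped onto background genes, preserving the
        # feature count); designated violators get the group scaled up instead
        if not flags["mito"][j]:
            _swap_out(col, mito_rows, ery_rows, rng)
        if not flags["erythroid"][j]:
            _swap_out(col, ery_rows, mito_rows, rng)
        if flags["mito"][j]:
            _force_share(col, mito_rows, thresholds.max_mito_fraction)
        if flags["erythroid"][j]:
            _force_share(col, ery_rows, thresholds.max_erythroid_fraction)
    truth = pd.DataFrame({"cell": cells, **{f"violates_{r}": flags[r] for r in _QC_RULES}})
    truth["retained_truth"] = ~(
        flags["features_low"] | flags["features_high"] | flags["mito"] | flags["erythroid"]
    )
    return sparse.csr_matrix(m), genes, cells, truth


def _force_feature_count(col: np.ndarray, target: int, rng: np.random.Generator) -> None:
    """Adjust a count column in place so its nonzero-gene count equals ``target``."""
    nz = np.flatnonzero(col)
    if len(nz) > target:
        drop = rng.choice(nz, size=len(nz) - target, replace=False)
        col[drop] = 0
    elif len(nz) < target:
        zeros = np.flatnonzero(col == 0)
        add = rng.choice(zeros, size=target - len(nz), replace=False)
        col[add] = 1


def _swap_out(col: np.ndarray, rows: np.ndarray, protected: np.ndarray, rng: np.random.Generator) -> None:
    """Zero the designated rows, activating equally many background zero rows
    so the cell's feature count is preserved."""
    nz = rows[col[rows] > 0]
    if len(nz) == 0:
        return
    blocked = set(rows.tolist()) | set(protected.tolist())
    candidates = np.array([i for i in np.flatnonzero(col == 0) if i not in blocked], dtype=int)
    k = min(len(candidates), len(nz))
    if k:
        col[rng.choice(candidates, size=k, replace=False)] = 1
    col[nz] = 0


def _force_share(col: np.ndarray, rows: np.ndarray, threshold: float) -> None:
    """Scale the designated rows so their UMI share strictly exceeds ``threshold``."""
    if len(rows) == 0:
        raise ConfigurationError("cannot force a fraction violation without designated genes")
    target = min(2.0 * threshold, 0.9)
    if col[rows].sum() == 0:
        others = np.flatnonzero(col)
        col[rows[0]] = 1
        if len(others):  # keep the feature count unchanged
            col[others[0]] = 0
    s_g = int(col[rows].sum())
    s_o = int(col.sum()) - s_g
    need = target / (1.0 - target) * s_o
    scale = max(1, math.ceil(need / s_g) + 1)
    col[rows] *= scale
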