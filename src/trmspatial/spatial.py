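"""Spatial quantification of immune–tumor organization.

Implements the per-sample spatial readouts used to characterize T-cell
infiltration around tumor cells:

* compartment densities (cells/mm²) and fractions of the CD8+ population,
* infiltration profiles over sequential distance bands from the tumor
  boundary,
* direct interaction counts (target cells within a fixed radius of each
  tumor cell),
* mean tumor-to-nearest-target distances,
* the cross-type nearest-neighbour distance distribution G_cross(r) with
  its area-under-curve proximity score.

Orientation is fixed throughout: tumor cells are the *reference* type and
the immune phenotype the *target* type (G-cross is asymmetric). Ĝ(r) is
the uncorrected empirical CDF of the reference-to-nearest-target
distances — the probability that a tumor cell has a target cell within
radius r. A reduced-sample border correction (drop reference cells closer
than r_max to the window edge) is available but off by default. Distances
are in µm and radius comparisons use closed balls (d <= r counts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import ConfigurationError
from .io import require_columns
from .phenotyping import select_phenotype

logger = logging.getLogger(__name__)

TUMOR = "tumor"


@dataclass
class GCrossCurve:
    """Empirical G-cross curve and its normalized proximity score.

    ``auc`` is the trapezoid-rule integral of Ĝ over [0, r_max] (µm);
    ``score = auc / r_max`` lies in [0, 1] and is comparable across r_max
    choices. ``empty_target`` flags samples where the target phenotype was
    absent: the score is then 0 by convention (absence of the subset is
    informative, not missing data).
    """

    r_grid: np.ndarray
    g_hat: np.ndarray
    n_reference: int
    n_target: int
    auc: float
    score: float
    empty_target: bool = False
    phenotype: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_um": self.r_grid, "g_hat": self.g_hat})


def _coords(cells: pd.DataFrame, mask) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    return np.column_stack(
        [cells["x_um"].to_numpy(dtype=float)[mask], cells["y_um"].to_numpy(dtype=float)[mask]]
    )


def _tumor_coords(cells: pd.DataFrame) -> np.ndarray:
    require_columns(cells, ("x_um", "y_um", "phenotype"), context="gated cell table")
    return _coords(cells, cells["phenotype"].to_numpy() == TUMOR)


def cross_nn_distances(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Distance from each reference point to its nearest target point."""
    if len(reference) == 0:
        return np.array([], dtype=float)
    if len(target) == 0:
        return np.full(len(reference), np.inf)
    tree = cKDTree(target)
    d, _ = tree.query(reference, k=1)
    return np.asarray(d, dtype=float)


def gcross(
    cells: pd.DataFrame,
    phenotype: str,
    r_max_um: float = 30.0,
    n_r: int = 61,
    border_correction: bool = False,
    window: tuple[float, float, float, float] | None = None,
) -> GCrossCurve:
    """Empirical G-cross curve from tumor cells to the nearest cell of ``phenotype``.

    Parameters
    ----------
    cells : gated cell table with ``x_um``/``y_um``/``phenotype`` columns.
    phenotype : target label or aggregate name (see ``select_phenotype``).
    r_max_um, n_r : uniform evaluation grid [0, r_max] with ``n_r`` points.
    border_correction : if True, restrict reference cells to those at least
        ``r_max_um`` from the window edge (reduced-sample estimator).
    window : (xmin, ymin, xmax, ymax); required meaningfully only for the
        border correction — defaults to the bounding box of all cells.
    """
    if r_max_um <= 0:
        raise ConfigurationError("r_max_um must be > 0")
    if n_r < 2:
        raise ConfigurationError("n_r must be >= 2")
    ref = _tumor_coords(cells)
    if len(ref) == 0:
        raise ValueError("gcross requires at least one tumor (reference) cell")
    tgt = _coords(cells, select_phenotype(cells, phenotype))
    if border_correction:
        if window is None:
            xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
            window = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
        xmin, ymin, xmax, ymax = window
        edge = np.minimum.reduce(
            [ref[:, 0] - xmin, xmax - ref[:, 0], ref[:, 1] - ymin, ymax - ref[:, 1]]
        )
        kept = ref[edge >= r_max_um]
        if len(kept) == 0:
            logger.warning("border correction removed all reference cells; falling back to uncorrected")
        else:
            ref = kept
    r_grid = np.linspace(0.0, r_max_um, n_r)
    if len(tgt) == 0:
        g = np.zeros_like(r_grid)
        return GCrossCurve(r_grid, g, len(ref), 0, 0.0, 0.0, empty_target=True, phenotype=phenotype)
    d = cross_nn_distances(ref, tgt)
    g = (d[None, :] <= r_grid[:, None]).mean(axis=1)
    auc = float(np.trapezoid(g, r_grid))
    return GCrossCurve(r_grid, g, len(ref), len(tgt), auc, auc / r_max_um, phenotype=phenotype)


def mean_nearest_distance(cells: pd.DataFrame, phenotype: str) -> float:
    """Mean over tumor cells of the distance to the nearest ``phenotype`` cell (µm).

    Returns NaN (with a logged reason) when the phenotype is absent.
    """
    ref = _tumor_coords(cells)
    if len(ref) == 0:
        raise ValueError("mean_nearest_distance requires at least one tumor cell")
    tgt = _coords(cells, select_phenotype(cells, phenotype))
    if len(tgt) == 0:
        logger.info("mean_nearest_distance: no %r cells in sample; returning NaN", phenotype)
        return float("nan")
    return float(cross_nn_distances(ref, tgt).mean())


def interaction_count(
    cells: pd.DataFrame, phenotype: str, radius_um: float = 10.0
) -> tuple[np.ndarray, float]:
    """Per-tumor-cell count of ``phenotype`` cells within ``radius_um`` (closed ball).

    Returns the per-reference-cell counts and their mean. Computed with a
    k-d tree but contractually identical to the all-pairs result.
    """
    if radius_um <= 0:
        raise ConfigurationError("radius_um must be > 0")
    ref = _tumor_coords(cells)
    if len(ref) == 0:
        raise ValueError("interaction_count requires at least one tumor cell")
    tgt = _coords(cells, select_phenotype(cells, phenotype))
    if len(tgt) == 0:
        counts = np.zeros(len(ref), dtype=int)
        return counts, 0.0
    tree = cKDTree(tgt)
    counts = np.asarray(tree.query_ball_point(ref, r=radius_um, return_length=True), dtype=int)
    return counts, float(counts.mean())


def infiltration_profile(
    cells: pd.DataFrame,
    phenotype: str,
    band_width_um: float = 10.0,
    max_dist_um: float = 100.0,
) -> tuple[np.ndarray, bool]:
    """Proportions of stromal ``phenotype`` cells in sequential distance bands.

    Band k covers boundary distances ((k-1)·w, k·w]; proportions are taken
    over the phenotype's cells within (0, max_dist]. Returns the proportion
    vector and an ``empty`` flag (all-zero vector when no cell lies in the
    zone). ``band_width_um`` must divide ``max_dist_um``.
    """
    n_bands_f = max_dist_um / band_width_um
    n_bands = round(n_bands_f)
    if not math.isclose(n_bands_f, n_bands, rel_tol=0, abs_tol=1e-9) or n_bands < 1:
        raise ConfigurationError("band_width_um must evenly divide max_dist_um")
    require_columns(cells, ("boundary_distance_um",), context="compartmentalized cell table")
    mask = select_phenotype(cells, phenotype)
    d = cells.loc[mask, "boundary_distance_um"].to_numpy(dtype=float)
    d = d[(d > 0) & (d <= max_dist_um) & np.isfinite(d)]
    if len(d) == 0:
        return np.zeros(n_bands), True
    # right-closed bands: band index = ceil(d / w) - 1
    idx = np.ceil(d / band_width_um).astype(int) - 1
    counts = np.bincount(idx, minlength=n_bands)[:n_bands]
    return counts / len(d), False


def density_and_fraction(
    cells: pd.DataFrame,
    compartment_areas: dict[str, float],
    phenotype: str,
) -> pd.DataFrame:
    """Per-compartment density (cells/mm²) and fraction of the CD8+ population.

    ``compartment_areas`` maps compartment name to area in mm² (> 0).
    ``fraction_of_cd8`` = |phenotype ∧ CD8+| / |CD8+| within the compartment,
    NaN when the compartment holds no CD8+ cells.
    """
    require_columns(cells, ("compartment",), context="compartmentalized cell table")
    for comp, area in compartment_areas.items():
        if not area > 0:
            raise ConfigurationError(f"area for compartment {comp!r} must be > 0 mm²")
    mask = select_phenotype(cells, phenotype)
    cd8 = select_phenotype(cells, "cd8_any")
    rows = []
    comp_col = cells["compartment"].to_numpy()
    for comp, area in compartment_areas.items():
        in_comp = comp_col == comp
        n_pheno = int((mask & in_comp).sum())
        n_cd8 = int((cd8 & in_comp).sum())
        n_both = int((mask & cd8 & in_comp).sum())
        rows.append(
            {
                "compartment": comp,
                "phenotype": phenotype,
                "count": n_pheno,
                "density_per_mm2": n_pheno / area,
                "fraction_of_cd8": (n_both / n_cd8) if n_cd8 > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def sample_qc(cells: pd.DataFrame, min_combined: int = 1500) -> bool:
    """Sample-level QC: tumor + CD8+ cells within tumor tissue must reach ``min_combined``.

    Counts tumor cells and CD8+ T cells in the intra-tumor compartment
    (whole sample if compartments are not assigned); inclusive lower bound.
    """
    if len(cells) == 0:
        return False
    tumor = (cells["phenotype"] == TUMOR).to_numpy()
    cd8 = select_phenotype(cells, "cd8_any")
    if "compartment" in cells.columns:
        in_tumor_tissue = (cells["compartment"] == "intra_tumor").to_numpy()
        combined = int(((tumor | cd8) & in_tumor_tissue).sum())
    else:
        combined = int((tumor | cd8).sum())
    passed = combined >= min_combined
    if not passed:
        logger.info("sample QC failed: %d combined tumor+CD8 cells < %d", combined, min_combined)
    return passed


def summarize_sample(
    cells: pd.DataFrame,
    compartment_areas: dict[str, float],
    phenotypes,
    r_max_um: float = 30.0,
    n_r: int = 61,
    band_width_um: float = 10.0,
    max_band_dist_um: float = 100.0,
    interaction_radius_um: float = 10.0,
    border_correction: bool = False,
    window: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Per-(phenotype, compartment) spatial summary for one gated, compartmentalized sample."""
    frames = []
    sample_id = cells["sample_id"].iloc[0] if "sample_id" in cells.columns and len(cells) else ""
    for phen in phenotypes:
        df = density_and_fraction(cells, compartment_areas, phen)
        curve = gcross(cells, phen, r_max_um=r_max_um, n_r=n_r,
                       border_correction=border_correction, window=window)
        _, mean_inter = interaction_count(cells, phen, radius_um=interaction_radius_um)
        bands, bands_empty = infiltration_profile(cells, phen, band_width_um, max_band_dist_um)
        df["mean_nn_dist_um"] = mean_nearest_distance(cells, phen)
        df["interactions_per_tumor_cell"] = mean_inter
        df["gcross_score"] = curve.score
        df["gcross_auc_um"] = curve.auc
        df["band_profile_empty"] = bands_empty
        for k, p in enumerate(bands, start=1):
            df[f"band_{k}"] = p
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "sample_id", sample_id)
    return out
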