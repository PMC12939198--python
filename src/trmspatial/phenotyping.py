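"""Hierarchical phenotype gating, scRNA quality control, and signature scoring.

Gating assigns each cell the first phenotype in an ordered hierarchy whose
marker requirements it satisfies (positivity = intensity >= threshold);
cells matching no rule are labelled ``other``. Per-marker boolean
positivity columns are emitted alongside the exclusive label so aggregate
subsets (e.g. all CD103+CD8+ resident cells, CD69+ or TCF-1+ CD8 cells)
remain recoverable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .config import GatingConfig, QCThresholds, SchemaError, OTHER_LABEL
from .io import require_columns

logger = logging.getLogger(__name__)

DEFAULT_ERYTHROID_GENES = ("HBA1", "HBA2", "HBB")
MITO_PREFIX = "MT-"


class PhenotypeGater(BaseEstimator):
    """Rule-based hierarchical gate over marker intensity columns.

    Parameters
    ----------
    config : GatingConfig
        Intensity thresholds and the ordered phenotype hierarchy.

    Attributes
    ----------
    markers_ : tuple of str
        Markers referenced by the hierarchy, fixed at :meth:`fit`.
    vocabulary_ : tuple of str
        Phenotype labels in gating order (excluding ``other``).
    """

    def __init__(self, config: GatingConfig):
        self.config = config

    def fit(self, cells: pd.DataFrame, y=None) -> "PhenotypeGater":
        markers = sorted(set().union(*(r.markers() for r in self.config.hierarchy)))
        require_columns(cells, markers, context="cell table")
        self.markers_ = tuple(markers)
        self.vocabulary_ = tuple(r.name for r in self.config.hierarchy)
        return self

    def transform(self, cells: pd.DataFrame) -> pd.DataFrame:
        """Return a copy with ``phenotype`` and ``<marker>_pos`` columns; row order preserved."""
        if not hasattr(self, "markers_"):
            self.fit(cells)
        require_columns(cells, self.markers_, context="cell table")
        out = cells.copy()
        pos = {
            m: (out[m].to_numpy(dtype=float) >= self.config.thresholds[m]) for m in self.markers_
        }
        label = np.full(len(out), OTHER_LABEL, dtype=object)
        unassigned = np.ones(len(out), dtype=bool)
        for rule in self.config.hierarchy:
            match = unassigned.copy()
            for m in rule.positive:
                match &= pos[m]
            for m in rule.negative:
                match &= ~pos[m]
            label[match] = rule.name
            unassigned &= ~match
        for m in self.markers_:
            out[f"{m}_pos"] = pos[m]
        out["phenotype"] = label
        return out

    def fit_transform(self, cells: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(cells).transform(cells)


def gate_phenotypes(cells: pd.DataFrame, config: GatingConfig) -> pd.DataFrame:
    """Functional wrapper over :class:`PhenotypeGater`."""
    return PhenotypeGater(config).fit_transform(cells)


def estimate_thresholds(cells: pd.DataFrame, markers, random_state: int = 0) -> dict[str, float]:
    """Estimate per-marker positivity cuts as the valley of a two-component fit.

    Fits a 2-component Gaussian mixture on log intensities and places the
    threshold at the midpoint of the component means, mapped back to the
    intensity scale. Intended as a starting point where no negative-control
    calibration is available; always review against controls.
    """
    out: dict[str, float] = {}
    for m in markers:
        if m not in cells.columns:
            raise SchemaError(f"cell table is missing required column(s): ['{m}']")
        x = np.log(np.clip(cells[m].to_numpy(dtype=float), 1e-9, None)).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3).fit(x)
        means = np.sort(gm.means_.ravel())
        out[m] = float(np.exp(means.mean()))
    return out


def select_phenotype(cells: pd.DataFrame, phenotype: str) -> np.ndarray:
    """Boolean mask of cells belonging to a phenotype.

    Accepts either an exclusive label from the gating hierarchy (matched
    against the ``phenotype`` column) or one of the aggregate marker
    combinations recoverable from the positivity columns:
    ``cd8_any`` (all non-tumor CD8+), ``trm`` / ``cd103_cd8``,
    ``pd1_cd8_any``, ``cd69_cd8``, ``tcf1_cd8``.
    """
    aggregates = {
        "cd8_any": lambda d: d["CD8_pos"] & ~_is_tumor(d),
        "trm": lambda d: d["CD8_pos"] & d["CD103_pos"] & ~_is_tumor(d),
        "cd103_cd8": lambda d: d["CD8_pos"] & d["CD103_pos"] & ~_is_tumor(d),
        "pd1_cd8_any": lambda d: d["CD8_pos"] & d["PD1_pos"] & ~_is_tumor(d),
        "cd69_cd8": lambda d: d["CD8_pos"] & d["CD69_pos"] & ~_is_tumor(d),
        "tcf1_cd8": lambda d: d["CD8_pos"] & d["TCF1_pos"] & ~_is_tumor(d),
    }
    if phenotype in aggregates:
        needed = {"CD8_pos"}
        require_columns(cells, sorted(needed), context="gated cell table")
        return aggregates[phenotype](cells).to_numpy(dtype=bool)
    require_columns(cells, ["phenotype"], context="gated cell table")
    return (cells["phenotype"] == phenotype).to_numpy(dtype=bool)


def _is_tumor(cells: pd.DataFrame):
    if "phenotype" in cells.columns:
        return cells["phenotype"] == "tumor"
    return cells["PanCK_pos"]


def qc_filter(
    matrix,
    genes,
    thresholds: QCThresholds = QCThresholds(),
    mito_prefix: str = MITO_PREFIX,
    erythroid_genes=DEFAULT_ERYTHROID_GENES,
) -> np.ndarray:
    """Indices of cells passing the single-cell RNA quality-control filter.

    ``matrix`` is genes x cells (dense or sparse, non-negative counts). A
    cell is retained iff its number of detected genes (count > 0) lies in
    ``[min_features, max_features]`` (inclusive), its mitochondrial UMI
    fraction is strictly below ``max_mito_fraction``, and its erythroid UMI
    fraction strictly below ``max_erythroid_fraction``. Cells with zero
    total counts have both fractions defined as 0 (they fail the feature
    floor anyway for any ``min_features`` >= 1).
    """
    genes = list(genes)
    m = sparse.csr_matrix(matrix) if not sparse.issparse(matrix) else matrix.tocsr()
    if m.shape[0] != len(genes):
        raise SchemaError(f"matrix has {m.shape[0]} rows but {len(genes)} gene names")
    if m.nnz and m.data.min() < 0:
        raise ValueError("expression matrix must be non-negative")
    n_cells = m.shape[1]
    if n_cells == 0:
        return np.array([], dtype=int)
    features = np.asarray((m > 0).sum(axis=0)).ravel()
    total = np.asarray(m.sum(axis=0)).ravel()
    mito_rows = [i for i, g in enumerate(genes) if str(g).startswith(mito_prefix)]
    ery_rows = [i for i, g in enumerate(genes) if str(g) in set(erythroid_genes)]
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, np.asarray(m[mito_rows].sum(axis=0)).ravel() / np.where(total > 0, total, 1), 0.0)
        ery_frac = np.where(total > 0, np.asarray(m[ery_rows].sum(axis=0)).ravel() / np.where(total > 0, total, 1), 0.0)
    keep = (
        (features >= thresholds.min_features)
        & (features <= thresholds.max_features)
        & (mito_frac < thresholds.max_mito_fraction)
        & (ery_frac < thresholds.max_erythroid_fraction)
    )
    return np.flatnonzero(keep)


def signature_score(matrix, genes, gene_set) -> np.ndarray:
    """Per-cell signature score: mean normalized expression of the signature genes.

    ``matrix`` is genes x cells on the normalized scale. Signature genes
    absent from the matrix are dropped with a logged warning; an empty
    intersection raises rather than silently scoring zero.
    """
    genes = list(genes)
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    index = {g: i for i, g in enumerate(genes)}
    present = [g for g in gene_set if g in index]
    missing = [g for g in gene_set if g not in index]
    if missing:
        logger.warning("signature genes absent from matrix and dropped: %s", missing)
    if not present:
        raise ValueError("no signature gene intersects the matrix gene names")
    rows = [index[g] for g in present]
    m = matrix.tocsr() if sparse.issparse(matrix) else np.asarray(matrix)
    sub = m[rows]
    mean = np.asarray(sub.mean(axis=0)).ravel() if sparse.issparse(sub) else sub.mean(axis=0)
    return np.asarray(mean, dtype=float)
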