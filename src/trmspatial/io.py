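"""Tabular and matrix I/O: cell tables, cohort tables, expression matrices, regions.

All tables travel as delimited text (CSV); expression matrices as
matrix-market triplets with gene/cell name sidecars; tumor regions as
GeoJSON-style polygon text for inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .config import SchemaError

CELL_KEY_COLUMNS = ("sample_id", "cell_id", "x_um", "y_um")


def require_columns(df: pd.DataFrame, columns, context: str = "table") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{context} is missing required column(s): {missing}")


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, CELL_KEY_COLUMNS, context=f"cell table {path}")
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, ("patient_id", "os_time", "event"), context=f"cohort table {path}")
    return df


def write_expression(matrix, genes, cells, prefix: str | Path) -> None:
    """Write a genes x cells matrix as ``<prefix>.mtx`` plus name sidecars."""
    prefix = Path(prefix)
    m = sparse.csr_matrix(matrix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), m)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{prefix}_genes.txt").write_text("\n".join(map(str, genes)) + ("\n" if len(genes) else ""))
    Path(f"{prefix}_cells.txt").write_text("\n".join(map(str, cells)) + ("\n" if len(cells) else ""))


def read_expression(prefix: str | Path):
    prefix = Path(prefix)
    m = sparse.csr_matrix(spio.mmread(str(prefix.with_suffix(".mtx"))))
    genes = Path(f"{prefix}_genes.txt").read_text().splitlines()
    cells = Path(f"{prefix}_cells.txt").read_text().splitlines()
    if m.shape != (len(genes), len(cells)):
        raise SchemaError(
            f"expression matrix shape {m.shape} does not match sidecars ({len(genes)} genes, {len(cells)} cells)"
        )
    return m, genes, cells


def region_to_geojson(region) -> dict:
    """GeoJSON-style mapping for a (Multi)Polygon tumor region; empty → empty collection."""
    if region is None or region.is_empty:
        return {"type": "MultiPolygon", "coordinates": []}
    from shapely.geometry import mapping

    geo = mapping(region)
    if geo["type"] == "Polygon":
        geo = {"type": "MultiPolygon", "coordinates": [geo["coordinates"]]}
    return json.loads(json.dumps(geo))  # plain lists, no tuples


def write_region(region, path: str | Path) -> None:
    Path(path).write_text(json.dumps(region_to_geojson(region)))


def sha256_file(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
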