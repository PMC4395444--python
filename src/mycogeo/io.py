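"""File formats: feature tables, metadata, GeoJSON masks/regions, manifests.

The canonical sample input is a wide CSV/TSV feature table (rows =
samples, columns = taxa; any positive count is binarized with a logged
warning) joined exactly on sample_id against a metadata CSV carrying
latitude/longitude and optional covariate columns.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .geometry import SpatialGrid
from .prediction import OriginPrediction
from .smoothing import SampleTable

logger = logging.getLogger("mycogeo")

__all__ = [
    "read_sample_table",
    "write_sample_table",
    "read_mask_geojson",
    "read_queries",
    "write_region_geojson",
    "write_predictions_csv",
    "write_manifest",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_sample_table(matrix_path, metadata_path) -> SampleTable:
    """Join a wide 0/1 (or count) feature table with coordinate metadata.

    Counts > 1 are binarized with a tallied warning. Duplicate sample IDs,
    missing coordinates and matrix samples absent from the metadata are
    errors naming the offending IDs.
    """
    matrix = _read_table(matrix_path)
    meta = pd.read_csv(metadata_path)
    if "sample_id" not in meta.columns:
        raise FormatError(f"{metadata_path} lacks a sample_id column")
    for col in ("latitude", "longitude"):
        if col not in meta.columns:
            raise FormatError(f"{metadata_path} lacks a {col} column")

    matrix.index = matrix.index.astype(str)
    meta["sample_id"] = meta["sample_id"].astype(str)
    dup = matrix.index[matrix.index.duplicated()].unique().tolist()
    dup += meta["sample_id"][meta["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate sample IDs: {sorted(set(dup))}")

    meta = meta.set_index("sample_id")
    missing = [s for s in matrix.index if s not in meta.index]
    if missing:
        raise FormatError(f"metadata missing samples: {missing}")
    meta = meta.loc[matrix.index]
    bad_coord = meta.index[
        meta["latitude"].isna() | meta["longitude"].isna()
    ].tolist()
    if bad_coord:
        raise FormatError(f"missing coordinates for samples: {bad_coord}")

    values = matrix.to_numpy()
    if not np.isfinite(values.astype(float)).all():
        raise FormatError(f"{matrix_path} contains non-finite entries")
    n_counts = int((values > 1).sum())
    if n_counts or (values < 0).any():
        if (values < 0).any():
            raise FormatError(f"{matrix_path} contains negative entries")
        logger.warning("binarized %d count entries (> 1) to presence", n_counts)
    Y = (values > 0).astype(np.int8)

    covars = meta.drop(columns=["latitude", "longitude"])
    logger.info(
        "read %d samples x %d taxa from %s", Y.shape[0], Y.shape[1], matrix_path
    )
    return SampleTable(
        sample_ids=list(matrix.index),
        lats=meta["latitude"].to_numpy(float),
        lons=meta["longitude"].to_numpy(float),
        taxon_ids=[str(c) for c in matrix.columns],
        Y=Y,
        covariates=covars.reset_index(drop=True) if covars.shape[1] else None,
    )


def write_sample_table(samples: SampleTable, matrix_path, metadata_path) -> None:
    pd.DataFrame(
        samples.Y, index=pd.Index(samples.sample_ids, name="sample_id"),
        columns=samples.taxon_ids,
    ).to_csv(matrix_path)
    meta = pd.DataFrame(
        {
            "sample_id": samples.sample_ids,
            "latitude": samples.lats,
            "longitude": samples.lons,
        }
    )
    if samples.covariates is not None:
        meta = pd.concat([meta, samples.covariates.reset_index(drop=True)], axis=1)
    meta.to_csv(metadata_path, index=False, float_format="%.17g")


def read_mask_geojson(path):
    """Load a GeoJSON Polygon/MultiPolygon (lon/lat order) as shapely geometry."""
    from shapely.geometry import shape

    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        from shapely.ops import unary_union

        geoms = [shape(f["geometry"]) for f in doc["features"]]
        return unary_union(geoms)
    if doc.get("type") == "Feature":
        doc = doc["geometry"]
    if doc.get("type") not in ("Polygon", "MultiPolygon"):
        raise FormatError(f"mask must be a Polygon/MultiPolygon, got {doc.get('type')}")
    return shape(doc)


def read_queries(path, taxon_ids: Sequence[str]) -> list[tuple[str, np.ndarray]]:
    """Read query samples as (query_id, presence vector) aligned to an atlas.

    Accepts either a wide 0/1 matrix (rows = queries) or a long CSV of
    (query_id, taxon_id) presence pairs. Taxa unknown to the atlas are
    dropped with a logged count.
    """
    df = _read_table(path)
    taxon_ids = [str(t) for t in taxon_ids]
    index = {t: j for j, t in enumerate(taxon_ids)}
    out: list[tuple[str, np.ndarray]] = []
    cols = [str(c) for c in df.columns]
    if cols == ["taxon_id"] or (len(cols) == 1 and cols[0] != taxon_ids[0]):
        # long format: index = query_id, single taxon_id column
        dropped = 0
        for qid, sub in df.groupby(level=0, sort=False):
            y = np.zeros(len(taxon_ids), dtype=np.int8)
            for t in sub.iloc[:, 0].astype(str):
                j = index.get(t)
                if j is None:
                    dropped += 1
                else:
                    y[j] = 1
            out.append((str(qid), y))
        if dropped:
            logger.warning("dropped %d query taxa absent from the atlas", dropped)
        return out
    known = [c for c in cols if c in index]
    dropped_cols = len(cols) - len(known)
    if dropped_cols:
        logger.warning("dropped %d query taxa absent from the atlas", dropped_cols)
    for qid, row in df.iterrows():
        y = np.zeros(len(taxon_ids), dtype=np.int8)
        for c in known:
            y[index[c]] = 1 if float(row[c]) > 0 else 0
        out.append((str(qid), y))
    return out


def _cell_polygon(grid: SpatialGrid, index: int) -> list[list[float]]:
    dlat = grid.provenance.get("dlat_deg")
    dlon = grid.provenance.get("dlon_deg")
    if dlat is None or dlon is None:
        raise FormatError("grid provenance lacks cell sizes; cannot draw cells")
    la, lo = float(grid.lats[index]), float(grid.lons[index])
    h, w = dlat / 2.0, dlon / 2.0
    return [
        [lo - w, la - h],
        [lo + w, la - h],
        [lo + w, la + h],
        [lo - w, la + h],
        [lo - w, la - h],
    ]


def write_region_geojson(
    prediction: OriginPrediction, grid: SpatialGrid, level: float, path
) -> None:
    """Export one nominal level's prediction region as GeoJSON MultiPolygon."""
    if level not in prediction.regions:
        raise KeyError(f"no region at level {level}; have {sorted(prediction.regions)}")
    cells = prediction.regions[level]
    features = []
    if cells.size:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "MultiPolygon",
                    "coordinates": [[_cell_polygon(grid, int(i))] for i in cells],
                },
                "properties": {
                    "query_id": prediction.query_id,
                    "level": level,
                    "q": prediction.thresholds.get(level),
                    "n_cells": int(cells.size),
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def write_predictions_csv(predictions: Sequence[OriginPrediction], path) -> None:
    pd.DataFrame(
        {
            "query_id": [p.query_id for p in predictions],
            "pred_lat": [p.s_hat.lat for p in predictions],
            "pred_lon": [p.s_hat.lon for p in predictions],
            "top_cell_index": [p.argmax_cell for p in predictions],
            "loglik_max": [float(p.loglik[p.argmax_cell]) for p in predictions],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_manifest(path, **entries) -> None:
    """Machine-readable run manifest: config, seed and library versions."""
    import mycogeo

    payload = {
        "mycogeo_version": mycogeo.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        **entries,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
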