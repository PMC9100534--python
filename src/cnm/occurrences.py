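"""Occurrence-record ingestion and depuration.

Presence records go through three cleaning stages before modelling: parsing
with coordinate validation, removal of urban points (records inside cities
reflect human water supply rather than climate), and spatial thinning — one
randomly chosen survivor per group of overlapping circular buffers — to
avoid duplicated information within a spatial unit, which overfits the model.

An occurrence table is a DataFrame with columns ``record_id``, ``lon``,
``lat``, ``retained`` (bool) and ``drop_reason`` in {none, urban, thinned}.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EnvGrid, GeoPoint, OutOfExtentError, pairwise_haversine_km

logger = logging.getLogger(__name__)

OCC_COLUMNS = ["record_id", "lon", "lat", "retained", "drop_reason"]


class SchemaError(ValueError):
    """Raised when an input table violates the occurrence schema."""


def _validate(occ: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OCC_COLUMNS if c not in occ.columns]
    if missing:
        raise SchemaError(f"occurrence table missing columns {missing}")
    if occ["record_id"].duplicated().any():
        dupes = occ.loc[occ["record_id"].duplicated(), "record_id"].tolist()
        raise SchemaError(f"duplicate record_id values: {dupes[:5]}")
    return occ


def retained_points(occ: pd.DataFrame) -> list[GeoPoint]:
    sub = occ[occ["retained"]]
    return [GeoPoint(lo, la) for lo, la in zip(sub["lon"], sub["lat"])]


def read_occurrences(
    path: str | Path,
    lon_column: str = "decimalLongitude",
    lat_column: str = "decimalLatitude",
    id_column: str | None = None,
) -> pd.DataFrame:
    """Read a delimited occurrence file, dropping unparsable coordinates.

    Rows whose coordinates do not parse as decimal degrees or fall outside
    [-180, 180] x [-90, 90] are dropped with a logged count.
    """
    df = pd.read_csv(path)
    for col in (lon_column, lat_column):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    lon = pd.to_numeric(df[lon_column], errors="coerce")
    lat = pd.to_numeric(df[lat_column], errors="coerce")
    ok = (
        lon.notna() & lat.notna()
        & lon.between(-180.0, 180.0) & lat.between(-90.0, 90.0)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d rows with invalid coordinates", n_dropped)
    if id_column is not None and id_column in df.columns:
        ids = df.loc[ok, id_column].astype(str)
    else:
        ids = pd.Series([f"rec{i:06d}" for i in np.flatnonzero(ok.to_numpy())])
    out = pd.DataFrame(
        {
            "record_id": ids.to_numpy(),
            "lon": lon[ok].to_numpy(),
            "lat": lat[ok].to_numpy(),
            "retained": True,
            "drop_reason": "none",
        }
    )
    return _validate(out)


def filter_urban(occ: pd.DataFrame, urban_mask: EnvGrid) -> pd.DataFrame:
    """Flag retained records on urban cells with drop_reason='urban'."""
    occ = _validate(occ).copy()
    for idx in occ.index[occ["retained"]]:
        pt = GeoPoint(occ.at[idx, "lon"], occ.at[idx, "lat"])
        try:
            row, col = urban_mask.cell_index(pt)
        except OutOfExtentError as exc:
            raise OutOfExtentError(f"record {occ.at[idx, 'record_id']}: {exc}")
        if not urban_mask.nodata_mask[row, col] and urban_mask.values[row, col] > 0:
            occ.at[idx, "retained"] = False
            occ.at[idx, "drop_reason"] = "urban"
    n = int((occ["drop_reason"] == "urban").sum())
    if n:
        logger.info("urban filter removed %d records", n)
    return occ


def _component_labels(adjacency: np.ndarray) -> np.ndarray:
    """Connected-component labels of a boolean adjacency matrix (union-find)."""
    n = adjacency.shape[0]
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in np.flatnonzero(adjacency[i, i + 1:]) + i + 1:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[rj] = ri
    return np.array([find(i) for i in range(n)])


def thin_buffers(
    occ: pd.DataFrame, radius_km: float = 2.5, seed: int = 0
) -> pd.DataFrame:
    """Spatial thinning by overlapping circular buffers.

    Two buffers of ``radius_km`` overlap when the great-circle distance
    between their centers is strictly below twice the radius. On each
    connected component of the resulting overlap graph exactly one record
    is retained, chosen uniformly at random. The choice is seeded per
    component from the global seed and the sorted member ids, so the result
    is independent of the input row order.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    occ = _validate(occ).copy()
    live = occ.index[occ["retained"]].to_numpy()
    if live.size <= 1:
        return occ
    sub = occ.loc[live]
    dist = pairwise_haversine_km(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    adj = dist < 2.0 * radius_km
    np.fill_diagonal(adj, False)
    labels = _component_labels(adj)
    for comp in np.unique(labels):
        members = live[labels == comp]
        if members.size == 1:
            continue
        ids = sorted(occ.loc[members, "record_id"])
        digest = hashlib.sha256(
            (f"{seed}|" + "|".join(ids)).encode()
        ).digest()
        comp_rng = np.random.default_rng(
            int.from_bytes(digest[:8], "little")
        )
        keep_id = ids[int(comp_rng.integers(len(ids)))]
        for m in members:
            if occ.at[m, "record_id"] != keep_id:
                occ.at[m, "retained"] = False
                occ.at[m, "drop_reason"] = "thinned"
    n = int((occ["drop_reason"] == "thinned").sum())
    if n:
        logger.info("buffer thinning removed %d records", n)
    return occ


def count_presences_per_decile(
    occ: pd.DataFrame, prob: EnvGrid
) -> pd.DataFrame:
    """Presence counts per occurrence-probability decile.

    Deciles are [0,0.1), [0.1,0.2), ..., [0.9,1.0]; the table carries counts,
    percentages, and cumulative percentages over the retained records. Points
    on nodata probability cells are excluded with a warning.
    """
    pts = retained_points(_validate(occ))
    probs = []
    n_excluded = 0
    for pt in pts:
        row, col = prob.cell_index(pt)
        if prob.nodata_mask[row, col]:
            n_excluded += 1
        else:
            probs.append(prob.values[row, col])
    if n_excluded:
        logger.warning("%d presences on nodata cells excluded", n_excluded)
    p = np.asarray(probs)
    edges = np.linspace(0.0, 1.0, 11)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, 9)
    counts = np.bincount(idx, minlength=10)
    total = counts.sum()
    pct = 100.0 * counts / total if total else np.zeros(10)
    return pd.DataFrame(
        {
            "decile": np.arange(1, 11),
            "prob_low": edges[:-1],
            "prob_high": edges[1:],
            "count": counts,
            "percent": pct,
            "cumulative_percent": np.cumsum(pct),
        }
    )
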