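"""Occurrence cleaning, systematic thinning and geographic profiles.

Record tables are plain DataFrames with columns ``species, lon, lat`` and an
optional ``year``.  Cleaning removes out-of-extent records, exact coordinate
duplicates and (when a collection window is given) records collected outside
it.  Systematic thinning lays a grid over the study extent and keeps one
record per grid cell, the standard correction for roadside/herbarium
sampling bias.  Geographic profiles summarize each species by its
geographical extent GE (cells inside the minimum convex polygon of its
records), number of records NR, record density DR = NR/GE, and the spread of
the first principal component captured at its records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import MultiPoint, Point

from .raster import GridLayer

__all__ = [
    "clean_records",
    "thin_systematic",
    "geo_profile",
    "correlate_profiles",
    "GeoProfile",
]


@dataclass
class GeoProfile:
    species_id: str
    GE: int
    NR: int
    DR: float
    sd_pc1: dict[str, float]


def _require_columns(occ: pd.DataFrame) -> None:
    for col in ("species", "lon", "lat"):
        if col not in occ.columns:
            raise ValueError(f"occurrence table lacks required column {col!r}")


def clean_records(
    occ: pd.DataFrame,
    extent_bbox: tuple[float, float, float, float],
    year_range: tuple[int, int] | None = None,
    strict_years: bool = False,
) -> pd.DataFrame:
    """Drop out-of-extent, duplicate-coordinate and out-of-window records.

    ``extent_bbox`` is (lon_min, lat_min, lon_max, lat_max), closed bounds.
    Records with no ``year`` are kept under a declared ``year_range`` unless
    ``strict_years`` is set (undated specimens are common; dropping them is
    an explicit choice).  Raises if nothing survives.
    """
    _require_columns(occ)
    out = occ.copy()
    lon_min, lat_min, lon_max, lat_max = extent_bbox
    inside = (
        (out["lon"] >= lon_min)
        & (out["lon"] <= lon_max)
        & (out["lat"] >= lat_min)
        & (out["lat"] <= lat_max)
    )
    out = out[inside]
    if year_range is not None and "year" in out.columns:
        y0, y1 = year_range
        year = pd.to_numeric(out["year"], errors="coerce")
        ok = (year >= y0) & (year <= y1)
        if not strict_years:
            ok |= year.isna()
        out = out[ok]
    out = out.drop_duplicates(subset=["lon", "lat"], keep="first")
    if out.empty:
        species = occ["species"].iloc[0] if len(occ) else "<unknown>"
        raise ValueError(f"no records left after cleaning for species {species!r}")
    return out.reset_index(drop=True)


def thin_systematic(
    occ: pd.DataFrame,
    resolution: float,
    seed: int = 0,
    anchor: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Keep one record per ``resolution``-degree grid cell, chosen at random.

    The thinning grid is anchored at ``anchor`` (top-left lon/lat; pass the
    study-extent corner to align it with the analysis grid; default is the
    global corner (-180, 90) so thinning is a pure function of the records).
    Seeded so the retained set is reproducible; output is sorted by
    (lon, lat) so the result is order-deterministic and idempotent at the
    same resolution and anchor.
    """
    _require_columns(occ)
    if resolution <= 0:
        raise ValueError("thinning resolution must be > 0")
    if occ.empty:
        return occ.copy()
    ax = anchor[0] if anchor is not None else -180.0
    ay = anchor[1] if anchor is not None else 90.0
    bj = np.floor((occ["lon"].to_numpy() - ax) / resolution).astype(int)
    bi = np.floor((ay - occ["lat"].to_numpy()) / resolution).astype(int)
    rng = np.random.default_rng(seed)
    # stable pick: shuffle row order once, keep first record seen per cell
    order = rng.permutation(len(occ))
    cells = {}
    for pos in order:
        cells.setdefault((bi[pos], bj[pos]), pos)
    keep = sorted(cells.values())
    out = occ.iloc[keep].sort_values(["lon", "lat"], kind="mergesort")
    return out.reset_index(drop=True)


def geo_profile(
    occ: pd.DataFrame,
    geometry: GridLayer,
    pc1_scores: dict[str, GridLayer] | None = None,
    species_id: str | None = None,
) -> GeoProfile:
    """Geographic characteristics of one species' records.

    GE counts the cells of ``geometry`` whose centers lie inside or on the
    convex hull of the records; degenerate hulls (fewer than 3 distinct
    non-collinear records) fall back to the number of occupied cells, as
    does a hull that covers no cell center (floor rule: GE >= occupied
    cells >= 1).  ``pc1_scores`` maps predictor-set labels to first-component
    score layers; the profile stores the SD of scores extracted at the
    records.
    """
    _require_columns(occ)
    if occ.empty:
        raise ValueError("geo_profile needs at least one record")
    sid = species_id or str(occ["species"].iloc[0])
    lon = occ["lon"].to_numpy(float)
    lat = occ["lat"].to_numpy(float)

    i, j, inside = geometry.point_to_cell(lon, lat)
    occupied = {(a, b) for a, b, ok in zip(i, j, inside) if ok}
    n_occupied = max(len(occupied), 1)

    hull = MultiPoint(list(zip(lon, lat))).convex_hull
    if hull.geom_type != "Polygon":
        ge = n_occupied
    else:
        minx, miny, maxx, maxy = hull.bounds
        lon_c, lat_c = geometry.cell_centers()
        js = np.flatnonzero((lon_c >= minx) & (lon_c <= maxx))
        is_ = np.flatnonzero((lat_c >= miny) & (lat_c <= maxy))
        count = 0
        prepared = hull.buffer(0)  # ensure validity
        for ii in is_:
            y = lat_c[ii]
            for jj in js:
                # boundary-inclusive: covers counts points on the hull edge
                if prepared.covers(Point(lon_c[jj], y)):
                    count += 1
        ge = count if count > 0 else n_occupied
    nr = len(occ)
    sd = {}
    if pc1_scores:
        for label, layer in pc1_scores.items():
            ii, jj, ok = layer.point_to_cell(lon, lat)
            vals = layer.values[ii[ok], jj[ok]]
            vals = vals[np.isfinite(vals)]
            sd[label] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
    return GeoProfile(sid, int(ge), int(nr), nr / ge, sd)


def profiles_to_frame(profiles: list[GeoProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"species": p.species_id, "GE": p.GE, "NR": p.NR, "DR": p.DR}
        row.update({f"sd_pc1_{k}": v for k, v in p.sd_pc1.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_profiles(
    table: pd.DataFrame, columns: tuple[str, ...] = ("GE", "NR", "DR")
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Pairwise Pearson r (with two-sided p) and VIF per characteristic.

    VIF_j = 1 / (1 - R²_j) from the OLS regression of characteristic j on
    the other characteristics (with intercept).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 species to correlate profiles")
    X = table.loc[:, list(columns)].to_numpy(float)
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("zero-variance characteristic")
    k = X.shape[1]
    r = np.eye(k)
    p = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            res = sps.pearsonr(X[:, a], X[:, b])
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    vif = {}
    for jcol in range(k):
        y = X[:, jcol]
        Z = np.column_stack([np.ones(len(X)), np.delete(X, jcol, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vif[columns[jcol]] = 1.0 / max(1.0 - r2, 1e-12)
    cols = list(columns)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        pd.Series(vif, name="VIF"),
    )
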