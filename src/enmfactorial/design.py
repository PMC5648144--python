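"""Pseudo-absence sampling and the adaptive checkerboard 2-fold partition.

True absences are unavailable for herbarium-type data, so balanced
pseudo-absences (prevalence 1: as many absences as presences) are drawn at
the centers of valid, presence-free cells of a raster mask.  Model
evaluation uses a spatially blocked 2-fold split: a checkerboard of square
blocks alternately assigns bins 1 and 2, and the block resolution is chosen
adaptively — every candidate from ``r_min`` to ``r_max`` in ``step``-degree
increments is scored, candidates that leave a bin without presences are
infeasible, and the feasible candidate with the smallest presence-count
imbalance (ties → finest blocks) wins.  Per-bin prevalence 1 is restored by
re-sampling surplus pseudo-absences into blocks of the deficient bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import GridLayer, GridStack, extract_values

__all__ = [
    "sample_pseudoabsences",
    "checkerboard_assign",
    "select_checkerboard_resolution",
    "allocate_pa_to_bins",
    "build_training_points",
    "PartitionSearchResult",
    "TrainingPoints",
]


@dataclass
class PartitionSearchResult:
    candidates: np.ndarray              # resolutions, degrees
    counts: np.ndarray                  # n_candidates x 2 presence counts
    feasible: np.ndarray                # bool per candidate
    chosen_resolution: float
    imbalance: int


@dataclass
class TrainingPoints:
    """Presences + pseudo-absences with bins; predictor values come later."""

    species_id: str
    lon: np.ndarray
    lat: np.ndarray
    y: np.ndarray                       # 1 presence, 0 pseudo-absence
    bin: np.ndarray                     # 1 or 2
    chosen_resolution: float
    search: PartitionSearchResult | None = None

    def extract(self, stack: GridStack) -> tuple[np.ndarray, np.ndarray]:
        return extract_values(stack, self.lon, self.lat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species_id,
                "lon": self.lon,
                "lat": self.lat,
                "label": self.y,
                "bin": self.bin,
            }
        )


def _presence_cells(mask: GridLayer, lon, lat) -> set[tuple[int, int]]:
    i, j, inside = mask.point_to_cell(lon, lat)
    return {(a, b) for a, b, ok in zip(i, j, inside) if ok}


def sample_pseudoabsences(
    presence_lon,
    presence_lat,
    mask_layer: GridLayer,
    seed: int = 0,
    n: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample pseudo-absence points at prevalence 1 under a raster mask.

    One pseudo-absence per presence (or ``n`` if given), placed at the
    centers of distinct cells that are valid under ``mask_layer`` and do not
    contain a presence; cells are drawn without replacement.
    """
    presence_lon = np.asarray(presence_lon, float)
    n_pa = int(n) if n is not None else presence_lon.size
    occupied = _presence_cells(mask_layer, presence_lon, presence_lat)
    eligible = np.argwhere(mask_layer.valid)
    if occupied:
        occ_arr = np.array(sorted(occupied))
        occ_flat = occ_arr[:, 0] * mask_layer.shape[1] + occ_arr[:, 1]
        elig_flat = eligible[:, 0] * mask_layer.shape[1] + eligible[:, 1]
        eligible = eligible[~np.isin(elig_flat, occ_flat)]
    if len(eligible) < n_pa:
        raise ValueError(
            f"only {len(eligible)} eligible cells for {n_pa} pseudo-absences"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(eligible), size=n_pa, replace=False)
    ii, jj = eligible[pick, 0], eligible[pick, 1]
    lon = mask_layer.origin_x + (jj + 0.5) * mask_layer.cell_size
    lat = mask_layer.origin_y - (ii + 0.5) * mask_layer.cell_size
    return lon, lat


def checkerboard_assign(
    lon, lat, resolution: float, anchor: tuple[float, float]
) -> np.ndarray:
    """Bin = 1 + ((block_i + block_j) mod 2), blocks anchored at ``anchor``.

    Blocks follow the same half-open, top-left-inclusive convention as grid
    cells, so every point gets exactly one bin.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    bj = np.floor((lon - anchor[0]) / resolution).astype(int)
    bi = np.floor((anchor[1] - lat) / resolution).astype(int)
    return 1 + ((bi + bj) % 2)


def candidate_resolutions(
    r_min: float = 0.5, r_max: float = 15.0, step: float = 0.5
) -> np.ndarray:
    n = int(round((r_max - r_min) / step)) + 1
    return r_min + step * np.arange(n)


def select_checkerboard_resolution(
    presence_lon,
    presence_lat,
    anchor: tuple[float, float],
    r_min: float = 0.5,
    r_max: float = 15.0,
    step: float = 0.5,
) -> PartitionSearchResult:
    """Choose the checkerboard resolution balancing the 2-fold split.

    Feasible candidates put at least one presence in each bin; among them the
    minimal presence-count imbalance wins, ties resolved toward the smallest
    (finest) resolution.
    """
    presence_lon = np.asarray(presence_lon, float)
    if presence_lon.size < 2:
        raise ValueError("need at least 2 presences to partition")
    cands = candidate_resolutions(r_min, r_max, step)
    counts = np.zeros((cands.size, 2), dtype=int)
    for idx, r in enumerate(cands):
        bins = checkerboard_assign(presence_lon, presence_lat, r, anchor)
        counts[idx] = [(bins == 1).sum(), (bins == 2).sum()]
    feasible = (counts > 0).all(axis=1)
    if not feasible.any():
        raise ValueError("no feasible checkerboard resolution for these presences")
    imbalance = np.abs(counts[:, 0] - counts[:, 1])
    imbalance_f = np.where(feasible, imbalance, np.iinfo(int).max)
    best = int(np.argmin(imbalance_f))  # argmin takes the first (= smallest r) tie
    return PartitionSearchResult(
        candidates=cands,
        counts=counts,
        feasible=feasible,
        chosen_resolution=float(cands[best]),
        imbalance=int(imbalance[best]),
    )


def allocate_pa_to_bins(
    pa_lon,
    pa_lat,
    presence_bins: np.ndarray,
    resolution: float,
    anchor: tuple[float, float],
    mask_layer: GridLayer,
    presence_lon,
    presence_lat,
    seed: int = 0,
    mode: str = "spatial",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Give each pseudo-absence a bin while restoring per-bin prevalence 1.

    ``mode="spatial"`` (default) keeps each pseudo-absence in the bin of its
    own checkerboard block and re-samples surplus points into valid,
    presence-free cells of the deficient bin's blocks; ``mode="relabel"``
    keeps the points in place and only reassigns labels at random.
    Returns (lon, lat, bins) — positions can change under ``spatial``.
    """
    pa_lon = np.asarray(pa_lon, float).copy()
    pa_lat = np.asarray(pa_lat, float).copy()
    presence_bins = np.asarray(presence_bins)
    if pa_lon.size != presence_bins.size:
        raise ValueError("pseudo-absence count must equal presence count")
    target = {b: int((presence_bins == b).sum()) for b in (1, 2)}
    rng = np.random.default_rng(seed)

    if mode == "relabel":
        bins = np.concatenate([np.full(target[1], 1), np.full(target[2], 2)])
        rng.shuffle(bins)
        return pa_lon, pa_lat, bins
    if mode != "spatial":
        raise ValueError(f"unknown allocation mode {mode!r}")

    bins = checkerboard_assign(pa_lon, pa_lat, resolution, anchor)
    # eligible cells per bin (valid, presence-free), as cell centers
    occupied = _presence_cells(mask_layer, presence_lon, presence_lat)
    ii, jj = np.nonzero(mask_layer.valid)
    lonc = mask_layer.origin_x + (jj + 0.5) * mask_layer.cell_size
    latc = mask_layer.origin_y - (ii + 0.5) * mask_layer.cell_size
    free = np.array(
        [(a, b) not in occupied for a, b in zip(ii, jj)], dtype=bool
    )
    cell_bins = checkerboard_assign(lonc, latc, resolution, anchor)

    for deficient, surplus in ((1, 2), (2, 1)):
        need = target[deficient] - int((bins == deficient).sum())
        if need <= 0:
            continue
        if target[deficient] > 0:
            pool = np.flatnonzero(free & (cell_bins == deficient))
            # exclude cells already holding a kept pseudo-absence
            pi, pj, _ = mask_layer.point_to_cell(pa_lon, pa_lat)
            taken = set(zip(pi.tolist(), pj.tolist()))
            pool = np.array(
                [c for c in pool if (ii[c], jj[c]) not in taken], dtype=int
            )
            if pool.size < need:
                raise ValueError(
                    f"bin {deficient} has presences but too few eligible "
                    "pseudo-absence cells"
                )
            move = rng.choice(np.flatnonzero(bins == surplus), size=need, replace=False)
            dest = rng.choice(pool, size=need, replace=False)
            pa_lon[move] = lonc[dest]
            pa_lat[move] = latc[dest]
            bins[move] = deficient
    return pa_lon, pa_lat, bins


def build_training_points(
    occ: pd.DataFrame,
    mask_layer: GridLayer,
    anchor: tuple[float, float],
    seed: int = 0,
    r_min: float = 0.5,
    r_max: float = 15.0,
    step: float = 0.5,
    pa_mode: str = "spatial",
) -> TrainingPoints:
    """Full per-species design: pseudo-absences, partition search, bins."""
    species = str(occ["species"].iloc[0])
    plon = occ["lon"].to_numpy(float)
    plat = occ["lat"].to_numpy(float)
    search = select_checkerboard_resolution(plon, plat, anchor, r_min, r_max, step)
    res = search.chosen_resolution
    pbins = checkerboard_assign(plon, plat, res, anchor)
    pa_lon, pa_lat = sample_pseudoabsences(plon, plat, mask_layer, seed=seed)
    pa_lon, pa_lat, pa_bins = allocate_pa_to_bins(
        pa_lon,
        pa_lat,
        pbins,
        res,
        anchor,
        mask_layer,
        plon,
        plat,
        seed=seed + 1,
        mode=pa_mode,
    )
    lon = np.concatenate([plon, pa_lon])
    lat = np.concatenate([plat, pa_lat])
    y = np.concatenate([np.ones(plon.size, int), np.zeros(pa_lon.size, int)])
    bins = np.concatenate([pbins, pa_bins])
    return TrainingPoints(species, lon, lat, y, bins, res, search)
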