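"""Synthetic environments and virtual species.

The factorial experiment needs worlds whose ground truth is known.  Two
families of standardized Gaussian random fields emulate the statistical
contrast between climatic and soil variables: climate-like fields are
smooth with long-range spatial autocorrelation, edaphic-like fields vary
over short ranges with much finer spatial complexity.  Virtual species are
defined by Gaussian response curves on chosen layers, so the true
suitability surface — and hence which predictor family can "see" the niche
— is known exactly.

Fields are produced by convolving seeded white noise with an isotropic
Gaussian kernel (wrap-around boundaries keep the marginal stationary) and
re-standardizing to mean 0, SD 1 over valid cells.  Within-family
collinearity, as displayed by real bioclim/soil stacks, is injected by
mixing a shared latent field into every member of the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .raster import GridLayer, GridStack

__all__ = [
    "FieldSpec",
    "WorldConfig",
    "VirtualSpecies",
    "gen_gaussian_field",
    "gen_environment",
    "make_virtual_species",
    "sample_occurrences",
]

#: Default geometry: the Neotropical-scale study window, top-left corner.
DEFAULT_ORIGIN = (-120.0, 35.0)
DEFAULT_CELL_SIZE = 0.5


@dataclass(frozen=True)
class FieldSpec:
    """Recipe for one standardized Gaussian random field."""

    name: str
    autocorr_range: float = 0.0  # Gaussian kernel scale, in cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.autocorr_range < 0:
            raise ValueError("autocorr_range must be >= 0")


@dataclass
class WorldConfig:
    """Configuration of a synthetic world (two predictor families)."""

    shape: tuple[int, int] = (150, 150)
    n_climate: int = 6
    n_edaphic: int = 8
    climate_range: float = 40.0   # cells; long-range, smooth
    edaphic_range: float = 4.0    # cells; short-range, complex
    climate_correlation: float = 0.6
    edaphic_correlation: float = 0.3
    # variance fraction of a planar geographic gradient mixed into each
    # climate-like layer (temperature-like trends: real climate varies along
    # broad monotone gradients, soils do not)
    climate_gradient: float = 0.5
    mask_hole_fraction: float = 0.0
    origin: tuple[float, float] = DEFAULT_ORIGIN
    cell_size: float = DEFAULT_CELL_SIZE
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "shape" in kwargs:
            kwargs["shape"] = tuple(kwargs["shape"])
        if "origin" in kwargs:
            kwargs["origin"] = tuple(kwargs["origin"])
        return cls(**kwargs)


@dataclass
class VirtualSpecies:
    """A species with a known (Gaussian-product) suitability surface."""

    species_id: str
    responses: list[tuple[str, float, float]]  # (layer name, optimum, breadth)
    true_suitability: GridLayer
    seed: int = 0


def _standardize(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    v = values[valid]
    out = (values - v.mean()) / v.std()
    out[~valid] = np.nan
    return out


def gen_gaussian_field(
    shape: tuple[int, int],
    spec: FieldSpec,
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    cell_size: float = DEFAULT_CELL_SIZE,
) -> GridLayer:
    """Generate one standardized random field; pure function of (shape, spec)."""
    nr, nc = shape
    if nr <= 0 or nc <= 0:
        raise ValueError("field shape must be positive in both dimensions")
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((nr, nc))
    if spec.autocorr_range > 0:
        noise = gaussian_filter(noise, sigma=spec.autocorr_range, mode="wrap")
    valid = np.ones((nr, nc), dtype=bool)
    values = _standardize(noise, valid)
    return GridLayer(
        name=spec.name,
        values=values,
        valid=valid,
        origin_x=origin[0],
        origin_y=origin[1],
        cell_size=cell_size,
    )


def _planar_gradient(shape, theta: float) -> np.ndarray:
    """Standardized planar trend with orientation ``theta``."""
    nr, nc = shape
    yy, xx = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    plane = np.cos(theta) * xx + np.sin(theta) * yy
    return (plane - plane.mean()) / plane.std()


def _gen_family(
    prefix: str,
    count: int,
    autocorr_range: float,
    correlation: float,
    cfg: WorldConfig,
    rng: np.random.Generator,
    gradient: float = 0.0,
) -> list[GridLayer]:
    """Generate one family, optionally sharing a latent field for collinearity.

    ``gradient`` mixes a planar geographic trend (shared orientation per
    family, like the latitudinal structure of temperature variables) into
    every layer with that variance fraction.
    """
    if not 0 <= correlation < 1:
        raise ValueError("within-family correlation must be in [0, 1)")
    if not 0 <= gradient < 1:
        raise ValueError("gradient fraction must be in [0, 1)")
    shared_seed = int(rng.integers(2**31))
    theta = float(rng.uniform(0, 2 * np.pi))
    shared = gen_gaussian_field(
        cfg.shape,
        FieldSpec(f"{prefix}_latent", autocorr_range, shared_seed),
        cfg.origin,
        cfg.cell_size,
    ).values
    plane = _planar_gradient(cfg.shape, theta)
    layers = []
    a, b = np.sqrt(correlation), np.sqrt(1.0 - correlation)
    g, h = np.sqrt(gradient), np.sqrt(1.0 - gradient)
    for k in range(count):
        seed = int(rng.integers(2**31))
        own = gen_gaussian_field(
            cfg.shape,
            FieldSpec(f"{prefix}{k + 1}", autocorr_range, seed),
            cfg.origin,
            cfg.cell_size,
        )
        mixed = a * shared + b * own.values
        # per-layer sign flips keep the trend from forcing correlation 1
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mixed = g * sign * plane + h * mixed
        own.values = _standardize(mixed, own.valid)
        layers.append(own)
    return layers


def gen_environment(cfg: WorldConfig) -> tuple[GridStack, GridStack]:
    """Generate the (climate, edaphic) stacks on one shared geometry.

    Mask holes (``mask_hole_fraction``) are punched into every edaphic layer
    only, mimicking soil grids that lack data where climate grids do not
    (lakes, ice, bare rock); the joint mask of a combined stack is then the
    intersection of both families' coverage.
    """
    rng = np.random.default_rng(cfg.seed)
    climate = _gen_family(
        "clim", cfg.n_climate, cfg.climate_range, cfg.climate_correlation,
        cfg, rng, gradient=cfg.climate_gradient,
    )
    edaphic = _gen_family(
        "soil", cfg.n_edaphic, cfg.edaphic_range, cfg.edaphic_correlation, cfg, rng
    )
    if cfg.mask_hole_fraction > 0:
        holes = rng.random(cfg.shape) < cfg.mask_hole_fraction
        for lyr in edaphic:
            lyr.valid &= ~holes
            lyr.values[holes] = np.nan
    return GridStack(climate), GridStack(edaphic)


def make_virtual_species(
    stack: GridStack,
    responses: Sequence[tuple[str, float, float]],
    species_id: str = "vs",
    seed: int = 0,
) -> VirtualSpecies:
    """Build a virtual species from Gaussian responses on named layers.

    ``true_suitability = prod_k exp(-(x_k - optimum_k)^2 / (2 breadth_k^2))``
    over jointly valid cells; 1 at the joint optimum, strictly below 1 as any
    variable departs from its optimum.
    """
    suit = np.ones(stack.shape)
    for name, optimum, breadth in responses:
        if breadth <= 0:
            raise ValueError("response breadth must be > 0")
        lyr = stack[name]  # KeyError for unknown layer names
        with np.errstate(invalid="ignore"):
            suit *= np.exp(-((lyr.values - optimum) ** 2) / (2.0 * breadth**2))
    valid = stack.joint_valid.copy()
    suit[~valid] = np.nan
    geom = stack.geometry
    layer = GridLayer(
        name=f"suitability_{species_id}",
        values=suit,
        valid=valid,
        origin_x=geom.origin_x,
        origin_y=geom.origin_y,
        cell_size=geom.cell_size,
    )
    return VirtualSpecies(species_id, list(responses), layer, seed)


def sample_occurrences(
    vs: VirtualSpecies,
    n: int,
    seed: int = 0,
    bias: GridLayer | None = None,
) -> pd.DataFrame:
    """Draw ``n`` presence records with cell weight ∝ suitability × bias.

    Cells are drawn with replacement proportionally to their weight and the
    record is placed uniformly inside the drawn cell, so multiple records can
    share a cell (mirroring herbarium data before thinning).  Returns a
    ``species,lon,lat`` DataFrame.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    layer = vs.true_suitability
    w = np.where(layer.valid, layer.values, 0.0).ravel()
    if bias is not None:
        if not layer.same_geometry(bias):
            raise ValueError("bias layer is not co-registered with the species grid")
        w = w * np.where(bias.valid, bias.values, 0.0).ravel()
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    rng = np.random.default_rng(seed)
    flat = rng.choice(w.size, size=n, replace=True, p=w / total)
    nr, nc = layer.shape
    i, j = np.unravel_index(flat, (nr, nc))
    u, v = rng.random(n), rng.random(n)
    lon = layer.origin_x + (j + u) * layer.cell_size
    lat = layer.origin_y - (i + v) * layer.cell_size
    return pd.DataFrame({"species": vs.species_id, "lon": lon, "lat": lat})
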