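"""Synthetic study systems with known truth.

Builds everything the niche-modelling pipeline consumes — spatially smooth
correlated environmental layers, a logistic true-suitability surface,
presence records sampled proportionally to that truth, additive climate
deltas per scenario, a Voronoi partition into climate zones, and an urban
mask — so every stage can be exercised against a ground truth without any
external download.

Environmental layers are Gaussian random fields: white noise convolved with
an isotropic Gaussian kernel (truncated at three length-scales, reflective
boundaries), then standardized to mean 0, sd 1 over valid cells. Pairwise
correlation between layers is induced by mixing a shared field into each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import EmptyDomainError, EnvGrid, GeoPoint, GridStack, write_grid

DEFAULT_ORIGIN_LON = -115.0
DEFAULT_ORIGIN_LAT = 33.0
DEFAULT_CELL_ARCMIN = 2.5


@dataclass(frozen=True)
class TrueNicheSpec:
    """The generating niche: logistic(intercept + sum coef * layer)."""

    intercept: float
    coefficients: dict[str, float]


@dataclass(frozen=True)
class ScenarioDelta:
    """An additive climate shift for one period x SSP scenario."""

    label: str
    shifts: dict[str, float]
    forcing: float

    ALLOWED_FORCINGS = (2.6, 4.5, 7.0, 8.5)

    def __post_init__(self) -> None:
        if self.forcing not in self.ALLOWED_FORCINGS:
            raise ValueError(
                f"forcing {self.forcing} not one of {self.ALLOWED_FORCINGS}"
            )


@dataclass
class SyntheticWorld:
    """A complete synthetic study system."""

    current: GridStack
    futures: list[tuple[ScenarioDelta, GridStack]]
    truth: EnvGrid
    niche: TrueNicheSpec
    occurrences: pd.DataFrame
    zones: EnvGrid
    urban_mask: EnvGrid
    seed: int


def _smooth_field(
    nrows: int, ncols: int, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    raw = rng.standard_normal((nrows, ncols))
    if smoothness > 0:
        raw = ndimage.gaussian_filter(
            raw, sigma=smoothness, mode="reflect", truncate=3.0
        )
    raw -= raw.mean()
    sd = raw.std()
    if sd > 0:
        raw /= sd
    return raw


def make_env_stack(
    nrows: int,
    ncols: int,
    layer_names: Sequence[str],
    smoothness: float = 5.0,
    seed: int = 0,
    mix_weight: float = 0.0,
    origin_lon: float = DEFAULT_ORIGIN_LON,
    origin_lat: float = DEFAULT_ORIGIN_LAT,
    cell_size: float = DEFAULT_CELL_ARCMIN,
) -> GridStack:
    """Stack of standardized smooth random fields.

    ``mix_weight`` in [0, 1] blends a single shared field into every layer
    (0 = independent layers, 1 = all layers identical), inducing positive
    cross-correlation.
    """
    if not layer_names:
        raise ValueError("layer_names must be non-empty")
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    if not (0.0 <= mix_weight <= 1.0):
        raise ValueError("mix_weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = _smooth_field(nrows, ncols, smoothness, rng)
    stack = GridStack()
    for name in layer_names:
        own = _smooth_field(nrows, ncols, smoothness, rng)
        vals = mix_weight * shared + (1.0 - mix_weight) * own
        # re-standardize after mixing
        vals = vals - vals.mean()
        sd = vals.std()
        if sd > 0:
            vals = vals / sd
        stack.add(
            name,
            EnvGrid(vals, origin_lon, origin_lat, cell_size,
                    np.zeros((nrows, ncols), dtype=bool)),
        )
    return stack


def true_suitability(stack: GridStack, spec: TrueNicheSpec) -> EnvGrid:
    """Cellwise logistic(intercept + sum coef * layer), the generating truth."""
    geom = stack.geometry
    eta = np.full(stack.shape, spec.intercept, dtype=np.float64)
    for name, coef in spec.coefficients.items():
        if name not in stack:
            raise KeyError(f"niche coefficient names unknown layer {name!r}")
        eta = eta + coef * stack[name].values
    mask = stack.combined_mask()
    with np.errstate(over="ignore"):
        suit = 1.0 / (1.0 + np.exp(-eta))
    suit[mask] = np.nan
    return EnvGrid(suit, geom.origin_lon, geom.origin_lat, geom.cell_size, mask)


def sample_occurrences(truth: EnvGrid, n: int, seed: int) -> pd.DataFrame:
    """Presence records drawn proportionally to suitability.

    Cells are drawn with probability proportional to their suitability (with
    replacement), each point jittered uniformly within its cell — the
    presence-only sampling model a maximum-entropy estimator assumes.
    """
    weights = np.where(truth.nodata_mask, 0.0, truth.values).ravel()
    weights = np.where(np.isfinite(weights), weights, 0.0)
    total = weights.sum()
    if total <= 0:
        raise EmptyDomainError("no valid cell has positive suitability")
    rng = np.random.default_rng(seed)
    cells = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    rows, cols = np.unravel_index(cells, truth.values.shape)
    cell_deg = truth.cell_deg
    u = rng.random(n)
    v = rng.random(n)
    lons = truth.origin_lon + (cols + u) * cell_deg
    lats = truth.origin_lat - (rows + v) * cell_deg
    return pd.DataFrame(
        {
            "record_id": [f"occ{i:05d}" for i in range(n)],
            "lon": lons,
            "lat": lats,
            "retained": True,
            "drop_reason": "none",
        }
    )


def make_future_stack(current: GridStack, delta: ScenarioDelta) -> GridStack:
    """Apply additive shifts to the named layers; others are copied."""
    unknown = set(delta.shifts) - set(current.layer_names)
    if unknown:
        raise KeyError(f"delta names unknown layers: {sorted(unknown)}")
    out = GridStack()
    for name, grid in current.items():
        g = grid.copy()
        if name in delta.shifts:
            g.values[~g.nodata_mask] += delta.shifts[name]
        out.add(name, g)
    return out


def make_zones(
    nrows: int,
    ncols: int,
    k: int,
    seed: int,
    origin_lon: float = DEFAULT_ORIGIN_LON,
    origin_lat: float = DEFAULT_ORIGIN_LAT,
    cell_size: float = DEFAULT_CELL_ARCMIN,
) -> EnvGrid:
    """Voronoi partition of the lattice into k zones coded 1..k."""
    ncells = nrows * ncols
    if k < 1 or k > ncells:
        raise ValueError(f"k must lie in [1, {ncells}], got {k}")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(ncells, size=k, replace=False)
    srow, scol = np.unravel_index(seeds, (nrows, ncols))
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    d2 = (rr[..., None] - srow) ** 2 + (cc[..., None] - scol) ** 2
    codes = np.argmin(d2, axis=-1) + 1
    return EnvGrid(
        codes.astype(np.float64),
        origin_lon,
        origin_lat,
        cell_size,
        np.zeros((nrows, ncols), dtype=bool),
    )


def make_urban_mask(
    nrows: int,
    ncols: int,
    n_towns: int,
    town_radius_cells: int,
    seed: int,
    origin_lon: float = DEFAULT_ORIGIN_LON,
    origin_lat: float = DEFAULT_ORIGIN_LAT,
    cell_size: float = DEFAULT_CELL_ARCMIN,
) -> EnvGrid:
    """Boolean grid (1 = urban) of circular towns at random centers."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((nrows, ncols), dtype=bool)
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    for _ in range(n_towns):
        r0 = rng.integers(nrows)
        c0 = rng.integers(ncols)
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= town_radius_cells**2
    return EnvGrid(
        mask.astype(np.float64),
        origin_lon,
        origin_lat,
        cell_size,
        np.zeros((nrows, ncols), dtype=bool),
    )


DEFAULT_LAYERS = ("temp_range", "temp_dryq", "temp_warmq",
                  "prec_season", "prec_wetq", "prec_coldq")
# Two informative layers define the niche; the rest are climate context the
# model must learn to ignore. The strongly negative intercept makes the
# species a climate specialist (suitable prevalence ~7-10% of the landscape),
# the regime where presence-background discrimination is high.
DEFAULT_NICHE = TrueNicheSpec(
    intercept=-9.0,
    coefficients={"temp_range": 5.0, "prec_season": -4.0},
)
DEFAULT_SCENARIO_GRID = [
    ("2041-2060", {"2.6": 0.15, "4.5": 0.3, "7.0": 0.45, "8.5": 0.6}),
    ("2061-2080", {"2.6": 0.2, "4.5": 0.5, "7.0": 0.8, "8.5": 1.0}),
    ("2081-2100", {"2.6": 0.2, "4.5": 0.6, "7.0": 1.1, "8.5": 1.5}),
]


def default_scenario_deltas(
    magnitude_scale: float = 1.0,
) -> list[ScenarioDelta]:
    """The 3 periods x 4 SSPs = 12 scenario ladder of additive shifts.

    Warming-type layers shift up, precipitation-regularity down, with
    magnitude growing by period and forcing — the qualitative shape of
    downscaled CMIP6 projections.
    """
    deltas = []
    for period, ssps in DEFAULT_SCENARIO_GRID:
        for ssp, mag in ssps.items():
            m = mag * magnitude_scale
            deltas.append(
                ScenarioDelta(
                    label=f"{period} SSP{ssp}",
                    shifts={
                        "temp_range": m,
                        "temp_dryq": 0.5 * m,
                        "temp_warmq": 0.5 * m,
                        "prec_season": -0.5 * m,
                    },
                    forcing=float(ssp),
                )
            )
    return deltas


def make_world(
    nrows: int = 100,
    ncols: int = 100,
    n_presences: int = 300,
    layer_names: Sequence[str] = DEFAULT_LAYERS,
    niche: TrueNicheSpec = DEFAULT_NICHE,
    smoothness: float = 5.0,
    n_zones: int = 21,
    seed: int = 0,
    deltas: Sequence[ScenarioDelta] | None = None,
) -> SyntheticWorld:
    """Assemble a full synthetic study system from one seed."""
    rng = np.random.default_rng(seed)
    s_env, s_occ, s_zone, s_urban = rng.integers(2**31, size=4)
    current = make_env_stack(nrows, ncols, list(layer_names),
                             smoothness=smoothness, seed=int(s_env))
    truth = true_suitability(current, niche)
    occ = sample_occurrences(truth, n_presences, seed=int(s_occ))
    zones = make_zones(nrows, ncols, n_zones, seed=int(s_zone))
    urban = make_urban_mask(nrows, ncols, n_towns=5,
                            town_radius_cells=2, seed=int(s_urban))
    if deltas is None:
        deltas = default_scenario_deltas()
    futures = [(d, make_future_stack(current, d)) for d in deltas]
    return SyntheticWorld(
        current=current,
        futures=futures,
        truth=truth,
        niche=niche,
        occurrences=occ,
        zones=zones,
        urban_mask=urban,
        seed=seed,
    )


def write_world(world: SyntheticWorld, out_dir: str | Path,
                format: str = "esri_ascii") -> None:
    """Write a world as grids + occurrences CSV + a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".asc" if format == "esri_ascii" else ".tif"
    for name, grid in world.current.items():
        write_grid(grid, out / f"current_{name}{suffix}", format)
    for delta, stack in world.futures:
        tag = delta.label.replace(" ", "_")
        for name, grid in stack.items():
            write_grid(grid, out / f"{tag}_{name}{suffix}", format)
    write_grid(world.truth, out / f"truth{suffix}", format)
    write_grid(world.zones, out / f"zones{suffix}", format)
    write_grid(world.urban_mask, out / f"urban_mask{suffix}", format)
    world.occurrences.to_csv(out / "occurrences.csv", index=False)
    manifest = {
        "seed": world.seed,
        "nrows": world.truth.nrows,
        "ncols": world.truth.ncols,
        "layers": world.current.layer_names,
        "niche_intercept": world.niche.intercept,
        "niche_coefficients": world.niche.coefficients,
        "scenarios": [d.label for d, _ in world.futures],
        "n_presences": int(len(world.occurrences)),
        "format": format,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
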