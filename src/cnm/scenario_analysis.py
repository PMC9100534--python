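"""Scenario projection, habitat classification, zonal overlap, and MESS.

The ensemble is projected onto current and future climate stacks; the
resulting occurrence probabilities are classified into unsuitable
(p < 0.1), moderately suitable (0.1 <= p <= 0.5) and highly suitable
(p > 0.5) habitat, summarized globally and per climate zone. Reliability of
a projection is screened with the multivariate environmental similarity
surface (MESS): per cell, each variable is scored against the calibration
reference sample,

    f = percent of reference values strictly below the cell value
    S = (p - min)/(max - min) * 100        if f = 0
        2 f                                if 0 < f <= 50
        2 (100 - f)                        if 50 < f < 100
        (max - p)/(max - min) * 100        if f = 100

and the cell's MESS value is the minimum over variables; a negative value
means at least one variable falls outside its reference range (novel
climate, extrapolated prediction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import EmptyDomainError, EnvGrid, GridStack
from .evaluation_ensemble import Ensemble, predict_grid

logger = logging.getLogger(__name__)

UNSUITABLE, MODERATE, HIGH = 0, 1, 2
CLASS_NAMES = {UNSUITABLE: "unsuitable", MODERATE: "moderate", HIGH: "high"}


def project(ensemble: Ensemble, stack: GridStack) -> EnvGrid:
    """Cellwise mean of the converged runs' logistic predictions on a stack.

    Each run's model uses its own training scalers; there is no re-fit.
    """
    grids = [
        predict_grid(r.model, stack, ensemble.variables)
        for r in ensemble.runs
        if r.model.converged
    ]
    if not grids:
        raise RuntimeError("ensemble has no converged runs")
    geom = stack.geometry
    arr = np.nanmean([g.values for g in grids], axis=0)
    mask = stack.combined_mask()
    arr[mask] = np.nan
    return EnvGrid(arr, geom.origin_lon, geom.origin_lat, geom.cell_size, mask)


def classify(prob: EnvGrid, t_low: float = 0.1, t_high: float = 0.5) -> EnvGrid:
    """Habitat classes: [0,t_low) unsuitable, [t_low,t_high] moderate, above high."""
    if not (0.0 < t_low < t_high < 1.0):
        raise ValueError("need 0 < t_low < t_high < 1")
    p = prob.values
    cls = np.where(p < t_low, UNSUITABLE, np.where(p <= t_high, MODERATE, HIGH))
    cls = cls.astype(np.float64)
    cls[prob.nodata_mask] = np.nan
    return EnvGrid(cls, prob.origin_lon, prob.origin_lat, prob.cell_size,
                   prob.nodata_mask.copy())


def class_fractions(cls: EnvGrid) -> dict[str, float]:
    """Percent of valid cells per habitat class; sums to 100."""
    valid = cls.values[~cls.nodata_mask]
    if valid.size == 0:
        raise EmptyDomainError("class grid has no valid cells")
    return {
        CLASS_NAMES[c]: 100.0 * float((valid == c).sum()) / valid.size
        for c in (HIGH, MODERATE, UNSUITABLE)
    }


def zonal_overlap(cls: EnvGrid, zones: EnvGrid) -> pd.DataFrame:
    """Per-zone percent composition of habitat classes (rows sum to 100)."""
    if not cls.same_geometry(zones):
        raise ValueError("class and zone grids must share geometry")
    both = ~cls.nodata_mask & ~zones.nodata_mask
    rows = []
    for code in np.unique(zones.values[~zones.nodata_mask]):
        sel = both & (zones.values == code)
        n = int(sel.sum())
        if n == 0:
            rows.append({"zone": code, "high_pct": np.nan,
                         "moderate_pct": np.nan, "unsuitable_pct": np.nan,
                         "n_cells": 0, "empty": True})
            continue
        vals = cls.values[sel]
        rows.append(
            {
                "zone": code,
                "high_pct": 100.0 * float((vals == HIGH).sum()) / n,
                "moderate_pct": 100.0 * float((vals == MODERATE).sum()) / n,
                "unsuitable_pct": 100.0 * float((vals == UNSUITABLE).sum()) / n,
                "n_cells": n,
                "empty": False,
            }
        )
    return pd.DataFrame(rows)


def _mess_scores(ref: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Similarity of values ``p`` to the reference sample of one variable."""
    ref = np.sort(np.asarray(ref, dtype=float))
    n = ref.size
    lo, hi = ref[0], ref[-1]
    if hi <= lo:
        raise ValueError("constant reference variable: MESS range degenerate")
    # percent of reference values strictly below p
    f = 100.0 * np.searchsorted(ref, p, side="left") / n
    span = hi - lo
    s = np.where(
        f == 0.0,
        (p - lo) / span * 100.0,
        np.where(
            f <= 50.0,
            2.0 * f,
            np.where(f < 100.0, 2.0 * (100.0 - f), (hi - p) / span * 100.0),
        ),
    )
    return s


def mess(reference: pd.DataFrame, stack: GridStack) -> EnvGrid:
    """MESS grid: per-cell minimum similarity over the reference variables."""
    variables = [c for c in reference.columns if c != "missing"]
    if len(reference) < 2:
        raise ValueError("reference needs at least 2 points")
    for v in variables:
        if v not in stack:
            raise KeyError(f"variable {v!r} not in stack")
    mask = stack.subset(variables).combined_mask()
    rows, cols = np.nonzero(~mask)
    out = np.full(stack.shape, np.nan)
    m = np.full(rows.size, np.inf)
    for v in variables:
        p = stack[v].values[rows, cols]
        m = np.minimum(m, _mess_scores(reference[v].to_numpy(), p))
    out[rows, cols] = m
    geom = stack.geometry
    return EnvGrid(out, geom.origin_lon, geom.origin_lat, geom.cell_size, mask)


def integrate_mess(per_run_mess: Sequence[EnvGrid]) -> tuple[EnvGrid, EnvGrid]:
    """Cellwise mean of per-run MESS grids and the negative-sign grid.

    A cell is flagged novel when the mean MESS is strictly negative (a mean
    of exactly 0 counts as non-negative).
    """
    if not per_run_mess:
        raise ValueError("need at least one MESS grid")
    ref = per_run_mess[0]
    for g in per_run_mess[1:]:
        if not g.same_geometry(ref):
            raise ValueError("MESS grids are not aligned")
    arr = np.nanmean([g.values for g in per_run_mess], axis=0)
    mask = np.logical_or.reduce([g.nodata_mask for g in per_run_mess])
    arr = arr.copy()
    arr[mask] = np.nan
    mean = EnvGrid(arr, ref.origin_lon, ref.origin_lat, ref.cell_size, mask)
    sign = np.where(arr < 0.0, 1.0, 0.0)
    sign[mask] = np.nan
    sign_grid = EnvGrid(sign, ref.origin_lon, ref.origin_lat,
                        ref.cell_size, mask.copy())
    return mean, sign_grid


def suitable_negative_overlap(cls: EnvGrid, mess_sign: EnvGrid) -> float:
    """Percent of suitable (moderate+high) cells falling on negative MESS."""
    if not cls.same_geometry(mess_sign):
        raise ValueError("grids must share geometry")
    both = ~cls.nodata_mask & ~mess_sign.nodata_mask
    suitable = both & (cls.values >= MODERATE)
    n = int(suitable.sum())
    if n == 0:
        logger.warning("no suitable cells; overlap undefined")
        return float("nan")
    neg = suitable & (mess_sign.values > 0)
    return 100.0 * int(neg.sum()) / n


@dataclass
class ScenarioResult:
    """One scenario's projection summary (a Table-2-shaped row)."""

    label: str
    forcing: float | None
    probability: EnvGrid
    classes: EnvGrid
    fractions: dict[str, float]
    mess_mean: EnvGrid | None = None
    mess_sign: EnvGrid | None = None
    negative_overlap_pct: float | None = None


def analyse_scenario(
    ensemble: Ensemble,
    stack: GridStack,
    label: str,
    forcing: float | None = None,
    t_low: float = 0.1,
    t_high: float = 0.5,
    run_mess: bool = True,
) -> ScenarioResult:
    """Project, classify and MESS-screen one scenario stack.

    The MESS reference for each run is that run's training presences plus the
    shared background sample; the per-run MESS grids are integrated by mean.
    """
    prob = project(ensemble, stack)
    cls = classify(prob, t_low, t_high)
    fractions = class_fractions(cls)
    mess_mean = mess_sign = None
    overlap = None
    if run_mess:
        # all runs share the background; training-presence part varies per run
        per_run = []
        pres_lookup = _presence_table_lookup(ensemble)
        for r in ensemble.runs:
            if not r.model.converged:
                continue
            ref = pd.concat(
                [ensemble.background_table[ensemble.variables],
                 pres_lookup.loc[
                     pres_lookup.index.intersection(r.train_ids)
                 ][ensemble.variables]],
                ignore_index=True,
            )
            per_run.append(mess(ref, stack.subset(ensemble.variables)))
        mess_mean, mess_sign = integrate_mess(per_run)
        overlap = suitable_negative_overlap(cls, mess_sign)
    return ScenarioResult(
        label=label,
        forcing=forcing,
        probability=prob,
        classes=cls,
        fractions=fractions,
        mess_mean=mess_mean,
        mess_sign=mess_sign,
        negative_overlap_pct=overlap,
    )


def _presence_table_lookup(ensemble: Ensemble) -> pd.DataFrame:
    """Training-presence environment values indexed by record id.

    Ensembles built by `run_ensemble` carry this; hand-built ones must set
    ``ensemble.presence_table`` (record-id index, variable columns).
    """
    table = ensemble.presence_table
    if table is None:
        raise ValueError("ensemble lacks a presence table for MESS references")
    return table


def scenario_summary(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Table of class fractions and negative-MESS overlap per scenario."""
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.label,
                "forcing": r.forcing,
                "high_pct": r.fractions["high"],
                "moderate_pct": r.fractions["moderate"],
                "unsuitable_pct": r.fractions["unsuitable"],
                "negative_mess_overlap_pct": r.negative_overlap_pct,
            }
        )
    return pd.DataFrame(rows)
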