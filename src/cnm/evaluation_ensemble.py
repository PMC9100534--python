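"""Model evaluation and bootstrap ensembling.

The niche model is calibrated many times (default 100) on bootstrap
replicates of the presence data; each run is validated with the area under
the ROC curve against the background sample, and the per-run probability
grids are integrated cellwise into a single ensemble prediction. Variable
importance comes from two complementary views: permutation importance
(AUC drop when a variable's values are shuffled across evaluation points)
and the jackknife of training gain (a with-only and a without model per
variable, compared to the full model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import EnvGrid, GridStack, extract_values
from .maxent_core import (
    AUTO_FEATURE_MIN_PRESENCES,
    DEFAULT_FEATURE_KINDS,
    REDUCED_FEATURE_KINDS,
    MaxentModel,
    build_features,
    fit_maxent,
    predict_raw,
    sample_background,
    to_logistic,
    training_gain,
)
from .occurrences import retained_points

logger = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    """Calibration settings for a bootstrap ensemble."""

    n_runs: int = 100
    train_fraction: float = 0.75
    background_n: int = 10000
    reg_multiplier: float = 1.0
    feature_kinds: tuple[str, ...] | None = None  # None = auto by presence count
    n_hinge_knots: int = 10
    max_iter: int = 1500
    tol: float = 1e-5
    replicate_mode: str = "bootstrap"  # bootstrap (out-of-bag test) | subsample


@dataclass
class EnsembleRun:
    model: MaxentModel
    train_ids: list[str]
    test_ids: list[str]
    test_auc: float


@dataclass
class Ensemble:
    runs: list[EnsembleRun]
    integrated: EnvGrid
    auc_mean: float
    auc_se: float
    variables: list[str]
    background_table: pd.DataFrame
    # record-id-indexed environment values of the presences (MESS references)
    presence_table: pd.DataFrame | None = None

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": np.arange(1, len(self.runs) + 1),
                "test_auc": [r.test_auc for r in self.runs],
                "converged": [r.model.converged for r in self.runs],
                "n_train": [len(r.train_ids) for r in self.runs],
                "n_test": [len(r.test_ids) for r in self.runs],
            }
        )


def split_presences(
    occ: pd.DataFrame, train_fraction: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive random split of retained presence ids."""
    ids = sorted(occ.loc[occ["retained"], "record_id"])
    n = len(ids)
    if n < 4:
        raise ValueError(f"need at least 4 retained presences, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = round(train_fraction * n)
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann-Whitney concordance: P(presence > background) + 0.5 P(tie).

    Computed from midranks of the pooled scores, equivalent to the all-pairs
    count but O(n log n).
    """
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _auto_kinds(n_presences: int) -> tuple[str, ...]:
    if n_presences >= AUTO_FEATURE_MIN_PRESENCES:
        return DEFAULT_FEATURE_KINDS
    return REDUCED_FEATURE_KINDS


def _fit_one(
    train_table: pd.DataFrame,
    bg_table: pd.DataFrame,
    variables: Sequence[str],
    config: EnsembleConfig,
) -> MaxentModel:
    kinds = config.feature_kinds or _auto_kinds(len(train_table))
    # presences are part of the background (presence-background convention)
    fit_bg = pd.concat(
        [bg_table[list(variables)], train_table[list(variables)]],
        ignore_index=True,
    )
    expansion, bg_feats = build_features(
        fit_bg, kinds=kinds, n_hinge_knots=config.n_hinge_knots
    )
    pres_feats = expansion.transform(train_table[list(variables)])
    bg_means = {v: float(fit_bg[v].mean()) for v in variables}
    return fit_maxent(
        pres_feats,
        bg_feats,
        expansion=expansion,
        reg_multiplier=config.reg_multiplier,
        max_iter=config.max_iter,
        tol=config.tol,
        background_means=bg_means,
    )


def predict_grid(
    model: MaxentModel, stack: GridStack, variables: Sequence[str]
) -> EnvGrid:
    """Project a single model onto a stack as a logistic probability grid."""
    mask = stack.combined_mask()
    rows, cols = np.nonzero(~mask)
    table = pd.DataFrame(
        {v: stack[v].values[rows, cols] for v in variables}
    )
    p = to_logistic(model, predict_raw(model, model.expansion.transform(table)))
    geom = stack.geometry
    out = np.full(stack.shape, np.nan)
    out[rows, cols] = p
    return EnvGrid(out, geom.origin_lon, geom.origin_lat, geom.cell_size, mask)


def run_ensemble(
    occ: pd.DataFrame,
    stack: GridStack,
    variables: Sequence[str],
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> Ensemble:
    """Bootstrap-calibrate the model ``config.n_runs`` times and integrate.

    Each run draws its training presences with replacement (size = the train
    fraction of n); presences never drawn form the out-of-bag test set. In
    ``subsample`` mode a plain disjoint split is used instead. Runs that fail
    to converge are flagged and excluded from the integration. The test AUC
    scores out-of-bag presences against the shared background sample.
    """
    config = config or EnsembleConfig()
    variables = list(variables)
    for v in variables:
        if v not in stack:
            raise KeyError(f"variable {v!r} not in stack")
    rng = np.random.default_rng(seed)
    bg_seed = int(rng.integers(2**31))
    _, _, bg_table = sample_background(
        stack.subset(variables), config.background_n, bg_seed
    )
    pts = retained_points(occ)
    ids = occ.loc[occ["retained"], "record_id"].tolist()
    table = extract_values(stack.subset(variables), pts)
    table["record_id"] = ids
    table = table[~table["missing"]].reset_index(drop=True)
    n = len(table)
    if n < 4:
        raise ValueError("too few presences on valid cells")

    runs: list[EnsembleRun] = []
    grids: list[EnvGrid] = []
    id_arr = table["record_id"].to_numpy()
    for _ in range(config.n_runs):
        run_seed = int(rng.integers(2**31))
        run_rng = np.random.default_rng(run_seed)
        n_train = round(config.train_fraction * n)
        if config.replicate_mode == "bootstrap":
            draw = run_rng.integers(n, size=n_train)
            train_idx = draw
            test_mask = np.ones(n, dtype=bool)
            test_mask[np.unique(draw)] = False
            test_idx = np.flatnonzero(test_mask)
        elif config.replicate_mode == "subsample":
            perm = run_rng.permutation(n)
            train_idx = perm[:n_train]
            test_idx = perm[n_train:]
        else:
            raise ValueError(f"unknown replicate_mode {config.replicate_mode!r}")
        train_table = table.iloc[train_idx][variables].reset_index(drop=True)
        model = _fit_one(train_table, bg_table, variables, config)
        if test_idx.size:
            test_table = table.iloc[test_idx][variables]
            pres_scores = to_logistic(
                model, predict_raw(model, model.expansion.transform(test_table))
            )
            bg_scores = to_logistic(
                model,
                predict_raw(model, model.expansion.transform(bg_table[variables])),
            )
            run_auc = auc(pres_scores, bg_scores)
        else:
            run_auc = float("nan")
        run = EnsembleRun(
            model=model,
            train_ids=[str(id_arr[i]) for i in train_idx],
            test_ids=[str(id_arr[i]) for i in test_idx],
            test_auc=run_auc,
        )
        runs.append(run)
        if model.converged:
            grids.append(predict_grid(model, stack, variables))
        else:
            logger.warning("run %d not converged; excluded from integration",
                           len(runs))

    if not grids:
        raise RuntimeError("no ensemble run converged")
    geom = stack.geometry
    arr = np.nanmean([g.values for g in grids], axis=0)
    mask = stack.combined_mask()
    integrated = EnvGrid(arr, geom.origin_lon, geom.origin_lat,
                         geom.cell_size, mask)
    aucs = np.array([r.test_auc for r in runs
                     if r.model.converged and np.isfinite(r.test_auc)])
    auc_mean = float(aucs.mean())
    auc_se = float(aucs.std(ddof=1) / np.sqrt(aucs.size)) if aucs.size > 1 else 0.0
    return Ensemble(
        runs=runs,
        integrated=integrated,
        auc_mean=auc_mean,
        auc_se=auc_se,
        variables=variables,
        background_table=bg_table,
        presence_table=table.set_index("record_id")[variables],
    )


def permutation_contribution(
    model: MaxentModel,
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    n_perm: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable percent contribution by permutation importance.

    For each variable, its values are shuffled jointly across the pooled
    presence + background evaluation rows; the drop in AUC relative to the
    unpermuted model, averaged over ``n_perm`` shuffles, floored at zero and
    normalized to sum to 100, is the variable's contribution.
    """
    variables = model.expansion.variable_names
    rng = np.random.default_rng(seed)

    def scores(ptab: pd.DataFrame, btab: pd.DataFrame) -> float:
        sp = predict_raw(model, model.expansion.transform(ptab))
        sb = predict_raw(model, model.expansion.transform(btab))
        return auc(sp, sb)

    base = scores(presence_table, background_table)
    n_pres = len(presence_table)
    drops = {}
    for v in variables:
        pooled = np.concatenate(
            [presence_table[v].to_numpy(), background_table[v].to_numpy()]
        )
        d = []
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            ptab = presence_table.copy()
            btab = background_table.copy()
            ptab[v] = perm[:n_pres]
            btab[v] = perm[n_pres:]
            d.append(base - scores(ptab, btab))
        drops[v] = max(0.0, float(np.mean(d)))
    total = sum(drops.values())
    if total == 0:
        logger.warning("no AUC drop for any variable; uniform shares reported")
        shares = {v: 100.0 / len(variables) for v in variables}
    else:
        shares = {v: 100.0 * d / total for v, d in drops.items()}
    return pd.DataFrame(
        {"variable": variables,
         "auc_drop": [drops[v] for v in variables],
         "contribution_pct": [shares[v] for v in variables]}
    )


@dataclass
class JackknifeReport:
    full_gain: float
    per_variable: pd.DataFrame  # variable, gain_with_only, gain_without


def jackknife_gains(
    occ: pd.DataFrame,
    stack: GridStack,
    variables: Sequence[str],
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> JackknifeReport:
    """Jackknife of training gain: with-only and without model per variable.

    A variable matters individually when its with-only gain is high, and is
    irreplaceable when the model without it loses gain relative to the full
    model. All sub-models share the training presences and background sample.
    """
    config = config or EnsembleConfig()
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    rng = np.random.default_rng(seed)
    bg_seed = int(rng.integers(2**31))
    _, _, bg_table = sample_background(
        stack.subset(variables), config.background_n, bg_seed
    )
    pts = retained_points(occ)
    table = extract_values(stack.subset(variables), pts)
    table = table[~table["missing"]].reset_index(drop=True)

    def gain_for(vs: list[str]) -> float:
        model = _fit_one(table[vs], bg_table, vs, config)
        pres = model.expansion.transform(table[vs])
        return training_gain(model, pres)

    full = gain_for(variables)
    rows = []
    for v in variables:
        rest = [w for w in variables if w != v]
        rows.append(
            {
                "variable": v,
                "gain_with_only": gain_for([v]),
                "gain_without": gain_for(rest),
            }
        )
    return JackknifeReport(full_gain=full, per_variable=pd.DataFrame(rows))
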