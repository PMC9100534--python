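"""L1-regularized maximum-entropy presence-background niche model.

The model estimates a Gibbs distribution over the study region's background
cells,

    q_lambda(x) = exp(sum_j lambda_j f_j(x)) / Z,

where the f_j are features derived from the environmental variables (linear,
quadratic, pairwise-product and hinge expansions, affinely scaled to [0, 1]
on the training data). The weights minimize the regularized negative mean
presence log-likelihood

    -mean_presences[lambda . f] + log Z + sum_j beta_j |lambda_j|,

a convex objective whose optimum satisfies the KKT conditions
|mean_presence[f_j] - E_q[f_j]| <= beta_j for every feature, with equality
(signed) whenever lambda_j is non-zero. The L1 penalty beta_j scales with
the feature's presence standard deviation and shrinks as 1/sqrt(m) with the
presence count m, so the feature-expectation constraints tighten as data
accumulate.

Fitting uses monotone FISTA (accelerated proximal gradient with
soft-thresholding and backtracking line search), terminating on the maximum
KKT violation. The raw Gibbs weights are mapped to an occurrence-probability
scale with the logistic transform p = e^H r / (1 + e^H r), where H is the
entropy of the fitted distribution over the background: a cell that looks
like a typical presence scores about 0.5, matching the default-prevalence
convention of MaxEnt-style software.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grids import EnvGrid, GridStack

logger = logging.getLogger(__name__)

DEFAULT_FEATURE_KINDS = ("linear", "quadratic", "product", "hinge")
REDUCED_FEATURE_KINDS = ("linear", "quadratic")
# Presence counts below this use the reduced feature set (auto-feature rule).
AUTO_FEATURE_MIN_PRESENCES = 80
# Per-class regularization constants.
CLASS_BETA = {"linear": 1.0, "quadratic": 1.0, "product": 1.0, "hinge": 0.5}
_BETA_FLOOR = 1e-6


@dataclass(frozen=True)
class Feature:
    """One term of the expansion."""

    name: str
    kind: str  # linear | quadratic | product | hinge
    variables: tuple[str, ...]
    knot: float | None = None


@dataclass
class FeatureExpansion:
    """Feature definitions plus the training scalers that ground them.

    ``var_stats`` maps each variable to its training (min, max); linear,
    quadratic and product features act on the affinely scaled variable
    (x - min)/(max - min), hinge features on the raw variable with knots in
    the training range. No clamping is applied on projection.
    """

    features: list[Feature]
    var_stats: dict[str, tuple[float, float]]

    @property
    def variable_names(self) -> list[str]:
        return list(self.var_stats)

    def _scaled(self, df: pd.DataFrame, var: str) -> np.ndarray:
        lo, hi = self.var_stats[var]
        x = df[var].to_numpy(dtype=float)
        return (x - lo) / (hi - lo)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        """Feature matrix for a points x variables table."""
        missing = [v for v in self.var_stats if v not in df.columns]
        if missing:
            raise KeyError(f"table lacks variables {missing}")
        cols = []
        for f in self.features:
            if f.kind == "linear":
                cols.append(self._scaled(df, f.variables[0]))
            elif f.kind == "quadratic":
                cols.append(self._scaled(df, f.variables[0]) ** 2)
            elif f.kind == "product":
                cols.append(
                    self._scaled(df, f.variables[0])
                    * self._scaled(df, f.variables[1])
                )
            elif f.kind == "hinge":
                var = f.variables[0]
                _, hi = self.var_stats[var]
                x = df[var].to_numpy(dtype=float)
                cols.append(np.maximum(0.0, (x - f.knot) / (hi - f.knot)))
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {f.kind!r}")
        return np.column_stack(cols) if cols else np.empty((len(df), 0))


def build_features(
    values: pd.DataFrame,
    kinds: Sequence[str] = DEFAULT_FEATURE_KINDS,
    n_hinge_knots: int = 10,
) -> tuple[FeatureExpansion, np.ndarray]:
    """Build the expansion from training data and return its matrix.

    Constant variables are dropped with a warning (their features carry no
    information); hinge knots are spaced evenly over [min, max) so the
    degenerate knot-at-max feature never arises.
    """
    if not len(kinds):
        raise ValueError("kinds must be non-empty")
    df = values.drop(columns=["missing"], errors="ignore")
    if df.shape[1] < 1:
        raise ValueError("need at least one variable")
    var_stats: dict[str, tuple[float, float]] = {}
    for var in df.columns:
        lo = float(df[var].min())
        hi = float(df[var].max())
        if hi <= lo:
            logger.warning("variable %s is constant; features dropped", var)
            continue
        var_stats[var] = (lo, hi)
    variables = list(var_stats)
    feats: list[Feature] = []
    if "linear" in kinds:
        feats += [Feature(v, "linear", (v,)) for v in variables]
    if "quadratic" in kinds:
        feats += [Feature(f"{v}^2", "quadratic", (v,)) for v in variables]
    if "product" in kinds:
        for i, a in enumerate(variables):
            for b in variables[i + 1:]:
                feats.append(Feature(f"{a}*{b}", "product", (a, b)))
    if "hinge" in kinds:
        for v in variables:
            lo, hi = var_stats[v]
            knots = np.linspace(lo, hi, n_hinge_knots + 1)[:-1]
            for k in knots:
                feats.append(
                    Feature(f"hinge({v},{k:.6g})", "hinge", (v,), float(k))
                )
    expansion = FeatureExpansion(feats, var_stats)
    return expansion, expansion.transform(df)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy niche model.

    log_z and entropy refer to the training background, which defines the
    normalization of the raw output everywhere the model is projected.
    """

    expansion: FeatureExpansion
    weights: np.ndarray
    betas: np.ndarray
    log_z: float
    entropy: float
    n_background: int
    background_means: dict[str, float]
    converged: bool = True
    n_iter: int = 0

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "features": [
                {"name": f.name, "kind": f.kind,
                 "variables": list(f.variables), "knot": f.knot}
                for f in self.expansion.features
            ],
            "var_stats": {k: list(v) for k, v in self.expansion.var_stats.items()},
            "weights": self.weights.tolist(),
            "betas": self.betas.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_background": self.n_background,
            "background_means": self.background_means,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        doc = json.loads(text)
        expansion = FeatureExpansion(
            [
                Feature(f["name"], f["kind"], tuple(f["variables"]), f["knot"])
                for f in doc["features"]
            ],
            {k: (v[0], v[1]) for k, v in doc["var_stats"].items()},
        )
        return cls(
            expansion=expansion,
            weights=np.asarray(doc["weights"], dtype=float),
            betas=np.asarray(doc["betas"], dtype=float),
            log_z=doc["log_z"],
            entropy=doc["entropy"],
            n_background=doc["n_background"],
            background_means=doc["background_means"],
            converged=doc["converged"],
            n_iter=doc["n_iter"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        return cls.from_json(Path(path).read_text())


def default_betas(
    presence_features: np.ndarray,
    expansion: FeatureExpansion,
    reg_multiplier: float = 1.0,
) -> np.ndarray:
    """Per-feature L1 penalties: multiplier * class constant * s_j / sqrt(m)."""
    m = presence_features.shape[0]
    s = presence_features.std(axis=0, ddof=0)
    consts = np.array([CLASS_BETA[f.kind] for f in expansion.features])
    return np.maximum(reg_multiplier * consts * s / np.sqrt(m), _BETA_FLOOR)


def _kkt_violation(grad: np.ndarray, lam: np.ndarray, betas: np.ndarray) -> float:
    """Max violation of the subgradient optimality conditions."""
    if lam.size == 0:
        return 0.0
    v = np.where(
        lam > 0, np.abs(grad + betas),
        np.where(lam < 0, np.abs(grad - betas),
                 np.maximum(0.0, np.abs(grad) - betas)),
    )
    return float(v.max())


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    expansion: FeatureExpansion | None = None,
    reg_multiplier: float = 1.0,
    betas: np.ndarray | None = None,
    max_iter: int = 1500,
    tol: float = 1e-5,
    background_means: dict[str, float] | None = None,
) -> MaxentModel:
    """Fit the Gibbs weights by monotone accelerated proximal gradient.

    The smooth part g(lambda) = -pbar.lambda + logsumexp(B lambda) is convex
    with Lipschitz gradient; the L1 part is handled by soft-thresholding.
    The accepted iterate never increases the objective (monotone FISTA), and
    iteration stops when the maximum KKT violation drops below ``tol``. If
    ``max_iter`` is reached first the best iterate is returned with
    ``converged=False``.
    """
    P = np.asarray(presence_features, dtype=float)
    B = np.asarray(background_features, dtype=float)
    if P.ndim != 2 or B.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if P.shape[0] < 1 or B.shape[0] < 2:
        raise ValueError("need >=1 presence and >=2 background rows")
    n_bg, n_feat = B.shape
    if betas is None:
        if expansion is not None:
            betas = default_betas(P, expansion, reg_multiplier)
        else:
            betas = np.maximum(
                reg_multiplier * P.std(axis=0) / np.sqrt(P.shape[0]),
                _BETA_FLOOR,
            )
    betas = np.asarray(betas, dtype=float)
    pbar = P.mean(axis=0)

    def l1(lam: np.ndarray) -> float:
        # convention: an infinite penalty on a zero weight contributes 0
        nz = lam != 0.0
        return float(np.sum(betas[nz] * np.abs(lam[nz])))

    def smooth(lam: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        scores = B @ lam
        lz = logsumexp(scores)
        q = np.exp(scores - lz)
        g = -float(pbar @ lam) + float(lz)
        grad = -pbar + B.T @ q
        return g, grad, q

    def objective(lam: np.ndarray) -> float:
        scores = B @ lam
        return -float(pbar @ lam) + float(logsumexp(scores)) + l1(lam)

    lam = np.zeros(n_feat)
    x_prev = lam.copy()
    y = lam.copy()
    t_prev = 1.0
    L = 1.0
    f_best = objective(lam)
    lam_best = lam.copy()
    n_iter = 0
    converged = n_feat == 0

    for n_iter in range(1, max_iter + 1):
        g_y, grad_y, _ = smooth(y)
        # backtracking on the smooth majorization
        while True:
            z = y - grad_y / L
            z = np.sign(z) * np.maximum(np.abs(z) - betas / L, 0.0)
            diff = z - y
            g_z = smooth(z)[0]
            if g_z <= g_y + grad_y @ diff + 0.5 * L * diff @ diff + 1e-12:
                break
            L *= 2.0
        f_z = g_z + l1(z)
        # monotone step: keep the better of the proximal point and previous x
        if f_z <= f_best:
            x = z
            f_best = f_z
        else:
            x = lam_best
        lam_best = x
        t = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_prev**2))
        y = x + (t_prev / t) * (z - x) + ((t_prev - 1.0) / t) * (x - x_prev)
        x_prev, t_prev = x, t
        _, grad_x, _ = smooth(x)
        if _kkt_violation(grad_x, x, betas) <= tol:
            converged = True
            break
        L = max(L / 1.5, 1e-6)  # gentle step recovery

    lam = lam_best
    scores = B @ lam if n_feat else np.zeros(n_bg)
    log_z = float(logsumexp(scores))
    logq = scores - log_z
    entropy = float(-(np.exp(logq) @ logq))
    if not converged:
        logger.warning(
            "maxent fit not converged after %d iterations (KKT %.2e)",
            max_iter, _kkt_violation(smooth(lam)[1], lam, betas),
        )
    if expansion is None:
        expansion = FeatureExpansion([], {})
    return MaxentModel(
        expansion=expansion,
        weights=lam,
        betas=betas,
        log_z=log_z,
        entropy=entropy,
        n_background=n_bg,
        background_means=background_means or {},
        converged=converged,
        n_iter=n_iter,
    )


def predict_raw(model: MaxentModel, features: np.ndarray) -> np.ndarray:
    """Raw Gibbs weights exp(lambda.f - log Z); sum to 1 over the background."""
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[1] != model.weights.size:
        raise ValueError(
            f"feature matrix has {F.shape[1] if F.ndim == 2 else '?'} columns, "
            f"model expects {model.weights.size}"
        )
    return np.exp(F @ model.weights - model.log_z)


def to_logistic(model: MaxentModel, raw: np.ndarray | float) -> np.ndarray:
    """Occurrence probability p = e^H r / (1 + e^H r), increasing in raw."""
    r = np.asarray(raw, dtype=float)
    er = np.exp(model.entropy) * r
    return er / (1.0 + er)


def predict_logistic(model: MaxentModel, table: pd.DataFrame) -> np.ndarray:
    """Occurrence probabilities for a points x variables table."""
    return to_logistic(model, predict_raw(model, model.expansion.transform(table)))


def training_gain(model: MaxentModel, presence_features: np.ndarray) -> float:
    """Regularized improvement of mean presence log-likelihood over uniform.

    gain = mean_presences[log(N * raw)] - sum_j beta_j |lambda_j|; the
    uniform (all-zero-weight) model scores exactly 0.
    """
    P = np.asarray(presence_features, dtype=float)
    loglik = P @ model.weights - model.log_z + np.log(model.n_background)
    nz = model.weights != 0.0
    penalty = float(np.sum(model.betas[nz] * np.abs(model.weights[nz])))
    return float(loglik.mean() - penalty)


def response_curve(
    model: MaxentModel, variable: str, n_points: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: sweep one variable, others at background means."""
    if variable not in model.expansion.var_stats:
        raise KeyError(f"unknown variable {variable!r}")
    lo, hi = model.expansion.var_stats[variable]
    xs = np.linspace(lo, hi, n_points)
    table = pd.DataFrame(
        {
            v: np.full(n_points, model.background_means.get(v, 0.0))
            for v in model.expansion.variable_names
        }
    )
    table[variable] = xs
    return xs, predict_logistic(model, table)


def sample_background(
    stack: GridStack, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Background cells drawn without replacement from the valid study region.

    Returns (rows, cols, value table). If fewer than ``n`` valid cells exist,
    all of them are used.
    """
    mask = stack.combined_mask()
    valid = np.flatnonzero(~mask.ravel())
    if valid.size == 0:
        raise ValueError("study region has no valid cells")
    rng = np.random.default_rng(seed)
    if valid.size <= n:
        chosen = valid
    else:
        chosen = rng.choice(valid, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, stack.shape)
    table = pd.DataFrame(
        {name: stack[name].values[rows, cols] for name in stack.layer_names}
    )
    return rows, cols, table
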