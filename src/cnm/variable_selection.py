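"""Redundancy pruning of candidate bioclimatic variables.

Niche models overpredict when calibrated with redundant environmental
variables, so candidates are screened pairwise with Spearman rank
correlation at the occurrence points and pruned: on the graph whose edges
join pairs with |rho| above the threshold (default 0.60), the variable with
the most strong correlations is retained and its neighbours dropped,
iterating until no edges remain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho matrix with unit diagonal.

    Entries involving a constant column are NaN (rank correlation undefined).
    """

    names: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.names)
        if self.rho.shape != (n, n):
            raise ValueError("matrix shape must match variable names")
        finite = np.isfinite(self.rho)
        if not np.allclose(self.rho[finite], self.rho.T[finite.T], atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.names, columns=self.names)


def spearman_matrix(values: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman rho over a points x variables table.

    Missing-flagged rows (a ``missing`` column, if present) are excluded;
    remaining NaNs are handled pairwise-complete. Constant columns yield
    NaN correlations with a warning.
    """
    df = values.copy()
    if "missing" in df.columns:
        df = df.loc[~df["missing"].astype(bool)].drop(columns=["missing"])
    names = list(df.columns)
    k = len(names)
    if len(df) < 3:
        raise ValueError("need at least 3 complete rows")
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            pair = df.iloc[:, [i, j]].dropna()
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                logger.warning(
                    "constant column in pair (%s, %s); rho undefined",
                    names[i], names[j],
                )
                rho[i, j] = rho[j, i] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = stats.spearmanr(x, y).statistic
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(names, rho)


def select_variables(
    corr: CorrelationMatrix,
    threshold: float = 0.60,
    use_absolute: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Iterative degree-based pruning of the strong-correlation graph.

    Repeatedly retain the variable with the highest number of strong
    correlations (|rho| > threshold; ties broken alphabetically), drop its
    neighbours, and remove all of them from the graph; isolated variables
    are retained. The retained set is an independent set of the threshold
    graph: no retained pair is strongly correlated.

    Returns the retained names (in original column order) and a report frame
    with columns variable/retained/cause.
    """
    names = list(corr.names)
    r = np.abs(corr.rho) if use_absolute else corr.rho
    edges = np.zeros_like(r, dtype=bool)
    finite = np.isfinite(r)
    edges[finite] = r[finite] > threshold
    np.fill_diagonal(edges, False)

    active = set(names)
    status: dict[str, tuple[bool, str]] = {}
    idx = {n: i for i, n in enumerate(names)}
    while True:
        degrees = {
            n: int(edges[idx[n], [idx[m] for m in active]].sum())
            for n in active
        }
        if not degrees or max(degrees.values()) == 0:
            break
        best = min(
            (n for n in active if degrees[n] == max(degrees.values()))
        )  # alphabetical tie-break
        neighbours = [
            m for m in active if m != best and edges[idx[best], idx[m]]
        ]
        status[best] = (True, "hub")
        for m in neighbours:
            status[m] = (False, f"correlated with {best}")
        active -= {best, *neighbours}
    for n in active:
        status[n] = (True, "independent")

    retained = [n for n in names if status[n][0]]
    report = pd.DataFrame(
        {
            "variable": names,
            "retained": [status[n][0] for n in names],
            "cause": [status[n][1] for n in names],
        }
    )
    return retained, report
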