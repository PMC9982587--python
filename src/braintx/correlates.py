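"""Spatial transcriptional correlates: per-gene Spearman screening.

Each gene's regional expression profile is rank-correlated with a target
map (funcPC1 or the GMV effect map); significance uses the t approximation
t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 df, except at very small n
(< 10 regions) where an exact permutation p is computed. Bonferroni
correction over the gene universe splits the significant genes into
positive and negative sets per target.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_N_MAX = 10  # below this, exact permutation p values are used

POSITIVE = "positive-significant"
NEGATIVE = "negative-significant"
NONSIG = "non-significant"


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def _spearman_r_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return float((rx * ry).sum() / denom)


def _t_approx_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation; |r| = 1 maps to p = 0."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def _exact_perm_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p over all orderings of y."""
    rx = _rank(x)
    ry = _rank(y)
    n = len(x)
    count = 0
    total = 0
    thresh = abs(r_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = _spearman_r_from_ranks(rx, ry[list(perm)])
        total += 1
        if abs(r) >= thresh:
            count += 1
    return count / total


def spearman(x, y, exact_max_n: int = EXACT_N_MAX) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and a two-sided p.

    For n < ``exact_max_n`` the p value is an exact permutation tail; for
    larger n the standard t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    r = _spearman_r_from_ranks(_rank(x), _rank(y))
    if abs(r) >= 1.0 - 1e-12:
        p = 0.0
    elif len(x) < exact_max_n:
        p = _exact_perm_p(x, y, r)
    else:
        p = float(_t_approx_p(np.array([r]), len(x))[0])
    return r, p


@dataclass
class CorrelateResult:
    table: pd.DataFrame   # gene, r_s, p, class, target
    target: str
    n_genes: int
    alpha: float


def gene_correlates(
    X: pd.DataFrame,
    target: pd.Series,
    target_name: str | None = None,
    alpha: float = 0.05,
) -> CorrelateResult:
    """Spearman correlation of every gene's regional profile with a target map.

    Regions must be identical and aligned between the expression matrix and
    the target (misalignment is an error, never fixed by silent reordering).
    Vectorized over genes; p values match :func:`spearman` at n >= 10.
    """
    if target_name is None:
        target_name = target.name or "target"
    if list(X.index) != list(target.index):
        raise ValueError(
            "region mismatch between expression matrix and target map; "
            "indices must be identical and in the same order"
        )
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 regions")

    ry = _rank(target.to_numpy(float))
    ry = (ry - ry.mean()) / ry.std(ddof=0)
    R = _rank(X.to_numpy(float))
    sd = R.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = list(X.columns[sd == 0])
        raise ValueError(f"constant expression for genes: {bad[:10]}")
    Rz = (R - R.mean(axis=0)) / sd
    r = (Rz * ry[:, None]).mean(axis=0)
    r = np.clip(r, -1.0, 1.0)
    p = _t_approx_p(r, n)

    G = X.shape[1]
    thr = alpha / G
    cls = np.where(
        (p < thr) & (r > 0), POSITIVE, np.where((p < thr) & (r < 0), NEGATIVE, NONSIG)
    )
    table = pd.DataFrame(
        {"gene": X.columns, "r_s": r, "p": p, "class": cls, "target": target_name}
    )
    return CorrelateResult(table=table, target=target_name, n_genes=G, alpha=alpha)


def select_significant(
    results: CorrelateResult | list[CorrelateResult],
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> dict[str, set[str]]:
    """Bonferroni-selected gene sets, keyed ``"<target>+"`` / ``"<target>-"``.

    The per-gene threshold is alpha / G with G the gene universe of each
    target's screen (each target is corrected as its own family).
    """
    if method != "bonferroni":
        raise ValueError("only bonferroni selection is supported")
    if isinstance(results, CorrelateResult):
        results = [results]
    out: dict[str, set[str]] = {}
    for res in results:
        thr = alpha / res.n_genes
        tab = res.table
        pos = set(tab.loc[(tab["p"] < thr) & (tab["r_s"] > 0), "gene"])
        neg = set(tab.loc[(tab["p"] < thr) & (tab["r_s"] < 0), "gene"])
        out[f"{res.target}+"] = pos
        out[f"{res.target}-"] = neg
    return out


__all__ = [
    "NEGATIVE",
    "NONSIG",
    "POSITIVE",
    "CorrelateResult",
    "gene_correlates",
    "select_significant",
    "spearman",
]
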