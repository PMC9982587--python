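"""Case-control effect-size maps and first-principal-component summaries.

Subject-level regional measures are residualized on nuisance covariates
(age, sex, education, head motion), compared between groups with pooled
two-sample t-tests, converted to Cohen's d, and FDR-corrected. Stacked
effect maps of the three functional measures are summarized by their first
principal component (funcPC1); the region x gene expression matrix by its
first principal component (genePC1). PCA is computed via singular value
decomposition of the column-standardized matrix — deterministic, with an
explicit sign convention recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COVARIATES = ("age", "sex", "education", "motion")


@dataclass
class PCSummary:
    """First principal component of a regions x variables matrix."""

    scores: pd.Series           # per-region component scores, z-scored
    variance_explained: float   # fraction in (0, 1]
    loadings: pd.Series         # per-variable loadings (unit vector)
    sign_flipped: bool          # True if SVD output was negated by the convention
    sign_convention: str


def _region_columns(table: pd.DataFrame) -> list[str]:
    meta = {"subject_id", "group", *COVARIATES}
    return [c for c in table.columns if c not in meta]


def residualize(
    table: pd.DataFrame, covariates: tuple[str, ...] = COVARIATES
) -> pd.DataFrame:
    """Replace each regional measure by OLS residuals on covariates + intercept.

    Fitted on all subjects pooled (cases and controls together), so group
    differences are preserved while covariate effects are removed. A
    rank-deficient design is rejected with the offending columns named.
    """
    regions = _region_columns(table)
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    # covariates constant in this sample (e.g. sex after a subgroup split)
    # carry no information beyond the intercept; drop them with a warning
    constant = [c for c in covariates if table[c].nunique() == 1]
    if constant:
        import warnings

        warnings.warn(
            f"constant covariate(s) dropped from residualization: {constant}",
            stacklevel=2,
        )
        covariates = tuple(c for c in covariates if c not in constant)
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        base_rank = np.linalg.matrix_rank(X)
        for i, c in enumerate(covariates, start=1):
            reduced = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(reduced) == base_rank:
                bad.append(c)
        raise ValueError(f"rank-deficient covariate design; offending columns: {bad}")

    Y = table[regions].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = table.copy()
    out[regions] = resid
    return out


def case_control_t(
    table: pd.DataFrame, group_col: str = "group", welch: bool = False
) -> pd.DataFrame:
    """Per-region two-sample t-test, case minus control.

    Pooled-variance (Student) t by default, df = n1 + n2 - 2; Welch optional.
    Regions with zero variance in both groups are rejected by name.
    """
    regions = _region_columns(table)
    groups = set(table[group_col])
    if groups != {"case", "control"}:
        raise ValueError(f"group column must contain 'case' and 'control', got {groups}")
    case = table.loc[table[group_col] == "case", regions].to_numpy(float)
    ctrl = table.loc[table[group_col] == "control", regions].to_numpy(float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 subjects per group")

    pooled_var = case.var(axis=0, ddof=1) * (len(case) - 1) + ctrl.var(
        axis=0, ddof=1
    ) * (len(ctrl) - 1)
    dead = np.flatnonzero(pooled_var == 0)
    if dead.size:
        raise ValueError(
            f"zero pooled variance in regions: {[regions[i] for i in dead]}"
        )
    t, p = stats.ttest_ind(case, ctrl, axis=0, equal_var=not welch)
    return pd.DataFrame({"region": regions, "t": t, "p": p}).set_index("region")


def t_to_d(t, n1: int, n2: int):
    """Convert two-sample t statistics to Cohen's d: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    return np.asarray(t, dtype=float) * np.sqrt(1.0 / n1 + 1.0 / n2)


def fdr_bh(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q values, significance mask)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def effect_size_map(
    table: pd.DataFrame,
    measure: str,
    alpha: float = 0.05,
    residualize_covariates: bool = True,
    welch: bool = False,
) -> pd.DataFrame:
    """Full per-measure map: residualize, t-test, Cohen's d, BH-FDR q."""
    tab = residualize(table) if residualize_covariates else table
    tp = case_control_t(tab, welch=welch)
    n1 = int((table["group"] == "case").sum())
    n2 = int((table["group"] == "control").sum())
    d = t_to_d(tp["t"].to_numpy(), n1, n2)
    q, sig = fdr_bh(tp["p"].to_numpy(), alpha=alpha)
    out = tp.copy()
    out["d"] = d
    out["q"] = q
    out["significant"] = sig
    out["measure"] = measure
    return out


def _standardize_columns(M: np.ndarray, drop_constant: bool = False):
    sd = M.std(axis=0, ddof=0)
    keep = sd > 0
    if not drop_constant and not keep.all():
        raise ValueError(f"constant column(s) at positions {list(np.flatnonzero(~keep))}")
    M = M[:, keep]
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)
    return Z, keep


def _pc1(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * s[0]
    return scores, Vt[0], float(s[0] ** 2 / np.sum(s**2))


def pc1_of_effects(maps: pd.DataFrame, standardize: bool = True) -> PCSummary:
    """funcPC1: first PC of stacked effect maps (regions x measures).

    Columns are standardized, PC1 scores are z-scored across regions, and
    the sign is fixed so the component correlates positively with the mean
    of the (standardized) input maps.
    """
    M = maps.to_numpy(float)
    if M.shape[1] < 2:
        raise ValueError("need at least 2 effect maps")
    Z, keep = _standardize_columns(M, drop_constant=False)
    if standardize is False:
        Z = M - M.mean(axis=0)
    scores, loadings, varexp = _pc1(Z)
    flipped = False
    ref = Z.mean(axis=1)
    if np.dot(scores, ref) < 0:
        scores, loadings, flipped = -scores, -loadings, True
    scores = (scores - scores.mean()) / scores.std(ddof=0)
    return PCSummary(
        scores=pd.Series(scores, index=maps.index, name="funcPC1"),
        variance_explained=varexp,
        loadings=pd.Series(loadings, index=maps.columns),
        sign_flipped=flipped,
        sign_convention="positive correlation with mean of input maps",
    )


def pc1_of_expression(X: pd.DataFrame) -> PCSummary:
    """genePC1: first PC of the region x gene expression matrix.

    Regions are observations, genes variables; gene columns are
    standardized (zero-variance genes dropped with a report in the loadings
    index), scores z-scored across regions. The sign is fixed so the mean
    gene loading is non-negative, i.e. the component tracks the dominant
    shared expression gradient rather than its mirror image.
    """
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 regions and 2 genes")
    Z, keep = _standardize_columns(X.to_numpy(float), drop_constant=True)
    kept_genes = X.columns[keep]
    scores, loadings, varexp = _pc1(Z)
    flipped = False
    if loadings.mean() < 0 or (loadings.mean() == 0 and loadings[0] < 0):
        scores, loadings, flipped = -scores, -loadings, True
    scores = (scores - scores.mean()) / scores.std(ddof=0)
    return PCSummary(
        scores=pd.Series(scores, index=X.index, name="genePC1"),
        variance_explained=varexp,
        loadings=pd.Series(loadings, index=kept_genes),
        sign_flipped=flipped,
        sign_convention="mean gene loading non-negative",
    )


__all__ = [
    "COVARIATES",
    "PCSummary",
    "case_control_t",
    "effect_size_map",
    "fdr_bh",
    "pc1_of_effects",
    "pc1_of_expression",
    "residualize",
    "t_to_d",
]
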