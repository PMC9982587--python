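"""Link transcriptional correlates to postmortem differential gene expression.

Meta-analytic DGE betas concentrate near zero with heavy tails, which
attenuates a direct gene-level rank correlation against the transcriptional
correlates. The bin-based estimator ranks genes by their correlate,
partitions them into B contiguous bins, and correlates the per-bin means:
averaging within bins cancels gene-level noise while the monotone signal
survives, increasing power. With B = N (one gene per bin) the estimator
collapses exactly to the direct gene-level Spearman correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .correlates import spearman


def intersect_genes(correlates: pd.DataFrame, dge: pd.DataFrame) -> list[str]:
    """Sorted intersection of the gene universes of the two tables."""
    a = set(correlates["gene"])
    b = set(dge["gene"])
    common = sorted(a & b)
    if not common:
        raise ValueError("no overlapping genes between correlate and DGE tables")
    return common


def bin_genes(
    correlates: pd.Series,
    dge: pd.Series,
    n_bins: int,
) -> pd.DataFrame:
    """Partition genes, ranked by correlate (descending), into contiguous bins.

    Both inputs are indexed by gene id and restricted to their common genes.
    Ties in the correlate are broken by gene id ascending. With N genes and
    B bins, the first N mod B bins hold ceil(N/B) genes, the rest floor(N/B);
    bin 1 holds the most-positive correlates. Returns one row per bin with
    member genes and the per-bin mean correlate and mean DGE beta.
    """
    common = sorted(set(correlates.index) & set(dge.index))
    if not common:
        raise ValueError("no overlapping genes")
    N = len(common)
    if not 1 <= n_bins <= N:
        raise ValueError(f"n_bins must lie in [1, {N}], got {n_bins}")

    sub = pd.DataFrame({"r": correlates.loc[common], "beta": dge.loc[common]})
    sub = sub.sort_values(["r"], ascending=False, kind="mergesort")
    # mergesort is stable; pre-sorting the index ascending fixes tie order
    order = sub.index.to_numpy()

    splits = np.array_split(np.arange(N), n_bins)
    rows = []
    for b, idx in enumerate(splits, start=1):
        genes = [order[i] for i in idx]
        rows.append(
            {
                "bin": b,
                "n_genes": len(genes),
                "genes": genes,
                "mean_correlate": float(sub["r"].iloc[idx].mean()),
                "mean_dge": float(sub["beta"].iloc[idx].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def bin_correlation(bins: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of (mean correlate, mean DGE beta) across bins."""
    if len(bins) < 4:
        raise ValueError("need at least 4 bins")
    return spearman(bins["mean_correlate"].to_numpy(), bins["mean_dge"].to_numpy())


def topk_updown(dge: pd.Series, k: int = 500) -> tuple[set[str], set[str]]:
    """Up/down-regulated gene sets: the K most-positive and K most-negative betas.

    Only genes with strictly positive (resp. negative) betas qualify; if
    fewer than K exist the set is truncated with a warning. The two sets are
    disjoint by construction.
    """
    if k < 1:
        raise ValueError("k must be positive")
    s = dge.sort_values(ascending=False, kind="mergesort")
    pos = s[s > 0]
    neg = s[s < 0]
    if len(pos) < k or len(neg) < k:
        warnings.warn(
            f"fewer than k={k} strictly positive ({len(pos)}) or negative "
            f"({len(neg)}) DGE values; sets truncated",
            stacklevel=2,
        )
    up = set(pos.index[: min(k, len(pos))])
    down = set(neg.index[-min(k, len(neg)):]) if len(neg) else set()
    return up, down


__all__ = ["bin_correlation", "bin_genes", "intersect_genes", "topk_updown"]
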