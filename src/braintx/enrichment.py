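"""Over-representation analysis of gene sets via one-sided Fisher tests.

Each query set (e.g. the four selected transcriptional-correlate sets) is
tested against every annotation set of a collection (cell classes, up/down
DGE sets, pathway collections read from GMT) on a 2x2 table over a stated
background universe — by default the gene universe of the correlate screen,
since selection happened within it. The p value is the exact hypergeometric
upper tail; BH-FDR is applied within each query across a collection.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .effects import fdr_bh


def fisher_enrich(
    query: set[str], annotation: set[str], background: set[str]
) -> dict:
    """One-sided (enrichment) Fisher exact test of query vs annotation.

    2x2 cells: a = overlap, b = query only, c = annotation only, d = rest.
    p = P(overlap >= a) under the hypergeometric null. The odds ratio is
    (a d)/(b c); when a zero cell makes it degenerate, a Haldane 0.5
    continuity correction is applied to the reported odds ratio only (the
    p value is exact and unaffected), flagged by ``or_continuity``.
    """
    bad_q = sorted(set(query) - set(background))
    bad_a = sorted(set(annotation) - set(background))
    if bad_q or bad_a:
        raise ValueError(
            f"sets not contained in background; offenders: query={bad_q[:10]}, "
            f"annotation={bad_a[:10]}"
        )
    N = len(background)
    q = len(query)
    m = len(annotation)
    a = len(set(query) & set(annotation))
    b = q - a
    c = m - a
    d = N - q - c
    p = float(stats.hypergeom.sf(a - 1, N, m, q))
    continuity = False
    if min(a, b, c, d) == 0:
        continuity = True
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {
        "overlap": a,
        "query_size": q,
        "annotation_size": m,
        "background_size": N,
        "odds_ratio": float(odds),
        "or_continuity": continuity,
        "p": p,
    }


def enrich_collection(
    queries: dict[str, set[str]],
    collection: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All query x annotation Fisher tests, BH-corrected within each query.

    Empty annotation sets are skipped with a warning. Row order is
    deterministic: queries then annotations, in the order given.
    """
    if not collection:
        raise ValueError("empty annotation collection")
    usable = {}
    for name, genes in collection.items():
        if not genes:
            warnings.warn(f"annotation set {name!r} is empty; skipped", stacklevel=2)
            continue
        usable[name] = genes
    if not usable:
        raise ValueError("all annotation sets empty")

    rows = []
    for qname, qset in queries.items():
        for aname, aset in usable.items():
            row = fisher_enrich(qset, aset, background)
            row["query"] = qname
            row["annotation"] = aname
            rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = 0.0
    out["significant"] = False
    for qname in queries:
        mask = out["query"] == qname
        # exact tail p can underflow to 0 for extreme overlaps; floor it so
        # the BH step-up (defined on (0, 1]) stays applicable
        pvals = out.loc[mask, "p"].to_numpy().clip(min=5e-324)
        qvals, sig = fdr_bh(pvals, alpha=alpha)
        out.loc[mask, "q"] = qvals
        out.loc[mask, "significant"] = sig
    cols = [
        "query", "annotation", "overlap", "query_size", "annotation_size",
        "background_size", "odds_ratio", "or_continuity", "p", "q", "significant",
    ]
    return out[cols]


__all__ = ["enrich_collection", "fisher_enrich"]
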