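"""Build a region x gene expression matrix from probe-level donor samples.

Mirrors the standard microarray-atlas workflow: intensity-based probe
filtering against background, selection of one representative probe per gene
by differential stability (mean cross-donor correlation of regional
expression profiles), within-donor normalization, and aggregation within
regions and across donors. Samples arrive pre-labeled with region ids;
coordinate-based sample-to-parcel matching is out of scope.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "donor", "sample", "region", "probe", "gene", "intensity", "above_background",
)


@dataclass
class FilterReport:
    dropped_probes: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)


def _check_columns(samples: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"probe sample table missing columns: {missing}")


def filter_probes(
    samples: pd.DataFrame, threshold_fraction: float = 0.5
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop probes above background in fewer than ``threshold_fraction`` of samples.

    A probe survives when its above-background fraction is at least the
    threshold (default 0.5). Genes whose probes are all dropped are reported
    in the :class:`FilterReport` together with the dropped probes.
    """
    _check_columns(samples)
    if samples.empty:
        raise ValueError("empty probe sample table")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")

    frac_above = samples.groupby("probe")["above_background"].mean()
    keep = frac_above[frac_above >= threshold_fraction].index
    dropped = sorted(set(frac_above.index) - set(keep))
    out = samples[samples["probe"].isin(keep)].copy()

    genes_before = set(samples["gene"])
    genes_after = set(out["gene"])
    report = FilterReport(
        dropped_probes=dropped, dropped_genes=sorted(genes_before - genes_after)
    )
    return out, report


def _donor_region_profiles(samples: pd.DataFrame) -> pd.DataFrame:
    """Mean intensity per (probe, donor, region), wide on region."""
    return (
        samples.groupby(["probe", "donor", "region"], sort=True)["intensity"]
        .mean()
        .unstack("region")
    )


def differential_stability(samples: pd.DataFrame) -> pd.Series:
    """Per-probe mean cross-donor-pair correlation of regional profiles."""
    prof = _donor_region_profiles(samples)
    scores = {}
    for probe, block in prof.groupby(level="probe"):
        mat = block.droplevel("probe")
        donors = list(mat.index)
        cors = []
        for a, b in itertools.combinations(donors, 2):
            x, y = mat.loc[a], mat.loc[b]
            ok = x.notna() & y.notna()
            if ok.sum() >= 3 and x[ok].std() > 0 and y[ok].std() > 0:
                cors.append(np.corrcoef(x[ok], y[ok])[0, 1])
        scores[probe] = float(np.mean(cors)) if cors else -np.inf
    return pd.Series(scores, name="differential_stability")


def select_representative_probe(samples: pd.DataFrame) -> dict[str, str]:
    """Pick one probe per gene maximizing differential stability.

    Ties are broken by the lexicographically smallest probe id. With a
    single donor the stability criterion is undefined; the probe with the
    highest mean intensity is used instead (with a warning).
    """
    _check_columns(samples)
    if samples.empty:
        raise ValueError("empty probe sample table")
    n_donors = samples["donor"].nunique()
    probe_gene = samples.drop_duplicates("probe").set_index("probe")["gene"]

    if n_donors < 2:
        warnings.warn(
            "single-donor input: falling back to highest mean intensity "
            "for representative-probe selection",
            stacklevel=2,
        )
        score = samples.groupby("probe")["intensity"].mean()
    else:
        score = differential_stability(samples)

    mapping: dict[str, str] = {}
    table = pd.DataFrame({"gene": probe_gene, "score": score})
    table.index.name = "probe"
    table = table.reset_index()
    table = table.sort_values(["gene", "score", "probe"], ascending=[True, False, True])
    for gene, block in table.groupby("gene", sort=True):
        best = block.iloc[0]
        # deterministic tie-break: among max-score probes, smallest id
        top = block[block["score"] == best["score"]]
        mapping[gene] = top["probe"].min()
    return mapping


def _normalize_within_donor(values: pd.Series, method: str) -> pd.Series:
    """Normalize one donor-gene vector of sample intensities."""
    x = values.astype(float)
    if method == "zscore":
        sd = x.std(ddof=0)
        if sd == 0:
            return x - x.mean()
        return (x - x.mean()) / sd
    if method == "srs":  # scaled robust sigmoid
        med = x.median()
        iqr = x.quantile(0.75) - x.quantile(0.25)
        scale = iqr / 1.35 if iqr > 0 else 1.0
        y = 1.0 / (1.0 + np.exp(-(x - med) / scale))
        lo, hi = y.min(), y.max()
        return (y - lo) / (hi - lo) if hi > lo else y * 0.0
    raise ValueError(f"unknown normalization {method!r}")


def aggregate_to_regions(
    samples: pd.DataFrame,
    representative: dict[str, str],
    normalization: str = "zscore",
) -> pd.DataFrame:
    """Aggregate representative-probe samples into a region x gene matrix.

    Per donor and gene, sample intensities are normalized across that donor's
    samples, averaged within regions, then averaged across donors. Regions
    with no sample in any donor are excluded with a warning, never imputed.
    """
    _check_columns(samples)
    keep = samples[samples["probe"].isin(set(representative.values()))].copy()
    if keep.empty:
        raise ValueError("no samples left after restricting to representative probes")

    keep["norm"] = (
        keep.groupby(["donor", "gene"])["intensity"]
        .transform(lambda v: _normalize_within_donor(v, normalization))
    )
    donor_region = (
        keep.groupby(["gene", "donor", "region"], sort=True)["norm"].mean()
    )
    matrix = donor_region.groupby(["gene", "region"]).mean().unstack("gene")

    all_regions = sorted(samples["region"].unique())
    missing = sorted(set(all_regions) - set(matrix.index))
    if missing:
        warnings.warn(f"regions with no usable sample excluded: {missing}", stacklevel=2)
    matrix = matrix.sort_index()
    matrix.index.name = "region"
    matrix.columns.name = None
    return matrix


def build_expression_matrix(
    samples: pd.DataFrame,
    threshold_fraction: float = 0.5,
    normalization: str = "zscore",
) -> tuple[pd.DataFrame, FilterReport, dict[str, str]]:
    """Full probe-to-region workflow: filter, select representatives, aggregate."""
    filtered, report = filter_probes(samples, threshold_fraction)
    if filtered.empty:
        raise ValueError("all probes removed by background filtering")
    rep = select_representative_probe(filtered)
    matrix = aggregate_to_regions(filtered, rep, normalization)
    return matrix, report, rep


__all__ = [
    "FilterReport",
    "aggregate_to_regions",
    "build_expression_matrix",
    "differential_stability",
    "filter_probes",
    "select_representative_probe",
]
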