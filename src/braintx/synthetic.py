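"""Synthetic data generators with planted ground truth.

Every pipeline input — the region x gene expression matrix, subject-level
regional measures for cases and controls, probe-level microarray samples,
voxel-neighborhood time series, and gene-level differential-expression (DGE)
betas — can be generated here with a known latent structure, so each
downstream stage is testable without any external download.

The central latent object is a per-region *gradient*: a z-scaled spatial
score. Causal genes load on it; the case-control difference maps are coupled
to it at a requested Spearman correlation. Couplings are planted on the
Spearman scale through the bivariate-normal calibration: mixing the
gradient's normal scores with independent Gaussian noise at Pearson weight
``2 sin(pi * rho / 6)`` yields population Spearman correlation ``rho``.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FUNCTIONAL_MEASURES = ("ALFF", "fALFF", "ReHo")
MEASURES = ("GMV",) + FUNCTIONAL_MEASURES

#: Default additive covariate effects on the (unit-noise) regional measures.
DEFAULT_COVARIATE_BETAS = {
    "age": 0.01,        # per year
    "sex": 0.2,         # male/female contrast
    "education": 0.02,  # per year of education
    "motion": 0.5,      # per unit mean framewise displacement
}

#: SD of the true per-region Cohen's d across regions.  Chosen so planted
#: couplings remain recoverable by the full pipeline at a few hundred
#: subjects per group (see docs/methods.md for the power calculation).
DEFAULT_EFFECT_SD = 0.12

#: Shared fraction of variance between the three functional difference maps
#: (pairwise correlation of the true maps = this value).
FUNCTIONAL_SHARED_VAR = 0.75


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=0)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Map a vector to standard-normal scores preserving its ranks."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.5) / len(x))


def _spearman_mix(anchor: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """A map whose population Spearman correlation with ``anchor`` is rho.

    ``anchor`` is replaced by its normal scores (a noise-free map perfectly
    rank-aligned with it), then mixed with independent Gaussian noise at the
    Pearson weight that calibrates the Spearman scale for bivariate normals.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"coupling must lie in [-1, 1], got {rho}")
    g = _normal_scores(anchor)
    r_p = 2.0 * np.sin(np.pi * rho / 6.0)
    eps = rng.standard_normal(len(g))
    return r_p * g + np.sqrt(1.0 - r_p**2) * eps


def region_ids(n: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n)]


def gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


@dataclass
class GroundTruth:
    """Planted latent structure behind one synthetic dataset."""

    gradient: pd.Series          # per-region latent score, z-scaled
    rho_func: float              # planted Spearman coupling, functional maps
    rho_gmv: float               # planted Spearman coupling, GMV map
    causal_genes: list[str]
    seed: int
    gene_gradient_corr: pd.Series | None = None  # per-gene true corr with gradient
    true_d: dict[str, pd.Series] = field(default_factory=dict)  # per-measure true Cohen's d

    def __post_init__(self) -> None:
        g = np.asarray(self.gradient, dtype=float)
        if not (abs(g.mean()) < 1e-8 and abs(g.std(ddof=0) - 1.0) < 1e-8):
            raise ValueError("gradient must be z-scaled (mean 0, sd 1)")
        if not (abs(self.rho_func) <= 1 and abs(self.rho_gmv) <= 1):
            raise ValueError("couplings must lie in [-1, 1]")


def gen_expression(
    n_regions: int,
    n_genes: int,
    n_causal: int,
    gradient_loading_sd: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    gradient_loading_mean: float = 0.5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Region x gene expression matrix with a planted low-rank gradient.

    Causal genes are ``gradient * loading + noise``; the remaining genes are
    independent noise. Loadings are Gaussian with a positive mean so the
    matrix's first principal component has a reproducible orientation with
    respect to the gradient, emulating the positive-dominant covariance of
    bulk cortical expression.

    Returns the matrix (regions as rows, genes as columns) and the
    :class:`GroundTruth`, which records the gradient, the causal gene ids,
    and each gene's true correlation with the gradient.
    """
    if n_regions <= 0 or n_genes <= 0 or n_causal < 0:
        raise ValueError("dimensions must be positive")
    if n_causal > n_genes:
        raise ValueError("n_causal cannot exceed n_genes")
    if gradient_loading_sd <= 0 or noise_sd <= 0:
        raise ValueError("standard deviations must be positive")

    rng = np.random.default_rng(seed)
    regions = region_ids(n_regions)
    genes = gene_ids(n_genes)

    gradient = _zscore(rng.standard_normal(n_regions))
    causal_idx = np.sort(rng.choice(n_genes, size=n_causal, replace=False))
    loadings = np.zeros(n_genes)
    loadings[causal_idx] = rng.normal(
        gradient_loading_mean, gradient_loading_sd, size=n_causal
    )

    X = noise_sd * rng.standard_normal((n_regions, n_genes))
    X += np.outer(gradient, loadings)

    # true corr(gene, gradient) under the generative model
    true_corr = loadings / np.sqrt(loadings**2 + noise_sd**2)

    grad = pd.Series(gradient, index=regions, name="gradient")
    truth = GroundTruth(
        gradient=grad,
        rho_func=0.0,
        rho_gmv=0.0,
        causal_genes=[genes[i] for i in causal_idx],
        seed=seed,
        gene_gradient_corr=pd.Series(true_corr, index=genes, name="true_corr"),
    )
    return pd.DataFrame(X, index=regions, columns=genes), truth


def gen_subjects(
    n_case: int,
    n_control: int,
    gradient: pd.Series,
    rho_func: float = -0.3,
    rho_gmv: float = 0.35,
    covariate_betas: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    effect_sd: float = DEFAULT_EFFECT_SD,
    shared_var: float = FUNCTIONAL_SHARED_VAR,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Subject x region measure tables for cases and controls.

    One table per measure (GMV, ALFF, fALFF, ReHo). The true per-region
    case-control difference of the three functional measures shares a latent
    map coupled to ``gradient`` at Spearman ``rho_func`` (pairwise
    correlation of the true maps = ``shared_var``); the GMV difference map is
    coupled at ``rho_gmv``. Each true difference map is z-scaled and scaled
    by ``effect_sd`` so it is the per-region Cohen's d in units of the
    within-group noise. Covariates (age, sex, education, head motion)
    contribute additively with the given betas.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    if not (-1 <= rho_func <= 1 and -1 <= rho_gmv <= 1):
        raise ValueError("couplings must lie in [-1, 1]")
    if covariate_betas is None:
        covariate_betas = dict(DEFAULT_COVARIATE_BETAS)

    rng = np.random.default_rng(seed)
    grad = np.asarray(gradient, dtype=float)
    regions = list(gradient.index)
    n_regions = len(regions)
    n = n_case + n_control

    # latent difference maps
    f_func = _spearman_mix(grad, rho_func, rng)
    f_gmv = _zscore(_spearman_mix(grad, rho_gmv, rng))
    w = np.sqrt(shared_var)
    true_d: dict[str, np.ndarray] = {
        "GMV": effect_sd * f_gmv,
    }
    for m in FUNCTIONAL_MEASURES:
        u = rng.standard_normal(n_regions)
        true_d[m] = effect_sd * _zscore(w * _zscore(f_func) + np.sqrt(1 - w**2) * u)

    # covariates, shared across measures
    group = np.array(["case"] * n_case + ["control"] * n_control)
    cov = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "group": group,
            "age": rng.uniform(18, 65, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "education": rng.integers(6, 23, size=n).astype(float),
            "motion": rng.lognormal(mean=-2.0, sigma=0.5, size=n),
        }
    )
    cov_effect = sum(
        covariate_betas.get(c, 0.0) * cov[c].to_numpy()
        for c in ("age", "sex", "education", "motion")
    )
    is_case = (group == "case").astype(float)

    tables: dict[str, pd.DataFrame] = {}
    for m in MEASURES:
        Y = noise_sd * rng.standard_normal((n, n_regions))
        Y += np.outer(is_case, noise_sd * true_d[m])
        Y += np.asarray(cov_effect)[:, None]
        tab = pd.concat(
            [cov, pd.DataFrame(Y, columns=regions, index=cov.index)], axis=1
        )
        tables[m] = tab

    truth = GroundTruth(
        gradient=pd.Series(_zscore(grad), index=regions, name="gradient"),
        rho_func=rho_func,
        rho_gmv=rho_gmv,
        causal_genes=[],
        seed=seed,
        true_d={m: pd.Series(v, index=regions) for m, v in true_d.items()},
    )
    return tables, truth


def gen_timeseries(
    n_timepoints: int = 250,
    n_voxels: int = 27,
    tr: float = 2.0,
    band_weight: float = 0.6,
    synchrony: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """A T x V voxel-neighborhood time-series block for the functional metrics.

    Each voxel is a mixture of a shared low-frequency (0.01-0.08 Hz)
    component (weight ``synchrony``, driving regional homogeneity) and
    independent noise; ``band_weight`` sets the fraction of signal amplitude
    placed in the low-frequency band versus broadband white noise.
    """
    if not (0 <= synchrony <= 1 and 0 <= band_weight <= 1):
        raise ValueError("synchrony and band_weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * tr
    freqs = rng.uniform(0.01, 0.08, size=5)
    phases = rng.uniform(0, 2 * np.pi, size=5)
    shared_low = np.sum(
        [np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)], axis=0
    )
    shared_low /= shared_low.std()

    out = np.empty((n_timepoints, n_voxels))
    for v in range(n_voxels):
        own_low = rng.standard_normal(n_timepoints)
        low = np.sqrt(synchrony) * shared_low + np.sqrt(1 - synchrony) * own_low
        broad = rng.standard_normal(n_timepoints)
        out[:, v] = band_weight * low + (1 - band_weight) * broad
    return out


@dataclass
class ProbeTruth:
    """Planted structure of a probe-level sample set."""

    representative: dict[str, str]      # gene -> planted high-stability probe
    below_background: list[str]         # probes planted below background
    profiles: pd.DataFrame              # regions x genes true profiles
    seed: int


def gen_probe_samples(
    n_donors: int,
    n_regions: int,
    n_genes: int,
    probes_per_gene: int = 3,
    background_rate: float = 0.2,
    seed: int = 0,
    samples_per_region: int = 1,
) -> tuple[pd.DataFrame, ProbeTruth]:
    """Probe-level microarray samples from multiple donors.

    Each gene has one planted *representative* probe whose intensity tracks a
    gene-specific regional profile consistently across donors; the remaining
    decoy probes are donor-specific noise (low cross-donor stability). A
    ``background_rate`` fraction of decoy probes is flagged below background
    in 70% of samples (so a 50% above-background filter removes exactly
    them); all other probes are above background in 95% of samples.

    Returns a long-format table with columns donor, sample, region, probe,
    gene, intensity, above_background, and the :class:`ProbeTruth`.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    if not 0 <= background_rate <= 1:
        raise ValueError("background_rate must lie in [0, 1]")
    if n_donors < 1 or n_regions < 1 or n_genes < 1:
        raise ValueError("dimensions must be positive")

    rng = np.random.default_rng(seed)
    regions = region_ids(n_regions)
    genes = gene_ids(n_genes)
    donors = [f"D{i + 1}" for i in range(n_donors)]

    profiles = pd.DataFrame(
        rng.standard_normal((n_regions, n_genes)), index=regions, columns=genes
    )

    representative: dict[str, str] = {}
    probe_gene: list[tuple[str, str, bool]] = []  # (probe, gene, is_rep)
    for gi, g in enumerate(genes):
        rep_j = int(rng.integers(probes_per_gene))
        for j in range(probes_per_gene):
            probe = f"{g}_P{j + 1}"
            is_rep = j == rep_j
            if is_rep:
                representative[g] = probe
            probe_gene.append((probe, g, is_rep))

    decoys = [p for p, _, is_rep in probe_gene if not is_rep]
    n_below = int(round(background_rate * len(decoys)))
    below = sorted(rng.choice(decoys, size=n_below, replace=False)) if n_below else []
    below_set = set(below)

    n_samples = n_donors * n_regions * samples_per_region
    rows = []
    for probe, gene, is_rep in probe_gene:
        prof = profiles[gene].to_numpy()
        # fixed count of above-background samples => exact filter behaviour
        frac = 0.3 if probe in below_set else 0.95
        n_above = int(round(frac * n_samples))
        above_flags = np.zeros(n_samples, dtype=bool)
        above_flags[rng.choice(n_samples, size=n_above, replace=False)] = True
        k = 0
        for d in donors:
            donor_decoy = rng.standard_normal(n_regions)  # fresh per donor
            for ri, r in enumerate(regions):
                for s in range(samples_per_region):
                    if is_rep:
                        val = prof[ri] + 0.15 * rng.standard_normal()
                    else:
                        val = donor_decoy[ri] + 0.15 * rng.standard_normal()
                    rows.append(
                        (d, f"{d}_{r}_{s + 1}", r, probe, gene, val, above_flags[k])
                    )
                    k += 1
    df = pd.DataFrame(
        rows,
        columns=[
            "donor", "sample", "region", "probe", "gene", "intensity",
            "above_background",
        ],
    )
    truth = ProbeTruth(
        representative=representative,
        below_background=list(below),
        profiles=profiles,
        seed=seed,
    )
    return df, truth


def gen_dge(
    correlate_truth: pd.Series,
    coupling_sign: float,
    zero_inflation: float = 0.8,
    seed: int = 0,
    noise_df: float = 3.0,
    noise_scale: float = 1.0,
    shrink_factor: float = 0.05,
    disorder: str = "MDD",
) -> pd.DataFrame:
    """Gene-level differential-expression betas coupled to a correlate vector.

    ``beta = coupling_sign * z(correlate_truth) + t_df noise``, after which a
    ``zero_inflation`` fraction of genes is shrunk toward zero by
    ``shrink_factor`` — emulating meta-analytic DGE estimates where most
    genes sit in a narrow band around zero with heavy tails.
    """
    if not 0 <= zero_inflation < 1:
        raise ValueError("zero_inflation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    truth = np.asarray(correlate_truth, dtype=float)
    n = len(truth)
    signal = coupling_sign * _zscore(truth) if truth.std() > 0 else np.zeros(n)
    beta = signal + noise_scale * rng.standard_t(noise_df, size=n)
    n_shrunk = int(round(zero_inflation * n))
    shrunk = rng.choice(n, size=n_shrunk, replace=False)
    beta[shrunk] *= shrink_factor
    return pd.DataFrame(
        {"gene": list(correlate_truth.index), "disorder": disorder, "beta": beta}
    )


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    """Serialize a GroundTruth to a JSON sidecar."""
    import json

    payload = {
        "seed": truth.seed,
        "rho_func": truth.rho_func,
        "rho_gmv": truth.rho_gmv,
        "causal_genes": truth.causal_genes,
        "gradient": {k: float(v) for k, v in truth.gradient.items()},
    }
    if truth.gene_gradient_corr is not None:
        payload["gene_gradient_corr"] = {
            k: float(v) for k, v in truth.gene_gradient_corr.items()
        }
    if truth.true_d:
        payload["true_d"] = {
            m: {k: float(v) for k, v in s.items()} for m, s in truth.true_d.items()
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


__all__ = [
    "DEFAULT_COVARIATE_BETAS",
    "DEFAULT_EFFECT_SD",
    "FUNCTIONAL_MEASURES",
    "MEASURES",
    "GroundTruth",
    "ProbeTruth",
    "gen_dge",
    "gen_expression",
    "gen_probe_samples",
    "gen_subjects",
    "gen_timeseries",
    "gene_ids",
    "region_ids",
    "write_ground_truth_json",
]
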