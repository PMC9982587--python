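"""End-to-end orchestration of the transcriptome-neuroimaging pipeline.

Synthetic mode: generate a planted expression matrix and case/control
subject tables, compute per-measure effect-size maps, summarize the three
functional maps as funcPC1 and the expression matrix as genePC1, screen
per-gene spatial correlates against funcPC1 and the GMV effect map, select
Bonferroni-significant gene sets, link correlates to (synthetic) DGE betas
directly and through the bin-based estimator, and run Fisher enrichment of
the selected sets against the up/down DGE sets. Deterministic for a fixed
config; every derived seed is a fixed offset of the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlates as corr
from . import dgelink, effects, enrichment, synthetic
from .io import RunConfig, ensure_dir, write_expression, write_gene_list, write_table


@dataclass
class PipelineResult:
    config: RunConfig
    effect_maps: dict[str, pd.DataFrame]
    func_pc: effects.PCSummary
    gene_pc: effects.PCSummary
    genepc1_func_rs: float
    genepc1_func_p: float
    genepc1_gmv_rs: float
    genepc1_gmv_p: float
    correlate_tables: dict[str, corr.CorrelateResult]
    gene_sets: dict[str, set[str]]
    dge: pd.DataFrame
    direct_rs: float
    bin_table: pd.DataFrame
    bin_rs: float
    bin_p: float
    updown: dict[str, set[str]]
    enrichment_table: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _apply_subgroup(table: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    if not subgroup:
        return table
    key, _, val = subgroup.partition("=")
    if key not in table.columns:
        raise ValueError(f"subgroup column {key!r} not in subject table")
    col = table[key]
    try:
        val_cast = float(val)
        mask = col.astype(float) == val_cast
    except ValueError:
        mask = col.astype(str) == val
    return table.loc[mask].reset_index(drop=True)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full synthetic analysis described in the module docstring."""
    cfg = config
    X, xtruth = synthetic.gen_expression(
        cfg.n_regions, cfg.n_genes, cfg.n_causal, seed=cfg.seed
    )
    tables, struth = synthetic.gen_subjects(
        cfg.n_case,
        cfg.n_control,
        xtruth.gradient,
        rho_func=cfg.rho_func,
        rho_gmv=cfg.rho_gmv,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed + 1_000_003,
        effect_sd=cfg.effect_sd,
    )

    maps = {}
    for m, tab in tables.items():
        tab = _apply_subgroup(tab, cfg.subgroup)
        maps[m] = effects.effect_size_map(
            tab, m, alpha=cfg.alpha, residualize_covariates=cfg.residualize
        )

    d_func = pd.DataFrame(
        {m: maps[m]["d"] for m in synthetic.FUNCTIONAL_MEASURES}
    )
    func_pc = effects.pc1_of_effects(d_func)
    gene_pc = effects.pc1_of_expression(X)
    gmv_d = maps["GMV"]["d"]

    rs_func, p_func = corr.spearman(gene_pc.scores, func_pc.scores)
    rs_gmv, p_gmv = corr.spearman(gene_pc.scores, gmv_d)

    res_func = corr.gene_correlates(X, func_pc.scores, "funcPC1", alpha=cfg.alpha)
    res_gmv = corr.gene_correlates(
        X, pd.Series(gmv_d.to_numpy(), index=X.index, name="GMV"), "GMV",
        alpha=cfg.alpha,
    )
    gene_sets = corr.select_significant([res_func, res_gmv], alpha=cfg.alpha)

    dge = synthetic.gen_dge(
        xtruth.gene_gradient_corr,
        coupling_sign=cfg.dge_coupling_sign,
        zero_inflation=cfg.dge_zero_inflation,
        seed=cfg.seed + 2_000_003,
    )
    dge_s = dge.set_index("gene")["beta"]
    corr_s = res_func.table.set_index("gene")["r_s"]
    common = dgelink.intersect_genes(res_func.table, dge)
    direct_rs, _ = corr.spearman(corr_s.loc[common], dge_s.loc[common])
    bins = dgelink.bin_genes(corr_s, dge_s, cfg.n_bins)
    bin_rs, bin_p = dgelink.bin_correlation(bins)
    up, down = dgelink.topk_updown(dge_s, cfg.top_k)

    background = set(X.columns)
    collection = {"DGE-up": up, "DGE-down": down}
    enrich = enrichment.enrich_collection(
        gene_sets, collection, background, alpha=cfg.alpha
    )

    truth = {
        "gradient": xtruth.gradient,
        "causal_genes": xtruth.causal_genes,
        "gene_gradient_corr": xtruth.gene_gradient_corr,
        "true_d": struth.true_d,
        "rho_func": cfg.rho_func,
        "rho_gmv": cfg.rho_gmv,
    }
    return PipelineResult(
        config=cfg,
        effect_maps=maps,
        func_pc=func_pc,
        gene_pc=gene_pc,
        genepc1_func_rs=rs_func,
        genepc1_func_p=p_func,
        genepc1_gmv_rs=rs_gmv,
        genepc1_gmv_p=p_gmv,
        correlate_tables={"funcPC1": res_func, "GMV": res_gmv},
        gene_sets=gene_sets,
        dge=dge,
        direct_rs=direct_rs,
        bin_table=bins,
        bin_rs=bin_rs,
        bin_p=bin_p,
        updown={"up": up, "down": down},
        enrichment_table=enrich,
        truth=truth,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_result(result: PipelineResult, outdir) -> Path:
    """Write all stage outputs as TSV plus a manifest with content hashes."""
    out = ensure_dir(outdir)
    cfg = result.config

    for m, df in result.effect_maps.items():
        write_table(df.reset_index(), out / f"effects_{m}.tsv")
    pc = pd.DataFrame(
        {"funcPC1": result.func_pc.scores, "genePC1": result.gene_pc.scores}
    )
    write_table(pc.reset_index().rename(columns={"index": "region"}), out / "pc_scores.tsv")
    for name, res in result.correlate_tables.items():
        write_table(res.table, out / f"correlates_{name}.tsv")
    for name, genes in result.gene_sets.items():
        safe = name.replace("+", "_pos").replace("-", "_neg")
        write_gene_list(genes, out / f"genes_{safe}.txt")
    write_table(result.dge, out / "dge.tsv")
    bt = result.bin_table.copy()
    bt["genes"] = bt["genes"].map(",".join)
    write_table(bt.reset_index(), out / "bins.tsv")
    write_table(result.enrichment_table, out / "enrichment.tsv")

    summary = {
        "funcPC1_variance_explained": result.func_pc.variance_explained,
        "genePC1_variance_explained": result.gene_pc.variance_explained,
        "genePC1_funcPC1_rs": result.genepc1_func_rs,
        "genePC1_funcPC1_p": result.genepc1_func_p,
        "genePC1_GMV_rs": result.genepc1_gmv_rs,
        "genePC1_GMV_p": result.genepc1_gmv_p,
        "gene_set_sizes": {k: len(v) for k, v in result.gene_sets.items()},
        "direct_rs": result.direct_rs,
        "bin_rs": result.bin_rs,
        "bin_p": result.bin_p,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    files = sorted(p for p in out.iterdir() if p.suffix in {".tsv", ".txt", ".json"})
    manifest = {
        "seed": cfg.seed,
        "config": {k: getattr(cfg, k) for k in vars(cfg)},
        "outputs": {p.name: _sha256(p) for p in files if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


__all__ = ["PipelineResult", "run_pipeline", "write_result"]
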