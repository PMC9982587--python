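"""TSV / GMT / config reading and writing for all pipeline artifacts."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Region x gene matrix as TSV: first column region ids, header gene ids."""
    matrix.to_csv(path, sep="\t", index_label="region")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="region")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_subject_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line, ``name <tab> description <tab> gene1 <tab> ...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(collection: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")


@dataclass
class RunConfig:
    """Flat, file-serializable configuration of one pipeline run."""

    seed: int = 0
    n_regions: int = 210
    n_genes: int = 2000
    n_causal: int = 300
    n_case: int = 200
    n_control: int = 200
    rho_func: float = -0.3
    rho_gmv: float = 0.35
    effect_sd: float = 0.12
    noise_sd: float = 1.0
    alpha: float = 0.05
    n_bins: int = 100
    top_k: int = 500
    dge_zero_inflation: float = 0.8
    dge_coupling_sign: float = 1.0
    normalization: str = "zscore"
    residualize: bool = True
    subgroup: str = ""           # e.g. "sex=1" to re-run effects on a subset
    outdir: str = "braintx_out"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


__all__ = [
    "RunConfig",
    "ensure_dir",
    "read_expression",
    "read_gene_list",
    "read_gmt",
    "read_subject_table",
    "write_expression",
    "write_gene_list",
    "write_gmt",
    "write_table",
]
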