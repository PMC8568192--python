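"""Readers and writers for the on-disk TSV/JSON/YAML formats.

All tables are UTF-8, tab-separated, '.' decimal.  Readers validate and
reject malformed input rather than silently coercing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .em import FitResult
from .model import GeneTable

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_variant_table",
    "write_fit_result",
    "write_posterior",
    "write_test_result",
    "load_yaml_config",
]


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a per-gene table: TSV with header ``gene_id  mu  y1  [y2]``.

    Duplicate gene identifiers, non-positive mutabilities and non-integer
    counts are rejected with the offending genes named.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = ["gene_id", "mu", "y1"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dupes = frame["gene_id"][frame["gene_id"].duplicated()].unique()
    if len(dupes):
        lines = frame.index[frame["gene_id"].isin(dupes)] + 2  # header is line 1
        raise ValueError(
            f"{path}: duplicate gene_id {list(dupes[:5])} at lines {list(lines[:10])}"
        )
    y2 = frame["y2"].to_numpy() if "y2" in frame.columns else None
    try:
        return GeneTable(
            gene_id=frame["gene_id"].to_numpy(dtype=object),
            mu=frame["mu"].to_numpy(dtype=float),
            y1=frame["y1"].to_numpy(),
            y2=y2,
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    data = {"gene_id": table.gene_id.astype(str), "mu": table.mu, "y1": table.y1}
    if table.y2 is not None:
        data["y2"] = table.y2
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant-level annotation table (one row per observed DNM)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "variant_id": str})
    for col in ("gene_id", "variant_id"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return frame


def write_fit_result(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def write_posterior(fit: FitResult, gene_id: np.ndarray, path: str | Path) -> None:
    n_classes = fit.posterior.shape[1]
    labels = ("z0", "z1") if n_classes == 2 else ("z00", "z10", "z01", "z11")
    frame = pd.DataFrame(fit.posterior, columns=list(labels))
    frame.insert(0, "gene_id", np.asarray(gene_id).astype(str))
    frame.to_csv(path, sep="\t", index=False)


def write_test_result(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({"q": result.attrs.get("q")}, indent=2) + "\n")


def load_yaml_config(path: str | Path, allowed_keys: set[str] | None = None) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = set(config) - allowed_keys
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return config
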