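"""Plain-text formats for analyte matrices, phenotype tables and results.

Canonical numeric serialization is TSV with 10-significant-digit scientific
notation, which round-trips the float64 values used throughout to within the
declared text precision; CSV is accepted on input by sniffing the delimiter.
A GCT 1.2 reader is provided for convenience.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimConfig, SimDataset
from .mediation import Direction

logger = logging.getLogger(__name__)

__all__ = [
    "read_analyte_matrix",
    "write_analyte_matrix",
    "read_pheno",
    "write_pheno",
    "write_result",
    "write_dataset",
    "read_dataset",
]

_FLOAT_FMT = "%.9e"  # 10 significant digits


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_analyte_matrix(path) -> pd.DataFrame:
    """Read an analytes x samples matrix (TSV/CSV, first column = analyte id,
    header row = sample ids; GCT 1.2 autodetected by its '#1.2' header)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        # GCT carries a Description column after the id
        if df.columns[0].lower() in ("description", "desc"):
            df = df.drop(columns=df.columns[0])
    else:
        df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"non-numeric sample column(s) in {path.name}: "
                         f"{list(bad)[:5]}")
    return df.astype(float)


def write_analyte_matrix(M: pd.DataFrame, path) -> None:
    M.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="analyte_id")


def read_pheno(path) -> pd.DataFrame:
    """Phenotype table keyed by sample id (first column)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.map(str)
    return df


def write_pheno(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="sample_id")


def write_result(results: pd.DataFrame, path) -> None:
    """Mediation result table, sorted by directional p with analyte-id
    tiebreak (already the estimator's order), deterministic formatting."""
    results.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=False)


def write_dataset(ds: SimDataset, outdir) -> dict:
    """Write a simulated dataset as a trio of TSVs plus a JSON config sidecar.

    Returns the mapping of roles to paths.  Round-trip via
    :func:`read_dataset` restores matrices to the serialized precision, and
    regenerating from the sidecar config + seed is bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "analytes": outdir / "analytes.tsv",
        "pheno": outdir / "pheno.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    write_analyte_matrix(ds.analytes, paths["analytes"])
    write_pheno(ds.pheno(), paths["pheno"])
    ds.truth.rename_axis("analyte_id").to_frame().to_csv(paths["truth"], sep="\t")
    sidecar = json.loads(ds.config.to_json()) if ds.config else {}
    sidecar["direction_sign"] = ds.direction.sign
    paths["config"].write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}


def read_dataset(outdir) -> SimDataset:
    """Inverse of :func:`write_dataset`."""
    outdir = Path(outdir)
    analytes = read_analyte_matrix(outdir / "analytes.tsv")
    pheno = read_pheno(outdir / "pheno.tsv")
    # keep_default_na: the literal label "null" must survive parsing
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t", index_col=0,
                        keep_default_na=False)["truth"]
    truth.index = truth.index.map(str)
    side = json.loads((outdir / "config.json").read_text())
    sign = side.pop("direction_sign", 1)
    config = SimConfig(**side) if {"n", "G"} <= side.keys() else None
    return SimDataset(
        exposure=pheno["exposure"].to_numpy(dtype=float),
        analytes=analytes,
        outcome=pheno["outcome"].to_numpy(dtype=float),
        truth=truth,
        direction=Direction(sign=sign, gate_mode="ignore"),
        config=config,
    )
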