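"""Plain-text I/O for cohort tables, scan matrices, bases, and models."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import GradientBasis, RegionalTimeseries
from .oscillator import CouplingModel

__all__ = [
    "write_scan",
    "read_scan",
    "write_basis",
    "read_basis",
    "write_table",
    "read_table",
    "write_coupling_model",
    "read_coupling_model",
]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_scan(scan: RegionalTimeseries, path: str | Path) -> None:
    """Scan matrix as gzipped TSV with a JSON sidecar (TR, region ids)."""
    path = Path(path)
    with gzip.open(path, "wt") as fh:
        np.savetxt(fh, scan.values, delimiter="\t", fmt="%.8g")
    sidecar = {
        "tr_seconds": scan.tr_seconds,
        "region_ids": scan.region_ids,
        "mean_fd": scan.mean_fd,
        "scan_id": scan.scan_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_scan(path: str | Path) -> RegionalTimeseries:
    path = Path(path)
    with gzip.open(path, "rt") as fh:
        values = np.loadtxt(fh, delimiter="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RegionalTimeseries(
        values,
        tr_seconds=meta["tr_seconds"],
        region_ids=meta["region_ids"],
        mean_fd=meta["mean_fd"],
        scan_id=meta["scan_id"],
    )


def write_basis(basis: GradientBasis, path: str | Path) -> None:
    """Basis weights as TSV (regions x K) plus JSON metadata."""
    path = Path(path)
    cols = [f"G{k + 1}" for k in range(basis.n_gradients)]
    idx = basis.region_ids or [f"R{i:03d}" for i in range(basis.n_regions)]
    pd.DataFrame(basis.eigenvectors, index=idx, columns=cols).to_csv(path, sep="\t")
    meta = {
        "explained_variance": basis.explained_variance.tolist(),
        "reference_id": basis.reference_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_basis(path: str | Path) -> GradientBasis:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return GradientBasis(
        df.to_numpy(),
        np.asarray(meta["explained_variance"]),
        region_ids=list(df.index),
        reference_id=meta.get("reference_id"),
    )


def write_coupling_model(model: CouplingModel, path: str | Path) -> None:
    payload = {
        "coefficients": model.coefficients.tolist(),
        "tr_seconds": model.tr_seconds,
        "r_squared": None if model.r_squared is None else model.r_squared.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_coupling_model(path: str | Path) -> CouplingModel:
    payload = json.loads(Path(path).read_text())
    r2 = payload["r_squared"]
    return CouplingModel(
        np.asarray(payload["coefficients"]),
        tr_seconds=payload["tr_seconds"],
        r_squared=None if r2 is None else np.asarray(r2),
    )
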