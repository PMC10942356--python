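"""File I/O: delimited matrices, embeddings with provenance, run manifests.

Matrices travel as CSV/TSV with a header row of feature names and the first
column holding subject IDs. Numbers are written with 6 significant digits;
computation is always double precision in memory. A minimal little-endian
binary matrix format (8-byte shape header: two uint32 for rows and columns,
followed by row-major float64 values) is available for large matrices.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import Embedding
from .evaluation import OutcomeTable
from .graph import DataMatrix
from .multiview import ExogenousMatrix
from .synthetic import SyntheticDataset

__all__ = [
    "read_data_matrix",
    "write_data_matrix",
    "read_exogenous",
    "write_exogenous",
    "read_outcomes",
    "write_embedding",
    "read_embedding",
    "write_binary_matrix",
    "read_binary_matrix",
    "write_dataset",
    "file_sha256",
]

_FLOAT_FORMAT = "%.6g"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def read_data_matrix(path: str | Path, view_name: str = "view") -> DataMatrix:
    """Read a subjects x features matrix from CSV/TSV (IDs in column 1)."""
    df = _read_table(path)
    return DataMatrix(
        subject_ids=[str(s) for s in df.index],
        values=df.to_numpy(dtype=float),
        view_name=view_name,
    )


def write_data_matrix(data: DataMatrix, path: str | Path,
                      feature_names: Sequence[str] | None = None) -> None:
    path = Path(path)
    names = feature_names or [f"f{j}" for j in range(data.n_features)]
    df = pd.DataFrame(data.values, index=data.subject_ids, columns=names)
    df.index.name = "subject_id"
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FORMAT)


def read_exogenous(path: str | Path, columns: Sequence[str] | None = None) -> ExogenousMatrix:
    """Read the exogenous-covariate table; ``columns`` selects a score
    subset (e.g. a single-variable variant)."""
    df = _read_table(path)
    if columns is not None:
        missing = set(columns) - set(df.columns)
        if missing:
            raise ValueError(f"exogenous columns not found: {sorted(missing)}")
        df = df[list(columns)]
    return ExogenousMatrix(
        subject_ids=[str(s) for s in df.index],
        values=df.to_numpy(dtype=float),
        feature_names=list(df.columns),
    )


def write_exogenous(env: ExogenousMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(env.values, index=env.subject_ids, columns=env.feature_names)
    df.index.name = "subject_id"
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FORMAT)


def read_outcomes(
    path: str | Path,
    outcome_columns: Sequence[str],
    covariate_columns: Sequence[str] = (),
) -> OutcomeTable:
    """Read outcomes plus covariates from one table."""
    df = _read_table(path)
    missing = (set(outcome_columns) | set(covariate_columns)) - set(df.columns)
    if missing:
        raise ValueError(f"outcome/covariate columns not found: {sorted(missing)}")
    cov = df[list(covariate_columns)] if covariate_columns else None
    return OutcomeTable(
        subject_ids=[str(s) for s in df.index],
        outcomes=df[list(outcome_columns)].astype(float),
        covariates=cov,
    )


def write_embedding(emb: Embedding, path: str | Path) -> None:
    """Embedding CSV (ID + D coordinate columns) plus a JSON provenance
    sidecar (same stem, ``.provenance.json``)."""
    path = Path(path)
    D = emb.coords.shape[1]
    df = pd.DataFrame(emb.coords, index=emb.subject_ids,
                      columns=[f"dim{j + 1}" for j in range(D)])
    df.index.name = "subject_id"
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FORMAT)
    sidecar = path.with_suffix(".provenance.json")
    record = {
        "method": emb.method,
        "n_components": D,
        "params": _jsonable(emb.params),
        "seed": emb.seed,
        "stress": emb.stress,
    }
    sidecar.write_text(json.dumps(record, indent=2) + "\n")


def read_embedding(path: str | Path) -> Embedding:
    df = _read_table(path)
    sidecar = Path(path).with_suffix(".provenance.json")
    record = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Embedding(
        subject_ids=[str(s) for s in df.index],
        coords=df.to_numpy(dtype=float),
        method=record.get("method", "unknown"),
        params=record.get("params", {}),
        seed=record.get("seed"),
        stress=record.get("stress"),
    )


def write_binary_matrix(values: np.ndarray, path: str | Path) -> None:
    """Little-endian binary matrix: uint32 rows, uint32 cols, float64 data."""
    values = np.ascontiguousarray(values, dtype="<f8")
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    with open(path, "wb") as fh:
        fh.write(struct.pack("<II", *values.shape))
        fh.write(values.tobytes(order="C"))


def read_binary_matrix(path: str | Path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(8)
        if len(header) != 8:
            raise ValueError(f"truncated binary matrix file: {path}")
        rows, cols = struct.unpack("<II", header)
        data = np.frombuffer(fh.read(), dtype="<f8")
    if data.size != rows * cols:
        raise ValueError(f"binary matrix payload does not match header shape: {path}")
    return data.reshape(rows, cols).astype(float)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic dataset's views, outcomes, latents and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "brain": outdir / "brain.csv",
        "env": outdir / "environment.csv",
        "outcomes": outdir / "outcomes.csv",
        "latents": outdir / "latents.csv",
        "config": outdir / "config.json",
    }
    write_data_matrix(dataset.brain, paths["brain"])
    write_exogenous(dataset.env, paths["env"])
    ot = dataset.outcomes
    df = ot.outcomes.copy()
    if ot.covariates is not None:
        for name in ot.covariates.columns:
            df[name] = ot.covariates[name].to_numpy()
    df.index = ot.subject_ids
    df.index.name = "subject_id"
    df.to_csv(paths["outcomes"], float_format=_FLOAT_FORMAT)
    lat = pd.DataFrame(
        dataset.latents, index=dataset.subject_ids,
        columns=[f"latent{j + 1}" for j in range(dataset.latents.shape[1])],
    )
    lat.index.name = "subject_id"
    lat.to_csv(paths["latents"], float_format=_FLOAT_FORMAT)
    from dataclasses import asdict

    paths["config"].write_text(json.dumps(_jsonable(asdict(dataset.config)), indent=2) + "\n")
    return paths


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
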