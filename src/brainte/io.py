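"""Readers and writers for the pipeline's on-disk formats.

Tabular interchange is TSV (UTF-8, '.' decimal, mandatory header); large
per-subject tensors go to an HDF5 container alongside a tidy long TSV.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from brainte.cohort import ParcellationScheme, SubjectTimeSeries

COVARIATE_COLUMNS = (
    "sex",
    "fh_group",
    "fhd",
    "age_months",
    "income_level",
    "parental_education",
    "race_ethnicity",
    "parental_mental_health",
    "prenatal_exposure",
    "scanner_model",
    "mean_fd",
    "puberty_stage",
)


def write_matrix_tsv(path: Path, matrix: np.ndarray, columns: list[str]) -> None:
    pd.DataFrame(np.asarray(matrix), columns=columns).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix file ({exc})") from exc
    return values, list(frame.columns)


def write_parcellation(path: Path, parcellation: ParcellationScheme) -> None:
    parcellation.to_frame().to_csv(path, sep="\t", index=False)


def read_parcellation(path: Path) -> ParcellationScheme:
    return ParcellationScheme.from_frame(pd.read_csv(path, sep="\t"))


def write_series(path: Path, series: SubjectTimeSeries, region_names: list[str]) -> None:
    write_matrix_tsv(path, series.data, region_names)


def read_series(path: Path, subject_id: str, expected_n: int | None = None) -> SubjectTimeSeries:
    values, columns = read_matrix_tsv(path)
    if expected_n is not None and values.shape[1] != expected_n:
        raise ValueError(
            f"{path}: series has {values.shape[1]} regions, expected {expected_n}"
        )
    return SubjectTimeSeries(subject_id=subject_id, data=values)


def write_manifest(path: Path, covariates: pd.DataFrame, series_paths: dict[str, Path]) -> None:
    table = covariates.copy()
    table.insert(1, "series_path", [str(series_paths[s]) for s in table["subject_id"]])
    table.to_csv(path, sep="\t", index=False)


def read_manifest(path: Path) -> pd.DataFrame:
    """Validated covariate manifest with a ``series_path`` column.

    Errors name the offending file/line; series files are loaded lazily by
    callers via :func:`read_series`.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = {"subject_id", "series_path", *COVARIATE_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    dup = table["subject_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}:{line}: duplicate subject_id {table['subject_id'][dup.idxmax()]!r}")
    return table


def load_cohort_series(manifest: pd.DataFrame, expected_n: int, base_dir: Path | None = None):
    series = []
    for _, row in manifest.iterrows():
        p = Path(row["series_path"])
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        series.append(read_series(p, subject_id=str(row["subject_id"]), expected_n=expected_n))
    return series


def write_te_h5(path: Path, tensors: dict[str, np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        for sid, tensor in tensors.items():
            f.create_dataset(sid, data=tensor)


def read_te_h5(path: Path) -> dict[str, np.ndarray]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            out[sid] = f[sid][()]
    return out


def write_te_long(path: Path, tensors: dict[str, np.ndarray], region_names: list[str]) -> None:
    rows = []
    for sid, tensor in tensors.items():
        n, k, _ = tensor.shape
        for i in range(n):
            for s in range(k):
                for t in range(k):
                    rows.append((sid, region_names[i], s, t, tensor[i, s, t]))
    pd.DataFrame(
        rows, columns=["subject_id", "region", "from_state", "to_state", "energy"]
    ).to_csv(path, sep="\t", index=False)


def read_te_long(path: Path, region_names: list[str]) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path, sep="\t")
    idx = {r: i for i, r in enumerate(region_names)}
    out: dict[str, np.ndarray] = {}
    k = int(frame["to_state"].max()) + 1
    for sid, group in frame.groupby("subject_id", sort=False):
        tensor = np.zeros((len(region_names), k, k))
        tensor[
            group["region"].map(idx).to_numpy(),
            group["from_state"].to_numpy(),
            group["to_state"].to_numpy(),
        ] = group["energy"].to_numpy()
        out[str(sid)] = tensor
    return out


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json_atomic(path: Path, payload: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as f:
        json.dump(payload, f, indent=2, sort_keys=True, default=str)
    os.replace(tmp, path)
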