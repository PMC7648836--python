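"""Tabular readers/writers and table alignment.

Canonical on-disk format: UTF-8 TSV with a header row, "NA" for missing
values, decimal point; CSV is accepted on read. All tables are keyed by a
unique ``subject_id`` column and aligned by sorting on it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

NA_VALUES = ["NA", ""]


class TableError(ValueError):
    pass


def _read(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, na_values=NA_VALUES,
                       keep_default_na=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class AlignedTables:
    """Covariate/feature/clinical tables aligned by subject_id."""

    covariates: pd.DataFrame
    features: pd.DataFrame
    clinical: Optional[pd.DataFrame] = None
    parcels: Optional[np.ndarray] = None
    dropped_subjects: list = field(default_factory=list)


def _check_ids(df: pd.DataFrame, name: str) -> None:
    if "subject_id" not in df.columns:
        raise TableError(f"{name} table lacks a subject_id column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise TableError(
            f"duplicate subject_id in {name} table: {sorted(set(dup))}")


def read_tables(covariates_path: str | Path, features_path: str | Path,
                clinical_path: Optional[str | Path] = None,
                parcels_path: Optional[str | Path] = None) -> AlignedTables:
    """Read and align the input tables by subject_id (sorted order).

    Covariate rows without a matching feature row are dropped and reported
    in ``dropped_subjects``; clinical rows are restricted to aligned
    subjects. Parcel labels must match the feature count.
    """
    covariates = _read(covariates_path)
    features = _read(features_path)
    _check_ids(covariates, "covariate")
    _check_ids(features, "feature")
    cov_ids = set(covariates["subject_id"])
    feat_ids = set(features["subject_id"])
    dropped = sorted(cov_ids - feat_ids)
    keep = sorted(cov_ids & feat_ids)
    covariates = (covariates[covariates["subject_id"].isin(keep)]
                  .sort_values("subject_id").reset_index(drop=True))
    features = (features[features["subject_id"].isin(keep)]
                .sort_values("subject_id").reset_index(drop=True))
    clinical = None
    if clinical_path is not None:
        clinical = _read(clinical_path)
        _check_ids(clinical, "clinical")
        clinical = (clinical[clinical["subject_id"].isin(keep)]
                    .sort_values("subject_id").reset_index(drop=True))
    parcels = None
    if parcels_path is not None:
        ptab = _read(parcels_path)
        col = "parcel" if "parcel" in ptab.columns else ptab.columns[-1]
        parcels = ptab[col].to_numpy()
        n_features = features.shape[1] - 1
        if len(parcels) != n_features:
            raise TableError(
                f"parcel labels ({len(parcels)}) do not match feature count "
                f"({n_features})")
    return AlignedTables(covariates=covariates, features=features,
                         clinical=clinical, parcels=parcels,
                         dropped_subjects=dropped)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default,
                                     allow_nan=True))
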