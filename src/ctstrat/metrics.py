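"""Atypicality indices: trimmed-top-quantile summaries of deviation maps.

A subject's atypicality index is the mean of the top ``fraction`` (default
1%) largest absolute Z-scores in the deviation map — a scalar describing the
subject's maximum overall deviation from the normative pattern. Regional
indices apply the same statistic within each parcel of a feature
parcellation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .normative import DeviationMap


def atypicality_index(z_row: np.ndarray, fraction: float = 0.01) -> float:
    """Mean of the k = max(1, floor(fraction * m)) largest |Z| values.

    Small vectors degrade gracefully to the max statistic (k >= 1). NaN
    entries are an error: callers must mask them explicitly.
    """
    z = np.asarray(z_row, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty deviation vector")
    if np.isnan(z).any():
        raise ValueError("NaN entries in deviation vector; mask them first")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, math.floor(fraction * z.size))
    a = np.abs(z)
    # Stable deterministic selection: sort by (|Z| desc, index asc), take k.
    order = np.argsort(-a, kind="stable")
    return float(a[order[:k]].mean())


def regional_atypicality(deviations: DeviationMap, parcels: np.ndarray,
                         fraction: float = 0.01) -> pd.DataFrame:
    """Global and per-parcel atypicality indices for every subject.

    Returns a DataFrame with columns ``subject_id``, ``global``, and
    ``parcel_<p>`` for each parcel label; the top-fraction count is computed
    per parcel (minimum 1 feature).
    """
    parcels = np.asarray(parcels)
    if parcels.shape[0] != len(deviations.feature_ids):
        raise ValueError("parcel labels must cover all features")
    out = {"subject_id": deviations.subject_id,
           "global": np.array([atypicality_index(row, fraction)
                               for row in deviations.z])}
    for parcel in np.unique(parcels):
        idx = np.where(parcels == parcel)[0]
        if idx.size == 0:
            raise ValueError(f"empty parcel {parcel}")
        out[f"parcel_{parcel}"] = np.array(
            [atypicality_index(row[idx], fraction) for row in deviations.z])
    return pd.DataFrame(out)
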