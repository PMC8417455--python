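"""Time integration: per-epoch median adjustment, then the 75th percentile.

Per-epoch feature values are noisy and drift together across channels (state
changes, medication, technical shifts move every channel at once).  Two steps
collapse them to one value per channel and feature:

1. *Median adjustment* — for each epoch, subtract the across-channel median,
   removing any common temporal shift.  The adjusted features measure each
   channel *relative to the rest of the implant at the same moment*.
2. *Q75 integration* — for each channel, take the 75th percentile of the
   adjusted values over all epochs, emphasising the epochs where the channel
   is most abnormal without being dominated by single outliers.

The percentile convention places the k-th order statistic of n values at
percentile 100*(k-0.5)/n with linear interpolation and clamping at the
extremes (the Hazen convention; Q75 of {1,2,3,4} is 3.5).  A
linear-interpolation variant is available via ``method``.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .features import FEATURE_IDS

PERCENTILE = 75.0
DEFAULT_METHOD = "hazen"


def median_adjust(F: np.ndarray) -> np.ndarray:
    """Subtract the across-channel median from every epoch column.

    ``F`` is a channels x epochs matrix of one feature (NaN allowed for
    flagged-missing records).  After adjustment every epoch's across-channel
    median is zero; adding any per-epoch constant to all channels leaves the
    output unchanged.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError("expected a channels x epochs matrix")
    if F.shape[0] < 2:
        raise ValueError(
            "median adjustment needs >= 2 channels (a single channel would be "
            "annihilated)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(F, axis=0, keepdims=True)
    return F - med


def integrate_q75(
    v: np.ndarray, q: float = PERCENTILE, method: str = DEFAULT_METHOD
) -> float:
    """Percentile of one channel's adjusted feature over epochs (NaN skipped)."""
    v = np.asarray(v, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        warnings.warn("no finite epoch values; channel value is missing")
        return np.nan
    return float(np.percentile(v, q, method=method))


def integrate_features(
    epoch_table: pd.DataFrame,
    q: float = PERCENTILE,
    method: str = DEFAULT_METHOD,
) -> pd.DataFrame:
    """Reduce a long-format epoch feature table to one row per channel.

    Input columns: patient, channel, epoch, band, f1..f19 (NaN for invalid
    records).  Output: one row per (patient, channel) with wide feature
    columns ``band1_f1 .. bandB_f19`` plus ``n_epochs_used`` (the minimum
    epoch count over features).  Median adjustment runs separately per
    patient, band and feature over all of that patient's channels.
    """
    out_rows: dict[tuple[str, str], dict] = {}
    n_used: dict[tuple[str, str], int] = {}
    for (patient, band), sub in epoch_table.groupby(["patient", "band"], sort=True):
        for fid in FEATURE_IDS:
            pivot = sub.pivot_table(
                index="channel", columns="epoch", values=fid, dropna=False
            )
            adj = median_adjust(pivot.to_numpy())
            for i, channel in enumerate(pivot.index):
                key = (patient, channel)
                row = out_rows.setdefault(key, {"patient": patient, "channel": channel})
                row[f"{band}_{fid}"] = integrate_q75(adj[i], q=q, method=method)
                n_fin = int(np.isfinite(adj[i]).sum())
                n_used[key] = min(n_used.get(key, np.inf), n_fin)
    frame = pd.DataFrame(list(out_rows.values()))
    frame["n_epochs_used"] = [int(n_used[k]) for k in out_rows]
    return frame.sort_values(["patient", "channel"]).reset_index(drop=True)
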