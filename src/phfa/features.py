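"""Morphology features of the high-frequency background (19 per band).

Each feature is built in three steps from the band-filtered, event-redacted
samples ``x`` of one channel/epoch:

1. *Normalisation.*  With one exception (``f5``), features start from
   ``y = (x - mean(x)) / sd(x)``, so they measure waveform shape rather than
   amplitude.  ``f5 = 10*log10(sd(x))`` is the only amplitude feature.
2. *Transformation.*  Identity, rectification ``R(y)_j = |y_j|``, line length
   ``L(y)_j = |y_{j+1} - y_j| * fS``, curvature
   ``C(y)_j = |y_{j+2} + y_j - 2*y_{j+1}| * fS**2`` and Teager-Kaiser energy
   ``T(y)_j = (y_j**2 - y_{j+1}*y_{j-1}) * fS**2``, with ``fS`` the sampling
   rate in kHz so units are per millisecond, independent of the inter-sample
   interval.
3. *Statistic + scaling.*  Mean, standard deviation, skewness or kurtosis of
   the transformed samples; decibel scaling ``10*log10`` for the nonnegative
   statistics and ``arctan`` for skewness (which can be negative).

Transforms are evaluated within each contiguous post-redaction segment so no
finite difference ever spans a redaction gap; transformed samples are pooled
across segments before the statistics.

The 19 features per band:

========  =================================  ========  ==================================
id        definition                         id        definition
========  =================================  ========  ==================================
f1        10*log10(mean(R(y)))               f11       arctan(skew(R(y)))
f2        10*log10(mean(L(y)))               f12       arctan(skew(L(y)))
f3        10*log10(mean(C(y)))               f13       arctan(skew(C(y)))
f4        10*log10(mean(T(y)))               f14       arctan(skew(T(y)))
f5        10*log10(sd(x))                    f15       10*log10(kurt(y))
f6        10*log10(sd(D(y)))                 f16       10*log10(kurt(D(y)))
f7        10*log10(sd(L(y)))                 f17       10*log10(kurt(L(y)))
f8        10*log10(sd(C(y)))                 f18       10*log10(kurt(C(y)))
f9        10*log10(sd(T(y)))                 f19       10*log10(kurt(T(y)))
========  =================================  ========  ==================================

``D(y)_j = (y_{j+1} - y_j) * fS`` is the signed first difference (so
``L = |D|``).  Conventions, pinned once and used everywhere: standard
deviations use the sample (n-1) denominator; skewness and kurtosis are the
moment ratios ``m3 / m2**1.5`` and ``m4 / m2**2`` (kurtosis non-excess, which
keeps every log argument positive; an excess-kurtosis variant is available via
``kurtosis="excess"``).  A non-positive log argument (possible for ``mean(T)``
or excess kurtosis) flags the record invalid rather than emitting infinities.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_FEATURES_PER_BAND = 19
FEATURE_IDS = [f"f{i}" for i in range(1, N_FEATURES_PER_BAND + 1)]

#: Minimum usable fraction of the nominal epoch below which a record is dropped.
MIN_USED_FRACTION = 0.25


def feature_columns(n_bands: int = 2) -> list[str]:
    """Wide-format column names, e.g. ``band1_f1 .. band2_f19`` (38 for 2 bands)."""
    return [
        f"band{b}_{f}" for b in range(1, n_bands + 1) for f in FEATURE_IDS
    ]


def normalize(x: np.ndarray, mean: float | None = None, sd: float | None = None) -> np.ndarray:
    """Zero-mean, unit-sd standardisation (sample sd, n-1 denominator)."""
    x = np.asarray(x, dtype=np.float64)
    mu = float(np.mean(x)) if mean is None else mean
    sigma = float(np.std(x, ddof=1)) if sd is None else sd
    if not sigma > 0:
        raise ValueError("cannot normalize a constant (zero-variance) signal")
    return (x - mu) / sigma


def rectify(y: np.ndarray) -> np.ndarray:
    return np.abs(y)


def first_difference(y: np.ndarray, fs_khz: float) -> np.ndarray:
    """Signed first difference scaled to per-millisecond units (length n-1)."""
    y = np.asarray(y, dtype=np.float64)
    _require(y, 2)
    return np.diff(y) * fs_khz


def line_length(y: np.ndarray, fs_khz: float) -> np.ndarray:
    """|first difference| * fS (length n-1)."""
    return np.abs(first_difference(y, fs_khz))


def curvature(y: np.ndarray, fs_khz: float) -> np.ndarray:
    """|second difference| * fS^2 (length n-2)."""
    y = np.asarray(y, dtype=np.float64)
    _require(y, 3)
    return np.abs(y[2:] + y[:-2] - 2.0 * y[1:-1]) * fs_khz**2


def teager(y: np.ndarray, fs_khz: float) -> np.ndarray:
    """Teager-Kaiser energy (y_j^2 - y_{j+1} y_{j-1}) * fS^2 (length n-2)."""
    y = np.asarray(y, dtype=np.float64)
    _require(y, 3)
    return (y[1:-1] ** 2 - y[2:] * y[:-2]) * fs_khz**2


def _require(y: np.ndarray, n: int) -> None:
    if y.shape[-1] < n:
        raise ValueError(f"input too short: need at least {n} samples")


def moments(v: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd, skewness, kurtosis) of a pooled sample.

    Two-pass computation on centred powers (numpy pairwise summation), so the
    result is stable and permutation-invariant to ~1e-9 relative.  sd uses the
    n-1 denominator; skew and kurt are the biased moment ratios
    ``m3/m2^1.5`` and ``m4/m2^2`` (kurtosis non-excess: 3 for a normal).
    """
    v = np.asarray(v, dtype=np.float64)
    n = v.size
    if n < 4:
        raise ValueError("need at least 4 samples for four moments")
    mu = float(np.mean(v))
    d = v - mu
    d2 = d * d
    m2 = float(np.mean(d2))
    if not m2 > 0:
        raise ValueError("zero variance: skewness/kurtosis undefined")
    m3 = float(np.mean(d2 * d))
    m4 = float(np.mean(d2 * d2))
    sd = float(np.sqrt(m2 * n / (n - 1)))
    return mu, sd, m3 / m2**1.5, m4 / m2**2


@dataclass
class EpochFeatureRecord:
    """Feature values for one (channel, epoch, band) combination."""

    patient: str
    channel: str
    epoch_index: int
    band: str
    values: dict  # f1..f19 -> float
    n_samples_used: int
    fs_khz: float
    valid: bool = True
    reason: str = ""


def _db(value: float) -> float:
    if not value > 0:
        raise FloatingPointError(f"non-positive dB argument: {value}")
    return 10.0 * np.log10(value)


def compute_epoch_features(
    segments: list[np.ndarray],
    fs: float,
    *,
    patient: str = "",
    channel: str = "",
    epoch_index: int = 0,
    band: str = "",
    nominal_n: int | None = None,
    min_used_fraction: float = MIN_USED_FRACTION,
    kurtosis: str = "pearson",
) -> EpochFeatureRecord:
    """Compute f1..f19 from the redacted, filtered segments of one epoch.

    ``segments`` are the contiguous sample runs surviving redaction for one
    channel/epoch in one band.  Normalisation statistics are pooled over the
    used samples only; each transform is evaluated per segment (segments
    shorter than the transform's support contribute nothing) and the
    transformed samples are pooled before the moments.
    """
    if kurtosis not in ("pearson", "excess"):
        raise ValueError("kurtosis must be 'pearson' or 'excess'")
    fs_khz = fs / 1000.0
    segments = [np.asarray(s, dtype=np.float64) for s in segments if len(s)]
    n_used = int(sum(s.size for s in segments))
    rec = EpochFeatureRecord(
        patient, channel, epoch_index, band, {}, n_used, fs_khz
    )
    floor = int(np.ceil(min_used_fraction * nominal_n)) if nominal_n else 4
    if n_used < max(floor, 4):
        rec.valid = False
        rec.reason = f"only {n_used} usable samples (minimum {max(floor, 4)})"
        return rec

    x = np.concatenate(segments)
    mu_x = float(np.mean(x))
    sd_x = float(np.std(x, ddof=1))
    if not sd_x > 0:
        rec.valid = False
        rec.reason = "degenerate (constant) signal"
        return rec

    y_segs = [(s - mu_x) / sd_x for s in segments]
    y = np.concatenate(y_segs)
    pooled = {
        "R": np.concatenate([rectify(s) for s in y_segs]),
        "D": np.concatenate(
            [first_difference(s, fs_khz) for s in y_segs if s.size >= 2]
        ),
        "L": np.concatenate(
            [line_length(s, fs_khz) for s in y_segs if s.size >= 2]
        ),
        "C": np.concatenate(
            [curvature(s, fs_khz) for s in y_segs if s.size >= 3]
        ),
        "T": np.concatenate(
            [teager(s, fs_khz) for s in y_segs if s.size >= 3]
        ),
    }

    excess = 3.0 if kurtosis == "excess" else 0.0
    try:
        m = {k: moments(v) for k, v in pooled.items()}
        m["y"] = moments(y)
        f = {}
        f["f1"] = _db(np.mean(pooled["R"]))
        f["f2"] = _db(np.mean(pooled["L"]))
        f["f3"] = _db(np.mean(pooled["C"]))
        f["f4"] = _db(np.mean(pooled["T"]))
        f["f5"] = _db(sd_x)
        f["f6"] = _db(m["D"][1])
        f["f7"] = _db(m["L"][1])
        f["f8"] = _db(m["C"][1])
        f["f9"] = _db(m["T"][1])
        for fid, key in zip(
            ("f10", "f11", "f12", "f13", "f14"), ("y", "R", "L", "C", "T")
        ):
            f[fid] = float(np.arctan(m[key][2]))
        f["f15"] = _db(m["y"][3] - excess)
        f["f16"] = _db(m["D"][3] - excess)
        f["f17"] = _db(m["L"][3] - excess)
        f["f18"] = _db(m["C"][3] - excess)
        f["f19"] = _db(m["T"][3] - excess)
    except (FloatingPointError, ValueError) as exc:
        rec.valid = False
        rec.reason = str(exc)
        return rec

    rec.values = f
    return rec


def records_to_frame(records: list[EpochFeatureRecord]) -> pd.DataFrame:
    """Long-format epoch feature table (one row per channel/epoch/band).

    Columns: patient, channel, epoch, band, f1..f19, n_samples_used, valid.
    Invalid records keep NaN feature values; downstream integration skips them.
    """
    rows = []
    for r in records:
        row = {
            "patient": r.patient,
            "channel": r.channel,
            "epoch": r.epoch_index,
            "band": r.band,
        }
        for fid in FEATURE_IDS:
            row[fid] = r.values.get(fid, np.nan)
        row["n_samples_used"] = r.n_samples_used
        row["valid"] = r.valid
        rows.append(row)
    return pd.DataFrame(rows)
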