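"""Per-patient asymmetry of channel biomarkers with respect to labelled regions.

For a nonnegative biomarker (HFO rate, pHFA score, or their product) the
asymmetry with respect to a labelled channel set is

    A = (x_in - x_out) / (x_in + x_out),

where ``x_in`` / ``x_out`` are the biomarker means over channels inside /
outside the region (seizure-onset zone, resected volume, or temporal lobe).
A lies in [-1, 1], is scale invariant (so the differing units of HFO rate and
pHFA cannot affect it), and serves as a per-patient effect size.  Cohort
summaries report the median asymmetry with a 95% bootstrap-percentile
confidence interval, and paired differences compare two biomarkers patient by
patient.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

N_BOOT = 10_000


def asymmetry(values: np.ndarray, in_mask: np.ndarray) -> float:
    """(mean_in - mean_out) / (mean_in + mean_out) over channels.

    Both groups must be non-empty; a zero denominator (both means zero) gives
    NaN with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    in_mask = np.asarray(in_mask, dtype=bool)
    if values.shape != in_mask.shape:
        raise ValueError("values and in_mask must align")
    if np.any(values < 0):
        raise ValueError("asymmetry is defined for nonnegative biomarkers")
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 1 or n_out < 1:
        raise ValueError(
            f"both groups must be non-empty (n_in={n_in}, n_out={n_out})"
        )
    x_in = values[in_mask].mean()
    x_out = values[~in_mask].mean()
    denom = x_in + x_out
    if denom == 0:
        warnings.warn("x_in + x_out = 0; asymmetry undefined")
        return np.nan
    return float((x_in - x_out) / denom)


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = N_BOOT,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile-bootstrap CI of the median (fixed seed for reproducibility)."""
    values = np.asarray(values, dtype=np.float64)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def cohort_summary(
    A: np.ndarray, n_boot: int = N_BOOT, seed: int = 0
) -> dict:
    """Cohort median asymmetry with a 95% bootstrap CI.

    With fewer than 3 patients the median is still reported but the CI is
    flagged unavailable (NaN bounds).
    """
    A = np.asarray(A, dtype=np.float64)
    A = A[np.isfinite(A)]
    if A.size == 0:
        raise ValueError("no finite asymmetry values")
    median = float(np.median(A))
    if A.size < 3:
        warnings.warn("fewer than 3 patients: CI unavailable")
        return {"median": median, "ci_lo": np.nan, "ci_hi": np.nan, "n": int(A.size)}
    lo, hi = bootstrap_median_ci(A, n_boot=n_boot, seed=seed)
    return {"median": median, "ci_lo": lo, "ci_hi": hi, "n": int(A.size)}


def paired_difference(
    A_a: pd.Series, A_b: pd.Series, n_boot: int = N_BOOT, seed: int = 0
) -> dict:
    """Median per-patient difference A_b - A_a with a 95% bootstrap CI.

    Series are indexed by patient; patients missing either biomarker are
    excluded (logged via warning).
    """
    joined = pd.concat({"a": A_a, "b": A_b}, axis=1)
    dropped = joined[joined.isna().any(axis=1)]
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} patient(s) missing one biomarker"
        )
    joined = joined.dropna()
    if not len(joined):
        raise ValueError("no patients present for both biomarkers")
    delta = (joined["b"] - joined["a"]).to_numpy()
    out = cohort_summary(delta, n_boot=n_boot, seed=seed)
    out["n_pairs"] = len(joined)
    return out


def asymmetry_table(
    scores: pd.DataFrame,
    channel_labels: pd.DataFrame,
    biomarkers: tuple[str, ...] = ("hfo_rate", "phfa", "product"),
    labels: tuple[str, ...] = ("soz", "rv", "tl"),
) -> pd.DataFrame:
    """Long-format per-patient asymmetries for each biomarker x label pair.

    ``scores`` has one row per channel with ``patient``, ``channel`` and the
    biomarker columns; ``channel_labels`` carries ``patient``, ``channel`` and
    binary label columns.  Patients whose label is all-0 or all-1 are skipped
    for that label (the asymmetry is undefined).
    """
    overlap = [c for c in labels if c in scores.columns]
    merged = scores.drop(columns=overlap).merge(
        channel_labels, on=["patient", "channel"], how="inner"
    )
    rows = []
    for patient, sub in merged.groupby("patient", sort=True):
        for label in labels:
            mask = sub[label].to_numpy(dtype=bool)
            if mask.all() or not mask.any():
                continue
            for biom in biomarkers:
                if biom not in sub.columns:
                    continue
                rows.append(
                    {
                        "patient": patient,
                        "biomarker": biom,
                        "label": label,
                        "A": asymmetry(sub[biom].to_numpy(), mask),
                        "n_in": int(mask.sum()),
                        "n_out": int((~mask).sum()),
                    }
                )
    return pd.DataFrame(rows)


def summarize_asymmetries(
    table: pd.DataFrame, n_boot: int = N_BOOT, seed: int = 0
) -> pd.DataFrame:
    """Cohort median + CI per (biomarker, label) from an asymmetry table."""
    rows = []
    for (biom, label), sub in table.groupby(["biomarker", "label"], sort=True):
        s = cohort_summary(sub["A"].to_numpy(), n_boot=n_boot, seed=seed)
        rows.append({"biomarker": biom, "label": label, **s})
    return pd.DataFrame(rows)


def plot_asymmetries(table: pd.DataFrame, label: str = "soz", ax=None):
    """Strip plot of per-patient asymmetries with cohort medians."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    sub = table[table["label"] == label]
    bioms = sorted(sub["biomarker"].unique())
    for i, biom in enumerate(bioms):
        vals = sub.loc[sub["biomarker"] == biom, "A"]
        ax.plot(np.full(len(vals), i), vals, "o", ms=4, alpha=0.6)
        ax.hlines(np.median(vals), i - 0.2, i + 0.2, color="k")
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xticks(range(len(bioms)))
    ax.set_xticklabels(bioms)
    ax.set_ylabel("asymmetry A")
    ax.set_title(label.upper())
    ax.set_ylim(-1.05, 1.05)
    return ax
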