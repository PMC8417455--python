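"""Simulation experiments that validate the statistical machinery.

These are the package's own calibration studies, in the spirit of the
simulation checks that accompany statistical software: they quantify, under
known data-generating processes, whether the association test keeps its
nominal type-I error, whether planted odds ratios are recovered, and whether
the end-to-end pipeline separates pathological from normal channels on
synthetic cohorts with a planted high-band contrast.  The same entry points
back the package's reproducibility script and its test suite.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .association import FeatureAssociation, smad
from .asymmetry import asymmetry_table
from .integrate import integrate_features
from .pipeline import PipelineConfig, extract_patient_features
from .scoring import lopo_scores
from .simulate import CohortSpec, generate_patient

#: Scaled-down end-to-end cohort: 20 patients, 8 channels (2 SOZ, 3 RV),
#: six 5-minute epochs at 2048 Hz.
ENDTOEND_COHORT = dict(
    n_patients=20,
    channels_per_patient=8,
    n_soz=2,
    n_rv=3,
    epoch_count=6,
    fs=2048.0,
)


def _single_feature_cohort(
    rng: np.random.Generator,
    n_patients: int,
    n_channels: int,
    beta1: float,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """One simulated cohort for the association test: a single Gaussian
    feature per channel and labels drawn from a logistic model with slope
    ``beta1`` per sMAD (``beta1 = 0`` gives a null cohort)."""
    n = n_patients * n_channels
    f = rng.standard_normal(n)
    patients = np.repeat([f"p{i:03d}" for i in range(n_patients)], n_channels)
    eta = -1.0 + beta1 * f / smad(f)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"feat": f}), y, patients


def null_type1_error(
    n_cohorts: int = 2000,
    n_patients: int = 10,
    n_channels: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the patient-weighted association test.

    Simulates ``n_cohorts`` label-independent cohorts and returns the
    fraction in which the feature's p-value falls below ``alpha``.  Cohorts
    where a class is absent or the fit separates are redrawn.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    done = 0
    while done < n_cohorts:
        feats, y, patients = _single_feature_cohort(
            rng, n_patients, n_channels, beta1=0.0
        )
        if y.min() == y.max():
            continue
        row = FeatureAssociation(feats, y, patients).fit(n_tests=1).table.iloc[0]
        if not np.isfinite(row["p"]):
            continue
        rejections += row["p"] < alpha
        done += 1
    return rejections / n_cohorts


def or_recovery(
    n_cohorts: int = 30,
    beta1: float = float(np.log(1.5)),
    n_patients: int = 40,
    n_channels: int = 50,
    seed: int = 0,
) -> float:
    """Mean recovered odds ratio across cohorts with a planted slope."""
    rng = np.random.default_rng(seed)
    ors = []
    while len(ors) < n_cohorts:
        feats, y, patients = _single_feature_cohort(
            rng, n_patients, n_channels, beta1=beta1
        )
        if y.min() == y.max():
            continue
        row = FeatureAssociation(feats, y, patients).fit(n_tests=1).table.iloc[0]
        if np.isfinite(row["or"]):
            ors.append(row["or"])
    return float(np.mean(ors))


def run_synthetic_cohort(
    band_power_gain: float,
    seed: int,
    cohort: dict | None = None,
) -> dict:
    """Full pipeline on a synthetic cohort; returns discrimination metrics.

    ``band_power_gain > 1`` plants the pathological contrast (with bursts and
    elevated SOZ HFO rates); ``band_power_gain = 1`` is the matching null
    cohort (no bursts, equal HFO rates everywhere).

    Returns LOPO AUC, per-(biomarker, label) median asymmetries, the fraction
    of patients whose SOZ channels have elevated integrated band-2 amplitude
    (f5), and the channel score table.
    """
    planted = band_power_gain > 1
    spec = CohortSpec(
        seed=seed,
        band_power_gain=band_power_gain,
        burst_rate=10.0 if planted else 0.0,
        hfo_rate_in=3.0 if planted else 0.3,
        hfo_rate_out=0.3,
        **(ENDTOEND_COHORT if cohort is None else cohort),
    )
    config = PipelineConfig(seed=seed)
    epoch_tables, rate_tables, metas = [], [], []
    for i in range(spec.n_patients):
        rec, ann, gt = generate_patient(spec, i)
        et, rt = extract_patient_features(rec, ann, config)
        epoch_tables.append(et)
        rate_tables.append(rt)
        metas.append(gt.channels)
    epoch_table = pd.concat(epoch_tables, ignore_index=True)
    rates = pd.concat(rate_tables, ignore_index=True)
    meta = pd.concat(metas, ignore_index=True).rename(columns={"name": "channel"})

    channel_features = integrate_features(epoch_table)
    merged = channel_features.merge(meta, on=["patient", "channel"]).merge(
        rates, on=["patient", "channel"]
    )
    f5_elevated = np.mean(
        [
            sub.loc[sub.soz == 1, "band2_f5"].mean()
            > sub.loc[sub.soz == 0, "band2_f5"].mean()
            for _, sub in merged.groupby("patient")
        ]
    )
    fcols = [c for c in channel_features.columns if c.startswith("band")]
    res = lopo_scores(
        merged[fcols],
        merged["soz"].to_numpy(),
        merged["patient"].to_numpy(),
        hfo_rates=merged["hfo_rate"].to_numpy(),
        channels=merged["channel"].to_numpy(),
    )
    auc = float(roc_auc_score(res.scores["soz"], res.scores["phfa"]))
    atab = asymmetry_table(res.scores, meta)
    medians = atab.groupby(["biomarker", "label"])["A"].median().to_dict()
    return {
        "auc": auc,
        "median_asymmetry": medians,
        "f5_band2_soz_elevated_fraction": float(f5_elevated),
        "scores": res.scores,
        "asymmetries": atab,
        "fold_k": {p: m.k_ for p, m in res.fold_models.items()},
    }
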