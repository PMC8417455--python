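"""End-to-end orchestration: simulate -> preprocess -> features -> scores.

A :class:`PipelineConfig` pins every tunable of the analysis (bands, epoch
length, interictal margin, percentile, PCA variance threshold, kurtosis
convention, Bonferroni family size, bootstrap replicates, master seed) and is
written verbatim, with a content hash, into the run manifest so that any
output can be traced to the exact configuration that produced it.  Reruns
with the same configuration reproduce all outputs bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import DEFAULT_N_TESTS, FeatureAssociation
from .asymmetry import N_BOOT, asymmetry_table, summarize_asymmetries
from .features import compute_epoch_features, records_to_frame
from .filters import DEFAULT_BANDS, apply_filter, default_bands, design_filter
from .integrate import DEFAULT_METHOD, PERCENTILE, integrate_features
from .preprocess import (
    AnnotationSet,
    Recording,
    build_epochs,
    common_average_reference,
    interictal_mask,
    redact_events,
)
from .scoring import VARIANCE_THRESHOLD, lopo_scores
from .simulate import CohortSpec, generate_patient


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    bands: tuple = DEFAULT_BANDS
    epoch_length_s: float = 300.0
    margin_s: float = 1800.0
    percentile: float = PERCENTILE
    percentile_method: str = DEFAULT_METHOD
    variance_threshold: float = VARIANCE_THRESHOLD
    kurtosis: str = "pearson"
    n_tests: int = DEFAULT_N_TESTS
    n_boot: int = N_BOOT
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides; empty = no simulation

    def __post_init__(self) -> None:
        self.bands = tuple(tuple(b) for b in self.bands)
        if not self.bands:
            raise ValueError("at least one band is required")
        for lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
        if self.kurtosis not in ("pearson", "excess"):
            raise ValueError("kurtosis must be 'pearson' or 'excess'")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.epoch_length_s <= 0 or self.margin_s < 0:
            raise ValueError("epoch_length_s > 0 and margin_s >= 0 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def cohort_spec(self) -> CohortSpec:
        kw = dict(self.cohort)
        kw.setdefault("seed", self.seed)
        kw.setdefault("epoch_length_s", self.epoch_length_s)
        return CohortSpec(**kw)


def extract_patient_features(
    rec: Recording,
    ann: AnnotationSet,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess and featurise one patient.

    Runs common-average referencing, interictal masking, epoching, band
    filtering of the full per-channel record (so redaction gaps never create
    filter transients), event redaction, and per-epoch feature computation.

    Returns the long-format epoch feature table and a per-channel HFO-rate
    table (events/min over the analysed interictal duration).
    """
    rec = common_average_reference(rec)
    mask = interictal_mask(ann, rec, config.margin_s)
    grid = build_epochs(mask, rec.fs, config.epoch_length_s)
    segs = redact_events(rec, grid, ann)
    bands = default_bands(config.bands)
    nominal_n = int(round(config.epoch_length_s * rec.fs))

    records = []
    names = rec.channels["name"].tolist()
    patient = str(rec.channels["patient"].iloc[0])
    usable = grid.table[grid.table["usable"]]
    for band in bands:
        fspec = design_filter(band, rec.fs)
        for ci, name in enumerate(names):
            filtered = apply_filter(rec.data[ci], fspec)
            for _, row in usable.iterrows():
                key = (name, int(row["index"]))
                segments = [filtered[s:e] for s, e in segs.get(key, [])]
                records.append(
                    compute_epoch_features(
                        segments,
                        rec.fs,
                        patient=patient,
                        channel=name,
                        epoch_index=int(row["index"]),
                        band=band.name,
                        nominal_n=nominal_n,
                        kurtosis=config.kurtosis,
                    )
                )
    epoch_table = records_to_frame(records)

    minutes = len(usable) * config.epoch_length_s / 60.0
    usable_iv = [
        (s / rec.fs + rec.t0, e / rec.fs + rec.t0)
        for s, e in zip(usable["start_sample"], usable["end_sample"])
    ]
    rates = []
    for name in names:
        ev = ann.events_on(name)
        hfo = ev[ev["kind"] == "hfo"] if len(ev) else ev
        n_in = sum(
            any(s <= t < e for s, e in usable_iv) for t in hfo["t_start"]
        )
        rates.append(
            {
                "patient": patient,
                "channel": name,
                "hfo_rate": n_in / minutes if minutes > 0 else np.nan,
            }
        )
    return epoch_table, pd.DataFrame(rates)


def run(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline on a simulated cohort and write all outputs.

    Stage outputs (CSV) plus ``manifest.json`` land in ``outdir``.  A stage
    failure preserves the outputs written so far and records the failure
    point in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "versions": {
            "phfa": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "failed_stage": None,
    }

    def _finish() -> Path:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return outdir

    try:
        spec = config.cohort_spec()
        epoch_tables, rate_tables, meta_tables = [], [], []
        for i in range(spec.n_patients):
            rec, ann, gt = generate_patient(spec, i)
            et, rt = extract_patient_features(rec, ann, config)
            epoch_tables.append(et)
            rate_tables.append(rt)
            meta_tables.append(gt.channels)
        epoch_table = pd.concat(epoch_tables, ignore_index=True)
        rates = pd.concat(rate_tables, ignore_index=True)
        meta = pd.concat(meta_tables, ignore_index=True).rename(
            columns={"name": "channel"}
        )
        epoch_table.to_csv(outdir / "epoch_features.csv", index=False)
        meta.to_csv(outdir / "channels.csv", index=False)
        rates.to_csv(outdir / "hfo_rates.csv", index=False)
        manifest["stages"]["features"] = {"rows": len(epoch_table)}
    except Exception as exc:  # pragma: no cover - failure plumbing
        manifest["failed_stage"] = f"features: {exc}"
        _finish()
        raise

    try:
        channel_features = integrate_features(
            epoch_table, q=config.percentile, method=config.percentile_method
        )
        channel_features.to_csv(outdir / "channel_features.csv", index=False)
        manifest["stages"]["integrate"] = {
            "rows": len(channel_features),
            "percentile_method": config.percentile_method,
        }

        merged = channel_features.merge(meta, on=["patient", "channel"])
        merged = merged.merge(rates, on=["patient", "channel"])
        fcols = [
            c for c in channel_features.columns
            if c.startswith("band") and "_f" in c
        ]

        for label in ("soz", "rv", "tl"):
            y = merged[label].to_numpy()
            if len(set(y)) < 2:
                warnings.warn(f"label {label}: single class; association skipped")
                continue
            res = FeatureAssociation(
                merged[fcols], y, merged["patient"].to_numpy(),
                label_name=label.upper(),
            ).fit(n_tests=config.n_tests)
            res.table.to_csv(outdir / f"association_{label}.csv", index=False)
        FeatureAssociation(
            merged[fcols], merged["soz"].to_numpy(),
            merged["patient"].to_numpy(),
        ).fit().correlation_matrix().to_csv(outdir / "feature_correlation.csv")
        manifest["stages"]["associate"] = {"n_features": len(fcols)}

        lopo = lopo_scores(
            merged[fcols],
            merged["soz"].to_numpy(),
            merged["patient"].to_numpy(),
            hfo_rates=merged["hfo_rate"].to_numpy(),
            channels=merged["channel"].to_numpy(),
            variance_threshold=config.variance_threshold,
        )
        lopo.scores.to_csv(outdir / "scores.csv", index=False)
        fold_meta = {
            str(p): {"k": m.k_} for p, m in lopo.fold_models.items()
        }
        (outdir / "fold_models.json").write_text(json.dumps(fold_meta, indent=1))
        manifest["stages"]["score"] = {
            "rows": len(lopo.scores),
            "failed_folds": sorted(map(str, lopo.failed_folds)),
        }

        atab = asymmetry_table(lopo.scores, meta)
        atab.to_csv(outdir / "asymmetry.csv", index=False)
        summary = summarize_asymmetries(atab, n_boot=config.n_boot, seed=config.seed)
        summary.to_csv(outdir / "asymmetry_summary.csv", index=False)
        manifest["stages"]["asymmetry"] = {"rows": len(atab)}
    except Exception as exc:
        manifest["failed_stage"] = f"downstream: {exc}"
        _finish()
        raise

    return _finish()
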