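"""Synthetic iEEG cohorts with planted pathological high-frequency background.

Real long-term intracranial EEG cannot ship with the package, so every
downstream stage is exercised on simulated cohorts that carry the statistical
contrast the pipeline is designed to detect:

- background = 1/f Gaussian noise plus white noise on every channel;
- *pathological* channels (the designated seizure-onset-zone channels)
  additionally carry (i) band-limited 80-500 Hz noise raising their
  high-band power by a configurable factor and (ii) intermittent
  Laplace-amplitude bursts at Poisson times, giving the heavy-tailed,
  bursty background that the skewness/kurtosis features target;
- HFO-like transients (windowed 80-250 Hz sinusoids, 20-100 ms) are injected
  at different rates inside and outside the SOZ, and broadband artifacts at a
  common rate; every injected event is returned in the annotation set so the
  preprocessing stage can redact it.

Generation is deterministic: patient ``i`` of a cohort uses seed
``master_seed + i``, so patients can be generated independently and in any
order.  The generator makes no attempt at seizure dynamics, sleep structure
or spatial correlation across the electrode array.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .preprocess import AnnotationSet, Recording

#: Background scale (µV): 1/f component and white component.
PINK_SIGMA_UV = 50.0
WHITE_SIGMA_UV = 5.0

#: Band receiving the pathological power elevation (Hz).
ELEVATION_BAND = (80.0, 500.0)

#: HFO-like transient parameters.
HFO_FREQ_RANGE = (80.0, 250.0)
HFO_DUR_RANGE_S = (0.020, 0.100)
HFO_AMP_RANGE_UV = (10.0, 40.0)

#: Burst (high-kurtosis background transient) parameters.
BURST_DUR_RANGE_S = (0.020, 0.050)
BURST_LAPLACE_SCALE_UV = 40.0

#: Artifact parameters: sharp broadband transients.
ARTIFACT_DUR_RANGE_S = (0.005, 0.030)
ARTIFACT_AMP_RANGE_UV = (100.0, 400.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a simulated cohort.

    Defaults emulate a surgical-evaluation cohort recorded at 4096 Hz with a
    clear planted contrast: a four-fold 80-500 Hz power elevation and frequent
    bursts on SOZ channels, HFO rates an order of magnitude higher inside the
    SOZ than outside, and a uniform artifact rate.
    """

    n_patients: int = 24
    channels_per_patient: int = 16
    n_soz: int = 2
    n_rv: int = 4
    epoch_count: int = 12
    fs: float = 4096.0
    band_power_gain: float = 4.0
    burst_rate: float = 10.0  # events/min on pathological channels
    hfo_rate_in: float = 3.0  # events/min on SOZ channels
    hfo_rate_out: float = 0.3
    artifact_rate: float = 1.0  # events/min on every channel
    seed: int = 0
    epoch_length_s: float = 300.0

    def validate(self) -> None:
        if self.channels_per_patient < 4:
            raise ValueError("channels_per_patient must be >= 4")
        if not 0 < self.n_soz <= self.channels_per_patient:
            raise ValueError("need 0 < n_soz <= channels_per_patient")
        if not self.n_soz <= self.n_rv <= self.channels_per_patient:
            raise ValueError("need n_soz <= n_rv <= channels_per_patient")
        if self.fs <= 1000:
            raise ValueError("fs must exceed 1000 Hz")
        for name in ("band_power_gain", "burst_rate", "hfo_rate_in",
                     "hfo_rate_out", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_patients < 1 or self.epoch_count < 1:
            raise ValueError("n_patients and epoch_count must be >= 1")


@dataclass
class GroundTruth:
    """True channel flags and injected event lists for one simulated patient."""

    channels: pd.DataFrame  # name, kind, patient, soz, rv, tl
    events: pd.DataFrame  # channel, t_start, t_end, kind


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Gaussian 1/f (alpha=1) noise, unit variance, via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to ``band`` (FFT brick-wall)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = band
    hi = min(hi, fs / 2)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_variance(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Power of ``x`` within ``band`` via the periodogram."""
    f, p = sp_signal.periodogram(x, fs=fs)
    lo, hi = band
    sel = (f >= lo) & (f <= min(hi, fs / 2))
    return float(np.trapezoid(p[sel], f[sel]))


def inject_events(
    x: np.ndarray,
    kind: str,
    rate: float,
    fs: float,
    seed: int,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Add Poisson-timed transient events to a signal.

    ``kind="hfo"``: Hann-windowed sinusoidal bursts, 80-250 Hz, 20-100 ms.
    ``kind="artifact"``: broadband sharp transients (windowed decaying spikes).
    Returns the modified copy and the exact (t_start, t_end) list in seconds.
    Samples outside event windows are untouched.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if kind not in ("hfo", "artifact"):
        raise ValueError("kind must be 'hfo' or 'artifact'")
    x = np.asarray(x, dtype=np.float64).copy()
    events: list[tuple[float, float]] = []
    if rate == 0:
        return x, events
    rng = np.random.default_rng(seed)
    duration_min = len(x) / fs / 60.0
    n_events = rng.poisson(rate * duration_min)
    for _ in range(n_events):
        if kind == "hfo":
            dur = rng.uniform(*HFO_DUR_RANGE_S)
            f0 = rng.uniform(*HFO_FREQ_RANGE)
            amp = rng.uniform(*HFO_AMP_RANGE_UV)
            n_ev = max(int(round(dur * fs)), 8)
            t = np.arange(n_ev) / fs
            wave = amp * np.hanning(n_ev) * np.sin(
                2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi)
            )
        else:
            dur = rng.uniform(*ARTIFACT_DUR_RANGE_S)
            amp = rng.uniform(*ARTIFACT_AMP_RANGE_UV) * rng.choice([-1.0, 1.0])
            n_ev = max(int(round(dur * fs)), 4)
            t = np.arange(n_ev) / fs
            wave = amp * np.hanning(n_ev) * np.exp(-t / (dur / 3.0))
        start = rng.integers(0, max(len(x) - n_ev, 1))
        x[start : start + n_ev] += wave[: len(x) - start]
        events.append((start / fs, (start + n_ev) / fs))
    events.sort()
    return x, events


def _add_bursts(
    x: np.ndarray, rate: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Laplace-amplitude band-limited bursts at Poisson times (not annotated)."""
    if rate == 0:
        return x
    duration_min = len(x) / fs / 60.0
    n_events = rng.poisson(rate * duration_min)
    for _ in range(n_events):
        dur = rng.uniform(*BURST_DUR_RANGE_S)
        n_ev = max(int(round(dur * fs)), 8)
        carrier = _bandlimited_noise(rng, n_ev, fs, ELEVATION_BAND)
        amp = rng.laplace(0.0, BURST_LAPLACE_SCALE_UV)
        start = rng.integers(0, max(len(x) - n_ev, 1))
        wave = amp * np.hanning(n_ev) * carrier
        x[start : start + n_ev] += wave[: len(x) - start]
    return x


def patient_channel_table(spec: CohortSpec, patient_index: int) -> pd.DataFrame:
    """Deterministic channel metadata for one simulated patient.

    First ``n_soz`` channels are SOZ (and RV); the next ``n_rv - n_soz`` are
    RV-only margin channels.  Half of the channels are depth electrodes, half
    grid, and a random half (independent of SOZ) is flagged temporal lobe.
    """
    rng = np.random.default_rng(int(spec.seed) + patient_index + 900_000)
    n = spec.channels_per_patient
    names = [f"ch{i + 1:02d}" for i in range(n)]
    kinds = ["depth" if i < n // 2 else "grid" for i in range(n)]
    soz = np.zeros(n, dtype=int)
    soz[: spec.n_soz] = 1
    rv = np.zeros(n, dtype=int)
    rv[: spec.n_rv] = 1
    tl = np.zeros(n, dtype=int)
    tl[rng.choice(n, size=n // 2, replace=False)] = 1
    return pd.DataFrame(
        {
            "name": names,
            "kind": kinds,
            "patient": f"sim{patient_index:02d}",
            "soz": soz,
            "rv": rv,
            "tl": tl,
        }
    )


def generate_patient(
    spec: CohortSpec, patient_index: int
) -> tuple[Recording, AnnotationSet, GroundTruth]:
    """Simulate one patient's interictal multichannel recording.

    Deterministic given ``(spec.seed, patient_index)``.  Pathological (SOZ)
    channels receive the band-power elevation and bursts; HFOs are injected at
    ``hfo_rate_in`` on SOZ channels and ``hfo_rate_out`` elsewhere, artifacts
    at ``artifact_rate`` everywhere, all recorded in the annotation set.
    """
    spec.validate()
    channels = patient_channel_table(spec, patient_index)
    n_samples = int(round(spec.epoch_count * spec.epoch_length_s * spec.fs))
    rng = np.random.default_rng(int(spec.seed) + patient_index)
    data = np.empty((spec.channels_per_patient, n_samples))
    event_rows = []
    for ci in range(spec.channels_per_patient):
        x = PINK_SIGMA_UV * _pink_noise(rng, n_samples, spec.fs)
        x += WHITE_SIGMA_UV * rng.standard_normal(n_samples)
        is_soz = bool(channels["soz"].iloc[ci])
        if is_soz and spec.band_power_gain > 1:
            base_power = _band_variance(x, spec.fs, ELEVATION_BAND)
            extra_sd = np.sqrt((spec.band_power_gain - 1.0) * base_power)
            x += extra_sd * _bandlimited_noise(rng, n_samples, spec.fs, ELEVATION_BAND)
        if is_soz:
            x = _add_bursts(x, spec.burst_rate, spec.fs, rng)
        hfo_rate = spec.hfo_rate_in if is_soz else spec.hfo_rate_out
        ev_seed = int(rng.integers(0, 2**31 - 1))
        x, hfo_ev = inject_events(x, "hfo", hfo_rate, spec.fs, ev_seed)
        ev_seed = int(rng.integers(0, 2**31 - 1))
        x, art_ev = inject_events(x, "artifact", spec.artifact_rate, spec.fs, ev_seed)
        data[ci] = x
        name = channels["name"].iloc[ci]
        event_rows += [
            {"channel": name, "t_start": a, "t_end": b, "kind": "hfo"}
            for a, b in hfo_ev
        ]
        event_rows += [
            {"channel": name, "t_start": a, "t_end": b, "kind": "artifact"}
            for a, b in art_ev
        ]
    events = pd.DataFrame(
        event_rows, columns=["channel", "t_start", "t_end", "kind"]
    )
    rec = Recording(data, spec.fs, channels)
    ann = AnnotationSet(seizures=[], events=events)
    gt = GroundTruth(channels=channels.copy(), events=events.copy())
    return rec, ann, gt


def generate_cohort(spec: CohortSpec):
    """Yield ``(Recording, AnnotationSet, GroundTruth)`` per patient."""
    spec.validate()
    for i in range(spec.n_patients):
        yield generate_patient(spec, i)
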