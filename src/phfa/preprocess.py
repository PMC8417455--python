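"""Recording containers, referencing, interictal masking, epoching and event redaction.

The preprocessing contract mirrors how long-term intracranial EEG is prepared
for background (non-event) analysis: channels are re-referenced with a common
average computed separately for depth and subdural (grid/strip) electrodes,
data near clinical seizures are excluded, the interictal record is tiled into
fixed-length epochs, and every annotated transient event (HFO or artifact) is
redacted from the epoch so that only background activity remains.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channel metadata columns expected on every :class:`Recording`.
CHANNEL_COLUMNS = ["name", "kind", "patient", "soz", "rv", "tl"]

#: Electrode kinds sharing the subdural common-average reference group.
SUBDURAL_KINDS = ("grid", "strip")

DEFAULT_EPOCH_S = 300.0
DEFAULT_MARGIN_S = 1800.0


@dataclass
class Recording:
    """Multichannel iEEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sample matrix in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : pandas.DataFrame
        One row per channel with columns ``name`` (str), ``kind``
        (``depth``/``grid``/``strip``), ``patient`` (str) and binary labels
        ``soz``, ``rv``, ``tl``.
    t0 : float
        Recording start time in seconds (annotation times are absolute).
    """

    data: np.ndarray
    fs: float
    channels: pd.DataFrame
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x time matrix")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel table has {len(self.channels)} rows for "
                f"{self.data.shape[0]} data channels"
            )
        missing = [c for c in CHANNEL_COLUMNS if c not in self.channels.columns]
        if missing:
            raise ValueError(f"channel table missing columns: {missing}")
        bad_kind = set(self.channels["kind"]) - {"depth", "grid", "strip"}
        if bad_kind:
            raise ValueError(f"unknown electrode kind(s): {sorted(bad_kind)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        idx = np.flatnonzero(self.channels["name"].to_numpy() == name)
        if idx.size == 0:
            raise KeyError(f"no channel named {name!r}")
        return int(idx[0])


@dataclass
class AnnotationSet:
    """Seizure intervals plus per-channel transient events.

    ``seizures`` holds ``(t_start, t_end)`` pairs in seconds; ``t_end`` may be
    ``None`` when only the electrographic onset is documented.  ``events`` is a
    table with columns ``channel``, ``t_start``, ``t_end``, ``kind`` where
    ``kind`` is ``"hfo"`` or ``"artifact"``.
    """

    seizures: list = field(default_factory=list)
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["channel", "t_start", "t_end", "kind"]
        )
    )

    def __post_init__(self) -> None:
        ev = self.events
        if len(ev):
            bad = ev[ev["t_start"] >= ev["t_end"]]
            if len(bad):
                raise ValueError("event intervals must satisfy t_start < t_end")
        for tz in self.seizures:
            t_start, t_end = tz
            if t_end is not None and not t_start < t_end:
                raise ValueError("seizure intervals must satisfy t_start < t_end")

    def events_on(self, channel: str) -> pd.DataFrame:
        if not len(self.events):
            return self.events
        return self.events[self.events["channel"] == channel]


@dataclass
class EpochGrid:
    """Non-overlapping epoch tiling anchored at the recording start."""

    epoch_length_s: float
    table: pd.DataFrame  # columns: index, start_sample, end_sample, usable

    @property
    def usable_indices(self) -> np.ndarray:
        return self.table.loc[self.table["usable"], "index"].to_numpy()

    def bounds(self, epoch_index: int) -> tuple[int, int]:
        row = self.table[self.table["index"] == epoch_index]
        if not len(row):
            raise KeyError(f"no epoch {epoch_index}")
        return int(row["start_sample"].iloc[0]), int(row["end_sample"].iloc[0])


class SegmentSet(dict):
    """Mapping ``(channel_name, epoch_index) -> list of (start, end) sample intervals``.

    Intervals are half-open ``[start, end)`` in absolute sample indices, sorted
    and disjoint; they are the data that survive event redaction.
    """

    def n_samples_used(self, key: tuple[str, int]) -> int:
        return int(sum(e - s for s, e in self.get(key, [])))


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference by subtracting the per-sample group mean.

    Depth channels form one reference group; grid and strip channels share a
    second group.  After referencing, each group's mean is zero at every
    sample.  An absent group is skipped with a warning.  The operation is
    idempotent.
    """
    data = rec.data.copy()
    kinds = rec.channels["kind"].to_numpy()
    groups = {
        "depth": np.flatnonzero(kinds == "depth"),
        "grid/strip": np.flatnonzero(np.isin(kinds, SUBDURAL_KINDS)),
    }
    for label, idx in groups.items():
        if idx.size == 0:
            warnings.warn(f"no {label} channels; reference group skipped")
            continue
        data[idx] -= data[idx].mean(axis=0, keepdims=True)
    return Recording(data, rec.fs, rec.channels.copy(), rec.t0)


def interictal_mask(
    ann: AnnotationSet, rec: Recording, margin_s: float = DEFAULT_MARGIN_S
) -> np.ndarray:
    """Boolean per-sample mask of data far enough from every seizure.

    A sample is excluded when it lies within ``margin_s`` of a seizure start
    (on either side) or inside the seizure interval itself when the end time
    is known.  Seizures entirely outside the recording span are ignored with a
    warning.
    """
    if margin_s < 0:
        raise ValueError("margin_s must be >= 0")
    mask = np.ones(rec.n_samples, dtype=bool)
    t_end_rec = rec.t0 + rec.duration
    for t_start, t_end in ann.seizures:
        lo = t_start - margin_s
        hi = max(t_start + margin_s, t_end if t_end is not None else -np.inf)
        if hi <= rec.t0 or lo >= t_end_rec:
            warnings.warn(
                f"seizure at {t_start:.1f}s outside recording span; ignored"
            )
            continue
        i0 = max(0, int(np.ceil((lo - rec.t0) * rec.fs)))
        i1 = min(rec.n_samples, int(np.ceil((hi - rec.t0) * rec.fs)))
        mask[i0:i1] = False
    return mask


def build_epochs(
    mask: np.ndarray, fs: float, epoch_length_s: float = DEFAULT_EPOCH_S
) -> EpochGrid:
    """Tile the recording into consecutive epochs; usable iff fully interictal."""
    n_per = epoch_length_s * fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_length_s * fs must be an integer sample count")
    n_per = int(round(n_per))
    n_epochs = len(mask) // n_per
    rows = []
    for k in range(n_epochs):
        s, e = k * n_per, (k + 1) * n_per
        rows.append((k, s, e, bool(mask[s:e].all())))
    table = pd.DataFrame(rows, columns=["index", "start_sample", "end_sample", "usable"])
    return EpochGrid(epoch_length_s, table)


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def redact_events(rec: Recording, grid: EpochGrid, ann: AnnotationSet) -> SegmentSet:
    """Remove annotated HFO/artifact sample ranges per channel and epoch.

    Redaction is per-channel: an event on one channel does not affect any
    other channel.  Abutting or overlapping events merge into a single gap.
    Returns the contiguous intervals that remain in each usable epoch; an
    epoch fully covered by events maps to an empty list.
    """
    segs = SegmentSet()
    usable = grid.table[grid.table["usable"]]
    names = rec.channels["name"].tolist()
    for name in names:
        ev = ann.events_on(name)
        ev_iv = [
            (
                int(np.floor((ts - rec.t0) * rec.fs)),
                int(np.ceil((te - rec.t0) * rec.fs)),
            )
            for ts, te in zip(ev["t_start"], ev["t_end"])
        ]
        ev_iv = _merge_intervals(ev_iv)
        for _, row in usable.iterrows():
            s0, e0 = int(row["start_sample"]), int(row["end_sample"])
            keep = []
            cursor = s0
            for s, e in ev_iv:
                s, e = max(s, s0), min(e, e0)
                if e <= cursor:
                    continue
                if s >= e0:
                    break
                if s > cursor:
                    keep.append((cursor, s))
                cursor = max(cursor, e)
            if cursor < e0:
                keep.append((cursor, e0))
            segs[(name, int(row["index"]))] = keep
    return segs
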