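"""EDF, annotation-JSON and channel-metadata I/O.

Recordings are exchanged as plain EDF (16-bit, one file per patient) with a
JSON annotation sidecar (``{"seizures": [...], "events": [{channel, t_start_s,
t_end_s, kind}, ...]}``) and a CSV channel-metadata table (patient, channel,
kind, soz, rv, tl).  EDF files are read through :mod:`mne`; writing uses a
minimal EDF encoder (16-bit, 1-second data records, per-channel physical
scaling) since no installed library exports EDF.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AnnotationSet, Recording

_EDF_DATE = "01.01.00"
_EDF_TIME = "00.00.00"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a recording to 16-bit EDF with 1-second data records.

    The recording length is truncated to a whole number of seconds (pipeline
    recordings are whole epochs, so nothing is lost in practice).  Each
    channel is scaled to its own symmetric physical range, so quantisation
    error is at most ``max|x| / 32767`` per channel.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    n_ch = rec.n_channels
    data = rec.data[:, : n_records * spr]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    scale = 32767.0 / phys_max
    digital = np.round(data * scale[:, None]).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(str(rec.channels["patient"].iloc[0]), 80),
            _pad("phfa synthetic", 80),
            _pad(_EDF_DATE, 8),
            _pad(_EDF_TIME, 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    names = [str(n) for n in rec.channels["name"]]
    fields = [
        ("".join(_pad(n, 16).decode() for n in names), None),
        ("".join(_pad("iEEG", 80).decode() for _ in names), None),
        ("".join(_pad("uV", 8).decode() for _ in names), None),
        ("".join(_pad(f"{-m:.6g}"[:8], 8).decode() for m in phys_max), None),
        ("".join(_pad(f"{m:.6g}"[:8], 8).decode() for m in phys_max), None),
        ("".join(_pad("-32767", 8).decode() for _ in names), None),
        ("".join(_pad("32767", 8).decode() for _ in names), None),
        ("".join(_pad("", 80).decode() for _ in names), None),
        ("".join(_pad(str(spr), 8).decode() for _ in names), None),
        ("".join(_pad("", 32).decode() for _ in names), None),
    ]
    sig_header = "".join(f[0] for f in fields).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path, channels: pd.DataFrame) -> Recording:
    """Read an EDF file into a :class:`Recording` (via ``mne``).

    ``channels`` is the metadata table (columns name/kind/patient/soz/rv/tl)
    aligned to the EDF channel order; channels absent from the table are
    dropped.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    wanted = [n for n in raw.ch_names if n in set(channels["name"])]
    raw.pick(wanted)
    meta = channels.set_index("name").loc[wanted].reset_index()
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(data, float(raw.info["sfreq"]), meta)


def write_annotations(path: str | Path, ann: AnnotationSet) -> Path:
    path = Path(path)
    payload = {
        "seizures": [
            {"t_start_s": s, "t_end_s": e} for s, e in ann.seizures
        ],
        "events": [
            {
                "channel": r["channel"],
                "t_start_s": float(r["t_start"]),
                "t_end_s": float(r["t_end"]),
                "kind": r["kind"],
            }
            for _, r in ann.events.iterrows()
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_annotations(path: str | Path) -> AnnotationSet:
    payload = json.loads(Path(path).read_text())
    seizures = [
        (s["t_start_s"], s.get("t_end_s")) for s in payload.get("seizures", [])
    ]
    events = pd.DataFrame(
        [
            {
                "channel": e["channel"],
                "t_start": e["t_start_s"],
                "t_end": e["t_end_s"],
                "kind": e["kind"],
            }
            for e in payload.get("events", [])
        ],
        columns=["channel", "t_start", "t_end", "kind"],
    )
    return AnnotationSet(seizures=seizures, events=events)


def write_channel_table(path: str | Path, channels: pd.DataFrame) -> Path:
    path = Path(path)
    out = channels.rename(columns={"name": "channel"})[
        ["patient", "channel", "kind", "soz", "rv", "tl"]
    ]
    out.to_csv(path, index=False)
    return path


def read_channel_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.rename(columns={"channel": "name"})[
        ["name", "kind", "patient", "soz", "rv", "tl"]
    ]
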