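import numpy as np
import pandas as pd
import pytest

from phfa import AnnotationSet, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_channels(n, kinds=None, soz=None, patient="p0"):
    kinds = kinds or ["depth"] * n
    soz = soz if soz is not None else [0] * n
    return pd.DataFrame(
        {
            "name": [f"ch{i + 1:02d}" for i in range(n)],
            "kind": kinds,
            "patient": patient,
            "soz": soz,
            "rv": soz,
            "tl": [0] * n,
        }
    )


@pytest.fixture
def small_recording(rng):
    """Four depth channels, 20 s at 1024 Hz."""
    fs = 1024.0
    data = rng.standard_normal((4, int(20 * fs)))
    return Recording(data, fs, make_channels(4))


@pytest.fixture
def empty_annotations():
    return AnnotationSet()
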