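"""Referencing, interictal masking, epoch tiling and event redaction."""
import numpy as np
import pandas as pd
import pytest

from phfa import (
    AnnotationSet,
    Recording,
    build_epochs,
    common_average_reference,
    interictal_mask,
    redact_events,
)
from tests.conftest import make_channels


class TestCommonAverageReference:
    def test_identical_channels_become_zero(self):
        data = np.tile(np.sin(np.linspace(0, 10, 2048)), (2, 1))
        rec = Recording(data, 1024.0, make_channels(2))
        out = common_average_reference(rec)
        assert np.allclose(out.data, 0.0)

    def test_zero_mean_pair_unchanged(self):
        data = np.vstack([np.ones(1000), -np.ones(1000)])
        rec = Recording(data, 1024.0, make_channels(2))
        out = common_average_reference(rec)
        assert np.allclose(out.data, data)

    def test_group_means_vanish(self, rng):
        kinds = ["depth", "depth", "grid", "strip"]
        rec = Recording(
            rng.standard_normal((4, 5000)), 1024.0, make_channels(4, kinds=kinds)
        )
        out = common_average_reference(rec)
        assert np.abs(out.data[:2].mean(axis=0)).max() < 1e-10
        assert np.abs(out.data[2:].mean(axis=0)).max() < 1e-10

    def test_groups_are_referenced_separately(self, rng):
        # adding an offset to the depth group must not leak into grid channels
        kinds = ["depth", "depth", "grid", "grid"]
        data = rng.standard_normal((4, 2000))
        rec = Recording(data, 1024.0, make_channels(4, kinds=kinds))
        shifted = data.copy()
        shifted[:2] += 100.0
        rec2 = Recording(shifted, 1024.0, make_channels(4, kinds=kinds))
        out1, out2 = common_average_reference(rec), common_average_reference(rec2)
        assert np.allclose(out1.data, out2.data)

    def test_idempotent(self, small_recording):
        once = common_average_reference(small_recording)
        twice = common_average_reference(once)
        assert np.abs(twice.data - once.data).max() < 1e-10

    def test_empty_group_warns(self, small_recording):
        with pytest.warns(UserWarning, match="grid/strip"):
            common_average_reference(small_recording)


class TestInterictalMask:
    def _rec(self, duration_s=7200.0, fs=16.0):
        n = int(duration_s * fs)
        return Recording(np.zeros((2, n)), fs, make_channels(2))

    def test_no_seizures_all_true(self, small_recording, empty_annotations):
        mask = interictal_mask(empty_annotations, small_recording)
        assert mask.all()

    def test_margin_window_masked(self):
        rec = self._rec()
        ann = AnnotationSet(seizures=[(3600.0, None)])
        mask = interictal_mask(ann, rec, margin_s=1800.0)
        t = np.arange(rec.n_samples) / rec.fs
        assert not mask[(t >= 1800.0) & (t < 5400.0)].any()
        assert mask[t < 1800.0].all()
        assert mask[t >= 5400.0].all()

    def test_known_end_extends_exclusion(self):
        rec = self._rec()
        ann = AnnotationSet(seizures=[(1000.0, 4000.0)])
        mask = interictal_mask(ann, rec, margin_s=1800.0)
        t = np.arange(rec.n_samples) / rec.fs
        assert not mask[(t >= 0.0) & (t < 4000.0)].any()

    def test_overlapping_windows_union(self):
        rec = self._rec()
        ann = AnnotationSet(seizures=[(2000.0, None), (2500.0, None)])
        m2 = interictal_mask(ann, rec, margin_s=1800.0)
        t = np.arange(rec.n_samples) / rec.fs
        assert not m2[(t >= 200.0) & (t < 4300.0)].any()
        assert m2[t < 200.0].all() and m2[t >= 4300.0].all()

    def test_out_of_span_seizure_ignored(self):
        rec = self._rec(duration_s=100.0)
        ann = AnnotationSet(seizures=[(50_000.0, None)])
        with pytest.warns(UserWarning, match="outside recording span"):
            mask = interictal_mask(ann, rec, margin_s=1800.0)
        assert mask.all()


class TestBuildEpochs:
    def test_hour_gives_twelve_epochs(self):
        fs = 64.0
        mask = np.ones(int(3600 * fs), dtype=bool)
        grid = build_epochs(mask, fs, 300.0)
        assert len(grid.table) == 12
        assert grid.table["usable"].all()

    def test_straddling_epoch_unusable(self):
        fs = 64.0
        mask = np.ones(int(900 * fs), dtype=bool)
        mask[int(450 * fs)] = False  # one bad sample in epoch 1
        grid = build_epochs(mask, fs, 300.0)
        assert list(grid.table["usable"]) == [True, False, True]

    def test_sample_count_arithmetic(self):
        mask = np.ones(int(300 * 4096), dtype=bool)
        grid = build_epochs(mask, 4096.0, 300.0)
        s, e = grid.bounds(0)
        assert e - s == 1_228_800

    def test_short_recording_empty_grid(self):
        grid = build_epochs(np.ones(100, dtype=bool), 64.0, 300.0)
        assert len(grid.table) == 0


class TestRedaction:
    def _setup(self, events, fs=64.0, n_epochs=1):
        n = int(n_epochs * 300 * fs)
        rec = Recording(np.zeros((2, n)), fs, make_channels(2))
        grid = build_epochs(np.ones(n, dtype=bool), fs, 300.0)
        ann = AnnotationSet(events=pd.DataFrame(events))
        return rec, grid, ann

    def test_no_events_full_epoch(self, empty_annotations):
        rec, grid, _ = self._setup([])
        segs = redact_events(rec, grid, empty_annotations)
        assert segs[("ch01", 0)] == [(0, int(300 * 64))]

    def test_single_event_splits_epoch(self):
        events = [{"channel": "ch01", "t_start": 150.0, "t_end": 150.1, "kind": "hfo"}]
        rec, grid, ann = self._setup(events)
        segs = redact_events(rec, grid, ann)
        parts = segs[("ch01", 0)]
        assert len(parts) == 2
        total = sum(e - s for s, e in parts)
        gap = int(np.ceil(150.1 * 64)) - int(np.floor(150.0 * 64))
        assert total == int(300 * 64) - gap

    def test_redaction_is_per_channel(self):
        events = [{"channel": "ch01", "t_start": 150.0, "t_end": 151.0, "kind": "hfo"}]
        rec, grid, ann = self._setup(events)
        segs = redact_events(rec, grid, ann)
        assert segs[("ch02", 0)] == [(0, int(300 * 64))]

    def test_abutting_events_merge(self):
        events = [
            {"channel": "ch01", "t_start": 100.0, "t_end": 101.0, "kind": "hfo"},
            {"channel": "ch01", "t_start": 101.0, "t_end": 102.0, "kind": "artifact"},
        ]
        rec, grid, ann = self._setup(events)
        segs = redact_events(rec, grid, ann)
        assert len(segs[("ch01", 0)]) == 2

    def test_full_cover_gives_empty_list(self):
        events = [{"channel": "ch01", "t_start": 0.0, "t_end": 300.0, "kind": "artifact"}]
        rec, grid, ann = self._setup(events)
        segs = redact_events(rec, grid, ann)
        assert segs[("ch01", 0)] == []

    def test_conservation(self, rng):
        # sum of kept + redacted sample counts equals epoch length
        events = [
            {
                "channel": "ch01",
                "t_start": float(t),
                "t_end": float(t) + 0.5,
                "kind": "hfo",
            }
            for t in sorted(rng.uniform(1, 295, size=20))
        ]
        rec, grid, ann = self._setup(events)
        segs = redact_events(rec, grid, ann)
        kept = segs.n_samples_used(("ch01", 0))
        iv = [
            (int(np.floor(e["t_start"] * 64)), int(np.ceil(e["t_end"] * 64)))
            for e in events
        ]
        from phfa.preprocess import _merge_intervals

        redacted = sum(e - s for s, e in _merge_intervals(iv))
        assert kept + redacted == int(300 * 64)
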