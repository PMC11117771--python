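"""Tests of mocap I/O, window segmentation, balancing and the synthetic
movement generator."""

import numpy as np
import pandas as pd
import pytest

from acanet.movement import (
    CLASSES,
    MARKER_COUNT,
    MovementSample,
    balance_classes,
    generate_synthetic_dataset,
    marker_columns,
    read_mocap_table,
    segment_windows,
    write_mocap_table,
)


def make_sample(F=300, label="turning", critical=(139, 159)) -> MovementSample:
    rng = np.random.default_rng(0)
    return MovementSample(
        positions=rng.normal(size=(MARKER_COUNT, 3, F)),
        label=label,
        critical_area=critical,
    )


def brute_force_labels(F, S, stride, critical, label):
    """Independent enumeration of window labels by explicit frame sets."""
    out = []
    for f in range(0, F - S + 1, stride):
        frames = set(range(f, f + S))
        if critical is not None and frames & set(range(critical[0], critical[1] + 1)):
            out.append(label)
        else:
            out.append("gait")
    return out


class TestSegmentation:
    def test_interval_intersection_against_brute_force(self):
        sample = make_sample(F=300, critical=(139, 159))
        windows = segment_windows(sample, S=100, stride=1)
        expected = brute_force_labels(300, 100, 1, (139, 159), "turning")
        assert [w.label for w in windows] == expected
        assert len(windows) == 201
        assert sum(w.label == "turning" for w in windows) == 120
        assert sum(w.label == "gait" for w in windows) == 81

    def test_gait_sample_yields_only_gait_windows(self):
        sample = make_sample(label="gait", critical=None)
        windows = segment_windows(sample, S=50)
        assert all(w.label == "gait" for w in windows)

    def test_window_count_identity_stride_one(self):
        for F, S in [(120, 30), (200, 200), (77, 13)]:
            sample = make_sample(F=F, critical=(0, 5))
            assert len(segment_windows(sample, S=S)) == F - S + 1

    def test_single_window_when_s_equals_f(self):
        windows = segment_windows(make_sample(F=150, critical=(10, 20)), S=150)
        assert len(windows) == 1
        assert windows[0].label == "turning"

    def test_enlarging_critical_area_never_loses_movement_windows(self):
        F, S = 200, 60
        base = make_sample(F=F, critical=(90, 100))
        grown = MovementSample(base.positions, "turning", (80, 110))
        n_base = sum(w.label != "gait" for w in segment_windows(base, S))
        n_grown = sum(w.label != "gait" for w in segment_windows(grown, S))
        assert n_grown >= n_base

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(make_sample(F=50, critical=(1, 2)), S=100)


class TestBalancing:
    def _windows(self, counts):
        sample = make_sample(F=40, critical=None, label="gait")
        out = []
        for label, n in counts.items():
            for _ in range(n):
                seg = segment_windows(sample, S=40)[0]
                seg.label = label
                out.append(seg)
        return out

    def test_downsamples_to_minimum(self):
        segs = self._windows({"gait": 10, "cutting": 4, "turning": 7})
        balanced = balance_classes(segs, seed=0)
        labels = pd.Series([s.label for s in balanced])
        assert labels.value_counts().tolist() == [4, 4, 4]

    def test_already_balanced_unchanged_in_counts(self):
        segs = self._windows({"gait": 5, "cutting": 5})
        assert len(balance_classes(segs, seed=1)) == 10

    def test_seeded_selection_is_reproducible(self):
        segs = self._windows({"gait": 9, "cutting": 3})
        a = balance_classes(segs, seed=5)
        b = balance_classes(segs, seed=5)
        assert [id(x) for x in a] == [id(x) for x in b]


class TestMocapIO:
    def test_roundtrip(self, tmp_path):
        sample = make_sample(F=200)
        write_mocap_table(sample, tmp_path / "rec.csv")
        loaded = read_mocap_table(tmp_path / "rec.csv")
        assert loaded.label == "turning"
        assert loaded.critical_area == (139, 159)
        np.testing.assert_allclose(loaded.positions, sample.positions)

    def test_wrong_column_count_rejected(self, tmp_path):
        df = pd.DataFrame(np.zeros((10, 111)), columns=marker_columns()[:111])
        df.insert(0, "frame", np.arange(10))
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="114"):
            read_mocap_table(tmp_path / "bad.csv")

    def test_nan_rejected(self, tmp_path):
        sample = make_sample(F=200)
        write_mocap_table(sample, tmp_path / "rec.csv")
        df = pd.read_csv(tmp_path / "rec.csv")
        df.loc[3, "m05_y"] = np.nan
        df.to_csv(tmp_path / "rec.csv", index=False)
        with pytest.raises(ValueError, match="NaN"):
            read_mocap_table(tmp_path / "rec.csv")


class TestSyntheticGenerator:
    def test_structure_one_per_class(self):
        samples = generate_synthetic_dataset(n_per_class=1, F=200, seed=0)
        assert len(samples) == 5
        by_label = {s.label: s for s in samples}
        assert set(by_label) == set(CLASSES)
        assert by_label["gait"].critical_area is None
        F = 200
        for lbl in ("cutting", "turning"):
            cs, ce = by_label[lbl].critical_area
            assert F * 0.25 < (cs + ce) / 2 < F * 0.75  # mid-sample
        for lbl in ("sitting down", "standing up"):
            cs, _ = by_label[lbl].critical_area
            assert cs < F * 0.15  # at onset

    def test_seed_determinism(self):
        a = generate_synthetic_dataset(2, F=120, seed=9)
        b = generate_synthetic_dataset(2, F=120, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.positions, y.positions)
            assert x.label == y.label and x.critical_area == y.critical_area

    def test_vertical_signature_of_transfers(self):
        samples = generate_synthetic_dataset(1, F=300, seed=3, noise_sd=0.0)
        by_label = {s.label: s for s in samples}
        sit = by_label["sitting down"].positions[4:10, 2, :].mean(axis=0)  # torso z
        stand = by_label["standing up"].positions[4:10, 2, :].mean(axis=0)
        assert sit[-1] < sit[0] - 0.3  # ends lower than it started
        assert stand[-1] > stand[0] + 0.3

    def test_invariants_of_every_sample(self):
        for s in generate_synthetic_dataset(2, F=150, seed=1):
            assert s.positions.shape == (MARKER_COUNT, 3, 150)
            assert np.all(np.isfinite(s.positions))
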