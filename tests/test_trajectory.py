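"""Strand geometric centres, rupture order and simulated-trace peaks."""

import numpy as np
import pytest

from azmech.trace import FXTrace
from azmech.trajectory import (
    GCDistanceSeries,
    StrandPair,
    curtailment_extension,
    fx_peaks,
    gc_distance_change,
    residue_pair_distance,
    rupture_order,
    strand_gc,
)


def _rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.asarray([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestStrandGC:
    def test_single_residue_strand_is_that_residue(self):
        frame = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(strand_gc(frame, (2, 2)), frame[2])

    def test_symmetric_beads_centre_at_origin(self):
        frame = np.asarray([[1.0, 0, 0], [-1.0, 0, 0]])
        assert np.allclose(strand_gc(frame, (0, 1)), 0.0)

    def test_matches_arithmetic_mean_oracle(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=(10, 3))
        assert np.allclose(strand_gc(frame, (2, 6)), frame[2:7].mean(axis=0))

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            strand_gc(np.zeros((4, 3)), (2, 5))


class TestGCDistanceChange:
    def setup_method(self):
        self.pairs = [StrandPair("a-b", (0, 1), (2, 3))]

    def test_rigid_translation_gives_zero_series(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(4, 3)) * 5
        frames = np.stack([base + np.asarray([t, 2 * t, -t]) for t in range(6)])
        series = gc_distance_change(frames, np.arange(6.0), self.pairs)
        assert np.allclose(series.distance_change["a-b"], 0.0, atol=1e-12)

    def test_rigid_rotation_gives_zero_series(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(4, 3)) * 5
        frames = np.stack([base @ _rotation(0.3 * t).T for t in range(6)])
        series = gc_distance_change(frames, np.arange(6.0), self.pairs)
        assert np.allclose(series.distance_change["a-b"], 0.0, atol=1e-9)

    def test_linear_separation_gives_linear_series(self):
        base = np.asarray([[0.0, 0, 0], [0, 1, 0], [10.0, 0, 0], [10.0, 1, 0]])
        frames = np.stack([base + np.asarray([0, 0, 0]) * 0 for _ in range(5)]).astype(float)
        for t in range(5):
            frames[t, 2:, 0] += 2.0 * t  # second strand moves 2 A per frame
        series = gc_distance_change(frames, np.arange(5.0), self.pairs)
        assert np.allclose(series.distance_change["a-b"], 0.2 * np.arange(5), atol=1e-12)

    def test_first_frame_defines_zero(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(size=(4, 4, 3))
        series = gc_distance_change(frames, np.arange(4.0), self.pairs)
        assert series.distance_change["a-b"][0] == 0.0


class TestRuptureOrder:
    def test_staggered_crossings_ordered_by_extension(self):
        ext = np.linspace(0, 10, 101)
        change = {
            "late": np.where(ext > 6, 1.0, 0.0),
            "early": np.where(ext > 2, 1.0, 0.0),
            "never": np.zeros_like(ext),
        }
        series = GCDistanceSeries(extension=ext, distance_change=change)
        ruptured, intact = rupture_order(series, threshold=0.5)
        assert [name for name, _ in ruptured] == ["early", "late"]
        assert intact == ["never"]

    def test_tie_broken_by_name_deterministically(self):
        ext = np.linspace(0, 10, 101)
        step = np.where(ext > 5, 1.0, 0.0)
        series = GCDistanceSeries(extension=ext, distance_change={"b": step.copy(), "a": step.copy()})
        ruptured, _ = rupture_order(series, threshold=0.5)
        assert [name for name, _ in ruptured] == ["a", "b"]
        assert ruptured[0][1] == ruptured[1][1]


class TestResiduePairDistance:
    def test_coincident_residues_zero(self):
        frames = np.zeros((3, 4, 3))
        out = residue_pair_distance(frames, {"p": (0, 1)})
        assert np.allclose(out["p"], 0.0)

    def test_static_trajectory_constant(self):
        frame = np.random.default_rng(4).normal(size=(5, 3))
        frames = np.stack([frame] * 7)
        out = residue_pair_distance(frames, {"p": (1, 3)})
        assert np.allclose(out["p"], out["p"][0])

    def test_matches_per_frame_norm_oracle(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(size=(6, 5, 3)) * 10
        out = residue_pair_distance(frames, {"p": (0, 4)})
        expected = [np.linalg.norm(f[0] - f[4]) * 0.1 for f in frames]
        assert np.allclose(out["p"], expected)


class TestFxPeaks:
    def test_constructed_two_peak_trace(self):
        ext = np.linspace(0, 10, 1001)
        force = np.zeros_like(ext)
        for centre in (3.0, 8.0):
            force += 200.0 * np.exp(-((ext - centre) / 0.3) ** 2)
        fx = FXTrace(extension=ext, force=force)
        peaks, separations = fx_peaks(fx, smooth_window=5, min_force=100, min_drop=100)
        assert peaks.size == 2
        assert separations[0] == pytest.approx(5.0, abs=0.1)

    def test_no_peaks_gives_empty_separations(self):
        fx = FXTrace(extension=np.linspace(0, 5, 100), force=np.zeros(100))
        peaks, separations = fx_peaks(fx)
        assert peaks.size == 0 and separations.size == 0


class TestCurtailmentExtension:
    def test_reports_first_crossing(self):
        ext = np.linspace(0, 10, 1001)
        force = np.where(ext > 7.0, 5000.0, 100.0)
        fx = FXTrace(extension=ext, force=force)
        assert curtailment_extension(fx, f_ref=2000.0, smooth_window=5) == pytest.approx(7.0, abs=0.1)

    def test_never_crossing_returns_max_extension(self):
        fx = FXTrace(extension=np.linspace(0, 10, 100), force=np.full(100, 100.0))
        assert curtailment_extension(fx, f_ref=2000.0) == pytest.approx(10.0)
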