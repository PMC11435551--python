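"""Cycle segmentation, phase durations via interval intersection, mean force
and stance-normalized curves, plus recovery against simulation truth."""

from __future__ import annotations

import numpy as np
import pytest

from insolegait.events import detect_events
from insolegait.io import GaitEvent, GaitEventSequence, InsoleRecording
from insolegait.parameters import (
    ContralateralCoverageError,
    CycleTriple,
    DegenerateCycleError,
    compute_phase_durations,
    extract_cycle_parameters,
    interval_overlap,
    mean_force_single_stance,
    normalize_force_curve,
    segment_cycles,
    single_stance_intervals,
)

FS = 110.0


def _seq(foot, *ic_to_pairs):
    events = []
    for ic, to in ic_to_pairs:
        events.append(GaitEvent("initial_contact", ic, int(round(ic * FS))))
        events.append(GaitEvent("toe_off", to, int(round(to * FS))))
    return GaitEventSequence(foot_side=foot, events=events)


class TestSegmentCycles:
    def test_two_cycles_without_trimming(self):
        seq = _seq("left", (0.0, 0.6), (1.0, 1.6), (2.0, 2.6))
        cycles = segment_cycles(seq, trim_boundary=False)
        assert [(c.ic_s, c.to_s, c.next_ic_s) for c in cycles] == [
            (0.0, 0.6, 1.0), (1.0, 1.6, 2.0),
        ]

    def test_boundary_trimming_drops_first_and_last(self):
        seq = _seq("left", *[(i, i + 0.6) for i in range(6)])
        cycles = segment_cycles(seq)
        assert [c.ic_s for c in cycles] == [1.0, 2.0, 3.0]

    def test_sequence_ending_in_ic_drops_open_cycle(self):
        seq = GaitEventSequence(
            "left",
            [
                GaitEvent("initial_contact", 0.0, 0),
                GaitEvent("toe_off", 0.6, 66),
                GaitEvent("initial_contact", 1.0, 110),
                GaitEvent("toe_off", 1.6, 176),
                GaitEvent("initial_contact", 2.0, 220),
            ],
        )
        cycles = segment_cycles(seq, trim_boundary=False)
        # the trailing IC opens a third cycle that has no closing events
        assert [c.ic_s for c in cycles] == [0.0, 1.0]

    def test_empty_sequence(self):
        assert segment_cycles(GaitEventSequence("left", []), trim_boundary=False) == []


class TestPhaseDurations:
    def test_hand_built_interval_intersection(self):
        """Two double-support sub-periods are summed: 160 + 315 ms."""
        cycle = CycleTriple(ic_s=0.0, to_s=0.730, next_ic_s=1.0)
        contra = _seq("right", (-0.5, 0.160), (0.415, 0.890))
        d = compute_phase_durations(cycle, contra)
        assert d["stance_ms"] == pytest.approx(730.0)
        assert d["double_stance_ms"] == pytest.approx(160.0 + 315.0)
        assert d["single_stance_ms"] == pytest.approx(730.0 - 475.0)
        assert d["swing_ms"] == pytest.approx(270.0)

    def test_contralateral_airborne_means_all_single_support(self):
        cycle = CycleTriple(0.0, 0.7, 1.0)
        contra = _seq("right", (-0.9, -0.1), (1.1, 1.8))
        d = compute_phase_durations(cycle, contra)
        assert d["double_stance_ms"] == 0.0
        assert d["single_stance_ms"] == pytest.approx(d["stance_ms"])

    def test_coverage_gap_is_flagged(self):
        cycle = CycleTriple(0.0, 0.7, 1.0)
        contra = _seq("right", (0.3, 0.9))  # starts after the cycle's IC
        with pytest.raises(ContralateralCoverageError):
            compute_phase_durations(cycle, contra)

    def test_interval_overlap_is_additive(self):
        assert interval_overlap(0, 10, [(2, 4), (6, 9), (20, 30)]) == pytest.approx(5.0)


class TestSingleStanceIntervals:
    def test_complement_of_double_support(self):
        cycle = CycleTriple(0.0, 0.730, 1.0)
        contra = _seq("right", (-0.5, 0.160), (0.415, 0.890))
        ints = single_stance_intervals(cycle, contra)
        assert ints == [(0.160, 0.415)]


def _flat_recording(n, level_per_cell):
    return InsoleRecording("left", FS, np.full((n, 18), level_per_cell))


class TestMeanForce:
    def test_constant_pressure_returns_that_sum(self):
        rec = _flat_recording(300, 0.5)  # summed pressure = 9.0 everywhere
        cycle = CycleTriple(0.5, 1.2, 1.5)
        contra = _seq("right", (-0.5, 0.4), (1.4, 2.2))
        assert mean_force_single_stance(rec, cycle, contra) == pytest.approx(9.0)

    def test_two_sample_interval_mean(self):
        S = np.zeros(300)
        lo = int(np.ceil(0.5 * FS))
        S[lo], S[lo + 1] = 8.0, 9.0
        rec = _flat_recording(300, 0.0)
        cycle = CycleTriple(0.5, 0.5 + 2 / FS, 0.6)
        contra = _seq("right", (-0.5, 0.4), (0.55, 1.2))
        got = mean_force_single_stance(rec, cycle, contra, _S_smooth=S)
        assert got == pytest.approx(8.5)

    def test_empty_single_stance_flagged(self):
        rec = _flat_recording(300, 0.5)
        cycle = CycleTriple(0.5, 0.7, 1.0)
        contra = _seq("right", (0.4, 0.8))  # covers the whole stance
        with pytest.raises(DegenerateCycleError):
            mean_force_single_stance(rec, cycle, contra)

    def test_zero_noise_mean_force_matches_truth(self, zero_noise_sym_trials):
        _, sims = zero_noise_sym_trials
        sim = sims[0]
        seqs = {f: detect_events(sim.recording(f))[0] for f in ("left", "right")}
        params, _, _ = extract_cycle_parameters(
            sim.left, seqs["left"], seqs["right"]
        )
        got = np.array([c.mean_force_single_stance for c in params])
        want = np.nanmean(sim.truth.feet["left"].mean_force)
        # one sample of edge error per interval boundary
        assert got.mean() == pytest.approx(want, rel=0.02)


class TestForceCurve:
    def test_constant_signal_gives_constant_curve(self):
        rec = _flat_recording(300, 0.5)
        curve = normalize_force_curve(rec, CycleTriple(0.5, 1.2, 1.5))
        assert np.allclose(curve.values, 9.0)

    def test_linear_ramp_interpolates_exactly(self):
        S = np.arange(300, dtype=float)
        rec = _flat_recording(300, 0.0)
        cycle = CycleTriple(0.5, 1.5, 2.0)
        curve = normalize_force_curve(rec, cycle, _S_smooth=S)
        t = np.linspace(0.5, 1.5, 101)
        assert np.allclose(curve.values, t * FS)

    def test_degenerate_stance_flagged(self):
        rec = _flat_recording(300, 0.5)
        with pytest.raises(DegenerateCycleError):
            normalize_force_curve(rec, CycleTriple(0.5, 0.505, 1.0))

    def test_grid_has_101_points(self):
        rec = _flat_recording(300, 0.5)
        curve = normalize_force_curve(rec, CycleTriple(0.5, 1.2, 1.5))
        assert curve.values.shape == (101,) and curve.grid[0] == 0.0 and curve.grid[-1] == 1.0


class TestPipelineRecovery:
    @staticmethod
    def _aligned_errors(sim, foot, parameter):
        seqs = {f: detect_events(sim.recording(f))[0] for f in ("left", "right")}
        contra = "right" if foot == "left" else "left"
        truth = sim.truth.feet[foot]
        errors = []
        for cycle in segment_cycles(seqs[foot]):
            d = compute_phase_durations(cycle, seqs[contra])
            k = int(np.argmin(np.abs(truth.cycle_ic_times_s - cycle.ic_s)))
            errors.append(abs(d[parameter] - getattr(truth, parameter)[k]))
        return np.array(errors)

    @pytest.mark.parametrize(
        "parameter", ["stance_ms", "swing_ms", "single_stance_ms", "double_stance_ms"]
    )
    def test_duration_mae_within_two_samples(self, noisy_sym_trials, parameter):
        _, sims = noisy_sym_trials
        err = self._aligned_errors(sims[0], "left", parameter)
        assert err.size > 40
        assert err.mean() <= 2000.0 / FS  # 2 samples, in ms

    def test_symmetric_zero_noise_feet_agree(self, zero_noise_sym_trials):
        _, sims = zero_noise_sym_trials
        sim = sims[0]
        seqs = {f: detect_events(sim.recording(f))[0] for f in ("left", "right")}
        stats = {}
        for foot in ("left", "right"):
            contra = "right" if foot == "left" else "left"
            params, _, _ = extract_cycle_parameters(
                sim.recording(foot), seqs[foot], seqs[contra]
            )
            stats[foot] = np.array([[c.stance_ms, c.swing_ms, c.single_stance_ms,
                                     c.double_stance_ms] for c in params]).mean(axis=0)
        # identical geometry on both feet up to one sample of detection error
        assert np.allclose(stats["left"], stats["right"], atol=1000.0 / FS)

    def test_conservation_exact_on_processed_cycles(self, noisy_sym_trials):
        _, sims = noisy_sym_trials
        sim = sims[0]
        seqs = {f: detect_events(sim.recording(f))[0] for f in ("left", "right")}
        for foot in ("left", "right"):
            contra = "right" if foot == "left" else "left"
            params, _, _ = extract_cycle_parameters(
                sim.recording(foot), seqs[foot], seqs[contra]
            )
            for c in params:
                assert c.single_stance_ms + c.double_stance_ms == pytest.approx(
                    c.stance_ms, abs=1e-9
                )
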