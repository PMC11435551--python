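"""Per-cycle spatio-temporal and force parameters.

A gait cycle runs from one initial contact to the next ipsilateral initial
contact (IC_i, TO_i, IC_{i+1}). From the two feet's event sequences this
module derives, per cycle:

* stance  = TO_i − IC_i
* swing   = IC_{i+1} − TO_i
* double support = total time within [IC_i, TO_i) that the contralateral
  foot is also on the ground (the sum of both sub-periods in normal gait)
* single support = stance − double support
* mean force during single stance = mean summed pressure (kg·cm⁻², smoothed)
  over the single-support sub-intervals
* a stance-normalized force curve on a 101-point grid.

The additive identities single + double = stance and stance + swing = cycle
hold exactly by construction and are asserted on every pipeline run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import DetectionThresholds, smooth, total_pressure
from .io import (
    CycleParameters,
    GaitEventSequence,
    InsoleRecording,
    NormalizedForceCurve,
)

logger = logging.getLogger("insolegait")


@dataclass(frozen=True)
class CycleTriple:
    """One complete cycle: ipsilateral (IC, TO, next IC) times in seconds."""

    ic_s: float
    to_s: float
    next_ic_s: float

    def __post_init__(self) -> None:
        if not (self.ic_s < self.to_s < self.next_ic_s):
            raise ValueError("cycle requires IC < TO < next IC")


def segment_cycles(seq: GaitEventSequence, trim_boundary: bool = True) -> list[CycleTriple]:
    """Split an alternating event sequence into complete cycles.

    With ``trim_boundary`` (the default) the first and last cycle are
    discarded: they abut the recording edges where the look-ahead window and
    partial contralateral coverage make them unreliable.
    """
    ev = seq.events
    triples: list[CycleTriple] = []
    for i in range(0, len(ev) - 2, 2):
        triples.append(
            CycleTriple(ic_s=ev[i].time_s, to_s=ev[i + 1].time_s, next_ic_s=ev[i + 2].time_s)
        )
    if trim_boundary:
        triples = triples[1:-1]
    if not triples:
        logger.warning("%s foot: fewer than 3 cycles, nothing to segment", seq.foot_side)
    return triples


def interval_overlap(start: float, stop: float,
                     intervals: list[tuple[float, float]]) -> float:
    """Total measure of [start, stop) ∩ ⋃ intervals."""
    total = 0.0
    for a, b in intervals:
        lo, hi = max(start, a), min(stop, b)
        if hi > lo:
            total += hi - lo
    return total


class ContralateralCoverageError(ValueError):
    """The contralateral sequence does not span the cycle."""


def compute_phase_durations(
    cycle: CycleTriple,
    contra_seq: GaitEventSequence,
    require_coverage: bool = True,
) -> dict[str, float]:
    """Stance/swing/single/double durations (ms) of one cycle.

    Double support is the measure of the stance interval during which the
    contralateral foot is also in stance, summed over both sub-periods;
    single support is the remainder of stance. Requires the contralateral
    sequence to cover the cycle's stance span, else the cycle is rejected.
    """
    contra = contra_seq.stance_intervals()
    if require_coverage:
        ev = contra_seq.events
        if not ev or ev[0].time_s > cycle.ic_s or ev[-1].time_s < cycle.to_s:
            raise ContralateralCoverageError(
                f"contralateral events do not cover cycle [{cycle.ic_s:.3f}, "
                f"{cycle.to_s:.3f}] s"
            )
    stance_s = cycle.to_s - cycle.ic_s
    swing_s = cycle.next_ic_s - cycle.to_s
    double_s = interval_overlap(cycle.ic_s, cycle.to_s, contra)
    single_s = stance_s - double_s
    return {
        "stance_ms": stance_s * 1000.0,
        "swing_ms": swing_s * 1000.0,
        "double_stance_ms": double_s * 1000.0,
        "single_stance_ms": single_s * 1000.0,
    }


def single_stance_intervals(
    cycle: CycleTriple, contra_seq: GaitEventSequence
) -> list[tuple[float, float]]:
    """Sub-intervals of [IC, TO) during which the contralateral foot is airborne."""
    edges = [cycle.ic_s, cycle.to_s]
    for a, b in contra_seq.stance_intervals():
        for t in (a, b):
            if cycle.ic_s < t < cycle.to_s:
                edges.append(t)
    edges = sorted(set(edges))
    out = []
    contra = contra_seq.stance_intervals()
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        if not any(a <= mid < b for a, b in contra):
            out.append((lo, hi))
    return out


class DegenerateCycleError(ValueError):
    """A cycle has no usable samples for a force computation."""


def _summed_pressure_smoothed(
    recording: InsoleRecording,
    thresholds: DetectionThresholds | None,
) -> np.ndarray:
    S = total_pressure(recording, channel="pressure")
    if thresholds is None:
        thresholds = DetectionThresholds()
    return smooth(S, thresholds)


def mean_force_single_stance(
    recording: InsoleRecording,
    cycle: CycleTriple,
    contra_seq: GaitEventSequence,
    thresholds: DetectionThresholds | None = None,
    force_normalization: float = 1.0,
    _S_smooth: np.ndarray | None = None,
) -> float:
    """Mean summed cell pressure over the cycle's single-support interval(s).

    Uses the smoothed pressure-channel sum divided by ``force_normalization``
    (a cell-area factor mapping the 18-cell sum onto the kg·cm⁻² scale;
    identity by default).
    """
    S = _S_smooth if _S_smooth is not None else _summed_pressure_smoothed(recording, thresholds)
    fs = recording.sample_rate_hz
    t0 = recording.start_time_s
    picks: list[np.ndarray] = []
    for a, b in single_stance_intervals(cycle, contra_seq):
        lo = int(np.ceil((a - t0) * fs))
        hi = int(np.ceil((b - t0) * fs))
        picks.append(np.arange(max(lo, 0), min(hi, S.size)))
    idx = np.concatenate(picks) if picks else np.array([], dtype=int)
    if idx.size == 0:
        raise DegenerateCycleError(
            f"cycle at {cycle.ic_s:.3f} s has an empty single-stance interval"
        )
    return float(S[idx].mean() / force_normalization)


def normalize_force_curve(
    recording: InsoleRecording,
    cycle: CycleTriple,
    n_points: int = 101,
    thresholds: DetectionThresholds | None = None,
    force_normalization: float = 1.0,
    _S_smooth: np.ndarray | None = None,
) -> NormalizedForceCurve:
    """Summed pressure linearly interpolated onto ``n_points`` even fractions
    of the stance phase [IC, TO]. Normalization is over stance rather than
    the whole cycle because the signal is identically ~0 in swing."""
    S = _S_smooth if _S_smooth is not None else _summed_pressure_smoothed(recording, thresholds)
    fs = recording.sample_rate_hz
    t0 = recording.start_time_s
    n_in_stance = (cycle.to_s - cycle.ic_s) * fs
    if n_in_stance < 2:
        raise DegenerateCycleError(f"stance at {cycle.ic_s:.3f} s has fewer than 2 samples")
    times = np.linspace(cycle.ic_s, cycle.to_s, n_points)
    sample_times = t0 + np.arange(S.size) / fs
    values = np.interp(times, sample_times, S) / force_normalization
    return NormalizedForceCurve(values=np.clip(values, 0.0, None), n_points=n_points)


@dataclass
class CycleDiagnostics:
    """Cycles rejected during parameter extraction, with reasons."""

    kept: int = 0
    dropped_coverage: int = 0
    dropped_degenerate: int = 0


def extract_cycle_parameters(
    recording: InsoleRecording,
    seq: GaitEventSequence,
    contra_seq: GaitEventSequence,
    thresholds: DetectionThresholds | None = None,
    n_curve_points: int = 101,
    force_normalization: float = 1.0,
    trim_boundary: bool = True,
) -> tuple[list[CycleParameters], list[NormalizedForceCurve], CycleDiagnostics]:
    """Full per-foot extraction: cycles → durations, mean force, force curves.

    Cycles whose contralateral coverage is incomplete or whose single-stance
    interval is empty are flagged and excluded, never silently filled.
    """
    S_smooth = _summed_pressure_smoothed(recording, thresholds)
    diag = CycleDiagnostics()
    params: list[CycleParameters] = []
    curves: list[NormalizedForceCurve] = []
    for k, cycle in enumerate(segment_cycles(seq, trim_boundary=trim_boundary)):
        try:
            durations = compute_phase_durations(cycle, contra_seq)
            force = mean_force_single_stance(
                recording, cycle, contra_seq,
                force_normalization=force_normalization, _S_smooth=S_smooth,
            )
            curve = normalize_force_curve(
                recording, cycle, n_points=n_curve_points,
                force_normalization=force_normalization, _S_smooth=S_smooth,
            )
        except ContralateralCoverageError:
            diag.dropped_coverage += 1
            continue
        except DegenerateCycleError:
            diag.dropped_degenerate += 1
            continue
        params.append(CycleParameters(cycle_index=k, mean_force_single_stance=force, **durations))
        curves.append(curve)
    diag.kept = len(params)
    return params, curves, diag
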