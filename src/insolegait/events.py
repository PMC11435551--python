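"""Gait-event detection from the summed insole pressure signal.

Initial contact (IC) and toe-off (TO) are found on the total cell signal S:

* IC at sample ``t`` when ``dS/dt[t] > derivative_min`` **and**
  ``S[t + lookahead] > sum_min_ic`` — the foot starts loading *and* the load
  is sustained 100 ms later, which rejects transient spikes;
* TO at sample ``t`` when ``S[t] < sum_max_to`` **and**
  ``S[t + lookahead] < sum_max_to`` — the foot is unloaded now and still
  unloaded 100 ms later, which rejects one-sample dropouts.

The threshold constants (0.2 for the derivative, 50/30 for the sums) act on
the working channel: 8-bit raw counts when the recording carries them, else
calibrated pressure. The derivative is the first difference per sample, so
one unit of threshold corresponds to one count of change per frame.

Within a maximal run of samples satisfying a predicate only the first sample
is reported, and like events closer than ``min_phase_ms`` are debounced.
A Savitzky–Golay smoother is provided and can be switched into the detection
path; by default detection runs on the unsmoothed sum, because a symmetric
smoothing window leaks the stance onset a few samples backwards in time and
biases IC early (the smoothed channel is still used for force curves, see
:mod:`insolegait.parameters`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .io import GaitEvent, GaitEventSequence, InsoleRecording

logger = logging.getLogger("insolegait")


class DetectionConfigError(ValueError):
    """Detection parameters are inconsistent with the signal."""


@dataclass
class DetectionThresholds:
    """Tunable constants of the event detector.

    Defaults are the device's published constants: derivative > 0.2 with the
    sum > 50 a 100 ms look-ahead later for IC; sum < 30 at both instants for
    TO. ``min_phase_ms`` debounces successive like events (no physiological
    gait phase is shorter than 100 ms). ``sg_window_samples``/``sg_polyorder``
    parametrize the Savitzky–Golay smoother.
    """

    derivative_min: float = 0.2
    sum_min_ic: float = 50.0
    sum_max_to: float = 30.0
    lookahead_ms: float = 100.0
    min_phase_ms: float = 100.0
    sg_window_samples: int = 11
    sg_polyorder: int = 3
    #: run detection on the SG-smoothed sum instead of the raw sum
    smooth_detection_channel: bool = False

    def __post_init__(self) -> None:
        if self.sg_window_samples % 2 != 1 or self.sg_window_samples <= self.sg_polyorder:
            raise DetectionConfigError(
                "sg_window_samples must be odd and greater than sg_polyorder"
            )
        if not self.lookahead_ms > 0:
            raise DetectionConfigError("lookahead_ms must be positive")
        for name in ("derivative_min", "sum_min_ic", "sum_max_to", "min_phase_ms"):
            if not np.isfinite(getattr(self, name)):
                raise DetectionConfigError(f"{name} must be finite")

    def lookahead_samples(self, sample_rate_hz: float) -> int:
        """100 ms at 110 Hz is exactly 11 samples; other rates round to nearest."""
        return int(round(self.lookahead_ms * sample_rate_hz / 1000.0))

    def min_phase_samples(self, sample_rate_hz: float) -> int:
        return int(round(self.min_phase_ms * sample_rate_hz / 1000.0))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionThresholds":
        return cls(**d)


def total_pressure(recording: InsoleRecording, channel: str = "auto") -> np.ndarray:
    """Sum of the 18 cell signals per frame (the signal S).

    ``channel`` selects ``"raw"`` counts, calibrated ``"pressure"``, or
    ``"auto"``: raw counts when present, else pressure.
    """
    if channel == "auto":
        channel = "raw" if recording.raw_counts is not None else "pressure"
    if channel == "raw":
        if recording.raw_counts is None:
            raise ValueError("recording has no raw-count channel")
        return recording.raw_counts.sum(axis=1).astype(float)
    if channel == "pressure":
        return recording.cell_pressures.sum(axis=1)
    raise ValueError(f"unknown channel {channel!r}")


def smooth(series: np.ndarray, thresholds: DetectionThresholds | None = None) -> np.ndarray:
    """Savitzky–Golay least-squares polynomial smoothing of S."""
    thresholds = thresholds or DetectionThresholds()
    series = np.asarray(series, dtype=float)
    if series.size < thresholds.sg_window_samples:
        raise DetectionConfigError(
            f"series of length {series.size} is shorter than the smoothing "
            f"window ({thresholds.sg_window_samples})"
        )
    return savgol_filter(series, thresholds.sg_window_samples, thresholds.sg_polyorder)


def derivative(series: np.ndarray, sample_rate_hz: float | None = None) -> np.ndarray:
    """First difference of S, in signal units per sample.

    dS/dt[k] = S[k] − S[k−1], with dS/dt[0] = 0 so the output aligns with the
    input. The per-sample (rather than per-second) scale keeps the 0.2
    threshold meaningful on an 8-bit count channel.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    out = np.empty_like(series)
    out[0] = 0.0
    out[1:] = np.diff(series)
    return out


def _run_starts(mask: np.ndarray) -> np.ndarray:
    """Indices where a maximal run of True begins."""
    if mask.size == 0:
        return np.array([], dtype=int)
    prev = np.concatenate(([False], mask[:-1]))
    return np.flatnonzero(mask & ~prev)


def _debounce(indices: np.ndarray, min_gap: int) -> list[int]:
    kept: list[int] = []
    for i in indices:
        if not kept or i - kept[-1] >= min_gap:
            kept.append(int(i))
    return kept


def detect_initial_contacts(
    S: np.ndarray,
    dSdt: np.ndarray,
    thresholds: DetectionThresholds,
    sample_rate_hz: float,
) -> list[int]:
    """Sample indices of initial contacts.

    Reports the first sample of every maximal run where the IC predicate
    holds, debounced by ``min_phase_ms``. The final look-ahead window of the
    recording cannot host detections.
    """
    S = np.asarray(S, dtype=float)
    dSdt = np.asarray(dSdt, dtype=float)
    if S.shape != dSdt.shape:
        raise ValueError("S and dS/dt must be aligned")
    la = thresholds.lookahead_samples(sample_rate_hz)
    if S.size <= la:
        logger.warning("recording shorter than the look-ahead window; no IC detection")
        return []
    mask = np.zeros(S.size, dtype=bool)
    mask[: S.size - la] = (dSdt[: S.size - la] > thresholds.derivative_min) & (
        S[la:] > thresholds.sum_min_ic
    )
    return _debounce(_run_starts(mask), thresholds.min_phase_samples(sample_rate_hz))


def detect_toe_offs(
    S: np.ndarray,
    thresholds: DetectionThresholds,
    sample_rate_hz: float,
) -> list[int]:
    """Sample indices of toe-offs (first sample of each unloaded run)."""
    S = np.asarray(S, dtype=float)
    la = thresholds.lookahead_samples(sample_rate_hz)
    if S.size <= la:
        logger.warning("recording shorter than the look-ahead window; no TO detection")
        return []
    mask = np.zeros(S.size, dtype=bool)
    mask[: S.size - la] = (S[: S.size - la] < thresholds.sum_max_to) & (
        S[la:] < thresholds.sum_max_to
    )
    return _debounce(_run_starts(mask), thresholds.min_phase_samples(sample_rate_hz))


@dataclass
class EventDiagnostics:
    """Bookkeeping of events discarded while enforcing alternation."""

    dropped_initial_contacts: int = 0
    dropped_toe_offs: int = 0
    kept: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_initial_contacts + self.dropped_toe_offs


def build_event_sequence(
    ics: Sequence[int],
    tos: Sequence[int],
    recording: InsoleRecording,
) -> tuple[GaitEventSequence, EventDiagnostics]:
    """Merge IC and TO indices into a validated alternating sequence.

    Events are walked in time order starting from the first IC; any event of
    the unexpected kind is dropped and counted. An all-dropped input yields
    an empty sequence with a warning, never a crash.
    """
    if list(ics) != sorted(ics) or list(tos) != sorted(tos):
        raise ValueError("event index lists must be sorted")
    fs = recording.sample_rate_hz
    merged = sorted(
        [(int(i), "initial_contact") for i in ics] + [(int(i), "toe_off") for i in tos]
    )
    diag = EventDiagnostics()
    events: list[GaitEvent] = []
    expected = "initial_contact"
    for idx, kind in merged:
        if kind == expected:
            events.append(
                GaitEvent(kind=kind, time_s=recording.start_time_s + idx / fs, sample_index=idx)
            )
            expected = "toe_off" if expected == "initial_contact" else "initial_contact"
        elif kind == "initial_contact":
            diag.dropped_initial_contacts += 1
        else:
            diag.dropped_toe_offs += 1
    diag.kept = len(events)
    if not events:
        logger.warning(
            "%s foot: no complete IC–TO pairs (dropped %d IC, %d TO)",
            recording.foot_side, diag.dropped_initial_contacts, diag.dropped_toe_offs,
        )
    return GaitEventSequence(foot_side=recording.foot_side, events=events), diag


def detect_events(
    recording: InsoleRecording,
    thresholds: DetectionThresholds | None = None,
) -> tuple[GaitEventSequence, EventDiagnostics]:
    """Full per-foot detection: sum → (optional smoothing) → IC/TO → sequence."""
    thresholds = thresholds or DetectionThresholds()
    S = total_pressure(recording)
    if thresholds.smooth_detection_channel:
        S = smooth(S, thresholds)
    dSdt = derivative(S, recording.sample_rate_hz)
    ics = detect_initial_contacts(S, dSdt, thresholds, recording.sample_rate_hz)
    tos = detect_toe_offs(S, thresholds, recording.sample_rate_hz)
    return build_event_sequence(ics, tos, recording)
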