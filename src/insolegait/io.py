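"""Domain types and file I/O for instrumented-insole gait analysis.

The insole hardware modelled here carries 18 capacitive pressure cells per
foot sampled at 110 Hz with an 8-bit digitizer. Recordings are exchanged as
one CSV file per foot with columns ``time_s, cell_01..cell_18`` (calibrated
pressure, kg·cm⁻²) and optionally ``raw_01..raw_18`` (integer counts in
[0, 255]). Metadata (foot side, sample rate, start time) travels in a single
``#``-prefixed header line so that a file round-trips to an identical
:class:`InsoleRecording`.

Reliability reports are written as a small family of CSV tables (per-cell
statistics, effect sizes, min/max summary, effect-size census) plus a
human-readable text rendering that mirrors the value-(percent) style used in
the gait-metrology literature.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("insolegait")

N_CELLS = 18
RAW_MAX = 255

FOOT_SIDES = ("left", "right")

#: canonical walking-condition labels: one overground walk, one symmetric
#: treadmill walk, and six split-belt walks with 16/33/50 % speed asymmetry
#: driving the left or right leg.
CONDITION_NAMES = (
    "TDM6-SYM-GROUND",
    "TDM6-SYM-MGAIT",
    "TDM6-ASYM-MGAIT-16L",
    "TDM6-ASYM-MGAIT-33L",
    "TDM6-ASYM-MGAIT-50L",
    "TDM6-ASYM-MGAIT-16R",
    "TDM6-ASYM-MGAIT-33R",
    "TDM6-ASYM-MGAIT-50R",
)

PARAMETER_COLUMNS = (
    "stance_ms",
    "single_stance_ms",
    "double_stance_ms",
    "swing_ms",
    "mean_force_single_stance",
)


class SchemaError(ValueError):
    """A file does not match the documented CSV schema."""


class IntegrityError(ValueError):
    """A file parses but violates a structural invariant (cell count,
    monotone time, value ranges)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class InsoleRecording:
    """One foot's time series of 18-cell pressure frames.

    Parameters
    ----------
    foot_side
        ``"left"`` or ``"right"``.
    sample_rate_hz
        Frame rate; the modelled device samples at 110 Hz.
    cell_pressures
        ``(n_frames, 18)`` array of non-negative pressures in kg·cm⁻².
    raw_counts
        Optional parallel ``(n_frames, 18)`` integer array of 8-bit ADC
        counts. When present, event detection operates on this channel.
    start_time_s
        Time of frame 0; frame ``k`` is at ``start_time_s + k / sample_rate_hz``.
    """

    foot_side: str
    sample_rate_hz: float
    cell_pressures: np.ndarray
    raw_counts: np.ndarray | None = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.foot_side not in FOOT_SIDES:
            raise ValueError(f"foot_side must be one of {FOOT_SIDES}, got {self.foot_side!r}")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        self.cell_pressures = np.asarray(self.cell_pressures, dtype=float)
        if self.cell_pressures.ndim != 2 or self.cell_pressures.shape[1] != N_CELLS:
            raise IntegrityError(
                f"cell_pressures must be (n_frames, {N_CELLS}); got {self.cell_pressures.shape}"
            )
        if self.cell_pressures.shape[0] < 1:
            raise IntegrityError("recording must contain at least one frame")
        if np.any(self.cell_pressures < 0) or not np.all(np.isfinite(self.cell_pressures)):
            raise IntegrityError("cell pressures must be finite and non-negative")
        if self.raw_counts is not None:
            self.raw_counts = np.asarray(self.raw_counts, dtype=np.int64)
            if self.raw_counts.shape != self.cell_pressures.shape:
                raise IntegrityError("raw_counts must parallel cell_pressures")
            if self.raw_counts.min() < 0 or self.raw_counts.max() > RAW_MAX:
                raise IntegrityError("raw counts must lie in [0, 255]")

    @property
    def n_frames(self) -> int:
        return self.cell_pressures.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_frames) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_hz

    def __eq__(self, other: object) -> bool:  # field-for-field identity
        if not isinstance(other, InsoleRecording):
            return NotImplemented
        raw_eq = (self.raw_counts is None) == (other.raw_counts is None) and (
            self.raw_counts is None or np.array_equal(self.raw_counts, other.raw_counts)
        )
        return (
            self.foot_side == other.foot_side
            and self.sample_rate_hz == other.sample_rate_hz
            and self.start_time_s == other.start_time_s
            and np.array_equal(self.cell_pressures, other.cell_pressures)
            and raw_eq
        )


@dataclass(frozen=True)
class GaitEvent:
    """A single gait event on one foot's timeline."""

    kind: str  # "initial_contact" | "toe_off"
    time_s: float
    sample_index: int

    def __post_init__(self) -> None:
        if self.kind not in ("initial_contact", "toe_off"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class GaitEventSequence:
    """Validated, strictly alternating IC/TO events for one foot.

    After validation the sequence starts with an initial contact and kinds
    alternate IC, TO, IC, TO, …; the constructor enforces this.
    """

    foot_side: str
    events: list[GaitEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.foot_side not in FOOT_SIDES:
            raise ValueError(f"foot_side must be one of {FOOT_SIDES}")
        times = [e.time_s for e in self.events]
        if times != sorted(times):
            raise ValueError("events must be time-ordered")
        expected = "initial_contact"
        for e in self.events:
            if e.kind != expected:
                raise ValueError("event kinds must alternate IC, TO, … starting with IC")
            expected = "toe_off" if expected == "initial_contact" else "initial_contact"

    def __len__(self) -> int:
        return len(self.events)

    @property
    def initial_contacts(self) -> list[GaitEvent]:
        return [e for e in self.events if e.kind == "initial_contact"]

    @property
    def toe_offs(self) -> list[GaitEvent]:
        return [e for e in self.events if e.kind == "toe_off"]

    def stance_intervals(self) -> list[tuple[float, float]]:
        """(IC, TO) pairs, i.e. the intervals the foot is on the ground."""
        out = []
        ev = self.events
        for i in range(0, len(ev) - 1, 2):
            out.append((ev[i].time_s, ev[i + 1].time_s))
        return out


@dataclass(frozen=True)
class CycleParameters:
    """The five analysed parameters of one gait cycle.

    Durations are in milliseconds; mean force in kg·cm⁻². By construction
    ``stance_ms + swing_ms`` equals the cycle duration and
    ``single_stance_ms + double_stance_ms`` equals ``stance_ms``.
    """

    cycle_index: int
    stance_ms: float
    swing_ms: float
    single_stance_ms: float
    double_stance_ms: float
    mean_force_single_stance: float

    def __post_init__(self) -> None:
        for name in ("stance_ms", "swing_ms", "single_stance_ms", "double_stance_ms"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    @property
    def cycle_ms(self) -> float:
        return self.stance_ms + self.swing_ms


@dataclass
class NormalizedForceCurve:
    """Summed plantar pressure resampled onto an even grid over stance.

    ``grid`` holds ``n_points`` fractions of the stance phase in [0, 1];
    ``values`` the interpolated summed pressure (kg·cm⁻²) at each fraction.
    """

    values: np.ndarray
    n_points: int = 101

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_points,):
            raise ValueError(f"curve must have exactly {self.n_points} points")
        if np.any(self.values < 0):
            raise ValueError("force values must be non-negative")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_points)


@dataclass
class TrialParameters:
    """Per-cycle parameters and force curves of one trial (both feet)."""

    cycles: dict[str, list[CycleParameters]]
    force_curves: dict[str, list[NormalizedForceCurve]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FOOT_SIDES) - set(self.cycles)
        if missing:
            raise ValueError(f"trial is missing feet: {sorted(missing)}")


@dataclass
class ConditionDataset:
    """Three repeated walk tests of one condition, both feet each.

    The protocol repeats each condition three times to bound intra-individual
    variability; per-trial variances feed the SEM formula.
    """

    condition_name: str
    trials: list[TrialParameters]
    n_required_trials: int = 3

    def __post_init__(self) -> None:
        if len(self.trials) != self.n_required_trials:
            raise ValueError(
                f"condition {self.condition_name!r} needs exactly "
                f"{self.n_required_trials} trials, got {len(self.trials)}"
            )

    def parameter_matrix(self, parameter: str, foot: str) -> np.ndarray:
        """Cycles × trials matrix for ICC, truncated to the common cycle count."""
        cols = [
            np.array([getattr(c, parameter) for c in t.cycles[foot]]) for t in self.trials
        ]
        n = min(len(c) for c in cols)
        return np.column_stack([c[:n] for c in cols])

    def pooled_values(self, parameter: str, foot: str) -> np.ndarray:
        return np.concatenate(
            [[getattr(c, parameter) for c in t.cycles[foot]] for t in self.trials]
        )


@dataclass
class ReliabilityReport:
    """Full metrology report: one row per (parameter, foot, condition) in
    ``cells``; effect sizes per condition pair in ``effect_sizes``; Table-style
    min/max summary rows in ``summary``; effect-size census in ``es_census``.
    """

    cells: pd.DataFrame
    effect_sizes: pd.DataFrame
    summary: pd.DataFrame
    es_census: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReliabilityReport):
            return NotImplemented
        try:
            for a, b in zip(self._frames(), other._frames()):
                pd.testing.assert_frame_equal(
                    a, b, check_exact=False, atol=1e-12, check_dtype=False
                )
        except AssertionError:
            return False
        return True

    def _frames(self) -> tuple[pd.DataFrame, ...]:
        return self.cells, self.effect_sizes, self.summary, self.es_census


# ---------------------------------------------------------------------------
# Recording CSV schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecordingSchema:
    """Column layout of the documented recording CSV dialect."""

    time_column: str = "time_s"
    pressure_prefix: str = "cell_"
    raw_prefix: str = "raw_"
    n_cells: int = N_CELLS

    @property
    def pressure_columns(self) -> list[str]:
        return [f"{self.pressure_prefix}{i:02d}" for i in range(1, self.n_cells + 1)]

    @property
    def raw_columns(self) -> list[str]:
        return [f"{self.raw_prefix}{i:02d}" for i in range(1, self.n_cells + 1)]


DEFAULT_SCHEMA = RecordingSchema()

_META_PREFIX = "# insolegait-recording"


def write_recording(recording: InsoleRecording, path: str | Path,
                    schema: RecordingSchema = DEFAULT_SCHEMA) -> Path:
    """Write a recording to CSV in the documented schema (deterministic
    column order, full float precision so the file round-trips exactly)."""
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(
                f"{_META_PREFIX} foot_side={recording.foot_side} "
                f"sample_rate_hz={recording.sample_rate_hz!r} "
                f"start_time_s={recording.start_time_s!r}\n"
            )
            cols: dict[str, np.ndarray] = {schema.time_column: recording.times_s}
            for j, name in enumerate(schema.pressure_columns):
                cols[name] = recording.cell_pressures[:, j]
            if recording.raw_counts is not None:
                for j, name in enumerate(schema.raw_columns):
                    cols[name] = recording.raw_counts[:, j]
            pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc
    return path


def read_recording(path: str | Path, schema: RecordingSchema = DEFAULT_SCHEMA) -> InsoleRecording:
    """Read and validate a recording CSV.

    Raises
    ------
    SchemaError
        Missing required columns or metadata header.
    IntegrityError
        Wrong cell count, malformed/missing values, or non-monotone time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(_META_PREFIX):
            raise SchemaError(f"{path}: missing '{_META_PREFIX}' metadata header")
        meta = dict(
            item.split("=", 1) for item in first[len(_META_PREFIX):].split() if "=" in item
        )
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except (pd.errors.ParserError, ValueError) as exc:
            raise IntegrityError(f"{path}: malformed CSV body: {exc}") from exc

    missing = [c for c in [schema.time_column, *schema.pressure_columns] if c not in df.columns]
    if missing:
        # distinguish wrong cell count from an unrelated schema mismatch
        present_cells = [c for c in df.columns if c.startswith(schema.pressure_prefix)]
        if present_cells and len(present_cells) != schema.n_cells:
            raise IntegrityError(
                f"{path}: expected {schema.n_cells} pressure columns, "
                f"found {len(present_cells)}"
            )
        raise SchemaError(f"{path}: missing columns {missing}")
    extra_cells = [
        c for c in df.columns
        if c.startswith(schema.pressure_prefix) and c not in schema.pressure_columns
    ]
    if extra_cells:
        raise IntegrityError(f"{path}: unexpected pressure columns {extra_cells}")

    pressures = df[schema.pressure_columns].to_numpy()
    if np.isnan(pressures).any():
        bad = int(np.where(np.isnan(pressures).any(axis=1))[0][0])
        raise IntegrityError(f"{path}: malformed pressure values at row {bad}")

    t = df[schema.time_column].to_numpy(dtype=float)
    if np.isnan(t).any() or np.any(np.diff(t) <= 0):
        raise IntegrityError(f"{path}: time column must be strictly increasing")

    raw = None
    if all(c in df.columns for c in schema.raw_columns):
        raw = df[schema.raw_columns].to_numpy()
        if np.isnan(raw).any():
            raise IntegrityError(f"{path}: malformed raw-count values")
        raw = raw.astype(np.int64)

    try:
        rate = float(meta["sample_rate_hz"])
        start = float(meta.get("start_time_s", t[0]))
        side = meta["foot_side"]
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: bad metadata header: {exc}") from exc

    return InsoleRecording(
        foot_side=side, sample_rate_hz=rate, cell_pressures=pressures,
        raw_counts=raw, start_time_s=start,
    )


# ---------------------------------------------------------------------------
# Cycle-parameter tables
# ---------------------------------------------------------------------------


def cycles_to_frame(cycles: Sequence[CycleParameters], foot: str | None = None) -> pd.DataFrame:
    """Flatten per-cycle parameters to a tidy table (one row per cycle)."""
    rows = [dataclasses.asdict(c) for c in cycles]
    df = pd.DataFrame(rows, columns=["cycle_index", *PARAMETER_COLUMNS])
    if foot is not None:
        df.insert(0, "foot", foot)
    return df


def frame_to_cycles(df: pd.DataFrame) -> list[CycleParameters]:
    return [
        CycleParameters(
            cycle_index=int(r.cycle_index),
            stance_ms=float(r.stance_ms),
            swing_ms=float(r.swing_ms),
            single_stance_ms=float(r.single_stance_ms),
            double_stance_ms=float(r.double_stance_ms),
            mean_force_single_stance=float(r.mean_force_single_stance),
        )
        for r in df.itertuples()
    ]


def write_cycle_table(trial: TrialParameters, path: str | Path) -> Path:
    path = Path(path)
    frames = [cycles_to_frame(trial.cycles[f], foot=f) for f in FOOT_SIDES]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return path


def read_cycle_table(path: str | Path) -> TrialParameters:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"foot", "cycle_index", *PARAMETER_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    cycles = {
        foot: frame_to_cycles(sub.drop(columns="foot"))
        for foot, sub in df.groupby("foot", sort=True)
    }
    for foot in FOOT_SIDES:
        cycles.setdefault(foot, [])
    return TrialParameters(cycles=cycles)


# ---------------------------------------------------------------------------
# Report I/O and display formatting
# ---------------------------------------------------------------------------

_REPORT_PARTS = ("cells", "effect_sizes", "summary", "es_census")


def _report_paths(path: Path) -> dict[str, Path]:
    stem = path.with_suffix("")
    return {
        "cells": path,
        "effect_sizes": stem.with_name(stem.name + ".effect_sizes.csv"),
        "summary": stem.with_name(stem.name + ".summary.csv"),
        "es_census": stem.with_name(stem.name + ".es_census.csv"),
    }


def write_report(report: ReliabilityReport, path: str | Path) -> list[Path]:
    """Write the four report tables as CSV files next to ``path``.

    ``path`` receives the per-cell statistics; the effect-size, summary and
    census tables are written alongside with suffixed names.
    """
    path = Path(path)
    paths = _report_paths(path)
    try:
        for part, p in paths.items():
            getattr(report, part).to_csv(p, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return list(paths.values())


def read_report(path: str | Path) -> ReliabilityReport:
    paths = _report_paths(Path(path))
    frames = {}
    for part, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"report table {p} is missing")
        frames[part] = pd.read_csv(p, float_precision="round_trip")
    return ReliabilityReport(**frames)


def format_value_percent(value: float, mean: float, value_decimals: int = 2,
                         percent_decimals: int = 2) -> str:
    """Render a statistic as ``"value (percent%)"``, e.g. ``"0.86 (10.58%)"``.

    The percent is taken relative to ``mean`` and computed from the
    *display-rounded* value, matching how such tables are conventionally
    typeset; trailing zeros in the percent are trimmed to one decimal.
    """
    rounded = round(value, value_decimals)
    pct = 100.0 * rounded / mean
    pct_str = f"{pct:.{percent_decimals}f}"
    if pct_str.endswith("0") and percent_decimals == 2:
        pct_str = f"{pct:.1f}"
    return f"{rounded:.{value_decimals}f} ({pct_str}%)"


def format_report_text(report: ReliabilityReport) -> str:
    """Human-readable rendering of the report tables."""
    out = []
    for part in _REPORT_PARTS:
        df = getattr(report, part)
        out.append(f"== {part} ==")
        out.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        out.append("")
    return "\n".join(out)
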