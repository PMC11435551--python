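"""Synthetic dual-insole walking recordings with known ground truth.

The generator emulates the device and protocol this package analyses: two
insoles with 18 capacitive cells each, sampled at 110 Hz with an 8-bit
digitizer, worn during 6-minute walk tests repeated three times per walking
condition. Eight conditions are modelled: one overground walk, one symmetric
dual-belt treadmill walk at 1.2 m/s, and six split-belt walks where one belt
runs 16/33/50 % faster to induce a controlled gait asymmetry.

Timing model (steady state, shared stride clock):

* both feet share one stride period per cycle; the contralateral initial
  contact is offset by ``interfoot_phase`` (0.5 = perfect alternation);
* stride period shortens mildly as mean belt speed rises (cadence increases
  with speed);
* each foot's stance fraction shrinks with the *maximum* belt speed (this is
  what shrinks double support for both legs), and the foot on the faster
  belt — the *driven* leg — loses additional stance in proportion to the
  speed ratio;
* per-cycle stride and stance times are drawn as condition mean + trial
  effect (between-trial SD) + step noise (within-trial SD), plus a slow
  within-trial drift that repeats across trials (an accommodation trend; it
  is what makes cycle-paired trials correlate).

Each stance is rendered as a double-bump vertical-load profile (loading and
push-off peaks with a mid-stance trough) distributed over the 18 cells with
a heel → midfoot → forefoot activation progression; swing frames are zero.
Sensor noise is contact-proportional: an unloaded capacitive cell reads a
clean zero after 8-bit quantization, so noise scales with instantaneous cell
load. The profile aims at plausibility on the kg·cm⁻² scale, not at
replicating force-platform curves.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import CONDITION_NAMES, FOOT_SIDES, InsoleRecording, RAW_MAX
from .parameters import interval_overlap

logger = logging.getLogger("insolegait")


class SimulationConfigError(ValueError):
    """The requested gait geometry is infeasible."""


#: Table of belt speeds (m/s) per condition, right then left belt. The
#: overground condition has no belts and is simulated as symmetric walking
#: at the reference speed with inflated variability.
CONDITION_BELT_SPEEDS: dict[str, tuple[float, float]] = {
    "TDM6-SYM-GROUND": (1.2, 1.2),
    "TDM6-SYM-MGAIT": (1.2, 1.2),
    "TDM6-ASYM-MGAIT-16L": (1.2, 1.4),
    "TDM6-ASYM-MGAIT-33L": (1.2, 1.6),
    "TDM6-ASYM-MGAIT-50L": (1.2, 1.8),
    "TDM6-ASYM-MGAIT-16R": (1.4, 1.2),
    "TDM6-ASYM-MGAIT-33R": (1.6, 1.2),
    "TDM6-ASYM-MGAIT-50R": (1.8, 1.2),
}

REFERENCE_SPEED_MPS = 1.2


@dataclass(frozen=True)
class VarianceComponents:
    """Gaussian SDs of the drawn gait quantities (stride/stance in ms,
    force amplitude in kg·cm⁻² on the profile peak)."""

    stride_ms: float = 8.0
    stance_ms: float = 10.0
    force_kg_cm2: float = 0.15

    def scaled(self, factor: float) -> "VarianceComponents":
        return VarianceComponents(
            stride_ms=self.stride_ms * factor,
            stance_ms=self.stance_ms * factor,
            force_kg_cm2=self.force_kg_cm2 * factor,
        )


@dataclass
class SimulationConfig:
    """Everything the generator needs for one condition.

    Defaults reproduce the study geometry: 3 trials of a 6-minute test,
    110 Hz sampling, 18 cells, 8-bit counts, stride ≈ 1.145 s and stance
    fraction ≈ 0.635 at the 1.2 m/s reference speed, summed-pressure peak
    ≈ 10.5 kg·cm⁻² (single-stance mean force ≈ 8.3).
    """

    condition_name: str = "TDM6-SYM-MGAIT"
    belt_speed_right_mps: float = 1.2
    belt_speed_left_mps: float = 1.2
    n_trials: int = 3
    trial_duration_s: float = 360.0
    sample_rate_hz: float = 110.0
    cadence_hz: float = 1.0 / 1.145  # strides per second at reference speed
    stance_fraction: float = 0.635
    interfoot_phase: float = 0.5
    peak_pressure_kg_cm2: float = 10.5
    within_trial_sd: VarianceComponents = field(default_factory=VarianceComponents)
    between_trial_sd: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(4.0, 4.0, 0.05)
    )
    cell_noise_sd: float = 0.02  # relative, contact-proportional
    quantize_8bit: bool = True
    seed: int = 0
    # shape/response constants (fixed plausible values, overridable)
    trough_depth: float = 0.25
    cadence_speed_exp: float = 0.3   # stride ∝ (v_ref/v_mean)^exp
    ds_speed_gain: float = 0.05      # stance-fraction loss per m/s of max speed
    asym_stance_gain: float = 0.20   # extra driven-leg loss per unit speed ratio − 1
    drift_ms: float = 6.0            # peak-to-peak within-trial drift, repeats per trial
    cell_full_scale_kg_cm2: float = 2.5  # per-cell pressure at count 255
    start_pad_s: float = 1.0

    def __post_init__(self) -> None:
        if self.belt_speed_left_mps <= 0 or self.belt_speed_right_mps <= 0:
            raise SimulationConfigError("belt speeds must be positive")
        if not 0 < self.stance_fraction < 1:
            raise SimulationConfigError("stance_fraction must lie in (0, 1)")
        if not 0 < self.interfoot_phase < 1:
            raise SimulationConfigError("interfoot_phase must lie in (0, 1)")
        if self.n_trials < 2:
            raise SimulationConfigError("need at least 2 trials")
        for comp in (self.within_trial_sd, self.between_trial_sd):
            if min(dataclasses.astuple(comp)) < 0:
                raise SimulationConfigError("variance components must be non-negative")
        if self.cell_noise_sd < 0:
            raise SimulationConfigError("cell_noise_sd must be non-negative")
        sf = self._stance_fractions()
        if min(sf.values()) <= 0.05 or max(sf.values()) >= 0.95:
            raise SimulationConfigError(
                f"infeasible geometry: stance fractions {sf} out of range"
            )

    # -- condition-dependent gait geometry ---------------------------------
    @property
    def belt_speeds(self) -> dict[str, float]:
        return {"left": self.belt_speed_left_mps, "right": self.belt_speed_right_mps}

    def _stride_s(self) -> float:
        v_mean = 0.5 * (self.belt_speed_left_mps + self.belt_speed_right_mps)
        return (1.0 / self.cadence_hz) * (REFERENCE_SPEED_MPS / v_mean) ** self.cadence_speed_exp

    def _stance_fractions(self) -> dict[str, float]:
        v = self.belt_speeds
        v_max = max(v.values())
        out = {}
        for foot in FOOT_SIDES:
            other = "right" if foot == "left" else "left"
            common = self.stance_fraction * (
                1.0 - self.ds_speed_gain * (v_max - REFERENCE_SPEED_MPS)
            )
            ratio_excess = max(0.0, v[foot] / v[other] - 1.0)
            out[foot] = common - self.asym_stance_gain * self.stance_fraction * ratio_excess
        return out

    @property
    def driven_foot(self) -> str | None:
        """The foot on the faster belt, or None for symmetric conditions."""
        v = self.belt_speeds
        if v["left"] == v["right"]:
            return None
        return "left" if v["left"] > v["right"] else "right"


def condition_preset(name: str, **overrides) -> SimulationConfig:
    """Config for one of the eight named walking conditions.

    The overground condition gets doubled within-trial and between-trial
    variability (walks outside the treadmill's pacing are less stereotyped);
    treadmill conditions use the defaults.
    """
    if name not in CONDITION_NAMES:
        raise KeyError(f"unknown condition {name!r}; choose from {CONDITION_NAMES}")
    v_right, v_left = CONDITION_BELT_SPEEDS[name]
    kwargs: dict = dict(
        condition_name=name,
        belt_speed_right_mps=v_right,
        belt_speed_left_mps=v_left,
    )
    if name == "TDM6-SYM-GROUND":
        kwargs["within_trial_sd"] = VarianceComponents().scaled(2.0)
        kwargs["between_trial_sd"] = VarianceComponents(4.0, 4.0, 0.05).scaled(2.0)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class FootTruth:
    """True event times and per-cycle quantities for one foot of one trial."""

    ic_times_s: np.ndarray
    to_times_s: np.ndarray
    stance_ms: np.ndarray
    swing_ms: np.ndarray
    single_stance_ms: np.ndarray
    double_stance_ms: np.ndarray
    cycle_ms: np.ndarray
    mean_force: np.ndarray
    cycle_ic_times_s: np.ndarray  # IC of each truth cycle, for alignment


@dataclass
class GroundTruth:
    """Oracle record emitted alongside each simulated trial."""

    feet: dict[str, FootTruth]
    trial_effects: dict[str, float]
    stride_s: float
    stance_fractions: dict[str, float]


@dataclass
class TrialSimulation:
    left: InsoleRecording
    right: InsoleRecording
    truth: GroundTruth

    def recording(self, foot: str) -> InsoleRecording:
        return {"left": self.left, "right": self.right}[foot]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

# fixed cell weights: 6 heel / 6 midfoot / 6 forefoot, mildly uneven so no
# two cells are identical (plausible anatomy, arbitrary constants)
_CELL_WEIGHTS = np.array(
    [1.3, 1.1, 0.9, 1.2, 0.8, 1.0,   # heel
     0.9, 1.2, 1.0, 1.1, 0.8, 1.0,   # midfoot
     1.2, 1.4, 1.0, 0.9, 1.1, 0.7]   # forefoot
)
_GROUP = np.repeat([0, 1, 2], 6)
_ENV_CENTER = np.array([0.22, 0.50, 0.78])
_ENV_WIDTH = np.array([0.20, 0.28, 0.20])


def _sum_profile(u: np.ndarray, peak: float, trough_depth: float) -> np.ndarray:
    """Double-bump summed-pressure profile over stance fraction u ∈ [0, 1]."""
    base = np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 0.6
    trough = 1.0 - trough_depth * np.exp(-(((u - 0.5) / 0.16) ** 2))
    return peak * base * trough


def _cell_weights_at(u: np.ndarray) -> np.ndarray:
    """(len(u), 18) row-normalized cell weights with heel→forefoot progression."""
    env = np.exp(-(((u[:, None] - _ENV_CENTER[None, :]) / _ENV_WIDTH[None, :]) ** 2))
    w = env[:, _GROUP] * _CELL_WEIGHTS[None, :]
    return w / w.sum(axis=1, keepdims=True)


def _drift(i: np.ndarray, n: int, drift_ms: float) -> np.ndarray:
    """Slow within-trial trend (ms), identical in every trial of a condition."""
    if n <= 1:
        return np.zeros_like(i, dtype=float)
    return drift_ms * (i / (n - 1) - 0.5)


def _simulate_trial(
    config: SimulationConfig, rng: np.random.Generator
) -> TrialSimulation:
    fs = config.sample_rate_hz
    stride = config._stride_s()
    sfs = config._stance_fractions()
    n_frames = int(np.ceil(config.trial_duration_s * fs))

    # how many full cycles fit after the start pad, leaving one stride of tail
    n_cycles = int(np.floor((config.trial_duration_s - config.start_pad_s) / stride)) - 1
    if n_cycles < 3:
        raise SimulationConfigError(
            f"trial_duration_s={config.trial_duration_s} fits only {n_cycles} cycles"
        )

    eff = {
        "stride_s": rng.normal(0.0, config.between_trial_sd.stride_ms / 1000.0),
        "stance_s": rng.normal(0.0, config.between_trial_sd.stance_ms / 1000.0),
        "force": rng.normal(0.0, config.between_trial_sd.force_kg_cm2),
    }

    i = np.arange(n_cycles)
    drift_s = _drift(i, n_cycles, config.drift_ms) / 1000.0
    strides = (
        stride + eff["stride_s"] + drift_s
        + rng.normal(0.0, config.within_trial_sd.stride_ms / 1000.0, n_cycles)
    )
    ic_left = config.start_pad_s + np.concatenate(([0.0], np.cumsum(strides[:-1])))
    ic_right = ic_left + config.interfoot_phase * strides

    stances: dict[str, np.ndarray] = {}
    amps: dict[str, np.ndarray] = {}
    ics = {"left": ic_left, "right": ic_right}
    for foot in FOOT_SIDES:
        st = (
            sfs[foot] * stride + eff["stance_s"] + drift_s
            + rng.normal(0.0, config.within_trial_sd.stance_ms / 1000.0, n_cycles)
        )
        stances[foot] = np.clip(st, 0.15 * stride, 0.93 * strides)
        amps[foot] = np.clip(
            config.peak_pressure_kg_cm2 + eff["force"]
            + rng.normal(0.0, config.within_trial_sd.force_kg_cm2, n_cycles),
            0.1, None,
        )

    recordings: dict[str, InsoleRecording] = {}
    clean_sums: dict[str, np.ndarray] = {}
    for foot in FOOT_SIDES:
        pressures = np.zeros((n_frames, 18))
        clean = np.zeros(n_frames)
        for k in range(n_cycles):
            ic, st, amp = ics[foot][k], stances[foot][k], amps[foot][k]
            lo = int(np.ceil(ic * fs))
            hi = min(int(np.ceil((ic + st) * fs)), n_frames)
            if hi <= lo:
                continue
            u = (np.arange(lo, hi) / fs - ic) / st
            s = _sum_profile(u, amp, config.trough_depth)
            clean[lo:hi] = s
            cells = s[:, None] * _cell_weights_at(u)
            if config.cell_noise_sd > 0:
                cells = cells * (
                    1.0 + rng.normal(0.0, config.cell_noise_sd, cells.shape)
                )
            pressures[lo:hi] = np.clip(cells, 0.0, None)
        raw = None
        if config.quantize_8bit:
            raw = np.clip(
                np.rint(pressures / config.cell_full_scale_kg_cm2 * RAW_MAX),
                0, RAW_MAX,
            ).astype(np.int64)
        recordings[foot] = InsoleRecording(
            foot_side=foot, sample_rate_hz=fs, cell_pressures=pressures, raw_counts=raw
        )
        clean_sums[foot] = clean

    truth_feet = {}
    stance_ints = {
        f: [(ics[f][k], ics[f][k] + stances[f][k]) for k in range(n_cycles)]
        for f in FOOT_SIDES
    }
    for foot in FOOT_SIDES:
        contra = "right" if foot == "left" else "left"
        contra_span = (stance_ints[contra][0][0], stance_ints[contra][-1][1])
        rows = {k: [] for k in (
            "stance_ms", "swing_ms", "single_stance_ms", "double_stance_ms",
            "cycle_ms", "mean_force", "cycle_ic_times_s",
        )}
        for k in range(n_cycles - 1):
            ic, to = stance_ints[foot][k]
            next_ic = ics[foot][k + 1]
            if ic < contra_span[0] or to > contra_span[1]:
                continue  # contralateral coverage incomplete at the edges
            double_s = interval_overlap(ic, to, stance_ints[contra])
            single_intervals = _complement(ic, to, stance_ints[contra])
            idx = np.concatenate(
                [np.arange(int(np.ceil(a * fs)), int(np.ceil(b * fs)))
                 for a, b in single_intervals]
            ) if single_intervals else np.array([], dtype=int)
            mean_force = float(clean_sums[foot][idx].mean()) if idx.size else np.nan
            rows["stance_ms"].append((to - ic) * 1000.0)
            rows["swing_ms"].append((next_ic - to) * 1000.0)
            rows["double_stance_ms"].append(double_s * 1000.0)
            rows["single_stance_ms"].append((to - ic - double_s) * 1000.0)
            rows["cycle_ms"].append((next_ic - ic) * 1000.0)
            rows["mean_force"].append(mean_force)
            rows["cycle_ic_times_s"].append(ic)
        truth_feet[foot] = FootTruth(
            ic_times_s=ics[foot].copy(),
            to_times_s=ics[foot] + stances[foot],
            **{k: np.asarray(v) for k, v in rows.items()},
        )

    truth = GroundTruth(
        feet=truth_feet, trial_effects=eff, stride_s=stride, stance_fractions=sfs
    )
    return TrialSimulation(left=recordings["left"], right=recordings["right"], truth=truth)


def _complement(start: float, stop: float,
                intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Sub-intervals of [start, stop) not covered by any of ``intervals``."""
    edges = [start, stop]
    for a, b in intervals:
        for t in (a, b):
            if start < t < stop:
                edges.append(t)
    edges = sorted(set(edges))
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        if not any(a <= mid < b for a, b in intervals):
            out.append((lo, hi))
    return out


def simulate_condition(config: SimulationConfig) -> list[TrialSimulation]:
    """Simulate all trials of one condition.

    Identical config + seed give bit-identical output; each trial draws from
    a deterministic child stream of the config seed.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    return [_simulate_trial(config, np.random.default_rng(c)) for c in children]


def simulate_parameter_table(
    subject_sd: float,
    error_sd: float,
    n_subjects: int,
    k_trials: int,
    seed: int | np.random.Generator = 0,
    mu: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Draws from the two-way mixed-effects model y_ij = μ + s_i + e_ij.

    Returns the n × k measurement matrix together with the closed-form
    population ICC(3,k) = σ_s² / (σ_s² + σ_e²/k) for recovery testing.
    """
    if subject_sd < 0 or error_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_subjects < 2 or k_trials < 2:
        raise ValueError("need n_subjects ≥ 2 and k_trials ≥ 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = rng.normal(0.0, subject_sd, size=(n_subjects, 1))
    e = rng.normal(0.0, error_sd, size=(n_subjects, k_trials))
    y = mu + s + e
    var_s, var_e = subject_sd**2, error_sd**2
    denom = var_s + var_e / k_trials
    icc = var_s / denom if denom > 0 else float("nan")
    return y, icc


# ---------------------------------------------------------------------------
# Disk output (used by the CLI `simulate` subcommand)
# ---------------------------------------------------------------------------


def write_simulation(trials: list[TrialSimulation], out_dir: str | Path,
                     condition_name: str) -> list[Path]:
    """Write per-trial per-foot recording CSVs plus a ground-truth JSON."""
    from .io import write_recording  # local import keeps module load light

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for t, trial in enumerate(trials, start=1):
        for foot in FOOT_SIDES:
            p = out_dir / f"{condition_name}_trial{t}_{foot}.csv"
            write_recording(trial.recording(foot), p)
            written.append(p)
        truth_path = out_dir / f"{condition_name}_trial{t}_truth.json"
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(_truth_to_jsonable(trial.truth), fh, indent=1)
        written.append(truth_path)
    return written


def _truth_to_jsonable(truth: GroundTruth) -> dict:
    return {
        "stride_s": truth.stride_s,
        "stance_fractions": truth.stance_fractions,
        "trial_effects": truth.trial_effects,
        "feet": {
            foot: {k: np.asarray(v).tolist() for k, v in dataclasses.asdict(ft).items()}
            for foot, ft in truth.feet.items()
        },
    }
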