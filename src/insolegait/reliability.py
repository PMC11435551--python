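"""Repeatability and responsiveness statistics for repeated gait tests.

For a parameter measured over many gait cycles in each of n repeated walk
tests (trials) of the same condition:

* SEM  = sqrt( (1/n) Σ_i σ_i² ), with σ_i² the sample variance across the
  cycles of trial i — the test–retest measurement noise in parameter units;
* SEM% = 100 · SEM / mean;
* MDD95 = 1.96 · √2 · SEM — the smallest between-session change
  distinguishable from measurement noise at 95 % confidence;
* ICC(3,k) = (BMS − EMS) / BMS — average-measures consistency intraclass
  correlation from the two-way (rows × trials) ANOVA mean squares, in the
  Shrout–Fleiss nomenclature;
* ES = (x̄_asym − x̄_without) / σ_without — responsiveness of the parameter
  to a belt-speed-induced gait asymmetry, signed.

The force signal gets a functional analogue: the SEM is computed at each of
the 101 stance-normalized grid instants and then averaged.

Aggregation follows the reporting conventions of test–retest tables: per
parameter the smallest and largest cell across feet are shown, the MDD row
uses the larger of the two feet's SEMs, and the pooled induced-asymmetry
column uses the maximum SEM over all asymmetric conditions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    FOOT_SIDES,
    PARAMETER_COLUMNS,
    ConditionDataset,
    NormalizedForceCurve,
    ReliabilityReport,
)

logger = logging.getLogger("insolegait")

#: 1.96·√2, the MDD95/SEM ratio
MDD95_FACTOR = 1.96 * math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SemInputs:
    """Per-trial variances (across cycles within each trial) and the mean."""

    trial_variances: tuple[float, ...]
    mean: float

    def __post_init__(self) -> None:
        if len(self.trial_variances) < 2:
            raise ValueError("SEM needs at least 2 trials")
        if any(v < 0 for v in self.trial_variances):
            raise ValueError("variances must be non-negative")


def sem(inputs: SemInputs) -> float:
    """Standard error of measurement: √(mean of per-trial variances)."""
    return math.sqrt(float(np.mean(inputs.trial_variances)))


def sem_percent(sem_value: float, mean: float) -> float:
    """SEM as a percentage of the parameter mean."""
    if mean == 0:
        raise ZeroDivisionError("SEM% is undefined for a zero mean")
    return 100.0 * sem_value / mean


def mdd95(sem_value: float) -> float:
    """Minimum detectable difference at 95 % confidence: 1.96·√2·SEM."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    return MDD95_FACTOR * sem_value


def curve_sem(trials_of_curves: list[list[NormalizedForceCurve]]) -> float:
    """SEM of the stance-normalized force signal.

    At each grid instant, the per-trial variance is taken across that trial's
    cycles and fed through the SEM formula; the per-instant SEMs are then
    averaged over the grid.
    """
    per_trial_var = []
    for i, curves in enumerate(trials_of_curves):
        if len(curves) < 2:
            raise ValueError(f"trial {i} has fewer than 2 cycles; cannot form a variance")
        stack = np.vstack([c.values for c in curves])  # cycles × grid
        per_trial_var.append(stack.var(axis=0, ddof=1))
    V = np.vstack(per_trial_var)  # trials × grid
    sem_per_instant = np.sqrt(V.mean(axis=0))
    return float(sem_per_instant.mean())


@dataclass(frozen=True)
class EffectSizeInputs:
    """Means under and without induced asymmetry, and the no-asymmetry SD."""

    mean_asym: float
    mean_without: float
    sd_without: float

    def __post_init__(self) -> None:
        if not self.sd_without > 0:
            raise ValueError("sd_without must be positive")


def effect_size(inputs: EffectSizeInputs) -> float:
    """Signed standardized mean difference (x̄_asym − x̄_without)/σ_without."""
    return (inputs.mean_asym - inputs.mean_without) / inputs.sd_without


# ---------------------------------------------------------------------------
# ICC(3,k)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaDecomposition:
    """Two-way ANOVA mean squares underlying ICC(3,k)."""

    bms: float  # between-rows (subjects) mean square
    ems: float  # residual mean square
    k: int      # trials (columns)
    n_subjects: int

    def __post_init__(self) -> None:
        if self.bms < 0 or self.ems < 0:
            raise ValueError("mean squares must be non-negative")
        if self.n_subjects < 2 or self.k < 2:
            raise ValueError("need at least 2 subjects and 2 trials")


def anova_decompose(measurements: np.ndarray) -> AnovaDecomposition:
    """Two-way (rows × columns) ANOVA sums of squares for a complete matrix."""
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("measurements must be an (n ≥ 2) × (k ≥ 2) matrix")
    if np.isnan(X).any():
        X = X[~np.isnan(X).any(axis=1)]  # listwise deletion
        if X.shape[0] < 2:
            raise ValueError("fewer than 2 complete rows after listwise deletion")
    n, k = X.shape
    grand = X.mean()
    ss_rows = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    return AnovaDecomposition(
        bms=float(ss_rows / (n - 1)),
        ems=float(ss_err / ((n - 1) * (k - 1))),
        k=k,
        n_subjects=n,
    )


def icc_3k(measurements: np.ndarray, max_missing_fraction: float = 0.1) -> float:
    """Average-measures consistency ICC from a subjects × trials matrix.

    ICC(3,k) = (BMS − EMS)/BMS; rows with missing cells are deleted listwise,
    and more than ``max_missing_fraction`` incomplete rows is an error.
    """
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2:
        raise ValueError("measurements must be 2-D")
    incomplete = np.isnan(X).any(axis=1).mean() if X.size else 0.0
    if incomplete > max_missing_fraction:
        raise ValueError(
            f"{incomplete:.0%} of rows are incomplete "
            f"(limit {max_missing_fraction:.0%})"
        )
    dec = anova_decompose(X)
    if dec.bms == 0:
        raise ZeroDivisionError("ICC(3,k) undefined: between-subjects mean square is 0")
    return (dec.bms - dec.ems) / dec.bms


# ---------------------------------------------------------------------------
# Classification bins
# ---------------------------------------------------------------------------

# Boundaries are closed on the lower edge of the higher category.
_ICC_BINS = ((0.80, "very good"), (0.60, "good"), (0.40, "moderate"))
_ES_BINS = ((1.2, "very large"), (0.8, "large"), (0.5, "moderate"), (0.2, "small"))


def classify_icc(value: float) -> str:
    """Bin an ICC: very good > 0.80 > good > 0.60 > moderate > 0.40 > poor."""
    if not np.isfinite(value):
        raise ValueError("ICC must be finite")
    for lo, label in _ICC_BINS:
        if value >= lo:
            return label
    return "poor"


def classify_es(value: float) -> str:
    """Bin an effect size by magnitude: very large ≥ 1.2 > large ≥ 0.8 >
    moderate ≥ 0.5 > small ≥ 0.2 > very small."""
    if not np.isfinite(value):
        raise ValueError("ES must be finite")
    mag = abs(value)
    for lo, label in _ES_BINS:
        if mag >= lo:
            return label
    return "very small"


# ---------------------------------------------------------------------------
# Aggregated report
# ---------------------------------------------------------------------------

OVERGROUND = "TDM6-SYM-GROUND"
TREADMILL_SYM = "TDM6-SYM-MGAIT"
_PAIR_BASELINES = {"O-TA": OVERGROUND, "T-TA": TREADMILL_SYM}


def _is_asym(name: str) -> bool:
    return "ASYM" in name


def condition_cell_stats(dataset: ConditionDataset, parameter: str, foot: str) -> dict:
    """mean/sd/SEM/SEM%/MDD/MDD%/ICC for one (parameter, foot, condition)."""
    pooled = dataset.pooled_values(parameter, foot)
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    if parameter == "mean_force_single_stance" and all(
        t.force_curves.get(foot) for t in dataset.trials
    ):
        # force reliability is assessed on the stance-normalized curve,
        # instant by instant, then averaged over the grid
        sem_value = curve_sem([t.force_curves[foot] for t in dataset.trials])
    else:
        variances = tuple(
            float(np.var([getattr(c, parameter) for c in t.cycles[foot]], ddof=1))
            for t in dataset.trials
        )
        sem_value = sem(SemInputs(trial_variances=variances, mean=mean))
    matrix = dataset.parameter_matrix(parameter, foot)
    try:
        icc = icc_3k(matrix)
        icc_label = classify_icc(icc)
    except (ValueError, ZeroDivisionError):
        icc, icc_label = float("nan"), "undefined"
    mdd = mdd95(sem_value)
    return {
        "parameter": parameter,
        "foot": foot,
        "condition": dataset.condition_name,
        "n_cycles": int(pooled.size),
        "mean": mean,
        "sd": sd,
        "sem": sem_value,
        "sem_percent": sem_percent(sem_value, mean),
        "mdd95": mdd,
        "mdd95_percent": 100.0 * mdd / mean,
        "icc_3k": icc,
        "icc_label": icc_label,
    }


def aggregate_report(datasets: list[ConditionDataset]) -> ReliabilityReport:
    """Build the full reliability report from per-condition datasets.

    ``cells``: one row per (parameter, foot, condition). ``effect_sizes``:
    one row per (parameter, foot, baseline pair, asymmetric condition), the
    asymmetric mean standardized by the baseline condition's pooled SD.
    ``summary``: per parameter and condition group, min/max across feet
    (and across asymmetric conditions for the pooled group), with the MDD
    derived from the max-across-feet SEM. ``es_census``: percentage of all
    ES cases per magnitude bin.
    """
    by_name = {d.condition_name: d for d in datasets}
    cell_rows = [
        condition_cell_stats(d, p, f)
        for d in datasets
        for p in PARAMETER_COLUMNS
        for f in FOOT_SIDES
    ]
    cells = pd.DataFrame(cell_rows)

    # --- effect sizes: asym condition vs each available baseline, per foot
    es_rows = []
    asym_names = [n for n in by_name if _is_asym(n)]
    duration_params = [p for p in PARAMETER_COLUMNS if p != "mean_force_single_stance"]
    for pair, baseline in _PAIR_BASELINES.items():
        if baseline not in by_name:
            continue
        base = by_name[baseline]
        for asym_name in sorted(asym_names):
            for p in duration_params:  # force curves are excluded from ES by design
                for f in FOOT_SIDES:
                    base_vals = base.pooled_values(p, f)
                    asym_vals = by_name[asym_name].pooled_values(p, f)
                    es = effect_size(
                        EffectSizeInputs(
                            mean_asym=float(asym_vals.mean()),
                            mean_without=float(base_vals.mean()),
                            sd_without=float(base_vals.std(ddof=1)),
                        )
                    )
                    es_rows.append(
                        {
                            "parameter": p,
                            "foot": f,
                            "pair": pair,
                            "asym_condition": asym_name,
                            "effect_size": es,
                            "es_label": classify_es(es),
                        }
                    )
    effect_sizes = pd.DataFrame(
        es_rows,
        columns=["parameter", "foot", "pair", "asym_condition", "effect_size", "es_label"],
    )

    # --- Table-style min/max summary per parameter × condition group
    groups: dict[str, list[str]] = {}
    for name in by_name:
        groups[name if not _is_asym(name) else "TDM6-ASYM-MGAIT"] = sorted(
            [n for n in by_name if (_is_asym(n) if _is_asym(name) else n == name)]
        )
    summary_rows = []
    for group, members in groups.items():
        sub = cells[cells.condition.isin(members)]
        for p in PARAMETER_COLUMNS:
            s = sub[sub.parameter == p]
            if s.empty:
                continue
            max_sem = float(s["sem"].max())  # max across feet (and asym conditions)
            mean_of_max = float(s.loc[s["sem"].idxmax(), "mean"])
            mdd = mdd95(max_sem)
            summary_rows.append(
                {
                    "parameter": p,
                    "condition_group": group,
                    "mean_min": float(s["mean"].min()),
                    "mean_max": float(s["mean"].max()),
                    "sem_min": float(s["sem"].min()),
                    "sem_max": max_sem,
                    "mdd95": mdd,
                    "mdd95_percent": 100.0 * mdd / mean_of_max,
                    "icc_min": float(s.icc_3k.min()),
                    "icc_max": float(s.icc_3k.max()),
                }
            )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "parameter", "condition_group", "mean_min", "mean_max", "sem_min",
            "sem_max", "mdd95", "mdd95_percent", "icc_min", "icc_max",
        ],
    )

    # --- ES census over all parameter × pair × foot × asym-condition cases
    if len(effect_sizes):
        counts = effect_sizes.groupby(["pair", "es_label"]).size()
        census_rows = []
        for pair in sorted(effect_sizes.pair.unique()):
            total = int(counts[pair].sum())
            for label in ("very large", "large", "moderate", "small", "very small"):
                n = int(counts.get((pair, label), 0))
                census_rows.append(
                    {"pair": pair, "es_label": label, "n_cases": n,
                     "percent": 100.0 * n / total}
                )
        es_census = pd.DataFrame(census_rows)
    else:
        es_census = pd.DataFrame(columns=["pair", "es_label", "n_cases", "percent"])

    return ReliabilityReport(
        cells=cells, effect_sizes=effect_sizes, summary=summary, es_census=es_census
    )
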