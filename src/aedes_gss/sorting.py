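"""COPAS sort-speed calibration and sort planning.

A COPAS large-particle flow cytometer sorts first-instar larvae by
fluorescence.  Pushing the instrument faster loses target larvae (recovery
falls) and eventually lets non-target larvae leak through (contamination
rises).  Empirically, male recovery versus sorting speed is well described by
a degree-two polynomial and contamination by a linear trend; this module fits
those calibration curves by ordinary least squares, predicts recovery and
contamination at a given speed, converts reservoir larval concentration to
speed, plans sorts (expected male yield, run duration, larvae required for a
male target), and simulates a sort stochastically.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationPoint",
    "SortingCurve",
    "SortPlan",
    "SortOutcome",
    "ExtrapolationWarning",
    "fit_curves",
    "predict",
    "concentration_to_speed",
    "plan_sort",
    "simulate_sort",
    "read_calibration_csv",
]

# One printed anchor ties reservoir concentration to event rate:
# 200 larvae/mL in the reservoir corresponds to 60 larvae/s.
_SPEED_PER_CONCENTRATION = 60.0 / 200.0


class ExtrapolationWarning(UserWarning):
    """Raised when predicting outside the calibrated speed range."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration measurement: recovery/contamination fractions at a speed."""

    speed: float  # larvae per second
    recovery: float  # fraction in [0, 1]
    contamination: float  # fraction in [0, 1]
    replicate_id: int = 0

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        for name in ("recovery", "contamination"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")


@dataclass(frozen=True)
class SortingCurve:
    """Fitted calibration: quadratic recovery and linear contamination in speed.

    ``recovery_coeffs`` are (a0, a1, a2) for a0 + a1*v + a2*v**2;
    ``contamination_coeffs`` are (b0, b1) for b0 + b1*v.  Predictions are
    clipped to [0, 1] because polynomial fits can stray outside physical
    bounds at the range edges.
    """

    recovery_coeffs: tuple[float, float, float]
    contamination_coeffs: tuple[float, float]
    r2_recovery: float
    r2_contamination: float
    speed_range: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.speed_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid calibrated speed range")


def _ols_poly(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    """Least-squares polynomial fit; returns ascending coeffs and r²."""
    if len(np.unique(x)) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct speeds for a degree-{degree} fit"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-24 else 0.0)
    return coeffs, r2


def fit_curves(
    points: Sequence[CalibrationPoint], on_means: bool = True
) -> SortingCurve:
    """Fit the recovery (quadratic) and contamination (linear) calibration.

    By default replicates are averaged per speed before fitting; set
    ``on_means=False`` to fit on replicate-level points.
    """
    if not points:
        raise ValueError("no calibration points")
    df = pd.DataFrame(
        {
            "speed": [p.speed for p in points],
            "recovery": [p.recovery for p in points],
            "contamination": [p.contamination for p in points],
        }
    )
    if on_means:
        df = df.groupby("speed", as_index=False).mean()
    x = df["speed"].to_numpy(dtype=float)
    rec_coeffs, r2_rec = _ols_poly(x, df["recovery"].to_numpy(dtype=float), 2)
    con_coeffs, r2_con = _ols_poly(x, df["contamination"].to_numpy(dtype=float), 1)
    speeds = [p.speed for p in points]
    return SortingCurve(
        recovery_coeffs=tuple(float(c) for c in rec_coeffs),
        contamination_coeffs=tuple(float(c) for c in con_coeffs),
        r2_recovery=float(r2_rec),
        r2_contamination=float(r2_con),
        speed_range=(min(speeds), max(speeds)),
    )


def predict(curve: SortingCurve, speed: float) -> tuple[float, float]:
    """Predicted (recovery, contamination) fractions at a sorting speed.

    Warns when extrapolating outside the calibrated range; errors on
    negative speed.  Values are clipped to [0, 1].
    """
    if speed < 0:
        raise ValueError("speed must be nonnegative")
    lo, hi = curve.speed_range
    if not lo <= speed <= hi:
        warnings.warn(
            f"speed {speed} outside calibrated range [{lo}, {hi}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    rec = float(np.polynomial.polynomial.polyval(speed, curve.recovery_coeffs))
    con = float(np.polynomial.polynomial.polyval(speed, curve.contamination_coeffs))
    return float(np.clip(rec, 0.0, 1.0)), float(np.clip(con, 0.0, 1.0))


def concentration_to_speed(concentration: float) -> float:
    """Map reservoir concentration (larvae/mL) to sorting speed (larvae/s).

    Proportional through the single measured anchor 200 larvae/mL ↔ 60
    larvae/s; the flow rate is assumed concentration-independent.
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    return concentration * _SPEED_PER_CONCENTRATION


@dataclass(frozen=True)
class SortPlan:
    """Deterministic plan for one sorting run."""

    speed: float  # larvae/s
    sex_ratio: float  # male fraction of the input
    recovery: float  # fraction of males recovered
    larvae_total: int  # larvae passing through the machine
    expected_males: int  # floor of the expectation
    duration_s: float  # larvae_total / speed

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "speed_larvae_per_s": self.speed,
                "sex_ratio": self.sex_ratio,
                "recovery": self.recovery,
                "larvae_total": self.larvae_total,
                "expected_males": self.expected_males,
                "duration_s": self.duration_s,
                "duration_min": self.duration_min,
            },
            indent=2,
        )

    def __str__(self) -> str:
        return (
            f"Sort {self.larvae_total:,} larvae at {self.speed:g} larvae/s "
            f"(sex ratio {self.sex_ratio:g}, recovery {self.recovery:.1%}): "
            f"~{self.expected_males:,} males in {self.duration_min:.1f} min"
        )


def plan_sort(
    speed: float,
    sex_ratio: float,
    recovery: float,
    reservoir_size: int | None = None,
    male_target: int | None = None,
) -> SortPlan:
    """Plan a sort from either a reservoir load or a male yield target.

    Planning from a reservoir: expected males = reservoir × sex_ratio ×
    recovery, rounded down.  Planning from a male target: larvae needed =
    ceil(target / (sex_ratio × recovery)) — resource planning never
    under-provisions.  Duration is larvae/speed in either case.
    """
    if (reservoir_size is None) == (male_target is None):
        raise ValueError("give exactly one of reservoir_size or male_target")
    if speed <= 0:
        raise ValueError("speed must be positive")
    if not 0.0 <= sex_ratio <= 1.0 or not 0.0 <= recovery <= 1.0:
        raise ValueError("sex_ratio and recovery must be fractions in [0, 1]")
    if reservoir_size is not None:
        if reservoir_size < 0:
            raise ValueError("reservoir_size must be nonnegative")
        larvae = int(reservoir_size)
        # tolerance guards the floor/ceil against binary representation error
        males = math.floor(larvae * sex_ratio * recovery + 1e-9)
    else:
        if male_target <= 0:
            raise ValueError("male_target must be positive")
        if sex_ratio * recovery == 0:
            raise ValueError("cannot reach a male target with zero sex_ratio or recovery")
        larvae = math.ceil(male_target / (sex_ratio * recovery) - 1e-9)
        males = int(male_target)
    return SortPlan(
        speed=float(speed),
        sex_ratio=float(sex_ratio),
        recovery=float(recovery),
        larvae_total=larvae,
        expected_males=males,
        duration_s=larvae / speed,
    )


@dataclass(frozen=True)
class SortOutcome:
    """Stochastic result of one sort: kept/rejected counts per true class."""

    kept: Mapping[str, int]
    rejected: Mapping[str, int]
    gate: str

    def __post_init__(self):
        for cls in self.kept:
            if self.kept[cls] < 0 or self.rejected.get(cls, 0) < 0:
                raise ValueError("counts must be nonnegative")

    @property
    def realized_recovery(self) -> float:
        n_in = self.kept[self.gate] + self.rejected[self.gate]
        return self.kept[self.gate] / n_in if n_in else float("nan")

    @property
    def realized_contamination(self) -> float:
        total_kept = sum(self.kept.values())
        leaked = total_kept - self.kept[self.gate]
        return leaked / total_kept if total_kept else 0.0


def simulate_sort(
    cohort: Mapping[str, int],
    speed: float,
    curve: SortingCurve,
    gate: str,
    seed: int,
) -> SortOutcome:
    """Simulate a sort: target-class larvae are kept with the predicted
    recovery, every other class leaks through with the predicted
    contamination; draws are binomial and seeded.

    The speed must lie inside the calibrated range (hard error here, unlike
    the extrapolation warning of :func:`predict`).
    """
    lo, hi = curve.speed_range
    if not lo <= speed <= hi:
        raise ValueError(f"speed {speed} outside calibrated range [{lo}, {hi}]")
    if gate not in cohort:
        raise ValueError(f"gate class {gate!r} not present in cohort")
    recovery, contamination = predict(curve, speed)
    rng = np.random.default_rng(seed)
    kept, rejected = {}, {}
    for cls in sorted(cohort):
        n = int(cohort[cls])
        if n < 0:
            raise ValueError("cohort counts must be nonnegative")
        p = recovery if cls == gate else contamination
        k = int(rng.binomial(n, p)) if n > 0 else 0
        kept[cls] = k
        rejected[cls] = n - k
    return SortOutcome(kept=kept, rejected=rejected, gate=gate)


def read_calibration_csv(path: str | Path) -> list[CalibrationPoint]:
    """Read a calibration table CSV with columns speed, recovery,
    contamination, replicate."""
    df = pd.read_csv(path, comment="#")
    required = {"speed", "recovery", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    reps = df["replicate"] if "replicate" in df.columns else pd.Series(0, index=df.index)
    return [
        CalibrationPoint(
            speed=float(r.speed),
            recovery=float(r.recovery),
            contamination=float(r.contamination),
            replicate_id=int(rep),
        )
        for (_, r), rep in zip(df.iterrows(), reps)
    ]
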