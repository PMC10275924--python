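"""Seeded synthetic-data generators with known ground truth.

Everything the other modules consume can be generated here: COPAS event
tables with genotype-conditional fluorescence clouds (including an
"intermediate fluorescence" nuisance class of dead or low-expressing larvae
and size outliers such as debris), noisy recovery-versus-speed calibration
replicates, and rare-event recombination screening counts.  All generators
are pure functions of (config, seed).

Fluorescence clouds are log-normal: the sorter works in log arbitrary units
and class separations are naturally expressed in log10 SD units.  The default
presets are well separated (gates and clustering should be near-perfect); a
``hard`` preset with overlapping clouds exists for stress testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import ScreeningRecord
from .sorting import CalibrationPoint

__all__ = [
    "ClassCloud",
    "EventGeneratorConfig",
    "CalibrationGeneratorConfig",
    "crossing_scheme_event_config",
    "single_strain_event_config",
    "default_gates",
    "printed_calibration_coeffs",
    "gen_copas_events",
    "gen_calibration_data",
    "gen_screening_data",
]


@dataclass(frozen=True)
class ClassCloud:
    """Log10-normal cloud parameters for one phenotype class."""

    mean_log_green: float
    mean_log_red: float
    sd_log_green: float = 0.15
    sd_log_red: float = 0.15
    mean_log_tof: float = 2.0
    mean_log_ext: float = 2.2
    sd_log_tof: float = 0.08
    sd_log_ext: float = 0.08

    def __post_init__(self):
        for name in ("sd_log_green", "sd_log_red", "sd_log_tof", "sd_log_ext"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EventGeneratorConfig:
    """Mixture of labelled clouds plus a uniform size-outlier component.

    ``proportions`` (class name → mass) and ``outlier_proportion`` must sum
    to 1.  Outliers emulate debris/doublets: fluorescence drawn from a random
    class but size drawn uniformly over an inflated log range, so they are
    caught by the size filters.
    """

    clouds: Mapping[str, ClassCloud]
    proportions: Mapping[str, float]
    outlier_proportion: float = 0.0
    outlier_log_size_range: tuple[float, float] = (1.0, 3.5)

    def __post_init__(self):
        if set(self.proportions) != set(self.clouds):
            raise ValueError("proportions and clouds must have identical class names")
        total = sum(self.proportions.values()) + self.outlier_proportion
        if any(p < 0 for p in self.proportions.values()) or self.outlier_proportion < 0:
            raise ValueError("proportions must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions (incl. outliers) sum to {total}, not 1")


# Default cloud placement (log10 arbitrary units).  Negative autofluorescence
# sits near 1.0; a single marker copy near 3.0; two copies ~0.3 log10 brighter
# (≈2x signal); the intermediate nuisance class midway between negative and
# hemizygous, with a wider spread.
_NEGATIVE = ClassCloud(mean_log_green=1.0, mean_log_red=1.0)
_HEMIZYGOUS = ClassCloud(mean_log_green=3.0, mean_log_red=1.2)
_HOMOZYGOUS = ClassCloud(mean_log_green=3.3, mean_log_red=1.2)
_INTERMEDIATE = ClassCloud(
    mean_log_green=2.0, mean_log_red=1.1, sd_log_green=0.25, sd_log_red=0.25
)


def crossing_scheme_event_config(
    intermediate_proportion: float = 0.0,
    outlier_proportion: float = 0.0,
    hard: bool = False,
) -> EventGeneratorConfig:
    """Preset emulating a crossing-scheme sort: a 1:1 mixture of
    non-fluorescent males and hemizygous-bright females, optionally with an
    intermediate nuisance class and size outliers.

    The ``hard`` variant narrows the separation to ~2 SD for stress tests.
    """
    clouds = {
        "negative": _NEGATIVE,
        "hemizygous": replace(_HEMIZYGOUS, mean_log_green=1.6) if hard else _HEMIZYGOUS,
    }
    rest = 1.0 - intermediate_proportion - outlier_proportion
    proportions = {"negative": rest / 2.0, "hemizygous": rest / 2.0}
    if intermediate_proportion > 0:
        clouds["intermediate"] = _INTERMEDIATE
        proportions["intermediate"] = intermediate_proportion
    return EventGeneratorConfig(
        clouds=clouds, proportions=proportions, outlier_proportion=outlier_proportion
    )


def single_strain_event_config(
    intermediate_proportion: float = 0.02, outlier_proportion: float = 0.0
) -> EventGeneratorConfig:
    """Preset emulating a GSS strain sort: hemizygous males, homozygous
    (brighter) females, and an intermediate nuisance class."""
    rest = 1.0 - intermediate_proportion - outlier_proportion
    clouds = {
        "hemizygous": _HEMIZYGOUS,
        "homozygous": _HOMOZYGOUS,
        "intermediate": _INTERMEDIATE,
    }
    proportions = {
        "hemizygous": rest / 2.0,
        "homozygous": rest / 2.0,
        "intermediate": intermediate_proportion,
    }
    return EventGeneratorConfig(
        clouds=clouds, proportions=proportions, outlier_proportion=outlier_proportion
    )


def default_gates() -> dict[str, dict[str, tuple[float, float]]]:
    """Rectangular log10 gates matching the default presets.

    The intermediate cloud (green ≈ 2.0) falls between the negative and
    bright gates and is therefore deliberately ungated.
    """
    return {
        "negative": {"FLU_GREEN": (0.0, 1.6)},
        "bright": {"FLU_GREEN": (2.5, 4.5)},
    }


def gen_copas_events(
    cfg: EventGeneratorConfig, n: int, seed: int = 0
) -> pd.DataFrame:
    """Generate ``n`` labelled COPAS events from the configured mixture.

    Returns a table with columns TOF, EXT, FLU_GREEN, FLU_RED (linear
    arbitrary units) and LABEL (true class, ``"outlier"`` for the debris
    component).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    names = sorted(cfg.clouds)
    probs = np.array([cfg.proportions[c] for c in names] + [cfg.outlier_proportion])
    counts = rng.multinomial(n, probs) if n > 0 else np.zeros(len(probs), dtype=int)
    frames = []
    for name, k in zip(names + ["outlier"], counts):
        if k == 0:
            continue
        cloud = cfg.clouds[name] if name != "outlier" else cfg.clouds[rng.choice(names)]
        g = rng.normal(cloud.mean_log_green, cloud.sd_log_green, k)
        r = rng.normal(cloud.mean_log_red, cloud.sd_log_red, k)
        if name == "outlier":
            lo, hi = cfg.outlier_log_size_range
            tof = rng.uniform(lo, hi, k)
            ext = rng.uniform(lo, hi, k)
        else:
            tof = rng.normal(cloud.mean_log_tof, cloud.sd_log_tof, k)
            ext = rng.normal(cloud.mean_log_ext, cloud.sd_log_ext, k)
        frames.append(
            pd.DataFrame(
                {
                    "TOF": 10.0**tof,
                    "EXT": 10.0**ext,
                    "FLU_GREEN": 10.0**g,
                    "FLU_RED": 10.0**r,
                    "LABEL": name,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            {c: pd.Series(dtype=float) for c in ("TOF", "EXT", "FLU_GREEN", "FLU_RED")}
            | {"LABEL": pd.Series(dtype=str)}
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def printed_calibration_coeffs() -> tuple[tuple[float, float, float], tuple[float, float]]:
    """Quadratic recovery / linear contamination coefficients interpolating
    the three measured mean calibration points (fractions vs larvae/s):
    (6, 0.915), (60, 0.696) and (300, 0.269), with zero contamination."""
    x = np.array([6.0, 60.0, 300.0])
    y = np.array([0.915, 0.696, 0.269])
    rec = tuple(float(c) for c in np.polynomial.polynomial.polyfit(x, y, 2))
    return rec, (0.0, 0.0)


@dataclass(frozen=True)
class CalibrationGeneratorConfig:
    """Truth + noise model for calibration replicates."""

    recovery_coeffs: tuple[float, float, float]
    contamination_coeffs: tuple[float, float] = (0.0, 0.0)
    speeds: tuple[float, ...] = (6.0, 60.0, 300.0)
    replicates: int = 3
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(s <= 0 for s in self.speeds):
            raise ValueError("speeds must be positive")


def gen_calibration_data(
    cfg: CalibrationGeneratorConfig, seed: int = 0
) -> list[CalibrationPoint]:
    """Generate noisy calibration replicates from known true curves.

    Recovery = quadratic(speed) + Gaussian noise, truncated to [0, 1];
    contamination = linear(speed) + noise, truncated below at 0.
    """
    rng = np.random.default_rng(seed)
    points = []
    for speed in cfg.speeds:
        true_rec = float(np.polynomial.polynomial.polyval(speed, cfg.recovery_coeffs))
        true_con = float(
            np.polynomial.polynomial.polyval(speed, cfg.contamination_coeffs)
        )
        for rep in range(cfg.replicates):
            rec = true_rec + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0)
            con = true_con + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0)
            points.append(
                CalibrationPoint(
                    speed=speed,
                    recovery=float(np.clip(rec, 0.0, 1.0)),
                    contamination=float(np.clip(con, 0.0, 1.0)),
                    replicate_id=rep,
                )
            )
    return points


def gen_screening_data(
    true_rate: float, n_screened: int, replicates: int, seed: int = 0
) -> list[ScreeningRecord]:
    """Binomial recombinant counts for replicate screening campaigns."""
    if not 0.0 <= true_rate <= 1.0:
        raise ValueError("true_rate must be a probability")
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_screened, true_rate, size=replicates)
    return [ScreeningRecord(n_screened=n_screened, n_recombinant=int(k)) for k in counts]
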