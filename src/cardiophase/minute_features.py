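"""Per-minute phase-plane features and per-phase regression.

The smoothed discriminant series is averaged per minute of the test (beats
are placed in time by cumulative RR) and paired with the per-minute relative
pulse amplitude ``(S − D)/S`` of the arterial blood pressure.  Each phase's
point cloud ``(rel_pulse, mean_disc)`` is then fitted by ordinary least
squares; the slope coefficient is the per-person summary statistic carried
into the cohort model, with Spearman's rank correlation as the goodness
measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFitError, InsufficientDataError, ValidationError
from .pmld_core import PHASES, BeatSeries, DiscriminantSeries

MS_PER_MINUTE = 60_000.0

#: unit string of phase-plane slope coefficients, kept opaque as printed
SLOPE_UNITS = "W·ms"

__all__ = [
    "SLOPE_UNITS",
    "PressureSeries",
    "RegressionResult",
    "beat_minutes",
    "minute_average",
    "relative_pulse_amplitude",
    "build_feature_table",
    "fit_phase_plane",
]


@dataclass(frozen=True)
class PressureSeries:
    """Once-per-minute systolic/diastolic arterial pressure readings, mmHg."""

    minute: np.ndarray
    systolic: np.ndarray
    diastolic: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        minute = np.asarray(self.minute, dtype=int)
        sys_ = np.asarray(self.systolic, dtype=float)
        dia = np.asarray(self.diastolic, dtype=float)
        phase = np.asarray(self.phase, dtype=object)
        if not (len(minute) == len(sys_) == len(dia) == len(phase)):
            raise ValidationError("pressure columns must have equal length")
        bad = set(phase) - set(PHASES)
        if bad:
            raise ValidationError(f"unknown phase labels: {sorted(bad)}")
        if len(minute):
            if minute[0] != 1 or np.any(np.diff(minute) != 1):
                raise ValidationError("minutes must be contiguous and start at 1")
            is_rec = phase == "recovery"
            if is_rec.any() and not is_rec[np.argmax(is_rec):].all():
                raise ValidationError("load minutes must precede recovery minutes")
        for m, s, d in zip(minute, sys_, dia):
            if not (s > d > 0):
                raise ValidationError(
                    f"minute {m}: require systolic > diastolic > 0, "
                    f"got S={s}, D={d}"
                )
        object.__setattr__(self, "minute", minute)
        object.__setattr__(self, "systolic", sys_)
        object.__setattr__(self, "diastolic", dia)
        object.__setattr__(self, "phase", phase)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PressureSeries":
        required = {"minute", "systolic_mmHg", "diastolic_mmHg", "phase"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"pressure table missing columns: {sorted(missing)}")
        return cls(
            minute=df["minute"].to_numpy(dtype=int),
            systolic=df["systolic_mmHg"].to_numpy(dtype=float),
            diastolic=df["diastolic_mmHg"].to_numpy(dtype=float),
            phase=df["phase"].to_numpy(dtype=object),
        )

    @classmethod
    def from_csv(cls, path) -> "PressureSeries":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute": self.minute,
                "systolic_mmHg": self.systolic,
                "diastolic_mmHg": self.diastolic,
                "phase": self.phase,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of mean discriminant on relative pulse amplitude for one phase."""

    slope: float
    intercept: float
    spearman_rho: float
    phase: str
    n_points: int
    units: str = SLOPE_UNITS


def beat_minutes(beats: BeatSeries) -> np.ndarray:
    """1-based minute index of each beat from cumulative RR time.

    Beat *j* belongs to minute ``ceil(t_j / 60 s)`` where ``t_j`` is the
    cumulative RR time at the end of beat *j* — the only timestamp derivable
    from interval data.
    """
    return np.ceil(beats.time_ms / MS_PER_MINUTE).astype(int)


def minute_average(disc: DiscriminantSeries, beats: BeatSeries) -> pd.DataFrame:
    """Arithmetic mean of ``s_k`` per minute of the test.

    Returns a frame with columns ``minute, mean_disc, phase``; minutes with
    no smoothed beats are absent.  The phase of a minute is the phase of the
    majority of its smoothed beats (ties go to load, which precedes).
    """
    if len(disc) == 0:
        return pd.DataFrame({"minute": [], "mean_disc": [], "phase": []}).astype(
            {"minute": int, "mean_disc": float, "phase": object}
        )
    if np.any(disc.k_index > beats.n):
        raise ValidationError("discriminant series is not aligned to the beat series")
    minutes = beat_minutes(beats)[disc.k_index - 1]
    df = pd.DataFrame({"minute": minutes, "s": disc.s, "phase": disc.phase})
    out = df.groupby("minute", as_index=False).agg(
        mean_disc=("s", "mean"),
        phase=("phase", lambda p: "load" if (p == "load").sum() * 2 >= len(p) else "recovery"),
    )
    return out


def relative_pulse_amplitude(pressures: PressureSeries) -> pd.DataFrame:
    """Relative pulse amplitude ``(S − D)/S`` per minute (dimensionless)."""
    rel = (pressures.systolic - pressures.diastolic) / pressures.systolic
    return pd.DataFrame(
        {"minute": pressures.minute, "rel_pulse": rel, "phase": pressures.phase}
    )


def build_feature_table(
    disc: DiscriminantSeries, beats: BeatSeries, pressures: PressureSeries
) -> pd.DataFrame:
    """Phase-plane point per minute: ``minute, rel_pulse, mean_disc, phase``.

    Minutes missing either the discriminant average or the pressure reading
    are dropped; the phase label of the pressure reading is authoritative.
    """
    disc_part = minute_average(disc, beats).drop(columns="phase")
    press_part = relative_pulse_amplitude(pressures)
    merged = press_part.merge(disc_part, on="minute", how="inner")
    return merged[["minute", "rel_pulse", "mean_disc", "phase"]]


def fit_phase_plane(features: pd.DataFrame, phase: str) -> RegressionResult:
    """OLS slope of ``mean_disc`` on ``rel_pulse`` over one phase's minutes.

    Spearman's rank correlation (midranks for ties) of the same point set is
    attached as the goodness-of-fit measure.
    """
    if phase not in PHASES:
        raise ValidationError(f"phase must be one of {PHASES}, got {phase!r}")
    sel = features[features["phase"] == phase]
    if len(sel) < 2:
        raise InsufficientDataError(
            f"need at least 2 minutes in phase {phase!r}, got {len(sel)}"
        )
    x = sel["rel_pulse"].to_numpy(dtype=float)
    y = sel["mean_disc"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError(
            f"relative pulse amplitude has zero variance in phase {phase!r}"
        )
    fit = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic if np.ptp(y) > 0 else 0.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        spearman_rho=float(rho),
        phase=phase,
        n_points=int(len(sel)),
    )
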