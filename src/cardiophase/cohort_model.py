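"""Gaussian cohort models, normality check and the one-sigma classifier range.

Per-person phase-plane slope coefficients are grouped by ABP status
(normal vs high) and test phase (load vs recovery).  Each group is
summarised by a Gaussian ``N(μ, σ²)`` (sample mean, n−1 standard
deviation), checked for normality with the Anderson–Darling test, and the
two load groups define the one-sigma *variation interval*

    [μ_high − σ_high,  μ_normal + σ_normal]

used to classify new candidates.  A classification is statistically
meaningful only when the separation condition ``|μ₂ − μ₁| ≥ min(σ₁, σ₂)``
holds — for the study cohorts it holds during load but not recovery, which
is why only load-phase intervals feed the classifier.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError
from .pmld_core import PHASES

GROUPS = ("normal_abp", "high_abp")

__all__ = [
    "GROUPS",
    "CohortDistribution",
    "VariationInterval",
    "SeparationReport",
    "CohortModel",
    "round_half_away",
    "fit_gaussian",
    "anderson_darling",
    "variation_interval",
    "separation_condition",
    "fit_cohorts",
    "load_reference_slopes",
]


def round_half_away(x: float, ndigits: int = 4) -> float:
    """Round half away from zero (reporting convention for tabulated values)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def load_reference_slopes() -> pd.DataFrame:
    """Packaged per-person slope coefficients of the two study cohorts.

    9 persons with normal ABP and 10 with high ABP, one load and one
    recovery slope each, with Spearman goodness values; columns
    ``person_id, group, phase, slope, spearman_rho``.
    """
    frames = []
    for name in ("table1_normal_abp.csv", "table2_high_abp.csv"):
        with resources.files("cardiophase.data").joinpath(name).open() as fh:
            frames.append(pd.read_csv(fh))
    return pd.concat(frames, ignore_index=True)


def fit_gaussian(slopes) -> tuple[float, float]:
    """Sample mean and n−1 standard deviation of a slope set.

    A zero standard deviation (all slopes identical) is flagged with a
    warning rather than an error: the fit exists but is degenerate.
    """
    slopes = np.asarray(slopes, dtype=float)
    if len(slopes) < 2:
        raise InsufficientDataError(
            f"need at least 2 slopes to fit a Gaussian, got {len(slopes)}"
        )
    mu = float(np.mean(slopes))
    sigma = float(np.std(slopes, ddof=1))
    if sigma == 0.0:
        warnings.warn("degenerate Gaussian fit: zero standard deviation", stacklevel=2)
    return mu, sigma


def anderson_darling(slopes) -> tuple[float, float]:
    """Anderson–Darling normality test with estimated parameters.

    Returns the uncorrected A² statistic and a p-value from Stephens'
    piecewise-exponential approximation applied to the small-sample
    corrected statistic ``A²* = A²·(1 + 0.75/n + 2.25/n²)``.
    """
    slopes = np.asarray(slopes, dtype=float)
    n = len(slopes)
    if n < 4:
        raise InsufficientDataError(
            f"Anderson–Darling test needs at least 4 observations, got {n}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        a2 = float(stats.anderson(slopes, dist="norm").statistic)
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s >= 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s >= 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return a2, float(min(max(p, 0.0), 1.0))


@dataclass(frozen=True)
class CohortDistribution:
    """Gaussian summary of one group/phase slope set."""

    mu: float
    sigma: float
    n: int
    ad_stat: float | None = None
    ad_p: float | None = None

    @property
    def one_sigma_interval(self) -> tuple[float, float]:
        return (self.mu - self.sigma, self.mu + self.sigma)

    @classmethod
    def from_slopes(cls, slopes) -> "CohortDistribution":
        slopes = np.asarray(slopes, dtype=float)
        mu, sigma = fit_gaussian(slopes)
        ad_stat = ad_p = None
        if len(slopes) >= 4 and sigma > 0:
            ad_stat, ad_p = anderson_darling(slopes)
        return cls(mu=mu, sigma=sigma, n=len(slopes), ad_stat=ad_stat, ad_p=ad_p)


@dataclass(frozen=True)
class VariationInterval:
    """One-sigma classification range built from two group distributions."""

    left: float
    right: float
    phase: str
    degenerate: bool = False

    @property
    def width(self) -> float:
        return self.right - self.left


@dataclass(frozen=True)
class SeparationReport:
    """Statistical separation of two group means against their spread."""

    mean_diff: float
    min_sigma: float
    satisfied: bool


def variation_interval(
    dist_normal: CohortDistribution, dist_high: CohortDistribution, phase: str = "load"
) -> VariationInterval:
    """``[μ_high − σ_high, μ_normal + σ_normal]`` for one phase.

    A non-positive width marks the interval degenerate (warning attached as
    a flag rather than raised, so diagnostics can still be reported).
    """
    left = dist_high.mu - dist_high.sigma
    right = dist_normal.mu + dist_normal.sigma
    degenerate = not left < right
    if degenerate:
        warnings.warn(
            f"variation interval is degenerate: left={left:.4f} >= right={right:.4f}",
            stacklevel=2,
        )
    return VariationInterval(left=left, right=right, phase=phase, degenerate=degenerate)


def separation_condition(
    d1: CohortDistribution, d2: CohortDistribution
) -> SeparationReport:
    """Check ``|μ₂ − μ₁| ≥ min(σ₁, σ₂)`` for two fitted groups."""
    mean_diff = abs(d2.mu - d1.mu)
    min_sigma = min(d1.sigma, d2.sigma)
    return SeparationReport(
        mean_diff=mean_diff, min_sigma=min_sigma, satisfied=mean_diff >= min_sigma
    )


@dataclass(frozen=True)
class CohortModel:
    """Fitted distributions, intervals and separation verdicts for all phases."""

    distributions: dict  # (group, phase) -> CohortDistribution
    intervals: dict  # phase -> VariationInterval
    separation: dict  # phase -> SeparationReport

    def distribution(self, group: str, phase: str) -> CohortDistribution:
        return self.distributions[(group, phase)]

    def classification_interval(self, phase: str = "load") -> VariationInterval:
        return self.intervals[phase]

    def to_dict(self) -> dict:
        return {
            "distributions": {
                f"{g}/{p}": asdict(d) for (g, p), d in self.distributions.items()
            },
            "intervals": {p: asdict(iv) for p, iv in self.intervals.items()},
            "separation": {p: asdict(r) for p, r in self.separation.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "CohortModel":
        dists = {}
        for key, d in payload["distributions"].items():
            group, phase = key.split("/")
            dists[(group, phase)] = CohortDistribution(**d)
        intervals = {p: VariationInterval(**iv) for p, iv in payload["intervals"].items()}
        separation = {p: SeparationReport(**r) for p, r in payload["separation"].items()}
        return cls(distributions=dists, intervals=intervals, separation=separation)

    @classmethod
    def from_json(cls, path) -> "CohortModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_cohorts(slope_table: pd.DataFrame) -> CohortModel:
    """Fit all four group/phase distributions and derive per-phase intervals.

    ``slope_table`` follows the ``person_id, group, phase, slope`` schema
    (``spearman_rho`` optional).  Duplicate (person, phase) rows are dropped
    with a warning; both groups must be present in every phase.
    """
    required = {"person_id", "group", "phase", "slope"}
    missing = required - set(slope_table.columns)
    if missing:
        raise ValidationError(f"slope table missing columns: {sorted(missing)}")
    dup = slope_table.duplicated(subset=["person_id", "phase"])
    if dup.any():
        warnings.warn(
            f"dropping {int(dup.sum())} duplicated (person_id, phase) rows",
            stacklevel=2,
        )
        slope_table = slope_table[~dup]
    distributions = {}
    for phase in PHASES:
        for group in GROUPS:
            sel = slope_table[
                (slope_table["group"] == group) & (slope_table["phase"] == phase)
            ]["slope"]
            if sel.empty:
                raise ValidationError(f"no slopes for group={group}, phase={phase}")
            distributions[(group, phase)] = CohortDistribution.from_slopes(sel)
    intervals = {
        phase: variation_interval(
            distributions[("normal_abp", phase)],
            distributions[("high_abp", phase)],
            phase=phase,
        )
        for phase in PHASES
    }
    separation = {
        phase: separation_condition(
            distributions[("normal_abp", phase)], distributions[("high_abp", phase)]
        )
        for phase in PHASES
    }
    return CohortModel(
        distributions=distributions, intervals=intervals, separation=separation
    )
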