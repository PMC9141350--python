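"""Synthetic graded bicycle stress-test recordings.

No public raw recordings exist for this kind of study, so end-to-end tests
run on synthetic persons that reproduce the statistical structure the
analysis assumes:

* heart rate climbs from rest toward peak in two-minute stages (mirroring
  50 W ergometer increments), then returns exponentially during recovery;
* the JT interval shortens toward ~160 ms at peak load, lagging the heart
  rate early in the load (repolarisation adapts more slowly than rate),
  which makes the normalised RR and JT series desynchronise mid-load — the
  smoothed discriminant rises in the first minutes, collapses towards zero
  at maximum load, and recovers afterwards;
* beat-to-beat variability is autocorrelated (AR(1)) and shrinks as load
  rises, as real heart-rate variability does;
* systolic pressure rises with load (steeper for the high-ABP profile)
  while diastolic pressure stays near rest; per-minute readings carry
  rounded measurement noise.

Cohort generation can target a Gaussian distribution of phase-plane load
slopes: each person's pressure-ramp steepness is calibrated against the
discriminant trend of their own simulated beats so that the induced
ordinary-least-squares slope matches a slope drawn from the target
distribution (the OLS slope is exact under linear reparametrisation of the
x axis, so only the per-minute relative-pulse increment needs solving).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np

from .exceptions import ValidationError
from .minute_features import PressureSeries, minute_average
from .pmld_core import BeatSeries, SmoothingConfig, discriminant_profile

__all__ = [
    "PersonProfile",
    "SyntheticRecording",
    "normal_profile",
    "high_profile",
    "generate_person",
    "generate_cohort",
]

#: AR(1) coefficient of the beat-to-beat noise
AR_COEFF = 0.3
#: fraction of rest-level variability retained at peak load
NOISE_FLOOR = 0.1
#: JT noise as a fraction of the RR noise level
JT_NOISE_RATIO = 0.4
#: hard physiological ceilings for exercise blood pressure, mmHg
MAX_SYSTOLIC = 250.0
MAX_DIASTOLIC = 110.0


@dataclass(frozen=True)
class PersonProfile:
    """Generator parameters for one synthetic stress-test subject.

    ``jt_lag_amp`` and ``jt_lag_pow`` shape how far the JT shortening lags
    the heart-rate progress ``p``: the normalised JT trend follows
    ``h(p) = p − amp·p·(1−p)^pow``, so the lag (and hence the discriminant
    hump) peaks early in the load and vanishes at rest and at peak.
    ``target_slope`` switches the pressure ramp to calibrated mode (see
    module docstring); when ``None`` the ramp interpolates the profile's
    rest/peak pressures directly.
    """

    group: str = "normal_abp"
    rest_hr: float = 70.0  # beats/min
    peak_hr: float = 165.0
    rest_jt: float = 320.0  # ms
    peak_jt: float = 160.0  # healthy JT shortens to ~160 ms at peak load
    rest_sys: float = 115.0  # mmHg
    rest_dia: float = 80.0
    peak_sys: float = 185.0
    peak_dia: float = 85.0
    load_minutes: int = 14
    recovery_minutes: int = 8
    hrv_noise_sd: float = 35.0  # ms, rest-level beat-to-beat variability
    pressure_noise_sd: float = 0.3  # mmHg, reading jitter around the ramp
    recovery_tau: float = 2.5  # minutes
    jt_lag_amp: float = 1.35
    jt_lag_pow: float = 2.0
    stage_minutes: float = 2.0
    jt_lag_recovery_ratio: float = 0.15
    target_slope: float | None = None
    recovery_target_slope: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("normal_abp", "high_abp"):
            raise ValidationError(f"unknown group {self.group!r}")
        if not self.peak_hr > self.rest_hr > 0:
            raise ValidationError("require peak_hr > rest_hr > 0")
        if not self.rest_jt > self.peak_jt > 0:
            raise ValidationError("require rest_jt > peak_jt > 0")
        if not self.peak_sys > self.rest_sys > self.rest_dia > 0:
            raise ValidationError("require peak_sys > rest_sys > rest_dia > 0")
        if self.load_minutes < 2 or self.recovery_minutes < 1:
            raise ValidationError("need >= 2 load minutes and >= 1 recovery minute")
        if self.hrv_noise_sd < 0 or self.pressure_noise_sd < 0:
            raise ValidationError("noise levels must be non-negative")
        if self.recovery_tau <= 0:
            raise ValidationError("recovery_tau must be positive")


@dataclass(frozen=True)
class SyntheticRecording:
    """Beats + pressures of one synthetic person, with generator truth."""

    beats: BeatSeries
    pressures: PressureSeries
    truth: dict


def normal_profile(**overrides) -> PersonProfile:
    """Default profile of a normal-ABP subject (115/80 mmHg at rest)."""
    return PersonProfile(**overrides)


def high_profile(**overrides) -> PersonProfile:
    """Default profile of a high-ABP subject (150/90 mmHg at rest).

    Steeper systolic rise, no pronounced early reorganisation: the JT lag
    hump is pushed earlier and the discriminant declines from the start.
    """
    base = dict(
        group="high_abp",
        rest_hr=75.0,
        peak_hr=160.0,
        rest_sys=150.0,
        rest_dia=90.0,
        peak_sys=235.0,
        peak_dia=100.0,
        jt_lag_amp=2.6,
        jt_lag_pow=3.0,
    )
    base.update(overrides)
    return PersonProfile(**base)


def _hr_progress(t_min: np.ndarray | float, profile: PersonProfile) -> np.ndarray:
    """Heart-rate progress p(t) in [0, 1]: staged ramp, then exponential return."""
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    load_end = float(profile.load_minutes)
    n_stages = max(1, math.ceil(load_end / profile.stage_minutes))
    p = np.empty_like(t)
    in_load = t <= load_end
    tl = t[in_load]
    stage = np.floor(tl / profile.stage_minutes)
    # HR climbs during the first half of each two-minute stage, then plateaus
    frac = np.clip((tl - stage * profile.stage_minutes) / (profile.stage_minutes / 2), 0.0, 1.0)
    p[in_load] = np.clip((stage + frac) / n_stages, 0.0, 1.0)
    tr = t[~in_load]
    p[~in_load] = np.exp(-(tr - load_end) / profile.recovery_tau)
    return p


def _jt_lag(p: np.ndarray, profile: PersonProfile) -> np.ndarray:
    """Lag of the JT progress behind the HR progress p."""
    return profile.jt_lag_amp * p * (1.0 - p) ** profile.jt_lag_pow


def _simulate_beats(profile: PersonProfile, rng: np.random.Generator) -> BeatSeries:
    total_ms = (profile.load_minutes + profile.recovery_minutes) * 60_000.0
    load_ms = profile.load_minutes * 60_000.0
    rest_rr = 60_000.0 / profile.rest_hr
    peak_rr = 60_000.0 / profile.peak_hr
    jt_span = profile.peak_jt - profile.rest_jt  # negative

    rr_list: list[float] = []
    jt_list: list[float] = []
    phase_list: list[str] = []
    t = 0.0
    e_rr = 0.0
    e_jt = 0.0
    ar_innov = math.sqrt(1.0 - AR_COEFF**2)
    while t < total_ms:
        p = float(_hr_progress(t / 60_000.0, profile)[0])
        hr = profile.rest_hr + (profile.peak_hr - profile.rest_hr) * p
        rr_trend = 60_000.0 / hr
        # HRV declines steadily over the load (reaching its floor exactly at
        # peak load, where the complexity collapse bottoms out) and rebounds
        # with the exponential heart-rate return during recovery
        if t <= load_ms:
            taper = NOISE_FLOOR + (1.0 - NOISE_FLOOR) * (1.0 - t / load_ms) ** 0.75
        else:
            taper = NOISE_FLOOR + (1.0 - NOISE_FLOOR) * (1.0 - p)
        sd_rr = profile.hrv_noise_sd * taper
        # repolarisation's own variability is suppressed harder under
        # sympathetic drive; the squared taper also keeps the JT extremes
        # trend-dominated, so its normalised minimum stays at peak load
        sd_jt = JT_NOISE_RATIO * profile.hrv_noise_sd * taper**2
        e_rr = AR_COEFF * e_rr + ar_innov * sd_rr * rng.standard_normal()
        e_jt = AR_COEFF * e_jt + ar_innov * sd_jt * rng.standard_normal()
        rr = max(rr_trend + e_rr, 0.4 * peak_rr)
        # JT is rate-dependent beat by beat: affine in the realised RR, so
        # min-max normalisation (which is affine-invariant) maps the shared
        # component of both series onto each other exactly.  What remains in
        # the normalised difference is the controlled desync: the
        # repolarisation lag (weaker on the way down) plus JT's own
        # tapered variability.
        rel = (rr - peak_rr) / (rest_rr - peak_rr)  # ~1 at rest, ~0 at peak
        lag_scale = 1.0 if t <= load_ms else profile.jt_lag_recovery_ratio
        # the lag keeps JT ABOVE its steady-state rate relation (hysteresis:
        # repolarisation shortens more slowly than the rate rises), so both
        # series still attain their extremes at rest and at peak load
        jt = (
            profile.peak_jt
            - jt_span * rel
            - jt_span * lag_scale * _jt_lag(np.asarray([p]), profile)[0]
            + e_jt
        )
        jt = max(jt, 0.5 * profile.peak_jt)
        t += rr
        rr_list.append(rr)
        jt_list.append(jt)
        phase_list.append("load" if t <= load_ms else "recovery")
    # interval data cannot resolve sub-beat phase boundaries; guard against a
    # pathological all-load record when recovery_minutes is tiny
    if "recovery" not in phase_list:
        phase_list[-1] = "recovery"
    return BeatSeries(
        rr=np.array(rr_list), jt=np.array(jt_list), phase=np.array(phase_list, dtype=object)
    )


def _minute_disc(beats: BeatSeries, profile: PersonProfile):
    """Per-minute mean discriminant of a recording, via the real pipeline."""
    disc = discriminant_profile(beats, SmoothingConfig(), normalize=True)
    return minute_average(disc, beats)


def _calibrated_coefficient(
    basis: np.ndarray, disc: np.ndarray, eps: np.ndarray, target: float
) -> float:
    """Coefficient c so that the OLS slope of ``disc`` on
    ``const + c·basis + eps`` equals ``target``.

    Solving cov(d, rp)/var(rp) = T for c with realised noise eps gives the
    quadratic  T·Vm·c² + (2T·Cme − Cdm)·c + (T·Ve − Cde) = 0, where m is
    the centred basis.
    """
    m = basis - basis.mean()
    d = disc - disc.mean()
    e = eps - eps.mean()
    vm = float(m @ m)
    cme = float(m @ e)
    ve = float(e @ e)
    cdm = float(d @ m)
    cde = float(d @ e)
    naive = cdm / (target * vm) if target * vm != 0 else 0.01
    a, b, cc = target * vm, 2.0 * target * cme - cdm, target * ve - cde
    disc_q = b * b - 4.0 * a * cc
    if a == 0 or disc_q < 0:
        c = naive
    else:
        roots = ((-b + math.sqrt(disc_q)) / (2 * a), (-b - math.sqrt(disc_q)) / (2 * a))
        positive = [r for r in roots if r > 0]
        c = min(positive, key=lambda r: abs(r - naive)) if positive else naive
    if not np.isfinite(c) or c <= 0:
        c = abs(naive) if naive not in (0.0,) and np.isfinite(naive) else 0.01
    return float(c)


def _simulate_pressures(
    profile: PersonProfile, beats: BeatSeries, rng: np.random.Generator
) -> tuple[PressureSeries, dict]:
    n_min = profile.load_minutes + profile.recovery_minutes
    minutes = np.arange(1, n_min + 1)
    mid = minutes - 0.5
    p = _hr_progress(mid, profile)
    phase = np.where(minutes <= profile.load_minutes, "load", "recovery").astype(object)
    rp0 = (profile.rest_sys - profile.rest_dia) / profile.rest_sys
    dia = profile.rest_dia + (profile.peak_dia - profile.rest_dia) * p
    # propagate the mmHg reading noise onto the relative pulse amplitude
    sd_rp = profile.pressure_noise_sd * math.hypot(
        profile.rest_dia / profile.rest_sys**2, 1.0 / profile.rest_sys
    )
    eps = sd_rp * rng.standard_normal(n_min)
    truth: dict = {}
    is_load = minutes <= profile.load_minutes
    rp_peak = (profile.peak_sys - profile.peak_dia) / profile.peak_sys

    dia_mmhg = np.clip(np.round(dia), 40.0, MAX_DIASTOLIC)

    def realise(rp_path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Integer-mmHg readings from a relative-pulse path, and the
        quantised path the analysis pipeline will actually see."""
        rp_c = np.clip(rp_path, 0.05, 0.85)
        sys_mmhg = np.clip(np.round(dia_mmhg / (1.0 - rp_c)), dia_mmhg + 5.0, MAX_SYSTOLIC)
        return sys_mmhg, (sys_mmhg - dia_mmhg) / sys_mmhg

    def refine(coeff, basis, anchor, d_vals, mask, target):
        """Fixed-point polish of a path coefficient against the quantised
        readings: regression on rounded mmHg, then multiplicative update,
        with a deterministic grid fallback when the analytic root is off."""
        from scipy.stats import linregress

        def achieved_slope(cand):
            path = rp.copy()
            path[mask] = anchor + cand * (basis - basis[0]) + eps[mask]
            _, rp_q = realise(path)
            return linregress(rp_q[mask][: len(d_vals)], d_vals).slope

        best, best_err = coeff, math.inf

        def polish(cur, rounds):
            nonlocal best, best_err
            for _ in range(rounds):
                achieved = achieved_slope(cur)
                err = abs(achieved - target)
                if err < best_err:
                    best, best_err = cur, err
                if not np.isfinite(achieved) or achieved * target <= 0:
                    cur *= 2.0  # strengthen the ramp until the sign resolves
                    continue
                cur *= float(np.clip(target / achieved, 0.5, 2.0))

        polish(coeff, 8)
        if best_err > 0.01 * abs(target) + 0.004:
            grid = np.geomspace(5e-4, 6e-2, 60)
            errors = [abs(achieved_slope(g) - target) for g in grid]
            polish(float(grid[int(np.argmin(errors))]), 6)
        return best

    rp = rp0 + (rp_peak - rp0) * p + eps  # uncalibrated default path
    if profile.target_slope is not None or profile.recovery_target_slope is not None:
        table = _minute_disc(beats, profile)
        rp_end = rp_peak
        if profile.target_slope is not None:
            load_tab = table[table["minute"] <= profile.load_minutes]
            m_load = load_tab["minute"].to_numpy(dtype=float)
            d_load = load_tab["mean_disc"].to_numpy(dtype=float)
            c = _calibrated_coefficient(
                m_load, d_load, eps[m_load.astype(int) - 1], profile.target_slope
            )
            c = refine(c, minutes[is_load].astype(float), rp0, d_load, is_load,
                       profile.target_slope)
            rp[is_load] = rp0 + c * (minutes[is_load] - 1) + eps[is_load]
            rp_end = rp0 + c * (profile.load_minutes - 1)
            rp[~is_load] = rp0 + (rp_end - rp0) * p[~is_load] + eps[~is_load]
            truth["rel_pulse_increment"] = c
        if profile.recovery_target_slope is not None:
            rec_tab = table[table["minute"] > profile.load_minutes]
            m_rec = rec_tab["minute"].to_numpy(dtype=int)
            d_rec = rec_tab["mean_disc"].to_numpy(dtype=float)
            if len(m_rec) >= 2:
                g_full = p[~is_load]  # exponential decay basis during recovery
                b = _calibrated_coefficient(
                    p[m_rec - 1], d_rec, eps[m_rec - 1], profile.recovery_target_slope
                )
                b = refine(b, g_full, rp_end, d_rec, ~is_load,
                           profile.recovery_target_slope)
                rp[~is_load] = rp_end + b * (g_full - g_full[0]) + eps[~is_load]
                truth["recovery_rel_pulse_coeff"] = b
    sys_mmhg, _ = realise(rp)
    return (
        PressureSeries(minute=minutes, systolic=sys_mmhg, diastolic=dia_mmhg, phase=phase),
        truth,
    )


def generate_person(profile: PersonProfile) -> SyntheticRecording:
    """Simulate one person's stress test; deterministic given ``profile.seed``."""
    rng = np.random.default_rng(profile.seed)
    beats = _simulate_beats(profile, rng)
    pressures, extra_truth = _simulate_pressures(profile, beats, rng)
    truth = {"profile": asdict(profile), **extra_truth}
    return SyntheticRecording(beats=beats, pressures=pressures, truth=truth)


def _draw_targets(
    rng: np.random.Generator,
    n: int,
    dist: tuple[float, float],
    cap: float,
    moment_match: bool,
) -> np.ndarray:
    """Slope targets from N(mean, sd²), capped above for physical pressure bounds.

    With ``moment_match`` the draw is a shuffled stratified-quantile sample
    whose sample mean and n−1 standard deviation equal the targets exactly,
    so cohort-level verdicts depend on the pipeline rather than on the luck
    of a small-sample draw.
    """
    from scipy.stats import norm

    mean, sd = dist
    if moment_match:
        z = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        z = (z - z.mean()) / np.std(z, ddof=1)
        rng.shuffle(z)
        targets = mean + sd * z
    else:
        targets = rng.normal(mean, sd, size=n)
    return np.minimum(targets, cap)


def generate_cohort(
    n: int,
    profile_template: PersonProfile,
    slope_target_distribution: tuple[float, float] | None = None,
    recovery_target_distribution: tuple[float, float] | None = None,
    seed: int = 0,
    moment_match: bool = False,
) -> list[SyntheticRecording]:
    """Generate ``n`` persons by jittering a profile template.

    When ``slope_target_distribution = (mean, sd)`` is given, each person's
    pressure ramp is calibrated so the induced load-phase phase-plane slope
    matches a draw from ``N(mean, sd²)`` (draws are capped at −0.15 so the
    relative pulse amplitude stays within physical bounds); analogously for
    ``recovery_target_distribution`` and the recovery pressure decay (cap
    −0.02).  A single master seed spawns independent per-person substreams.
    """
    if n < 2:
        raise ValidationError(f"a cohort needs at least 2 persons, got n={n}")
    master = np.random.default_rng(seed)
    load_targets = rec_targets = None
    if slope_target_distribution is not None:
        load_targets = _draw_targets(
            master, n, slope_target_distribution, -0.15, moment_match
        )
    if recovery_target_distribution is not None:
        rec_targets = _draw_targets(
            master, n, recovery_target_distribution, -0.02, moment_match
        )
    recordings = []
    for i in range(n):
        person_seed = int(master.integers(0, 2**31 - 1))
        jitter = master.normal
        target = float(load_targets[i]) if load_targets is not None else None
        # steeper pressure-dominant responders desynchronise harder: scale
        # the repolarisation-lag amplitude with the relative target
        # steepness so their discriminant carries a resolvable trend
        amp_scale = 1.0
        if target is not None and slope_target_distribution is not None:
            mean_t = abs(slope_target_distribution[0])
            amp_scale = float(np.clip(abs(target) / max(mean_t, 1e-6), 1.0, 2.2))
        profile = replace(
            profile_template,
            seed=person_seed,
            target_slope=target,
            recovery_target_slope=(
                float(rec_targets[i]) if rec_targets is not None else None
            ),
            rest_hr=max(45.0, profile_template.rest_hr + jitter(0, 3.0)),
            peak_hr=max(
                profile_template.rest_hr + 60.0, profile_template.peak_hr + jitter(0, 5.0)
            ),
            rest_jt=profile_template.rest_jt + jitter(0, 12.0),
            peak_jt=max(120.0, profile_template.peak_jt + jitter(0, 6.0)),
            recovery_tau=max(1.0, profile_template.recovery_tau + jitter(0, 0.4)),
            jt_lag_amp=min(
                4.2,
                max(0.5, profile_template.jt_lag_amp + jitter(0, 0.15)) * amp_scale,
            ),
        )
        recordings.append(generate_person(profile))
    return recordings
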