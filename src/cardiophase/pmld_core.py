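"""Perfect matrices of Lagrange differences and the discriminant map.

Two synchronously recorded cardiac interval series — RR (series *x*) and JT
(series *y*) — are analysed beat by beat.  For a centre beat ``k`` and a lag
``delta`` the six elements ``x_{k−δ}, x_k, x_{k+δ}, y_{k−δ}, y_k, y_{k+δ}``
are arranged into the first (β = 1) perfect matrix of Lagrange differences

    [[ x_k,              x_{k+δ} − y_{k+δ} ],
     [ x_{k−δ} − y_{k−δ},  y_k             ]]

which is mapped to a scalar by its discriminant
``(a11 − a22)² + 4·a12·a21``.  The discriminant collapses towards zero when
the variability of the two series becomes similar — the signature of the
loss of complexity at peak exercise load.  Internal (over lags δ = 1…Ri)
and external (over a window of radius Re around the centre beat) smoothing
turns the matrix sequence into a single smoothed scalar series ``s_k``.

Beat indices ``k`` follow the 1-based convention of the defining formulas
throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SeriesTooShortError, ValidationError

PHASES = ("load", "recovery")

__all__ = [
    "PHASES",
    "BeatSeries",
    "LagrangeMatrix",
    "SmoothingConfig",
    "DiscriminantSeries",
    "build_pmld",
    "discriminant",
    "smooth_series",
    "normalize_unit_interval",
    "discriminant_profile",
]


@dataclass(frozen=True)
class BeatSeries:
    """Per-beat RR/JT intervals with a load/recovery phase tag.

    Parameters
    ----------
    rr : array-like
        RR intervals per heartbeat, ms (series *x*).
    jt : array-like
        JT intervals per heartbeat, ms (series *y*).
    phase : array-like of str
        Per-beat label, ``"load"`` or ``"recovery"``; the load block must be
        contiguous and precede the contiguous recovery block.
    """

    rr: np.ndarray
    jt: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr, dtype=float)
        jt = np.asarray(self.jt, dtype=float)
        phase = np.asarray(self.phase, dtype=object)
        if rr.ndim != 1 or jt.ndim != 1 or phase.ndim != 1:
            raise ValidationError("rr, jt and phase must be one-dimensional")
        if not (len(rr) == len(jt) == len(phase)):
            raise ValidationError(
                f"length mismatch: rr={len(rr)}, jt={len(jt)}, phase={len(phase)}"
            )
        if len(rr) and (not np.all(np.isfinite(rr)) or not np.all(np.isfinite(jt))):
            raise ValidationError("rr and jt must be finite")
        if np.any(rr <= 0) or np.any(jt <= 0):
            raise ValidationError("rr and jt intervals must be positive")
        bad = set(phase) - set(PHASES)
        if bad:
            raise ValidationError(f"unknown phase labels: {sorted(bad)}")
        is_rec = phase == "recovery"
        if is_rec.any() and not is_rec[np.argmax(is_rec):].all():
            raise ValidationError(
                "phase labels must form one contiguous load block "
                "followed by one contiguous recovery block"
            )
        object.__setattr__(self, "rr", rr)
        object.__setattr__(self, "jt", jt)
        object.__setattr__(self, "phase", phase)

    @property
    def n(self) -> int:
        return len(self.rr)

    @property
    def time_ms(self) -> np.ndarray:
        """Cumulative time at the end of each beat, ms from test start."""
        return np.cumsum(self.rr)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BeatSeries":
        required = {"rr_ms", "jt_ms", "phase"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"beat table missing columns: {sorted(missing)}")
        return cls(
            rr=df["rr_ms"].to_numpy(dtype=float),
            jt=df["jt_ms"].to_numpy(dtype=float),
            phase=df["phase"].to_numpy(dtype=object),
        )

    @classmethod
    def from_csv(cls, path) -> "BeatSeries":
        """Read ``beat_index, rr_ms, jt_ms, phase`` CSV (header required)."""
        # round_trip parsing keeps write->read->write bit-identical
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_index": np.arange(1, self.n + 1),
                "rr_ms": self.rr,
                "jt_ms": self.jt,
                "phase": self.phase,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LagrangeMatrix:
    """A 2x2 perfect matrix of Lagrange differences (β = 1 arrangement)."""

    a11: float
    a12: float
    a21: float
    a22: float
    delta: int
    k: int
    beta: int = 1

    def as_array(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]], dtype=float)


@dataclass(frozen=True)
class SmoothingConfig:
    """Smoothing radii for the discriminant series.

    ``ri`` is the internal radius (the upper bound of the lag δ) and ``re``
    the external radius (beat window half-width).  The defaults ``ri=3,
    re=4, beta=1`` are the cohort-level optimum imported from the method's
    source literature and are kept fixed for all computations here.
    """

    ri: int = 3
    re: int = 4
    beta: int = 1

    def __post_init__(self) -> None:
        if self.ri < 1:
            raise ValidationError(f"internal radius ri must be >= 1, got {self.ri}")
        if self.re < 0:
            raise ValidationError(f"external radius re must be >= 0, got {self.re}")
        if self.beta != 1:
            raise NotImplementedError(
                f"only the beta=1 perfect matrix is implemented, got beta={self.beta}"
            )

    @property
    def min_beats(self) -> int:
        """Smallest series length that yields at least one smoothed value."""
        return 2 * (self.ri + self.re) + 1


@dataclass(frozen=True)
class DiscriminantSeries:
    """Smoothed discriminant values ``s_k`` with their centre-beat indices.

    ``k_index`` holds 1-based beat numbers ``k = (1+Ri+Re) … (n−Ri−Re)``;
    ``phase`` is inherited from the centre beat.
    """

    k_index: np.ndarray
    s: np.ndarray
    phase: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        k = np.asarray(self.k_index, dtype=int)
        s = np.asarray(self.s, dtype=float)
        if self.phase is None:
            phase = np.full(len(k), "load", dtype=object)
        else:
            phase = np.asarray(self.phase, dtype=object)
        if not (len(k) == len(s) == len(phase)):
            raise ValidationError("k_index, s and phase must have equal length")
        if len(s) and not np.all(np.isfinite(s)):
            raise ValidationError("smoothed values must be finite")
        object.__setattr__(self, "k_index", k)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "phase", phase)

    def __len__(self) -> int:
        return len(self.s)


def build_pmld(x, y, k: int, delta: int, beta: int = 1) -> LagrangeMatrix:
    """Construct the β=1 perfect matrix of Lagrange differences at beat *k*.

    Parameters
    ----------
    x, y : array-like
        The two synchronised series (RR and JT).
    k : int
        1-based centre beat index.
    delta : int
        Time lag in beats, ``delta >= 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValidationError(f"series lengths differ: {n} vs {len(y)}")
    if beta != 1:
        raise NotImplementedError(
            f"only the beta=1 perfect matrix is implemented, got beta={beta}"
        )
    if delta < 1:
        raise ValidationError(f"lag delta must be >= 1, got {delta}")
    if not (1 + delta <= k <= n - delta):
        raise ValidationError(
            f"centre index k={k} with delta={delta} outside admissible range "
            f"[{1 + delta}, {n - delta}] for n={n}"
        )
    i = k - 1  # 0-based
    return LagrangeMatrix(
        a11=x[i],
        a12=x[i + delta] - y[i + delta],
        a21=x[i - delta] - y[i - delta],
        a22=y[i],
        delta=delta,
        k=k,
        beta=1,
    )


def discriminant(m: LagrangeMatrix) -> float:
    """Discriminant map ``(a11 − a22)² + 4·a12·a21`` of a Lagrange matrix."""
    entries = (m.a11, m.a12, m.a21, m.a22)
    if not np.all(np.isfinite(entries)):
        raise ValidationError(f"matrix entries must be finite, got {entries}")
    return (m.a11 - m.a22) ** 2 + 4.0 * m.a12 * m.a21


def smooth_series(beats: BeatSeries, cfg: SmoothingConfig | None = None) -> DiscriminantSeries:
    """Internally and externally smoothed discriminant series ``s_k``.

    For each admissible centre beat ``k`` (1-based),

        s_k = 1 / (Ri·(2Re+1)) · Σ_{j=k−Re}^{k+Re} Σ_{δ=1}^{Ri} disc(L_{δ,j})

    where ``disc(L_{δ,j}) = (x_j − y_j)² + 4·(x−y)_{j+δ}·(x−y)_{j−δ}``.

    Raises
    ------
    SeriesTooShortError
        If ``n < 2·(Ri+Re) + 1``.
    """
    cfg = cfg or SmoothingConfig()
    n = beats.n
    if n < cfg.min_beats:
        raise SeriesTooShortError(
            f"series of {n} beats is too short for smoothing with ri={cfg.ri}, "
            f"re={cfg.re}; at least {cfg.min_beats} beats are required"
        )
    ri, re = cfg.ri, cfg.re
    u = beats.rr - beats.jt
    # disc(L_{δ,j}) depends on x and y only through u = x − y:
    #   (x_j − y_j)² + 4 u_{j+δ} u_{j−δ}
    # f[j] (0-based centre j in [ri, n-1-ri]) is the internal sum over δ.
    f = ri * u**2
    for delta in range(1, ri + 1):
        prod = u[2 * delta:] * u[: n - 2 * delta]  # centred at delta..n-1-delta
        f[delta: n - delta] += 4.0 * prod
    core = f[ri: n - ri]  # internal sums at admissible centres
    window = 2 * re + 1
    # moving sum of length `window` over the admissible centres
    ext = np.convolve(core, np.ones(window), mode="valid")
    s = ext / (ri * window)
    k_index = np.arange(1 + ri + re, n - ri - re + 1)
    return DiscriminantSeries(k_index=k_index, s=s, phase=beats.phase[k_index - 1])


def normalize_unit_interval(values: np.ndarray) -> np.ndarray:
    """Linearly rescale a series to [0, 1] over its full extent.

    Applied to RR and JT independently before matrix construction so that
    the discriminant is dimensionless and O(1) regardless of the native
    interval units; a constant series has no scale and is rejected.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise ValidationError("cannot normalise a constant series to [0, 1]")
    return (values - lo) / (hi - lo)


def discriminant_profile(
    beats: BeatSeries, cfg: SmoothingConfig | None = None, normalize: bool = True
) -> DiscriminantSeries:
    """Full per-person discriminant pipeline: normalise (optionally) then smooth.

    With ``normalize=True`` (the default used by the feature pipeline) both
    interval series are min–max rescaled to [0, 1] over the whole recording,
    which puts the smoothed discriminant on a dimensionless O(0–1) scale and
    makes its collapse towards zero at peak load directly visible.
    """
    if not normalize:
        return smooth_series(beats, cfg)
    scaled = BeatSeries(
        # same +eps shift on both series keeps positivity and leaves u = x − y
        # (hence every discriminant) unchanged
        rr=normalize_unit_interval(beats.rr) + 1e-9,
        jt=normalize_unit_interval(beats.jt) + 1e-9,
        phase=beats.phase,
    )
    return smooth_series(scaled, cfg)
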