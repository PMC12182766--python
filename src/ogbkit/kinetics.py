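"""Degassing kinetics: the 4-parameter logistic release model.

During the passive degassing stage, trapped gas escapes the granular bed
and the remaining liquid fraction (as % of the initial volume) falls
along an S-shaped curve

    f(t) = d + (c - d) / (1 + exp(-a (t - b)))

with ``d`` the upper asymptote (100 % before degassing starts), ``c`` the
plateau after degassing completes, ``b`` the semi-degassing time (the
inflection point, where exactly half the releasable volume has escaped:
f(b) = (c + d)/2), and ``a`` the release rate per minute.  ``d`` is fixed
at 100 % by default since the series is normalized to the initial volume;
it can be freed for non-normalized data.

Fitting is unweighted nonlinear least squares on all replicate points;
with balanced replicates this yields the same estimates as fitting the
per-time means.  Standard errors come from the Jacobian-based covariance
at the optimum.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .errors import DegenerateDataError, FitConvergenceError, ValidationError

__all__ = [
    "DegassingSeries",
    "LogisticModel",
    "ReplicateSummary",
    "logistic_value",
    "fit_degassing_curve",
    "r_squared",
    "summarize_replicates",
]


@dataclass(frozen=True)
class LogisticModel:
    """Fitted (or constructed) 4-parameter logistic release model."""

    a: float                     # release rate, per minute
    b: float                     # semi-degassing time, minutes
    c: float                     # plateau, % of initial volume
    d: float = 100.0             # upper asymptote, %
    se_a: Optional[float] = None
    se_b: Optional[float] = None
    se_c: Optional[float] = None
    se_d: Optional[float] = None
    r2: Optional[float] = None
    n_obs: Optional[int] = None
    d_fixed: bool = True

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.a, self.b, self.c, self.d)):
            raise ValidationError("logistic parameters must be finite")
        if self.a <= 0:
            raise ValidationError(f"release rate a must be positive, got {self.a}")
        # c == d is allowed (a degenerate flat curve, useful as a null model)
        if self.c > self.d:
            raise ValidationError(
                f"plateau c ({self.c}) must not exceed the upper asymptote d ({self.d})"
            )

    def __call__(self, t):
        return logistic_value(self, t)


@dataclass(frozen=True)
class DegassingSeries:
    """Replicate time series of remaining liquid, % of initial volume."""

    sample_id: str
    points: tuple  # of (t_min, pct, replicate)

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError(f"{self.sample_id}: empty degassing series")
        for t, pct, rep in self.points:
            if not (math.isfinite(t) and t >= 0):
                raise ValidationError(f"{self.sample_id}: time must be >= 0, got {t}")
            if not (0 < pct <= 110):
                raise ValidationError(
                    f"{self.sample_id}: pct must be in (0, 110], got {pct} at t={t}"
                )

    @classmethod
    def from_arrays(cls, sample_id, t, pct, replicate=None) -> "DegassingSeries":
        t = np.asarray(t, dtype=float)
        pct = np.asarray(pct, dtype=float)
        if replicate is None:
            replicate = np.ones(len(t), dtype=int)
        return cls(
            sample_id=sample_id,
            points=tuple((float(a), float(b), int(r)) for a, b, r in zip(t, pct, replicate)),
        )

    @property
    def t(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def pct(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def replicate(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    def n_distinct_times(self) -> int:
        return len(set(p[0] for p in self.points))


def logistic_value(model: LogisticModel, t):
    """Evaluate f(t) = d + (c-d)/(1+exp(-a(t-b))), overflow-safe.

    Uses the logistic sigmoid ``expit`` so large |a (t-b)| saturates
    cleanly at the asymptotes instead of overflowing.
    """
    t = np.asarray(t, dtype=float)
    out = model.d + (model.c - model.d) * expit(model.a * (t - model.b))
    return float(out) if out.ndim == 0 else out


def _curve(t, a, b, c, d):
    return d + (c - d) * expit(a * (t - b))


def fit_degassing_curve(
    series: DegassingSeries,
    d_fixed: Optional[float] = 100.0,
    max_iter: int = 500,
) -> LogisticModel:
    """Least-squares fit of the logistic release model to a series.

    ``d_fixed`` pins the upper asymptote (default 100 %, appropriate for
    series normalized to the initial volume); pass ``None`` to estimate
    ``d`` as a fourth free parameter.

    Initial guesses: ``c`` at the series minimum, ``b`` at the time of
    the observation nearest the half-way level, ``a = 0.5`` /min — robust
    for monotone release curves.
    """
    if series.n_distinct_times() < 4:
        raise ValidationError(
            f"{series.sample_id}: need >= 4 distinct time points to fit, "
            f"got {series.n_distinct_times()}"
        )
    t = series.t
    y = series.pct
    if np.ptp(y) == 0:
        raise DegenerateDataError(
            f"{series.sample_id}: all percentages equal ({y[0]}); no release signal"
        )

    c0 = float(y.min())
    half = (float(y.max()) + c0) / 2.0
    b0 = float(t[np.argmin(np.abs(y - half))])
    a0 = 0.5

    if d_fixed is not None:
        fun = lambda tt, a, b, c: _curve(tt, a, b, c, d_fixed)
        p0 = [a0, b0, c0]
    else:
        fun = _curve
        p0 = [a0, b0, c0, float(y.max())]

    try:
        popt, pcov = optimize.curve_fit(
            fun, t, y, p0=p0, maxfev=max_iter * (len(p0) + 1), xtol=1e-10, ftol=1e-10
        )
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"{series.sample_id}: logistic fit did not converge: {exc}", last_params=p0
        ) from exc

    se = np.sqrt(np.diag(pcov))
    if d_fixed is not None:
        model = LogisticModel(
            a=popt[0], b=popt[1], c=popt[2], d=d_fixed,
            se_a=float(se[0]), se_b=float(se[1]), se_c=float(se[2]),
            n_obs=len(t), d_fixed=True,
        )
    else:
        model = LogisticModel(
            a=popt[0], b=popt[1], c=popt[2], d=popt[3],
            se_a=float(se[0]), se_b=float(se[1]), se_c=float(se[2]), se_d=float(se[3]),
            n_obs=len(t), d_fixed=False,
        )
    r2 = r_squared(series, model)
    return dataclasses.replace(model, r2=r2)


def r_squared(series: DegassingSeries, model: LogisticModel) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot on the series points.

    Nonlinear (unadjusted) R²; can be negative for a model worse than the
    flat mean line.
    """
    y = series.pct
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateDataError(
            f"{series.sample_id}: zero total variance, R² undefined"
        )
    res = y - logistic_value(model, series.t)
    return 1.0 - float((res**2).sum()) / ss_tot


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-time-point replicate statistics with a Student-t 95 % interval."""

    t: float
    n: int
    mean: float
    sd: Optional[float]     # None when n = 1 (undefined)
    sem: Optional[float]
    ci_low: float
    ci_high: float


def summarize_replicates(
    series: DegassingSeries, confidence: float = 0.95
) -> list[ReplicateSummary]:
    """Mean, sample SD, SEM and two-sided t-interval at each time point.

    With a single replicate the SD/SEM are undefined (reported as None)
    and the interval collapses to the point.
    """
    if not (0 < confidence < 1):
        raise ValidationError(f"confidence must be in (0, 1), got {confidence}")
    out = []
    t_arr, y_arr = series.t, series.pct
    for tp in sorted(set(t_arr)):
        vals = y_arr[t_arr == tp]
        n = len(vals)
        mean = float(vals.mean())
        if n == 1:
            out.append(ReplicateSummary(float(tp), 1, mean, None, None, mean, mean))
            continue
        sd = float(vals.std(ddof=1))
        sem = sd / math.sqrt(n)
        tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
        out.append(
            ReplicateSummary(
                float(tp), n, mean, sd, sem,
                mean - tcrit * sem, mean + tcrit * sem,
            )
        )
    return out
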