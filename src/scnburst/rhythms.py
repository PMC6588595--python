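"""Core circadian statistics.

Chi-square periodogram in the Sokolove-Bushell form, single-component
cosinor fitting (fixed or free period), Rayleigh circular statistics,
standardized amplitude / damping metrics, and conversion to circadian time
(CT), where CT12 is anchored to the PER2 peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .containers import ConfigurationError

__all__ = [
    "CTAnchor",
    "to_ct",
    "PeriodogramResult",
    "ChiSquarePeriodogram",
    "chisq_periodogram",
    "CosinorFit",
    "Cosinor",
    "cosinor_fit",
    "RayleighResult",
    "rayleigh_stats",
    "AmplitudeMetrics",
    "amplitude_metrics",
]


@dataclass(frozen=True)
class CTAnchor:
    """Circadian-time anchor: the PER2 peak defines CT12."""

    per2_peak_s: float
    tau_h: float

    def to_ct(self, time_s) -> np.ndarray:
        return to_ct(time_s, self.per2_peak_s, self.tau_h)


def to_ct(time_s, per2_peak_time_s: float, tau_h: float):
    """Convert absolute time (s) to circadian time (hours in [0, 24)).

    CT(t) = (12 + 24 * (t - per2_peak) / (3600 * tau)) mod 24.
    """
    if tau_h <= 0:
        raise ConfigurationError("tau_h must be positive")
    t = np.asarray(time_s, dtype=float)
    ct = (12.0 + 24.0 * (t - per2_peak_time_s) / (3600.0 * tau_h)) % 24.0
    return ct if ct.ndim else float(ct)


# ---------------------------------------------------------------------------
# chi-square periodogram
# ---------------------------------------------------------------------------


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    qp: np.ndarray
    sig_line: np.ndarray
    best_period_h: float | None
    qp_peak: float | None
    is_rhythmic: bool


class ChiSquarePeriodogram(BaseEstimator):
    """Sokolove-Bushell chi-square periodogram.

    For each candidate period of P samples the series is truncated to K
    complete blocks, folded into a K x P array, and

        Qp = K * N * sum_h (M_h - M)^2 / sum_i (x_i - M)^2

    with column means M_h, grand mean M and N = K*P.  Under a white-noise
    null Qp follows a chi-square law with P-1 degrees of freedom; the
    significance line is its upper-``alpha`` quantile, pointwise per period
    (no multiplicity correction), matching the usual plotted threshold.

    Attributes (after :meth:`fit`): ``periods_h_``, ``qp_``, ``sig_line_``,
    ``best_period_h_`` (argmax of Qp among supra-line periods, None if no
    period is significant), ``qp_peak_``, ``is_rhythmic_``.
    """

    def __init__(
        self,
        period_range_h: tuple[float, float] = (20.0, 28.0),
        alpha: float = 0.01,
        min_cycles: int = 3,
    ):
        self.period_range_h = period_range_h
        self.alpha = alpha
        self.min_cycles = min_cycles

    def fit(self, y: np.ndarray, sampling_interval_s: float) -> "ChiSquarePeriodogram":
        y = np.asarray(y, dtype=float)
        if y.ndim != 1:
            raise ConfigurationError("series must be one-dimensional")
        dt = float(sampling_interval_s)
        if dt <= 0:
            raise ConfigurationError("sampling interval must be positive")
        lo, hi = self.period_range_h
        p_lo = max(2, int(np.ceil(lo * 3600.0 / dt - 1e-9)))
        p_hi = int(np.floor(hi * 3600.0 / dt + 1e-9))
        if p_hi < p_lo:
            raise ConfigurationError("period grid empty at this sampling interval")
        n = y.size
        if n < self.min_cycles * p_hi:
            raise ConfigurationError(
                f"need >= {self.min_cycles} cycles of data at the longest tested period"
            )
        grand_var = np.var(y)
        periods = np.arange(p_lo, p_hi + 1)
        qp = np.zeros(periods.size)
        sig = stats.chi2.ppf(1.0 - self.alpha, periods - 1)
        if grand_var == 0:
            self._finalize(periods * dt / 3600.0, qp, sig, None, None, False)
            return self
        for i, p in enumerate(periods):
            k = n // p
            x = y[: k * p].reshape(k, p)
            m_h = x.mean(axis=0)
            m = x.mean()
            denom = np.sum((x - m) ** 2)
            if denom == 0:
                continue
            qp[i] = k * (k * p) * np.sum((m_h - m) ** 2) / denom
        above = qp > sig
        if above.any():
            best_i = int(np.argmax(np.where(above, qp, -np.inf)))
            self._finalize(
                periods * dt / 3600.0, qp, sig,
                float(periods[best_i] * dt / 3600.0), float(qp[best_i]), True,
            )
        else:
            self._finalize(periods * dt / 3600.0, qp, sig, None, None, False)
        return self

    def _finalize(self, periods_h, qp, sig, best, peak, rhythmic) -> None:
        self.periods_h_ = periods_h
        self.qp_ = qp
        self.sig_line_ = sig
        self.best_period_h_ = best
        self.qp_peak_ = peak
        self.is_rhythmic_ = rhythmic

    def result_(self) -> PeriodogramResult:
        return PeriodogramResult(
            periods_h=self.periods_h_,
            qp=self.qp_,
            sig_line=self.sig_line_,
            best_period_h=self.best_period_h_,
            qp_peak=self.qp_peak_,
            is_rhythmic=self.is_rhythmic_,
        )


def chisq_periodogram(
    values: np.ndarray,
    sampling_interval_s: float,
    period_range_h: tuple[float, float] = (20.0, 28.0),
    alpha: float = 0.01,
    min_cycles: int = 3,
) -> PeriodogramResult:
    """Chi-square periodogram; see :class:`ChiSquarePeriodogram`."""
    est = ChiSquarePeriodogram(period_range_h, alpha, min_cycles)
    return est.fit(values, sampling_interval_s).result_()


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    rsq: float


class Cosinor(BaseEstimator):
    """Least-squares fit of ``M + A*cos(2*pi*(t - phi)/tau)``.

    With ``period_h`` fixed the fit is the closed-form linear regression on
    cosine/sine regressors; with ``period_h=None`` the period is profiled
    over ``period_bounds_h`` (coarse grid plus bounded scalar refinement).
    The acrophase is returned as the peak time of the fitted curve, wrapped
    to ``[0, tau)``.
    """

    def __init__(
        self,
        period_h: float | None = 24.0,
        period_bounds_h: tuple[float, float] = (20.0, 28.0),
    ):
        self.period_h = period_h
        self.period_bounds_h = period_bounds_h

    @staticmethod
    def _linear_fit(t_h, y, tau_h):
        w = 2.0 * np.pi / tau_h
        X = np.column_stack([np.ones_like(t_h), np.cos(w * t_h), np.sin(w * t_h)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return beta, float(np.sum(resid**2))

    def fit(self, t_h: np.ndarray, y: np.ndarray) -> "Cosinor":
        t_h = np.asarray(t_h, dtype=float)
        y = np.asarray(y, dtype=float)
        if t_h.shape != y.shape or t_h.ndim != 1:
            raise ConfigurationError("t_h and y must be matching 1-D arrays")
        if y.size < (4 if self.period_h is None else 3):
            raise ConfigurationError("fewer samples than parameters")
        if self.period_h is not None:
            tau = float(self.period_h)
            beta, ssr = self._linear_fit(t_h, y, tau)
        else:
            lo, hi = self.period_bounds_h
            taus = np.arange(lo, hi + 1e-9, 0.1)
            ssrs = [self._linear_fit(t_h, y, tau)[1] for tau in taus]
            tau0 = taus[int(np.argmin(ssrs))]
            res = optimize.minimize_scalar(
                lambda tau: self._linear_fit(t_h, y, tau)[1],
                bounds=(max(lo, tau0 - 0.2), min(hi, tau0 + 0.2)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            tau = float(res.x)
            beta, ssr = self._linear_fit(t_h, y, tau)
        m, a, b = beta
        amp = float(np.hypot(a, b))
        phi = float((np.arctan2(b, a) / (2.0 * np.pi) * tau) % tau)
        sst = float(np.sum((y - y.mean()) ** 2))
        self.mesor_ = float(m)
        self.amplitude_ = amp
        self.acrophase_h_ = phi
        self.period_h_ = tau
        self.rsq_ = 1.0 - ssr / sst if sst > 0 else 0.0
        return self

    def predict(self, t_h: np.ndarray) -> np.ndarray:
        t_h = np.asarray(t_h, dtype=float)
        w = 2.0 * np.pi / self.period_h_
        return self.mesor_ + self.amplitude_ * np.cos(w * (t_h - self.acrophase_h_))

    def result_(self) -> CosinorFit:
        return CosinorFit(
            mesor=self.mesor_,
            amplitude=self.amplitude_,
            acrophase_h=self.acrophase_h_,
            period_h=self.period_h_,
            rsq=self.rsq_,
        )


def cosinor_fit(t_h, y, tau_h: float | None = 24.0) -> CosinorFit:
    """Cosinor fit; ``tau_h=None`` frees the period in [20, 28] h."""
    return Cosinor(period_h=tau_h).fit(t_h, y).result_()


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------


@dataclass
class RayleighResult:
    n: int
    mean_angle_h: float
    r: float


def rayleigh_stats(phases_h, tau_h: float) -> RayleighResult:
    """Circular mean and mean vector length of acrophases.

    Phases (hours modulo ``tau_h``) map to angles ``2*pi*phase/tau``; the
    mean vector length r is 1 for perfect synchrony and 0 for uniform
    dispersion.
    """
    phases = np.asarray(phases_h, dtype=float)
    if phases.size == 0:
        raise ConfigurationError("rayleigh_stats requires at least one phase")
    theta = 2.0 * np.pi * phases / tau_h
    z = np.exp(1j * theta).mean()
    r = float(np.abs(z))
    mean_h = float((np.angle(z) / (2.0 * np.pi) * tau_h) % tau_h)
    return RayleighResult(n=phases.size, mean_angle_h=mean_h, r=r)


# ---------------------------------------------------------------------------
# amplitude metrics
# ---------------------------------------------------------------------------


@dataclass
class AmplitudeMetrics:
    """Per-cycle standardized amplitude (peak - trough)/peak and the damping
    ratio, cycle-6 over cycle-1 standardized amplitude."""

    standardized_amplitude: np.ndarray
    damping_ratio: float | None


def amplitude_metrics(
    t_h: np.ndarray,
    y: np.ndarray,
    tau_h: float,
    smooth_h: float = 2.0,
) -> AmplitudeMetrics:
    """Cycle-wise standardized amplitude of a rhythmic series.

    The series is smoothed with a centered moving average of width
    ``smooth_h`` (removes burst-band contamination without materially
    shifting circadian phase); within each full cycle ``[k*tau, (k+1)*tau)``
    the peak and trough of the smoothed series give
    ``(peak - trough)/peak``.  A non-positive peak leaves that cycle NaN.
    The damping ratio is amplitude(cycle 6)/amplitude(cycle 1) when six
    cycles are available.
    """
    t_h = np.asarray(t_h, dtype=float)
    y = np.asarray(y, dtype=float)
    if t_h.size != y.size or t_h.size < 2:
        raise ConfigurationError("need a sampled series")
    dt = float(np.median(np.diff(t_h)))
    win = max(1, int(round(smooth_h / dt)))
    if win > 1:
        kernel = np.ones(win) / win
        pad = win // 2
        ypad = np.pad(y, pad, mode="edge")
        ys = np.convolve(ypad, kernel, mode="same")[pad : pad + y.size]
    else:
        ys = y
    n_cycles = int(np.floor((t_h[-1] - t_h[0] + dt) / tau_h + 1e-9))
    amps = np.full(n_cycles, np.nan)
    for k in range(n_cycles):
        m = (t_h >= t_h[0] + k * tau_h) & (t_h < t_h[0] + (k + 1) * tau_h)
        if not m.any():
            continue
        peak, trough = float(np.max(ys[m])), float(np.min(ys[m]))
        if peak > 0:
            amps[k] = (peak - trough) / peak
    damping = None
    if n_cycles >= 6 and np.isfinite(amps[0]) and np.isfinite(amps[5]) and amps[0] > 0:
        damping = float(amps[5] / amps[0])
    return AmplitudeMetrics(standardized_amplitude=amps, damping_ratio=damping)
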