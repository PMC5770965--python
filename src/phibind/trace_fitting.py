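"""Extraction of rate constants from stopped-flow-style data.

Three reductions are implemented, one per reported rate constant:

* per-trace exponential fitting (one or two phases, AICc model choice)
  yields the observed fast and slow relaxation rates at each partner
  concentration;
* a weighted straight-line fit of the fast rate against partner
  concentration yields the association rate constant ``k_ass_fast``
  (the slope) and its intercept;
* the slow rates, which carry no concentration dependence, are summarized
  by their mean (``k_ass_slow``) together with a zero-slope test;
* a saturating fit of observed displacement rates against competitor
  concentration yields the dissociation rate constant ``k_diss`` as the
  asymptote.

Fits that fail to converge are flagged, never raised, so that a panel run
can carry unusable variants through to reporting (mirroring how a real
panel handles variants with no measurable signal change).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .kinetic_model import Trace

__all__ = [
    "ExponentialFit",
    "RateFitResult",
    "CompetitionSeries",
    "fit_exponential",
    "choose_phases",
    "fit_trace_auto",
    "fit_association_series",
    "summarize_slow_phase",
    "fit_dissociation_asymptote",
]

# two 2-phase rates closer than this ratio are considered unresolved
_DEGENERATE_RATE_RATIO = 1.05


@dataclass
class ExponentialFit:
    """Result of a 1- or 2-phase exponential fit to a single trace.

    Rates are sorted descending.  ``aicc`` enables model comparison between
    the 1- and 2-phase fits of the same trace.
    """

    n_phases: int
    rates: np.ndarray  # s^-1, descending
    amplitudes: np.ndarray  # signal units, matching rates
    offset: float
    rate_se: np.ndarray
    amplitude_se: np.ndarray
    offset_se: float
    aicc: float
    residual_sd: float
    converged: bool = True
    degenerate: bool = False

    @property
    def rate_separation(self) -> float:
        """Ratio fast/slow for a 2-phase fit; inf for 1 phase."""
        if self.n_phases == 2 and self.rates[1] > 0:
            return self.rates[0] / self.rates[1]
        return math.inf


@dataclass
class RateFitResult:
    """The three rate constants reported for one variant.

    ``k_ass_fast`` is the slope of the fast observed rate vs partner
    concentration (M^-1 s^-1); ``k_ass_slow`` the mean plateau of the slow
    phase (s^-1); ``k_diss`` the competition asymptote (s^-1).  Each carries
    a standard error.  ``usable`` is False when any stage failed (e.g. no
    measurable signal change).
    """

    k_ass_fast: float = np.nan
    k_ass_fast_se: float = np.nan
    intercept: float = np.nan
    intercept_se: float = np.nan
    k_ass_slow: float = np.nan
    k_ass_slow_se: float = np.nan
    slow_slope_pvalue: float = np.nan
    k_diss: float = np.nan
    k_diss_se: float = np.nan
    usable: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class CompetitionSeries:
    """Observed apparent dissociation rates at competitor concentrations."""

    competitor_conc: np.ndarray  # M
    k_obs: np.ndarray  # s^-1
    k_obs_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.competitor_conc = np.asarray(self.competitor_conc, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.k_obs_se is not None:
            self.k_obs_se = np.asarray(self.k_obs_se, dtype=float)
        if len(np.unique(self.competitor_conc)) < 4:
            raise ValueError("competition series needs >= 4 distinct concentrations")
        if np.any(self.k_obs <= 0):
            raise ValueError("observed dissociation rates must be positive")


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for a Gaussian LS fit."""
    if n <= k + 1:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _initial_guesses(t: np.ndarray, y: np.ndarray, n_phases: int):
    """Deterministic starting values from log-linear segmentation.

    The offset is taken from the trace tail, the total amplitude from the
    initial deviation, and rate guesses from the times at which the
    deviation from the plateau decays to fixed fractions.  Entirely
    data-driven and deterministic so repeated fits are reproducible.
    """
    offset0 = float(np.mean(y[-max(3, len(y) // 10):]))
    dev = y - offset0
    a_tot = float(dev[0])
    scale = float(np.max(np.abs(dev)))
    if scale <= 0:
        scale = max(abs(offset0), 1.0) * 1e-6
        a_tot = scale
    # time at which |deviation| first falls below a fraction of its start
    def t_at_fraction(frac: float) -> float:
        target = abs(a_tot) * frac
        below = np.nonzero(np.abs(dev) < target)[0]
        if below.size and below[0] > 0:
            return float(t[below[0]])
        return float(t[-1] - t[0]) / 2 + float(t[0])

    t_e = max(t_at_fraction(math.exp(-1)) - t[0], (t[1] - t[0]))
    rate0 = 1.0 / t_e
    if n_phases == 1:
        return [a_tot, rate0, offset0]
    # split the amplitude; separate rate guesses by a factor of 5 around rate0
    return [0.7 * a_tot, 5.0 * rate0, 0.3 * a_tot, rate0 / 2.0, offset0]


def _model(t: np.ndarray, *params) -> np.ndarray:
    offset = params[-1]
    y = np.full_like(t, offset, dtype=float)
    for i in range(0, len(params) - 1, 2):
        y = y + params[i] * np.exp(-params[i + 1] * t)
    return y


def fit_exponential(trace: Trace | tuple, n_phases: int = 2) -> ExponentialFit:
    """Nonlinear least-squares fit of ``offset + sum_i A_i exp(-k_i t)``.

    Accepts a :class:`~phibind.kinetic_model.Trace` or a ``(time, signal)``
    pair.  Standard errors come from the fit covariance.  Non-convergence
    and degenerate two-phase fits (rates within 5% of each other, or a
    vanishing amplitude) are flagged on the result rather than raised.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    if isinstance(trace, Trace):
        t, y = trace.time_s, trace.signal
    else:
        t, y = (np.asarray(a, dtype=float) for a in trace)
    if t.size < 20:
        raise ValueError("need >= 20 time points for a reliable exponential fit")
    t0 = t[0]
    ts = t - t0  # fit from zero for conditioning; amplitudes refer to t[0]

    p0 = _initial_guesses(ts, y, n_phases)
    k = len(p0)
    scale = max(float(np.ptp(y)), 1e-12)
    bounds_lo = [-np.inf, 1e-12] * n_phases + [-np.inf]
    bounds_hi = [np.inf] * k
    try:
        popt, pcov = optimize.curve_fit(
            _model, ts, y, p0=p0, bounds=(bounds_lo, bounds_hi), maxfev=20000
        )
        converged = np.all(np.isfinite(popt))
    except (RuntimeError, ValueError):
        popt = np.asarray(p0, dtype=float)
        pcov = np.full((k, k), np.nan)
        converged = False

    perr = np.sqrt(np.abs(np.diag(pcov))) if np.all(np.isfinite(pcov)) else np.full(k, np.nan)
    resid = y - _model(ts, *popt)
    rss = float(resid @ resid)
    dof = max(t.size - k, 1)
    residual_sd = math.sqrt(rss / dof)

    amps = popt[0:-1:2]
    rates = popt[1:-1:2]
    amp_se = perr[0:-1:2]
    rate_se = perr[1:-1:2]
    order = np.argsort(rates)[::-1]
    amps, rates = amps[order], rates[order]
    amp_se, rate_se = amp_se[order], rate_se[order]

    degenerate = False
    if n_phases == 2 and converged:
        if rates[1] > 0 and rates[0] / rates[1] < _DEGENERATE_RATE_RATIO:
            degenerate = True
        # a phase outside the observable window is a fitting artifact, not a
        # resolved kinetic phase: slower than ~half a decay over the trace or
        # faster than the sampling interval.  A poorly determined but
        # in-window phase is NOT degenerate — it keeps its honest large SE
        # and is downweighted by the series regression downstream.
        t_span = float(ts[-1] - ts[0])
        dt = float(np.median(np.diff(ts)))
        if rates[1] < 0.5 / t_span or rates[0] > 2.0 / dt:
            degenerate = True
        if not np.all(np.isfinite(rate_se)):
            degenerate = True
    # amplitudes indistinguishable from the noise floor -> nothing to fit
    if converged and np.all(np.abs(amps) < 3.0 * residual_sd) and np.ptp(y) < 10 * residual_sd:
        degenerate = True
    if np.ptp(y) == 0.0:  # perfectly flat trace: no kinetics present at all
        degenerate = True

    return ExponentialFit(
        n_phases=n_phases,
        rates=rates,
        amplitudes=amps,
        offset=float(popt[-1]),
        rate_se=rate_se,
        amplitude_se=amp_se,
        offset_se=float(perr[-1]),
        aicc=_aicc(rss, t.size, k) if converged else math.inf,
        residual_sd=residual_sd,
        converged=bool(converged),
        degenerate=degenerate,
    )


def choose_phases(fit1: ExponentialFit, fit2: ExponentialFit, margin: float = 2.0) -> int:
    """Pick 1 or 2 phases for a trace fitted both ways.

    Returns 2 iff the two-phase fit is converged, non-degenerate, and its
    AICc beats the one-phase AICc by more than ``margin``.  Deterministic.
    """
    if fit1.n_phases != 1 or fit2.n_phases != 2:
        raise ValueError("pass the 1-phase fit first and the 2-phase fit second")
    if not fit2.converged or fit2.degenerate:
        return 1
    if fit2.aicc < fit1.aicc - margin:
        return 2
    return 1


def fit_trace_auto(trace: Trace | tuple) -> ExponentialFit:
    """Fit a trace with both 1 and 2 phases and return the AICc winner."""
    f1 = fit_exponential(trace, n_phases=1)
    f2 = fit_exponential(trace, n_phases=2)
    return f2 if choose_phases(f1, f2) == 2 else f1


def _weighted_linefit(x: np.ndarray, y: np.ndarray, se: np.ndarray | None):
    """Straight-line fit; known-error weighting when SEs are supplied.

    When per-point SEs are given, weights are 1/SE^2 and the parameter
    covariance is the unscaled (X' W X)^-1 — the standard treatment when
    the measurement errors are believed, which keeps downstream propagated
    errors calibrated.  Without SEs, ordinary least squares with
    residual-based errors is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([x, np.ones_like(x)])
    if se is not None and np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / np.asarray(se, dtype=float) ** 2
        xtwx = X.T @ (w[:, None] * X)
        cov = np.linalg.inv(xtwx)
        beta = cov @ (X.T @ (w * y))
    else:
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
    return beta, cov


def fit_association_series(partner_conc, lambda_fast, lambda_fast_se=None):
    """Fit the fast observed rate against partner concentration.

    The slope of the straight line is the association rate constant
    ``k_ass_fast`` (M^-1 s^-1); the intercept estimates the dissociation
    contribution to the observed rate.  Weighted regression (1/SE^2) when
    per-point standard errors are available.

    Returns ``(slope, slope_se, intercept, intercept_se)``.

    Raises
    ------
    ValueError
        For fewer than 4 concentrations, or a negative fitted slope
        (unphysical association).
    """
    x = np.asarray(partner_conc, dtype=float)
    y = np.asarray(lambda_fast, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct partner concentrations")
    se = None if lambda_fast_se is None else np.asarray(lambda_fast_se, dtype=float)
    beta, cov = _weighted_linefit(x, y, se)
    slope, intercept = float(beta[0]), float(beta[1])
    if slope <= 0:
        raise ValueError(f"fitted association slope is non-positive ({slope:g} M^-1 s^-1)")
    return slope, float(np.sqrt(cov[0, 0])), intercept, float(np.sqrt(cov[1, 1]))


def summarize_slow_phase(partner_conc, lambda_slow, lambda_slow_se=None):
    """Summarize the slow phase over the concentration series.

    The slow association phase is expected to be concentration-independent,
    so it is reported as a mean with a standard error, plus the p-value of
    a regression slope against zero as the concentration-independence check.

    Returns ``(mean, se_of_mean, slope_pvalue)``.
    """
    x = np.asarray(partner_conc, dtype=float)
    y = np.asarray(lambda_slow, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct partner concentrations")
    if lambda_slow_se is not None:
        se = np.asarray(lambda_slow_se, dtype=float)
        if np.all(se > 0):
            w = 1.0 / se**2
            mean = float(np.sum(w * y) / np.sum(w))
            mean_se = float(1.0 / math.sqrt(np.sum(w)))
        else:
            mean = float(np.mean(y))
            mean_se = float(np.std(y, ddof=1) / math.sqrt(len(y)))
    else:
        mean = float(np.mean(y))
        mean_se = float(np.std(y, ddof=1) / math.sqrt(len(y)))
    if np.allclose(y, y[0]):
        pvalue = 1.0  # perfectly constant: no evidence of a slope
    else:
        lr = stats.linregress(x, y)
        pvalue = float(lr.pvalue)
    return mean, mean_se, pvalue


def _hyperbola(c, k_diss, k_half):
    return k_diss * c / (c + k_half)


def _saturating_exponential(c, k_diss, c0):
    return k_diss * (1.0 - np.exp(-c / c0))


_COMPETITION_MODELS = {
    "hyperbola": _hyperbola,
    "exponential": _saturating_exponential,
}


def fit_dissociation_asymptote(
    series: CompetitionSeries, model: str = "hyperbola"
) -> tuple[float, float, list[str]]:
    """Fit the competition series and report the asymptote ``k_diss``.

    The default functional form is a saturating hyperbola through the
    origin, ``k_obs(c) = k_diss * c / (c + K_half)``; an exponential
    saturation form is available via ``model="exponential"``.  The
    asymptote is the reported dissociation rate constant.

    Returns ``(k_diss, k_diss_se, flags)``.  Flags include
    ``"no_plateau"`` when the series has visibly not saturated,
    ``"saturated"`` when the half-point is unidentifiable because every
    point sits on the plateau, and ``"not_converged"`` on fit failure.

    Raises
    ------
    ValueError
        If k_obs decreases significantly with concentration
        (model mismatch).
    """
    if model not in _COMPETITION_MODELS:
        raise ValueError(f"unknown competition model {model!r}")
    func = _COMPETITION_MODELS[model]
    c = series.competitor_conc
    k = series.k_obs
    order = np.argsort(c)
    c, k = c[order], k[order]
    se = series.k_obs_se[order] if series.k_obs_se is not None else None

    lr = stats.linregress(c, k)
    if lr.slope < 0 and lr.pvalue < 0.05:
        raise ValueError(
            "observed dissociation rates decrease with competitor concentration: "
            "saturating model does not apply"
        )

    flags: list[str] = []
    k_sorted = np.sort(k)
    if k_sorted[-1] > 1.10 * k_sorted[-2]:
        flags.append("no_plateau")
        warnings.warn(
            "competition series may not have plateaued (max k_obs more than "
            "10% above second max); asymptote extrapolation is uncertain",
            stacklevel=2,
        )
    # an essentially flat series leaves the half-point unidentifiable
    if np.ptp(k) < 0.02 * np.max(k):
        flags.append("saturated")
        if se is not None and np.all(se > 0):
            w = 1.0 / se**2
            kd = float(np.sum(w * k) / np.sum(w))
            kd_se = float(1.0 / math.sqrt(np.sum(w)))
        else:
            kd = float(np.mean(k))
            kd_se = float(np.std(k, ddof=1) / math.sqrt(len(k)))
        return kd, kd_se, flags

    p0 = [float(np.max(k)), float(np.median(c)) / 10.0]
    sigma = se if (se is not None and np.all(se > 0)) else None
    try:
        popt, pcov = optimize.curve_fit(
            func,
            c,
            k,
            p0=p0,
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        flags.append("not_converged")
        return math.nan, math.nan, flags
    kd = float(popt[0])
    kd_se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else math.nan
    return kd, kd_se, flags
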