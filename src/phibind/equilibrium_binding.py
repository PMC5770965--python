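"""Equilibrium binding (anisotropy titrations) and residual-helicity estimation.

The anisotropy isotherm is fitted with the exact, ligand-depletion-corrected
single-site binding solution (the physical root of the mass-action
quadratic), not the hyperbolic approximation: the labelled-probe
concentration in a titration is often comparable to the tightest Kd values
in a mutant panel, where the hyperbola is biased.

The helicity estimator converts a mean-residue ellipticity at 222 nm into a
fraction helix using standard chain-length- and temperature-dependent helix
and coil baselines.  The baseline constants are configuration with
documented defaults; they are conventions, not measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationCurve",
    "EquilibriumResult",
    "HelicityBaselines",
    "fraction_bound",
    "fit_anisotropy_isotherm",
    "estimate_fraction_helix",
    "mre_from_fraction_helix",
]


@dataclass(frozen=True)
class TitrationCurve:
    """One fluorescence-anisotropy titration at fixed probe concentration."""

    probe_conc: float  # M, fixed labelled-peptide concentration
    partner_total: np.ndarray  # M, total partner per point
    anisotropy: np.ndarray  # unitless

    def __post_init__(self) -> None:
        object.__setattr__(self, "partner_total", np.asarray(self.partner_total, dtype=float))
        object.__setattr__(self, "anisotropy", np.asarray(self.anisotropy, dtype=float))
        if self.partner_total.shape != self.anisotropy.shape:
            raise ValueError("partner_total and anisotropy must have equal length")
        if np.any(self.partner_total < 0):
            raise ValueError("partner concentrations must be non-negative")
        if np.any(np.diff(self.partner_total) < 0):
            raise ValueError("partner_total must be sorted ascending")
        if np.any((self.anisotropy < 0) | (self.anisotropy > 0.4)):
            raise ValueError("anisotropy values must lie within [0, 0.4]")


@dataclass
class EquilibriumResult:
    """Fitted equilibrium dissociation constant and signal endpoints."""

    kd_equb: float  # M
    kd_se: float  # M
    r_free: float
    r_bound: float
    converged: bool = True
    poorly_determined: bool = False

    def __post_init__(self) -> None:
        if self.converged and self.kd_equb <= 0:
            raise ValueError("fitted Kd must be positive")


def fraction_bound(partner_total, probe_total: float, kd: float):
    """Exact fraction of probe bound under ligand depletion.

    Solves the single-site mass-action equilibrium for the complex
    concentration [PL], the physical root of

        [PL]^2 - (P + L + Kd) [PL] + P*L = 0,

    and returns [PL]/P.  Vectorized over ``partner_total``.  Zero probe or
    zero partner returns 0; the result is monotone increasing in L and
    decreasing in Kd.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if probe_total < 0:
        raise ValueError("probe concentration must be non-negative")
    L = np.asarray(partner_total, dtype=float)
    if np.any(L < 0):
        raise ValueError("partner concentrations must be non-negative")
    if probe_total == 0.0:
        out = np.zeros_like(L)
        return out if out.ndim else float(out)
    P = probe_total
    s = P + L + kd
    # numerically stable smaller quadratic root: 2PL / (s + sqrt(s^2 - 4PL))
    disc = s * s - 4.0 * P * L
    disc = np.maximum(disc, 0.0)
    pl = 2.0 * P * L / (s + np.sqrt(disc))
    frac = pl / P
    frac = np.clip(frac, 0.0, 1.0)
    return frac if frac.ndim else float(frac)


def fit_anisotropy_isotherm(curve: TitrationCurve) -> EquilibriumResult:
    """Fit Kd, r_free and r_bound to an anisotropy titration.

    The model is ``r(L) = r_free + (r_bound - r_free) * f_bound(L; P, Kd)``
    with the depletion-corrected :func:`fraction_bound`.  Plain (not
    intensity-weighted) averaging of the free and bound anisotropies is
    assumed, i.e. the total fluorescence intensity change on binding is
    taken as negligible.

    The result is flagged ``poorly_determined`` when the fitted Kd exceeds
    the highest partner concentration titrated (the curve never reaches its
    inflection, so the plateau — and hence Kd — is an extrapolation), or
    when the Kd standard error exceeds half the estimate.
    """
    L = curve.partner_total
    r = curve.anisotropy
    if L.size < 6:
        raise ValueError("need >= 6 titration points")
    P = curve.probe_conc

    # Kd is fitted on a log10 scale: it spans decades across a panel and the
    # optimizer needs a well-scaled parameter for nanomolar affinities
    def model(Lv, lg_kd, r_free, r_bound):
        return r_free + (r_bound - r_free) * fraction_bound(Lv, P, 10.0**lg_kd)

    r_lo, r_hi = float(np.min(r)), float(np.max(r))
    # guess Kd from the half-rise point
    half = r_lo + 0.5 * (r_hi - r_lo)
    above = np.nonzero(r >= half)[0]
    kd0 = float(L[above[0]]) if above.size else float(L[-1])
    kd0 = max(kd0, 1e-12)
    try:
        popt, pcov = optimize.curve_fit(
            model,
            L,
            r,
            p0=[math.log10(kd0), r_lo, r_hi],
            bounds=([-15.0, 0.0, 0.0], [0.0, 0.4, 0.4]),
            maxfev=20000,
        )
        converged = True
    except (RuntimeError, ValueError):
        return EquilibriumResult(
            kd_equb=math.nan, kd_se=math.nan, r_free=math.nan, r_bound=math.nan,
            converged=False, poorly_determined=True,
        )
    lg_kd, r_free, r_bound = (float(v) for v in popt)
    kd = 10.0**lg_kd
    kd_se = (
        kd * math.log(10.0) * float(np.sqrt(pcov[0, 0]))
        if np.isfinite(pcov[0, 0])
        else math.nan
    )
    poorly = bool(kd > float(L[-1])) or not math.isfinite(kd_se) or kd_se > 0.5 * kd
    return EquilibriumResult(
        kd_equb=kd, kd_se=kd_se, r_free=r_free, r_bound=r_bound,
        converged=converged, poorly_determined=poorly,
    )


@dataclass(frozen=True)
class HelicityBaselines:
    """Helix/coil mean-residue-ellipticity baselines at 222 nm.

    Standard empirical forms (deg cm^2 dmol^-1 residue^-1, temperature in
    kelvin internally, the conventional parameterization being in Celsius):

        mre_helix(n, T) = helix_inf * (1 - x_helix / n) + helix_t * T_C
        mre_coil(T)     = coil_0 + coil_t * T_C

    Defaults are the widely used values helix_inf = -40000, x_helix = 2.5,
    helix_t = +100 per degree C, coil_0 = +640, coil_t = -45 per degree C.
    These are conventions of the field, configurable rather than fitted.
    """

    helix_inf: float = -40000.0
    x_helix: float = 2.5
    helix_t: float = 100.0
    coil_0: float = 640.0
    coil_t: float = -45.0

    def mre_helix(self, n_residues: int, temperature: float) -> float:
        t_c = temperature - 273.15
        return self.helix_inf * (1.0 - self.x_helix / n_residues) + self.helix_t * t_c

    def mre_coil(self, temperature: float) -> float:
        t_c = temperature - 273.15
        return self.coil_0 + self.coil_t * t_c


def estimate_fraction_helix(
    mre_222: float,
    n_residues: int,
    temperature: float = 298.15,
    baselines: HelicityBaselines | None = None,
) -> float:
    """Fraction helix from the mean residue ellipticity at 222 nm.

    Linear interpolation between the coil and full-helix baselines:
    ``f_H = (mre_222 - mre_coil) / (mre_helix - mre_coil)``, clipped to
    [0, 1] with a warning for out-of-range inputs.
    """
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5")
    b = baselines or HelicityBaselines()
    coil = b.mre_coil(temperature)
    helix = b.mre_helix(n_residues, temperature)
    f = (mre_222 - coil) / (helix - coil)
    if f < 0.0 or f > 1.0:
        warnings.warn(
            f"fraction helix {f:.3f} outside [0, 1]; clipping — check baselines",
            stacklevel=2,
        )
        f = min(max(f, 0.0), 1.0)
    return float(f)


def mre_from_fraction_helix(
    f_helix: float,
    n_residues: int,
    temperature: float = 298.15,
    baselines: HelicityBaselines | None = None,
) -> float:
    """Inverse of :func:`estimate_fraction_helix` under the same baselines."""
    if not 0.0 <= f_helix <= 1.0:
        raise ValueError("fraction helix must lie in [0, 1]")
    b = baselines or HelicityBaselines()
    coil = b.mre_coil(temperature)
    helix = b.mre_helix(n_residues, temperature)
    return float(coil + f_helix * (helix - coil))
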