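"""Phi-value analysis of a mutant panel.

The core statistic: for a mutation that destabilizes a binding reaction,
the phi-value

    phi = ln(k_ass_ref / k_ass_mut) / ln(Kd_mut / Kd_ref)

partitions the stability loss between the association barrier and the bound
state.  phi ~ 1 means the mutated interaction is fully formed at the
rate-limiting transition state, phi ~ 0 means it forms only after the
barrier, and phi < 0 (the mutation speeds association while destabilizing
the complex) points to nonnative transition-state contacts.

Two branches are computed for every variant: an equilibrium branch using
the titration Kd and a kinetic branch using Kd_kin = k_diss / k_ass_fast.
Phi-values are reported only where both branches show a free-energy change
of at least a threshold (default 0.34 kcal/mol), where the two branches
agree within tolerance, and averaged into phi_average.

All standard errors are first-order (delta-method) propagation on
ln-transformed quantities; the shared reference (wild-type) enters every
variant's error independently — the correlation this induces across the
panel is deliberately ignored and recorded in output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .measurement import Measurement, as_measurement
from .trace_fitting import RateFitResult
from .equilibrium_binding import EquilibriumResult

__all__ = [
    "GAS_CONSTANT_KCAL",
    "VariantRecord",
    "PhiResult",
    "UndefinedPhiError",
    "kd_kin",
    "delta_delta_g",
    "phi_value",
    "phi_for_variant",
    "composite_ala_gly",
    "apply_report_filter",
    "consistency_check",
    "lfe_table",
    "compare_kd",
    "classify_transition_state",
    "region_summary",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3

REGIONS = ("helix_A", "kink", "helix_B")
SITE_CLASSES = ("interface", "surface")
SUBSTITUTIONS = ("X->A", "A->G", "wild-type")


class UndefinedPhiError(ValueError):
    """Phi is undefined (no stability change between mutant and reference)."""


@dataclass
class VariantRecord:
    """One peptide variant: metadata plus measured kinetic/equilibrium data."""

    variant_id: str
    position: int
    region: str  # helix_A | kink | helix_B
    site_class: str  # interface | surface
    substitution: str  # "X->A" | "A->G" | "wild-type"
    rates: RateFitResult | None = None
    equilibrium: EquilibriumResult | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.substitution not in SUBSTITUTIONS:
            raise ValueError(f"unknown substitution {self.substitution!r}")

    @property
    def is_wild_type(self) -> bool:
        return self.substitution == "wild-type"

    @property
    def usable(self) -> bool:
        return (
            self.rates is not None
            and self.rates.usable
            and self.equilibrium is not None
            and self.equilibrium.converged
        )


@dataclass
class PhiResult:
    """Phi-analysis output for one variant (relative to its reference)."""

    variant_id: str
    kd_kin: Measurement | None = None  # M
    ddg_equb: Measurement | None = None  # kcal/mol, destabilizing positive
    ddg_kin: Measurement | None = None  # kcal/mol
    phi_equb: Measurement | None = None
    phi_kin: Measurement | None = None
    phi_average: Measurement | None = None
    reportable: bool = False
    consistent: bool = True
    ts_class: str | None = None
    flags: list[str] = field(default_factory=list)


def kd_kin(k_diss, k_ass_fast) -> Measurement:
    """Kinetic dissociation constant Kd_kin = k_diss / k_ass_fast (M).

    First-order error propagation on the ratio:
    relSE^2 = relSE(k_diss)^2 + relSE(k_ass_fast)^2.
    """
    kd_m = as_measurement(k_diss)
    ka_m = as_measurement(k_ass_fast)
    if kd_m.value <= 0 or ka_m.value <= 0:
        raise ValueError("rate constants must be positive")
    value = kd_m.value / ka_m.value
    rel = math.hypot(kd_m.rel_se, ka_m.rel_se)
    return Measurement(value, value * rel)


def delta_delta_g(kd_mut, kd_ref, temperature: float = 298.15) -> Measurement:
    """Free-energy change on mutation, ddG = R T ln(Kd_mut / Kd_ref).

    Destabilizing mutations (weaker binding, larger Kd) are positive.
    R = 1.987e-3 kcal mol^-1 K^-1.  SE by propagation of the logarithm:
    SE(ddG) = R T sqrt(relSE_mut^2 + relSE_ref^2).
    """
    mut = as_measurement(kd_mut)
    ref = as_measurement(kd_ref)
    if mut.value <= 0 or ref.value <= 0:
        raise ValueError("Kd values must be positive")
    rt = GAS_CONSTANT_KCAL * temperature
    value = rt * math.log(mut.value / ref.value)
    se = rt * math.hypot(mut.rel_se, ref.rel_se)
    return Measurement(value, se)


def phi_value(k_ass_ref, k_ass_mut, kd_mut, kd_ref) -> Measurement:
    """Phi = ln(k_ass_ref / k_ass_mut) / ln(Kd_mut / Kd_ref), with SE.

    Delta-method propagation: with numerator A and denominator B,
    sigma_A^2 = relSE(k_ass_ref)^2 + relSE(k_ass_mut)^2 and
    sigma_B^2 = relSE(kd_mut)^2 + relSE(kd_ref)^2, then
    sigma_phi = |phi| sqrt((sigma_A/A)^2 + (sigma_B/B)^2); at A -> 0 the
    limit sigma_phi = sigma_A / |B| is used.

    Raises
    ------
    UndefinedPhiError
        If Kd_mut equals Kd_ref (zero denominator: no stability change to
        partition).
    """
    ka_ref = as_measurement(k_ass_ref)
    ka_mut = as_measurement(k_ass_mut)
    kdm = as_measurement(kd_mut)
    kdr = as_measurement(kd_ref)
    for m in (ka_ref, ka_mut, kdm, kdr):
        if m.value <= 0:
            raise ValueError("all rate and equilibrium constants must be positive")
    if kdm.value == kdr.value:
        raise UndefinedPhiError("Kd unchanged by mutation: phi undefined")
    num = math.log(ka_ref.value / ka_mut.value)
    den = math.log(kdm.value / kdr.value)
    phi = num / den
    sigma_a = math.hypot(ka_ref.rel_se, ka_mut.rel_se)
    sigma_b = math.hypot(kdm.rel_se, kdr.rel_se)
    if abs(num) < 1e-12:
        se = sigma_a / abs(den)
    else:
        se = abs(phi) * math.hypot(sigma_a / num, sigma_b / den)
    return Measurement(phi, abs(se))


def _average_phi(phi_e: Measurement, phi_k: Measurement) -> Measurement:
    """Mean of the two branch phi-values; SE = sqrt(se_e^2 + se_k^2)/2.

    Valid only when the branches are independent — the pipeline instead
    uses :func:`phi_average_correlated`, since both branches share the
    association-rate numerator exactly.  Kept as the simple combination
    for callers with genuinely independent branch estimates.
    """
    return Measurement(
        0.5 * (phi_e.value + phi_k.value),
        0.5 * math.hypot(phi_e.se, phi_k.se),
    )


def phi_average_correlated(
    sigma_a2: float,
    num: float,
    den_e: float,
    sigma_e2: float,
    den_k: float,
    sigma_c2: float,
) -> Measurement:
    """Average phi with the shared-numerator covariance propagated.

    Both branches are ``phi = A / B`` with the *same* numerator
    ``A = ln(k_ass,ref / k_ass,mut)``; the kinetic denominator further
    decomposes as ``B_kin = C + A`` with ``C = ln(k_diss ratio)``.  Writing
    the average in the independent variables (A, B_equb, C),

        phi_avg = (A/2) (1/B_equb + 1/(C + A)),

    the delta method gives

        var = [ (1/B_e + C/B_k^2) / 2 ]^2 sigma_A^2
            + [ A / (2 B_e^2) ]^2 sigma_Be^2
            + [ A / (2 B_k^2) ]^2 sigma_C^2 .

    The naive independent-branch combination sqrt(s1^2 + s2^2)/2
    underestimates this whenever sigma_A contributes, because the shared
    numerator correlates the branches (verified by Monte Carlo and by the
    end-to-end coverage test).
    """
    value = 0.5 * num * (1.0 / den_e + 1.0 / den_k)
    d_a = 0.5 * (1.0 / den_e + (den_k - num) / den_k**2)
    d_be = -num / (2.0 * den_e**2)
    d_c = -num / (2.0 * den_k**2)
    var = d_a**2 * sigma_a2 + d_be**2 * sigma_e2 + d_c**2 * sigma_c2
    return Measurement(value, math.sqrt(max(var, 0.0)))


def _rates_measurements(rates: RateFitResult) -> tuple[Measurement, Measurement]:
    return (
        Measurement(rates.k_ass_fast, rates.k_ass_fast_se),
        Measurement(rates.k_diss, rates.k_diss_se),
    )


def phi_for_variant(
    mutant: VariantRecord,
    reference: VariantRecord,
    temperature: float = 298.15,
) -> PhiResult:
    """Full two-branch phi analysis of one variant against a reference.

    The reference is normally the wild-type; for the glycine member of a
    surface Ala/Gly pair it is the alanine variant (see
    :func:`composite_ala_gly`).  Unusable inputs yield a flagged,
    non-reportable result rather than an exception.
    """
    result = PhiResult(variant_id=mutant.variant_id)
    if not mutant.usable or not reference.usable:
        result.flags.append("unusable_input")
        return result
    ka_mut, kdiss_mut = _rates_measurements(mutant.rates)
    ka_ref, kdiss_ref = _rates_measurements(reference.rates)
    kd_equb_mut = Measurement(mutant.equilibrium.kd_equb, mutant.equilibrium.kd_se)
    kd_equb_ref = Measurement(reference.equilibrium.kd_equb, reference.equilibrium.kd_se)
    kd_kin_mut = kd_kin(kdiss_mut, ka_mut)
    kd_kin_ref = kd_kin(kdiss_ref, ka_ref)

    result.kd_kin = kd_kin_mut
    result.ddg_equb = delta_delta_g(kd_equb_mut, kd_equb_ref, temperature)
    result.ddg_kin = delta_delta_g(kd_kin_mut, kd_kin_ref, temperature)
    try:
        result.phi_equb = phi_value(ka_ref, ka_mut, kd_equb_mut, kd_equb_ref)
        result.phi_kin = phi_value(ka_ref, ka_mut, kd_kin_mut, kd_kin_ref)
        result.phi_average = phi_average_correlated(
            sigma_a2=ka_ref.rel_se**2 + ka_mut.rel_se**2,
            num=math.log(ka_ref.value / ka_mut.value),
            den_e=math.log(kd_equb_mut.value / kd_equb_ref.value),
            sigma_e2=kd_equb_mut.rel_se**2 + kd_equb_ref.rel_se**2,
            den_k=math.log(kd_kin_mut.value / kd_kin_ref.value),
            sigma_c2=kdiss_mut.rel_se**2 + kdiss_ref.rel_se**2,
        )
    except UndefinedPhiError:
        result.flags.append("phi_undefined")
    if mutant.equilibrium.poorly_determined:
        result.flags.append("kd_poorly_determined")
    return result


def composite_ala_gly(
    ala: VariantRecord, gly: VariantRecord, temperature: float = 298.15
) -> PhiResult:
    """Phi analysis of the composite Ala->Gly step at a surface position.

    The helix-probing perturbation at a solvent-exposed position is the
    Ala->Gly substitution, so the alanine variant — not the wild-type — is
    the reference state; both kinetic and equilibrium branches are
    computed.  ddG values for surface positions therefore refer to the
    composite Ala-Gly mutation.
    """
    if ala.position != gly.position:
        raise ValueError(
            f"Ala/Gly pair positions differ: {ala.position} vs {gly.position}"
        )
    if ala.substitution != "X->A" or gly.substitution != "A->G":
        raise ValueError("composite analysis needs an X->A and an A->G variant")
    result = phi_for_variant(gly, ala, temperature)
    result.flags.append("composite_ala_gly")
    return result


def apply_report_filter(
    results: list[PhiResult], threshold: float = 0.34
) -> list[PhiResult]:
    """Mark phi-values reportable when both branches pass the ddG filter.

    A phi-value is only trustworthy when the mutation is sufficiently
    destabilizing in BOTH the equilibrium and the kinetic branch:
    reportable iff ddg_equb >= threshold AND ddg_kin >= threshold
    (inclusive boundary).  Stabilizing mutations (ddG < 0) are never
    reportable: the filter is written for destabilization, and a negative
    denominator makes phi statistically pathological.  Returns new result
    objects; the count of reportable values is available to callers via
    ``sum(r.reportable for r in ...)``.
    """
    out = []
    for r in results:
        ok = (
            r.ddg_equb is not None
            and r.ddg_kin is not None
            and r.phi_average is not None
            and r.ddg_equb.value >= threshold
            and r.ddg_kin.value >= threshold
        )
        out.append(replace(r, reportable=bool(ok), flags=list(r.flags)))
    return out


def consistency_check(
    ddg_equb: Measurement, ddg_kin: Measurement, tolerance_multiple: float = 2.0
) -> bool:
    """Do the equilibrium and kinetic ddG branches agree?

    Returns True (consistent) when |ddg_equb - ddg_kin| does not exceed
    ``tolerance_multiple`` times the combined standard error
    sqrt(se_e^2 + se_k^2).  Variants failing this check are excluded from
    the reported transition-state pattern even if both branches pass the
    magnitude filter.
    """
    combined = math.hypot(ddg_equb.se, ddg_kin.se)
    diff = abs(ddg_equb.value - ddg_kin.value)
    if combined == 0.0:
        return diff == 0.0
    return diff <= tolerance_multiple * combined


def apply_consistency(
    results: list[PhiResult], tolerance_multiple: float = 2.0
) -> list[PhiResult]:
    """Apply :func:`consistency_check` across a panel of results."""
    out = []
    for r in results:
        if r.ddg_equb is None or r.ddg_kin is None:
            out.append(replace(r, consistent=False, flags=list(r.flags)))
            continue
        ok = consistency_check(r.ddg_equb, r.ddg_kin, tolerance_multiple)
        flags = list(r.flags)
        if not ok:
            flags.append("branch_disagreement")
        out.append(replace(r, consistent=ok, flags=flags))
    return out


def lfe_table(variants: list[VariantRecord]):
    """Linear free-energy relationship across the panel.

    Returns ``(table, slopes)`` where ``table`` is a pandas DataFrame with
    per-variant log10 Kd_equb, log10 k_ass_fast and log10 k_diss, and
    ``slopes`` maps each rate constant to ``(slope, se)`` from the
    regression of its log against log Kd.  A panel whose stability changes
    live entirely in the dissociation rate shows
    slope(k_diss) = 1, slope(k_ass) = 0; a panel with all effect on
    association shows slope(k_ass) = -1, slope(k_diss) = 0.
    """
    import pandas as pd

    rows = []
    for v in variants:
        if not v.usable:
            continue
        rows.append(
            {
                "variant_id": v.variant_id,
                "log10_kd": math.log10(v.equilibrium.kd_equb),
                "log10_k_ass_fast": math.log10(v.rates.k_ass_fast),
                "log10_k_diss": math.log10(v.rates.k_diss),
            }
        )
    if len(rows) < 3:
        raise ValueError("LFE analysis needs >= 3 variants with complete rates")
    table = pd.DataFrame(rows)
    slopes = {}
    for col, key in (("log10_k_ass_fast", "k_ass_fast"), ("log10_k_diss", "k_diss")):
        lr = stats.linregress(table["log10_kd"], table[col])
        slopes[key] = (float(lr.slope), float(lr.stderr))
    return table, slopes


def compare_kd(variants: list[VariantRecord], ci_multiple: float = 1.96):
    """Kinetic-vs-equilibrium Kd agreement across the panel.

    Returns ``(table, fraction_covering)``: a DataFrame with the per-variant
    ratio Kd_kin / Kd_equb, its propagated SE and the confidence interval
    ``ratio +/- ci_multiple * se``, and the fraction of variants whose
    interval covers 1 (the identity expected when two observed rates
    suffice to describe the binding free energy).

    The interval half-width carries a floor of 1e-6 relative: on noiseless
    data the fit covariance collapses below the solvers' convergence
    tolerance, and agreement at that level is exact, not a discrepancy.
    """
    import pandas as pd

    rows = []
    for v in variants:
        if not v.usable:
            continue
        kk = kd_kin(
            Measurement(v.rates.k_diss, v.rates.k_diss_se),
            Measurement(v.rates.k_ass_fast, v.rates.k_ass_fast_se),
        )
        ke = Measurement(v.equilibrium.kd_equb, v.equilibrium.kd_se)
        ratio = kk.value / ke.value
        rel = math.hypot(kk.rel_se, ke.rel_se)
        se = ratio * rel
        half = max(ci_multiple * se, 1e-6 * abs(ratio))
        lo, hi = ratio - half, ratio + half
        rows.append(
            {
                "variant_id": v.variant_id,
                "kd_kin_M": kk.value,
                "kd_equb_M": ke.value,
                "ratio": ratio,
                "ratio_se": se,
                "ci_lo": lo,
                "ci_hi": hi,
                "covers_unity": bool(lo <= 1.0 <= hi),
            }
        )
    if not rows:
        raise ValueError("no usable variants for the Kd comparison")
    table = pd.DataFrame(rows)
    return table, float(table["covers_unity"].mean())


@dataclass(frozen=True)
class ClassificationThresholds:
    """Interpretive phi bands for transition-state structure.

    ``nonnative``: phi + SE below this bound (default 0) marks a candidate
    nonnative contact (the mutation speeds transition-state formation).
    ``unstructured`` and ``weak`` bound the |phi| <= 0.1 and
    0.1 < phi <= 0.5 bands; phi above ``weak`` counts as structured.
    The bands are conventions, configurable, not measurements.
    """

    nonnative: float = 0.0
    unstructured: float = 0.1
    weak: float = 0.5


def classify_transition_state(
    result: PhiResult, thresholds: ClassificationThresholds | None = None
) -> str:
    """Assign a transition-state structure class from phi_average.

    Order of precedence: a phi whose whole 1-SE band is negative is a
    ``nonnative_candidate``; then |phi| <= 0.1 -> ``unstructured``;
    0.1 < phi <= 0.5 -> ``weakly_structured``; phi > 0.5 -> ``structured``.
    """
    th = thresholds or ClassificationThresholds()
    if result.phi_average is None:
        raise ValueError("cannot classify a variant without a phi value")
    phi = result.phi_average
    if phi.value + phi.se < th.nonnative:
        return "nonnative_candidate"
    if abs(phi.value) <= th.unstructured:
        return "unstructured"
    if phi.value <= th.weak:
        return "weakly_structured"
    return "structured"


def classify_panel(
    results: list[PhiResult], thresholds: ClassificationThresholds | None = None
) -> list[PhiResult]:
    """Classify every reportable, consistent result in a panel."""
    out = []
    for r in results:
        if r.reportable and r.consistent and r.phi_average is not None:
            out.append(replace(r, ts_class=classify_transition_state(r, thresholds),
                               flags=list(r.flags)))
        else:
            out.append(replace(r, ts_class=None, flags=list(r.flags)))
    return out


def region_summary(results: list[PhiResult], variants: list[VariantRecord]):
    """Per-region phi pattern of the reported (filtered, consistent) values.

    Returns a DataFrame with, for each region, the number of reported
    phi-values, their mean, minimum and maximum, and the count classified
    as nonnative candidates — the per-region view of where the transition
    state is structured.
    """
    import pandas as pd

    region_of = {v.variant_id: v.region for v in variants}
    buckets: dict[str, list[PhiResult]] = {r: [] for r in REGIONS}
    for res in results:
        if res.reportable and res.consistent and res.phi_average is not None:
            buckets[region_of[res.variant_id]].append(res)
    rows = []
    for region in REGIONS:
        vals = [r.phi_average.value for r in buckets[region]]
        n_nonnative = sum(1 for r in buckets[region] if r.ts_class == "nonnative_candidate")
        rows.append(
            {
                "region": region,
                "n_reported": len(vals),
                "phi_mean": float(np.mean(vals)) if vals else math.nan,
                "phi_min": float(np.min(vals)) if vals else math.nan,
                "phi_max": float(np.max(vals)) if vals else math.nan,
                "n_nonnative": n_nonnative,
            }
        )
    return pd.DataFrame(rows)
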