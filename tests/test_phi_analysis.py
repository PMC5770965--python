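"""Phi-value statistics: formulas, error propagation, filters, classification."""

import math

import numpy as np
import pytest

from phibind import (
    ClassificationThresholds,
    EquilibriumResult,
    GAS_CONSTANT_KCAL,
    Measurement,
    PhiResult,
    RateFitResult,
    UndefinedPhiError,
    VariantRecord,
    apply_report_filter,
    classify_transition_state,
    compare_kd,
    composite_ala_gly,
    consistency_check,
    delta_delta_g,
    kd_kin,
    lfe_table,
    phi_value,
)
from phibind.phi_analysis import phi_for_variant, region_summary

RT = GAS_CONSTANT_KCAL * 298.15


def make_record(vid, k_ass, k_diss, kd_equb, rel_se=0.0, position=1,
                region="helix_A", site_class="interface", substitution="X->A"):
    rates = RateFitResult(
        k_ass_fast=k_ass, k_ass_fast_se=rel_se * k_ass,
        k_diss=k_diss, k_diss_se=rel_se * k_diss,
        intercept=k_diss, intercept_se=0.0,
        k_ass_slow=1.0, k_ass_slow_se=0.0, slow_slope_pvalue=1.0,
    )
    eq = EquilibriumResult(
        kd_equb=kd_equb, kd_se=rel_se * kd_equb, r_free=0.05, r_bound=0.25
    )
    return VariantRecord(
        variant_id=vid, position=position, region=region, site_class=site_class,
        substitution=substitution, rates=rates, equilibrium=eq,
    )


class TestKdKin:
    def test_ratio(self):
        m = kd_kin(Measurement(0.078), Measurement(1e6))
        assert m.value == pytest.approx(7.8e-8, rel=1e-12)
        assert m.se == 0.0

    def test_relative_se_combines_in_quadrature(self):
        m = kd_kin(Measurement(0.078, 0.0078), Measurement(1e6, 1e5))
        assert m.rel_se == pytest.approx(math.sqrt(2) * 0.10, rel=1e-9)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            kd_kin(Measurement(-1.0), Measurement(1e6))


class TestDeltaDeltaG:
    def test_tenfold_ratio(self):
        m = delta_delta_g(Measurement(1e-5), Measurement(1e-6))
        assert m.value == pytest.approx(RT * math.log(10), rel=1e-9)
        assert m.value == pytest.approx(1.364, abs=2e-3)

    def test_identity(self):
        assert delta_delta_g(Measurement(1e-6), Measurement(1e-6)).value == 0.0

    def test_thousandfold_ratio(self):
        m = delta_delta_g(Measurement(1e-3), Measurement(1e-6))
        assert m.value == pytest.approx(3 * RT * math.log(10), rel=1e-9)
        assert m.value == pytest.approx(4.09, abs=5e-3)

    def test_se_propagation_of_log(self):
        m = delta_delta_g(Measurement(1e-5, 1e-6), Measurement(1e-6, 1e-7))
        assert m.se == pytest.approx(RT * math.sqrt(0.01 + 0.01), rel=1e-9)


class TestPhiValue:
    def test_half(self):
        """k_ass halves while Kd quadruples: phi = ln2 / ln4 = 0.5."""
        m = phi_value(Measurement(20.0), Measurement(10.0),
                      Measurement(4e-6), Measurement(1e-6))
        assert m.value == pytest.approx(0.5, rel=1e-12)

    def test_zero_when_association_unchanged(self):
        m = phi_value(Measurement(1e6), Measurement(1e6),
                      Measurement(5e-6), Measurement(1e-6))
        assert m.value == 0.0

    def test_negative_when_mutation_speeds_association(self):
        m = phi_value(Measurement(1e6), Measurement(1.3e6),
                      Measurement(3e-6), Measurement(1e-6))
        assert m.value < 0

    def test_undefined_for_equal_kd(self):
        with pytest.raises(UndefinedPhiError):
            phi_value(Measurement(2e6), Measurement(1e6),
                      Measurement(1e-6), Measurement(1e-6))

    def test_unit_rescaling_invariance(self):
        """Phi depends only on ratios: common rescaling leaves it unchanged."""
        args = (20.0, 10.0, 4e-6, 1e-6)
        base = phi_value(*(Measurement(a) for a in args))
        for scale_k, scale_c in ((1e3, 1.0), (1.0, 1e6), (60.0, 1e9)):
            scaled = phi_value(
                Measurement(args[0] * scale_k), Measurement(args[1] * scale_k),
                Measurement(args[2] * scale_c), Measurement(args[3] * scale_c),
            )
            assert scaled.value == pytest.approx(base.value, rel=1e-12)

    def test_zero_numerator_se_limit(self):
        m = phi_value(Measurement(1e6, 1e5), Measurement(1e6, 1e5),
                      Measurement(1e-5), Measurement(1e-6))
        assert m.value == 0.0
        assert m.se == pytest.approx(math.sqrt(2) * 0.1 / math.log(10), rel=1e-9)


class TestMonteCarloPropagation:
    """Delta-method SEs vs sampled propagation (small-scale unit check;
    the full-resolution validation lives in the acceptance suite)."""

    def test_phi_se_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        n = 30_000
        rel = 0.05
        ka_ref, ka_mut, kd_mut, kd_ref = 2e6, 1.2e6, 6e-6, 1e-6
        analytic = phi_value(
            Measurement(ka_ref, rel * ka_ref), Measurement(ka_mut, rel * ka_mut),
            Measurement(kd_mut, rel * kd_mut), Measurement(kd_ref, rel * kd_ref),
        )
        samples = np.log(
            rng.normal(ka_ref, rel * ka_ref, n) / rng.normal(ka_mut, rel * ka_mut, n)
        ) / np.log(
            rng.normal(kd_mut, rel * kd_mut, n) / rng.normal(kd_ref, rel * kd_ref, n)
        )
        assert analytic.se == pytest.approx(np.std(samples), rel=0.10)

    def test_phi_average_se_accounts_for_shared_numerator(self):
        """Both phi branches share ln(k_ass ratio); the SE of their average
        must match a Monte Carlo in which that numerator is drawn once."""
        from phibind.phi_analysis import phi_average_correlated

        rng = np.random.default_rng(8)
        n = 50_000
        rel = 0.04
        ka_ref, ka_mut = 1e6, 8e5
        kdiss_ref, kdiss_mut = 0.5, 2.0
        kde_ref, kde_mut = 5e-7, 2.4e-6

        def draw(m):
            return rng.normal(m, rel * m, n)

        a = np.log(draw(ka_ref) / draw(ka_mut))
        b_e = np.log(draw(kde_mut) / draw(kde_ref))
        c = np.log(draw(kdiss_mut) / draw(kdiss_ref))
        phi_avg = 0.5 * a * (1 / b_e + 1 / (c + a))
        analytic = phi_average_correlated(
            sigma_a2=2 * rel**2,
            num=math.log(ka_ref / ka_mut),
            den_e=math.log(kde_mut / kde_ref),
            sigma_e2=2 * rel**2,
            den_k=math.log(kdiss_mut * ka_ref / (kdiss_ref * ka_mut)),
            sigma_c2=2 * rel**2,
        )
        assert analytic.value == pytest.approx(np.mean(phi_avg), abs=0.01)
        assert analytic.se == pytest.approx(np.std(phi_avg), rel=0.10)
        # the independent-branch half-width combination underestimates here
        from phibind.phi_analysis import _average_phi, phi_value

        naive = _average_phi(
            phi_value(Measurement(ka_ref, rel * ka_ref),
                      Measurement(ka_mut, rel * ka_mut),
                      Measurement(kde_mut, rel * kde_mut),
                      Measurement(kde_ref, rel * kde_ref)),
            phi_value(Measurement(ka_ref, rel * ka_ref),
                      Measurement(ka_mut, rel * ka_mut),
                      kd_kin(Measurement(kdiss_mut, rel * kdiss_mut),
                             Measurement(ka_mut, rel * ka_mut)),
                      kd_kin(Measurement(kdiss_ref, rel * kdiss_ref),
                             Measurement(ka_ref, rel * ka_ref))),
        )
        assert naive.se < np.std(phi_avg)


class TestCompositeAlaGly:
    def test_identical_pair_has_zero_ddg_and_undefined_phi(self):
        ala = make_record("S10A", 1e6, 1.0, 1e-6, site_class="surface",
                          position=10)
        gly = make_record("S10G", 1e6, 1.0, 1e-6, site_class="surface",
                          position=10, substitution="A->G")
        res = composite_ala_gly(ala, gly)
        assert res.ddg_equb.value == 0.0
        assert "phi_undefined" in res.flags
        assert not apply_report_filter([res])[0].reportable

    def test_thermodynamic_cycle_additivity(self):
        """ddG(WT->A) + ddG(A->G) = ddG(WT->G) to machine precision."""
        kd_wt, kd_a, kd_g = 1e-6, 1.3e-6, 3.1e-6
        wt = Measurement(kd_wt)
        step1 = delta_delta_g(Measurement(kd_a), wt)
        step2 = delta_delta_g(Measurement(kd_g), Measurement(kd_a))
        total = delta_delta_g(Measurement(kd_g), wt)
        assert step1.value + step2.value == pytest.approx(total.value, abs=1e-14)

    def test_mismatched_positions_rejected(self):
        ala = make_record("S10A", 1e6, 1.0, 1e-6, site_class="surface", position=10)
        gly = make_record("S11G", 1e6, 1.0, 1e-6, site_class="surface",
                          position=11, substitution="A->G")
        with pytest.raises(ValueError, match="positions differ"):
            composite_ala_gly(ala, gly)

    def test_ala_is_reference_state(self):
        """The composite phi uses the alanine variant, not WT, as reference."""
        ala = make_record("S10A", 2e6, 1.0, 5e-7, site_class="surface", position=10)
        gly = make_record("S10G", 1e6, 4.0, 2e-6, site_class="surface",
                          position=10, substitution="A->G")
        res = composite_ala_gly(ala, gly)
        expected = phi_value(Measurement(2e6), Measurement(1e6),
                             Measurement(2e-6), Measurement(5e-7))
        assert res.phi_equb.value == pytest.approx(expected.value, rel=1e-12)


class TestReportFilter:
    def _result(self, ddg_e, ddg_k):
        return PhiResult(
            variant_id="x",
            ddg_equb=Measurement(ddg_e, 0.05),
            ddg_kin=Measurement(ddg_k, 0.05),
            phi_equb=Measurement(0.2, 0.05),
            phi_kin=Measurement(0.2, 0.05),
            phi_average=Measurement(0.2, 0.05),
        )

    def test_both_branches_must_pass(self):
        assert not apply_report_filter([self._result(0.50, 0.30)])[0].reportable

    def test_inclusive_boundary(self):
        assert apply_report_filter([self._result(0.34, 0.34)])[0].reportable

    def test_stabilizing_never_reportable(self):
        assert not apply_report_filter([self._result(-0.8, -0.9)])[0].reportable

    def test_count_matches_construction(self):
        """A panel built with a known number above threshold reports exactly it."""
        rng = np.random.default_rng(3)
        ddgs = list(rng.uniform(0.4, 2.0, 11)) + list(rng.uniform(0.0, 0.30, 9))
        results = apply_report_filter([self._result(d, d) for d in ddgs])
        assert sum(r.reportable for r in results) == 11


class TestConsistency:
    def test_identical_values_consistent(self):
        m = Measurement(1.0, 0.1)
        assert consistency_check(m, m)

    def test_three_sigma_difference_flagged(self):
        a = Measurement(1.0, 0.1)
        b = Measurement(1.0 + 3 * math.hypot(0.1, 0.1), 0.1)
        assert not consistency_check(a, b)

    def test_noiseless_self_consistent(self):
        a = Measurement(0.75, 0.0)
        assert consistency_check(a, Measurement(0.75, 0.0))


class TestLfe:
    def _panel(self, phi):
        """Panel whose mutational effect is split by a common phi."""
        wt = make_record("WT", 1e6, 0.5, 5e-7, substitution="wild-type")
        records = [wt]
        for i, factor in enumerate((2.0, 5.0, 12.0, 30.0)):
            kd = 5e-7 * factor
            k_ass = 1e6 * factor ** (-phi)
            records.append(
                make_record(f"M{i}", k_ass, kd * k_ass, kd, position=i + 2)
            )
        return records

    def test_all_effect_in_dissociation(self):
        _, slopes = lfe_table(self._panel(phi=0.0))
        assert slopes["k_diss"][0] == pytest.approx(1.0, abs=1e-9)
        assert slopes["k_ass_fast"][0] == pytest.approx(0.0, abs=1e-9)

    def test_all_effect_in_association(self):
        _, slopes = lfe_table(self._panel(phi=1.0))
        assert slopes["k_ass_fast"][0] == pytest.approx(-1.0, abs=1e-9)
        assert slopes["k_diss"][0] == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_points_rejected(self):
        wt = make_record("WT", 1e6, 0.5, 5e-7, substitution="wild-type")
        with pytest.raises(ValueError, match=">= 3"):
            lfe_table([wt])


class TestCompareKd:
    def test_two_state_exact_agreement(self):
        records = [
            make_record("WT", 1e6, 0.5, 5e-7, substitution="wild-type"),
            make_record("M1", 1e6, 2.0, 2e-6, position=2),
        ]
        table, frac = compare_kd(records)
        assert np.allclose(table["ratio"], 1.0)
        assert frac == 1.0

    def test_three_state_worked_scheme_offset(self, worked_scheme):
        """Kinetic Kd runs ~14% below equilibrium Kd for the worked scheme."""
        from phibind import apparent_koff, equilibrium_kd

        kd_eq = equilibrium_kd(worked_scheme)
        rec = make_record("WT", worked_scheme.k_on, apparent_koff(worked_scheme),
                          kd_eq, rel_se=0.05, substitution="wild-type")
        table, _ = compare_kd([rec])
        assert table["ratio"].iloc[0] == pytest.approx(0.857, abs=5e-3)
        assert bool(table["covers_unity"].iloc[0])  # within the noise CI

    def test_weak_affinity_variant_has_widest_ci(self):
        records = [
            make_record("WT", 1e6, 0.5, 5e-7, rel_se=0.02, substitution="wild-type"),
            make_record("tight", 1e6, 1.0, 1e-6, rel_se=0.02, position=2),
            make_record("weak", 1e6, 30.0, 3e-5, rel_se=0.20, position=3),
        ]
        table = compare_kd(records)[0].set_index("variant_id")
        widths = table["ci_hi"] - table["ci_lo"]
        assert widths["weak"] == widths.max()


class TestClassification:
    def test_bands(self):
        cases = [
            (Measurement(-0.15, 0.05), "nonnative_candidate"),
            (Measurement(0.35, 0.10), "weakly_structured"),
            (Measurement(0.05, 0.02), "unstructured"),
            (Measurement(0.70, 0.10), "structured"),
            (Measurement(-0.05, 0.10), "unstructured"),  # negative but within SE of 0
        ]
        for phi, expected in cases:
            res = PhiResult(variant_id="x", phi_average=phi)
            assert classify_transition_state(res) == expected

    def test_custom_thresholds(self):
        res = PhiResult(variant_id="x", phi_average=Measurement(0.45, 0.01))
        th = ClassificationThresholds(weak=0.4)
        assert classify_transition_state(res, th) == "structured"

    def test_kink_region_negative_patch_summarized(self):
        """Negative-phi kink variants surface as a nonnative patch."""
        variants, results = [], []
        spec = [("A1", "helix_A", 0.25), ("K1", "kink", -0.15),
                ("K2", "kink", -0.10), ("B1", "helix_B", 0.3)]
        for vid, region, phi in spec:
            variants.append(make_record(vid, 1e6, 1.0, 1e-6, region=region,
                                        position=len(variants) + 1))
            res = PhiResult(
                variant_id=vid, phi_average=Measurement(phi, 0.03),
                ddg_equb=Measurement(1.0, 0.05), ddg_kin=Measurement(1.0, 0.05),
                reportable=True, consistent=True,
            )
            res.ts_class = classify_transition_state(res)
            results.append(res)
        summary = region_summary(results, variants).set_index("region")
        assert summary.loc["kink", "n_nonnative"] == 2
        assert summary.loc["kink", "phi_max"] < 0
        assert summary.loc["helix_A", "n_nonnative"] == 0


class TestPhiForVariant:
    def test_branches_agree_when_kds_agree(self):
        wt = make_record("WT", 1e6, 0.5, 5e-7, substitution="wild-type")
        mut = make_record("M1", 8e5, 3.0, 3.75e-6, position=2)
        res = phi_for_variant(mut, wt)
        # kd_kin == kd_equb for both records by construction
        assert res.phi_equb.value == pytest.approx(res.phi_kin.value, rel=1e-9)
        assert res.phi_average.value == pytest.approx(res.phi_equb.value, rel=1e-9)

    def test_unusable_input_flagged(self):
        wt = make_record("WT", 1e6, 0.5, 5e-7, substitution="wild-type")
        mut = make_record("M1", 8e5, 3.0, 3.75e-6, position=2)
        mut.rates.usable = False
        res = phi_for_variant(mut, wt)
        assert "unusable_input" in res.flags
        assert res.phi_average is None
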