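"""Cohort formation, NCP power machinery and the design curves."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lodsim import (
    cases_needed,
    design_curves,
    effect_from_frequencies,
    form_cases,
    ncp,
    sample_controls,
    statistical_power,
)


class TestFormCases:
    def test_zero_incidence_raises_with_max_achieved(self, small_spec):
        from lodsim import MortalityTable, PopulationState, run_simulation
        from lodsim.aging import MAX_AGE
        from lodsim.incidence import IncidenceModel

        state = PopulationState(genotypes=None, prs=np.ones(1000))
        trace = run_simulation(
            state,
            IncidenceModel("null", lambda t: 0.0),
            MortalityTable(np.zeros(MAX_AGE + 1)),
            seed=0,
        )
        with pytest.raises(ValueError, match="maximum achieved"):
            form_cases(state, trace)

    def test_mid_age_is_prevalence_crossing(self, small_sim):
        state, trace, _ = small_sim
        ids, mid_age = form_cases(state, trace)
        cum = trace.cumulative_incidence_curve
        assert cum[mid_age] >= 0.0025
        assert mid_age == 0 or cum[mid_age - 1] < 0.0025
        # cases all diagnosed within the 10-year window ending at mid_age
        dx = state.age_at_diagnosis[ids]
        assert np.all((dx > mid_age - 10) & (dx <= mid_age))

    def test_synthetic_crossing_age_by_construction(self):
        """A hazard pulse at one age puts the crossing exactly there."""
        from lodsim import MortalityTable, PopulationState, run_simulation
        from lodsim.aging import MAX_AGE
        from lodsim.incidence import IncidenceModel

        pulse = IncidenceModel("pulse", lambda t: 0.01 if t == 47 else 0.0)
        state = PopulationState(genotypes=None, prs=np.ones(10_000))
        trace = run_simulation(state, pulse, MortalityTable(np.zeros(MAX_AGE + 1)), seed=3)
        _, mid_age = form_cases(state, trace)
        assert mid_age == 47


class TestSampleControls:
    def test_full_pool_returned(self, small_sim):
        state, trace, _ = small_sim
        pool = int(state.unaffected_alive_at(60).sum())
        ids = sample_controls(state, 60, pool, seed=1)
        assert len(ids) == pool

    def test_oversized_request_reports_pool(self, small_sim):
        state, _, _ = small_sim
        with pytest.raises(ValueError, match="unaffected"):
            sample_controls(state, 60, 10**9, seed=1)

    def test_sample_mean_prs_matches_pool(self, small_sim):
        state, _, _ = small_sim
        pool = np.flatnonzero(state.unaffected_alive_at(60))
        ids = sample_controls(state, 60, 2000, seed=5)
        se = state.prs[pool].std() / math.sqrt(2000)
        assert abs(state.prs[ids].mean() - state.prs[pool].mean()) < 3 * se

    def test_older_controls_have_lower_mean_prs(self, big_sim):
        state, _, _ = big_sim
        young = sample_controls(state, 45, 3000, seed=7)
        old = sample_controls(state, 85, 3000, seed=8)
        assert state.prs[old].mean() < state.prs[young].mean()


class TestEffectFromFrequencies:
    def test_equal_frequencies_null(self):
        beta, pooled = effect_from_frequencies(0.5, 0.5)
        assert beta == 0.0
        assert pooled == 0.5

    def test_known_value(self):
        beta, pooled = effect_from_frequencies(0.55, 0.50)
        assert beta == pytest.approx(0.20067, abs=1e-5)
        assert pooled == pytest.approx(0.525)

    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_antisymmetry(self, fa, fb):
        b1, p1 = effect_from_frequencies(fa, fb)
        b2, p2 = effect_from_frequencies(fb, fa)
        assert b1 == pytest.approx(-b2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_frequency_rejected(self):
        for bad in ((0.0, 0.5), (0.5, 1.0)):
            with pytest.raises(ValueError):
                effect_from_frequencies(*bad)


class TestNcp:
    def test_known_value(self):
        assert ncp(10_000, 0.5, 0.5, 0.1397619) == pytest.approx(24.417, abs=1e-3)

    def test_null_effect(self):
        assert ncp(1000, 0.5, 0.3, 0.0) == 0.0

    def test_maximized_at_balanced_design(self):
        thetas = np.linspace(0.05, 0.95, 19)
        lams = [ncp(1000, t, 0.3, 0.1) for t in thetas]
        assert thetas[int(np.argmax(lams))] == pytest.approx(0.5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ncp(0, 0.5, 0.3, 0.1)
        with pytest.raises(ValueError):
            ncp(100, 1.0, 0.3, 0.1)
        with pytest.raises(ValueError):
            ncp(100, 0.5, 0.0, 0.1)


class TestStatisticalPower:
    def test_null_ncp_gives_significance_level(self):
        for n in (100, 10_000):
            assert statistical_power(0.0, n) == pytest.approx(5e-8, rel=1e-6)

    def test_monotone_in_ncp(self):
        powers = [statistical_power(lam, 10_000) for lam in (1.0, 5.0, 20.0, 40.0, 80.0)]
        assert np.all(np.diff(powers) > 0)

    def test_eighty_percent_point(self):
        # sqrt(lambda) = z(1 - 2.5e-8) + z(0.8) gives lambda ~ 39.60
        assert statistical_power(39.60, 10**6) == pytest.approx(0.80, abs=0.01)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            statistical_power(10.0, 4)

    @pytest.mark.parametrize("n", [10_000, 100_000, 1_000_000])
    def test_matches_noncentral_chi2_oracle(self, n):
        """Large-sample equivalence of the F and chi-square formulations."""
        crit = stats.chi2.isf(5e-8, 1)
        for lam in (1.0, 10.0, 25.0, 39.6, 60.0):
            oracle = stats.ncx2.sf(crit, 1, lam)
            assert statistical_power(lam, n) == pytest.approx(oracle, abs=0.005)


class TestCasesNeeded:
    @staticmethod
    def _frequencies_for(beta, pooled=0.5):
        # symmetric case/control frequencies giving the target allelic log-OR
        half = 1.0 / (1.0 + math.exp(-beta / 2.0))
        return half, 1.0 - half

    def test_reference_point(self):
        """Near the closed-form inversion lambda* ~ 39.60 -> ~8109 cases.

        The normal-approximation oracle gives 8109.4; the exact
        noncentral-F bisection lands a fraction of a percent above it
        (the F and chi-square formulations differ by <0.001 in power).
        """
        f_case, f_ctrl = self._frequencies_for(math.log(1.15))
        assert cases_needed(f_case, f_ctrl) == pytest.approx(8109, rel=2e-3)

    def test_round_trip_with_power(self):
        f_case, f_ctrl = self._frequencies_for(0.1)
        n_cases = cases_needed(f_case, f_ctrl)
        beta, pooled = effect_from_frequencies(f_case, f_ctrl)
        total = int(round(n_cases / 0.5))
        assert statistical_power(ncp(total, 0.5, pooled, beta), total) >= 0.8
        assert statistical_power(ncp(total - 2, 0.5, pooled, beta), total - 2) < 0.8

    def test_doubling_effect_quarters_sample(self):
        small = cases_needed(*self._frequencies_for(0.05))
        large = cases_needed(*self._frequencies_for(0.10))
        assert small / large == pytest.approx(4.0, rel=0.02)

    def test_equal_frequencies_rejected(self):
        with pytest.raises(ValueError):
            cases_needed(0.3, 0.3)


class TestDesignCurves:
    def test_multiple_is_one_at_youngest_age(self, big_sim):
        state, trace, spec = big_sim
        for design in ("age_matched", "young_cases_old_controls"):
            curve = design_curves(state, trace, spec, design)
            first = curve.table.iloc[0]
            assert first.control_mid_age == curve.case_mid_age
            assert first.multiple_vs_youngest == pytest.approx(1.0)

    def test_designs_share_first_point(self, big_sim):
        state, trace, spec = big_sim
        am = design_curves(state, trace, spec, "age_matched").table.iloc[0]
        yo = design_curves(state, trace, spec, "young_cases_old_controls").table.iloc[0]
        assert am.n_cases_80pct == yo.n_cases_80pct
        assert am.f_case == yo.f_case and am.f_ctrl == yo.f_ctrl

    def test_curves_end_at_pool_threshold(self, big_sim):
        state, trace, spec = big_sim
        curve = design_curves(state, trace, spec, "young_cases_old_controls")
        last = int(curve.table.control_mid_age.max())
        thr = 0.0025 * trace.n_initial
        assert state.unaffected_alive_at(last).sum() >= thr
        assert state.unaffected_alive_at(last + 1).sum() < thr

    def test_risk_alleles_enriched_in_young_cases(self, big_sim):
        state, trace, spec = big_sim
        curve = design_curves(state, trace, spec, "young_cases_old_controls", cells="all")
        young = curve.table[curve.table.control_mid_age == curve.case_mid_age]
        assert np.all(young.f_case.to_numpy() > young.f_ctrl.to_numpy())

    def test_unknown_design_rejected(self, big_sim):
        state, trace, spec = big_sim
        with pytest.raises(ValueError):
            design_curves(state, trace, spec, "case_only")
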