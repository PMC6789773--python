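"""The yearly aging loop: diagnosis selection, mortality, conservation."""

import numpy as np
import pytest
from scipy import stats

from lodsim import (
    IncidenceModel,
    MortalityTable,
    PopulationState,
    cumulative_incidence,
    gompertz_makeham_table,
    run_simulation,
    simulate_year,
)
from lodsim.incidence import MAX_AGE, logistic_incidence


def _flat_hazard(p):
    return IncidenceModel("flat", lambda t: p, {"p": p})


def _no_mortality():
    return MortalityTable(np.zeros(MAX_AGE + 1), name="immortal")


def _equal_prs_state(n):
    return PopulationState(genotypes=None, prs=np.ones(n))


class TestSimulateYear:
    def test_zero_hazard_only_mortality(self):
        state = _equal_prs_state(1000)
        rec = simulate_year(
            state, _flat_hazard(0.0), MortalityTable(np.full(MAX_AGE + 1, 0.1)), np.random.default_rng(0)
        )
        assert len(rec.newly_diagnosed) == 0
        assert len(rec.newly_dead) > 0
        assert state.current_age == 1

    def test_equal_prs_selection_is_uniform(self):
        """With identical scores the weighted draw must be index-uniform."""
        n, k_frac = 20_000, 0.1
        state = _equal_prs_state(n)
        rec = simulate_year(
            state, _flat_hazard(k_frac), _no_mortality(), np.random.default_rng(42)
        )
        chosen = rec.newly_diagnosed
        counts, _ = np.histogram(chosen, bins=10, range=(0, n))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_diagnosed_have_higher_prs_than_remaining(self, small_sim):
        _, trace, _ = small_sim
        mask = trace.n_newly_diagnosed >= 100
        assert mask.sum() > 10
        assert np.all(
            trace.mean_prs_newly_diagnosed[mask] > trace.mean_prs_unaffected[mask]
        )

    def test_excess_diagnosis_request_truncates_with_warning(self):
        state = _equal_prs_state(10)
        with pytest.warns(UserWarning, match="diagnoses"):
            rec = simulate_year(
                state, _flat_hazard(1.0), _no_mortality(), np.random.default_rng(1), carry=5.0
            )
        assert len(rec.newly_diagnosed) == 10

    def test_fractional_carry_accumulates(self):
        """A hazard of 0.0006 on 1000 individuals diagnoses ~3 over 5 years."""
        state = _equal_prs_state(1000)
        carry, total = 0.0, 0
        for _ in range(5):
            rec = simulate_year(
                state, _flat_hazard(0.0006), _no_mortality(), np.random.default_rng(2), carry=carry
            )
            carry = rec.carry
            total += len(rec.newly_diagnosed)
        assert total in (2, 3)  # floor accumulation of 5 * 0.6


class TestRunSimulation:
    def test_zero_incidence_gives_zero_cumulative(self):
        state = _equal_prs_state(2000)
        trace = run_simulation(state, _flat_hazard(0.0), gompertz_makeham_table(), seed=7)
        assert np.all(trace.cumulative_incidence_curve == 0)

    def test_conservation_every_age(self, small_sim):
        state, trace, _ = small_sim
        dead_unaffected = trace.n_dead_total
        assert np.all(
            trace.n_unaffected_alive
            + trace.n_diagnosed_total
            - _diag_dead(state, trace)
            + dead_unaffected
            == trace.n_initial
        )

    def test_identical_seeds_identical_traces(self, small_spec):
        inc = logistic_incidence("x", 0.02, 0.2, 40)
        mort = gompertz_makeham_table()
        traces = []
        for _ in range(2):
            state = PopulationState.from_architecture(small_spec, 5000, 77)
            traces.append(run_simulation(state, inc, mort, seed=99, max_age=80))
        a, b = traces
        assert np.array_equal(a.n_newly_diagnosed, b.n_newly_diagnosed)
        assert np.array_equal(a.n_dead_total, b.n_dead_total)
        assert np.array_equal(a.freq_unaffected, b.freq_unaffected, equal_nan=True)

    def test_unaffected_pool_allele_frequencies_non_increasing(self, big_sim):
        """Risk alleles deplete from the aging unaffected pool at every SNP."""
        state, trace, spec = big_sim
        thr = 0.0025 * trace.n_initial
        last = int(trace.ages[trace.n_unaffected_alive >= thr][-1])
        f = trace.freq_unaffected[: last + 1]
        total_drop = f[0] - f[last]
        # every SNP declines up to binomial noise of the final pool, and the
        # decline is overwhelmingly real across the architecture
        se_last = np.sqrt(f[0] * (1 - f[0]) / (2 * trace.n_unaffected_alive[last]))
        assert np.all(total_drop > -4 * se_last)
        # pooling the SNPs of each (MAF, OR) cell averages the noise away:
        # every cell's mean frequency declines
        from lodsim.power import _fast_cell_index

        cell = _fast_cell_index(spec)
        cell_drop = np.array([total_drop[cell == c].mean() for c in range(25)])
        assert np.all(cell_drop > 0)
        # yearly wiggles stay within binomial sampling noise of the pool
        pool = trace.n_unaffected_alive[: last + 1, None]
        se = np.sqrt(f[:-1] * (1 - f[:-1]) / (2 * pool[:-1]))
        assert np.all(np.diff(f, axis=0) < 5 * se)

    def test_null_weighting_preserves_pool_frequencies(self, null_sim):
        """PRS-blind removal leaves unaffected-pool frequencies flat."""
        state, trace, spec = null_sim
        thr = 0.0025 * trace.n_initial
        last = int(trace.ages[trace.n_unaffected_alive >= thr][-1])
        f = trace.freq_unaffected[: last + 1]
        pool = trace.n_unaffected_alive[last]
        se = np.sqrt(spec.mafs * (1 - spec.mafs) / (2 * pool))
        assert np.mean(np.abs(f[last] - f[0]) < 4 * se) > 0.99


class TestCumulativeIncidence:
    def test_definition_and_monotonicity(self, small_sim):
        _, trace, _ = small_sim
        cum = trace.cumulative_incidence_curve
        assert np.all(np.diff(cum) >= 0)
        assert cum[-1] == pytest.approx(trace.n_newly_diagnosed.sum() / trace.n_initial)
        assert cumulative_incidence(trace, 0) == cum[0]

    def test_out_of_range_age_rejected(self, small_sim):
        _, trace, _ = small_sim
        with pytest.raises(ValueError):
            cumulative_incidence(trace, 500)


def _diag_dead(state, trace):
    """Diagnosed-then-dead count by the end of each traced age."""
    dx, dd = state.age_at_diagnosis, state.age_at_death
    both = (dx >= 0) & (dd >= 0)
    return np.array([np.sum(both & (dd <= t)) for t in trace.ages])
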