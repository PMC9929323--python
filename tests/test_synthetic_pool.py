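"""Forward model: hazards, two-state kinetics, count simulation, FASTQ."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from uvpool import (
    DoseSchedule,
    PhotophysicsParams,
    PoolSpec,
    emit_fastq,
    index_of,
    intact_fraction,
    pool_hazards,
    seq_of,
    simulate_counts,
    strand_hazard,
)
from uvpool.read_counting import ReadFilterConfig, count_files


class TestStrandHazard:
    def test_zero_yields_give_zero_hazard(self):
        params = PhotophysicsParams(phi=np.zeros((4, 4)))
        assert strand_hazard("ACGTACGT", "ACAC", params) == 0.0

    def test_poly_t_octamer_enumerates_nine_pairs(self):
        # CT junction + 7 internal TT + TA junction (zero) = 0.158
        params = PhotophysicsParams.from_yields(
            {"TT": 0.021, "CT": 0.011, "TC": 0.011}, q=0.0
        )
        h = strand_hazard("TTTTTTTT", "ACAC", params)
        assert h == pytest.approx(7 * 0.021 + 0.011, abs=1e-12)

    def test_guanine_quench_reduces_pyrimidine_dimers(self):
        params = PhotophysicsParams.from_yields({"TT": 0.02}, q=0.5)
        # GTTG: internal TT flanked by two G -> factor (1-q)^2
        h_quenched = strand_hazard("AAGTTGAA", "ACAC", params)
        h_free = strand_hazard("AAATTAAA", "ACAC", params)
        assert h_quenched == pytest.approx(0.02 * 0.25, abs=1e-12)
        assert h_free == pytest.approx(0.02, abs=1e-12)

    def test_vectorized_pool_hazards_match_scalar(self, canonical_params, rng):
        H = pool_hazards(canonical_params)
        for i in rng.integers(0, 4**8, size=25):
            s = seq_of(int(i), 8)
            assert H[i] == pytest.approx(
                strand_hazard(s, "ACAC", canonical_params), abs=1e-12
            )


class TestIntactFraction:
    def test_reduces_to_exponential_without_reversal(self):
        D = np.linspace(0, 500, 11)
        np.testing.assert_allclose(
            intact_fraction(0.03, 0.0, 0.0, D), np.exp(-0.03 * D), rtol=1e-12
        )

    def test_unit_at_zero_dose(self):
        assert intact_fraction(0.5, 0.01, 0.002, 0.0) == 1.0

    def test_stationary_state_without_sink(self):
        # conservative two-state system: I(inf) = rho / (h + rho)
        h, rho = 0.05, 0.01
        assert intact_fraction(h, rho, 0.0, 1e6) == pytest.approx(
            rho / (h + rho), rel=1e-9
        )

    def test_matches_numerical_ode_integration(self, rng):
        """Closed form vs generic ODE solver on random parameter draws."""
        D_grid = np.linspace(0.0, 500.0, 21)
        for _ in range(20):
            h, rho, sigma = rng.uniform(0, 0.2, 3)

            def rhs(_, y):
                return [-h * y[0] + rho * y[1], h * y[0] - (rho + sigma) * y[1]]

            num = solve_ivp(
                rhs, (0, 500.0), [1.0, 0.0], t_eval=D_grid, rtol=1e-11, atol=1e-12
            )
            np.testing.assert_allclose(
                intact_fraction(h, rho, sigma, D_grid), num.y[0], atol=1e-8
            )

    def test_monotone_and_bounded(self, rng):
        D = np.linspace(0, 500, 50)
        for _ in range(10):
            h, rho, sigma = rng.uniform(0, 0.3, 3)
            I = intact_fraction(h, rho, sigma, D)
            assert np.all((0.0 <= I) & (I <= 1.0))
            if rho == 0.0:
                assert np.all(np.diff(I) <= 0)
        # explicitly: no reversal -> non-increasing
        I0 = intact_fraction(0.07, 0.0, 0.0, D)
        assert np.all(np.diff(I0) <= 0)

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            intact_fraction(-0.1, 0.0, 0.0, 1.0)


class TestSimulateCounts:
    def test_multinomial_closure_and_determinism(self, canonical_params):
        pool = PoolSpec(depth=50_000)
        schedule = DoseSchedule.log_spaced(5, 100.0)
        t1 = simulate_counts(pool, canonical_params, schedule, seed=3)
        t2 = simulate_counts(pool, canonical_params, schedule, seed=3)
        assert np.all(t1.totals == pool.depth)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        t3 = simulate_counts(pool, canonical_params, schedule, seed=4)
        assert np.any(t3.counts != t1.counts)

    def test_zero_yields_give_dose_independent_frequencies(self):
        params = PhotophysicsParams(phi=np.zeros((4, 4)))
        pool = PoolSpec(depth=400_000, bias_sigma=0.0, random_length=4)
        schedule = DoseSchedule(doses=np.array([0.0, 100.0, 500.0]))
        table = simulate_counts(pool, params, schedule, seed=5)
        mean = pool.depth / 4**4
        # all per-class frequencies stay near the flat expectation
        z = (table.counts - mean) / np.sqrt(mean)
        assert np.abs(z).max() < 5.5

    def test_hazard_recovery_by_regression(self):
        """-log of normalized frequency regressed on dose recovers the hazard."""
        params = PhotophysicsParams.from_yields(
            {"TT": 0.021, "CT": 0.011, "TC": 0.011}, q=0.0, rho=0.0, sigma=0.0,
            epsilon=0.0,
        )
        pool = PoolSpec(depth=1_000_000, bias_sigma=0.0, random_length=4)
        schedule = DoseSchedule(doses=np.array([0.0, 5.0, 10.0, 20.0, 30.0]))
        table = simulate_counts(pool, params, schedule, seed=6)
        H = pool_hazards(params, random_length=4)
        for seq in ("TTTT", "ACTT", "AAAA"):
            i = index_of(seq)
            freq = table.counts[i] / table.totals
            y = -np.log(freq / freq[0])
            slope = linregress(schedule.doses, y).slope
            # three Monte-Carlo standard errors at this depth
            n0 = table.counts[i, 0]
            se = 3.0 / np.sqrt(n0 * schedule.doses.max())
            assert slope == pytest.approx(H[i], abs=3 * se + 0.002)

    def test_leak_through_floor(self):
        """A fully damaged class retains ~epsilon of its zero-dose share."""
        params = PhotophysicsParams.from_yields(
            {"TT": 0.5}, q=0.0, rho=0.0, sigma=0.0, epsilon=1e-3
        )
        pool = PoolSpec(depth=2_000_000, bias_sigma=0.0, random_length=4)
        schedule = DoseSchedule(doses=np.array([0.0, 400.0]))
        table = simulate_counts(pool, params, schedule, seed=7)
        i = index_of("TTTT")  # intact fraction exp(-0.5*3*400) ~ 0
        share0 = table.counts[i, 0] / table.totals[0]
        share1 = table.counts[i, 1] / table.totals[1]
        assert share1 / share0 == pytest.approx(1e-3, rel=0.35)

    def test_bias_spread_matches_spec(self, canonical_params):
        """Log-normal sigma=1 produces a max/mean ratio of order 40."""
        pool = PoolSpec(depth=2_000_000, bias_sigma=1.0)
        schedule = DoseSchedule(doses=np.array([0.0, 1.0]))
        table = simulate_counts(pool, canonical_params, schedule, seed=8)
        ratio = table.counts[:, 0].max() / table.counts[:, 0].mean()
        assert 15 < ratio < 120


class TestFastq:
    def test_roundtrip_through_counting(self, tmp_path, small_pool_table):
        files = emit_fastq(small_pool_table, tmp_path, quality=40)
        table, reports = count_files(
            [p for _, p in files], [d for d, _ in files], ReadFilterConfig()
        )
        np.testing.assert_array_equal(table.counts, small_pool_table.counts)
        assert all(r.failed_tag == 0 and r.failed_quality == 0 for r in reports)

    def test_low_quality_injection_rejected_downstream(self, tmp_path):
        from uvpool import CountTable

        counts = np.zeros((4**8, 1), dtype=np.int64)
        counts[index_of("AAGGTTCC")] = 20_000
        table = CountTable(counts=counts, doses=np.array([0.0]), k=8)
        rate = 0.02
        files = emit_fastq(
            table, tmp_path, quality=40, low_quality_rate=rate, low_quality=2, seed=9
        )
        counted, (report,) = count_files([files[0][1]], [0.0], ReadFilterConfig())
        # a read fails iff any of its 8 octamer bases was demoted
        expect_fail = 1.0 - (1.0 - rate) ** 8
        observed = report.failed_quality / report.total
        assert observed == pytest.approx(expect_fail, rel=0.15)
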