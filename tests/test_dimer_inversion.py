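"""Design rows, linear/quench inversions and the curve-level model fit."""

import numpy as np
import pytest

from uvpool import (
    DIMERS,
    DimerYieldEstimator,
    DoseSchedule,
    PhotophysicsParams,
    PoolSpec,
    all_kmers,
    design_row,
    index_of,
    invert_naive,
    invert_quench,
    marginalize,
    pool_hazards,
    relative_frequencies,
    seq_of,
    simulate_counts,
    strand_hazard,
)
from uvpool.dimer_inversion import (
    _fold_columns,
    design_matrix,
    fit_pool_model,
    predicted_hazard,
)


def _phi_vec(**yields):
    phi = np.zeros(16)
    for xy, v in yields.items():
        phi[index_of(xy)] = v
    return phi


class TestDesignRow:
    def test_dimer_class_coefficients(self):
        """TT with randomized neighbors: 1 on TT, 1/4 on each X-T and T-X."""
        row = design_row("TT", q=0.0)
        assert row[index_of("TT")] == pytest.approx(1.0 + 0.25 + 0.25)
        for x in "ACG":
            assert row[index_of(x + "T")] == pytest.approx(0.25)
            assert row[index_of("T" + x)] == pytest.approx(0.25)
        assert row[index_of("AA")] == 0.0

    def test_poly_g_tetramer_coefficients(self):
        row = design_row("GGGG", q=0.0)
        assert row[index_of("GG")] == pytest.approx(3.0 + 0.25 + 0.25)
        for x in "ACT":
            assert row[index_of(x + "G")] == pytest.approx(0.25)
            assert row[index_of("G" + x)] == pytest.approx(0.25)

    def test_full_quench_kills_guaranteed_g_adjacent_dimers(self):
        # GTTG: the internal TT is flanked by G on both sides
        row = design_row("GTTG", q=1.0)
        assert row[index_of("TT")] == 0.0

    def test_quench_counts_random_flanks_probabilistically(self):
        # internal TT of ATTA has two random-neighbor-free fixed A neighbors
        row_a = design_row("ATTA", q=0.5)
        assert row_a[index_of("TT")] == pytest.approx(1.0)
        # the boundary dimers of "TT" see one random neighbor each:
        # E(1-q)^g = 3/4 + (1-q)/4
        row_tt = design_row("TT", q=0.5)
        assert row_tt[index_of("TT")] == pytest.approx(
            (0.75 + 0.125) ** 2 + 2 * 0.25 * (0.75 + 0.125)
        )

    def test_pool_rows_reproduce_strand_hazards_for_octamers(self, rng):
        """Full-length classes have no flanks: row . phi == strand hazard."""
        params = PhotophysicsParams.default()
        phi = params.phi.reshape(-1)
        H = pool_hazards(params)
        for i in rng.integers(0, 4**8, size=10):
            s = seq_of(int(i), 8)
            row = design_row(s, params.q, context="pool")
            assert row @ phi == pytest.approx(H[i], abs=1e-12)

    def test_randomized_tt_expected_hazard(self):
        """Central TT with random neighbors: phi_TT + flank averages = 0.037."""
        phi = PhotophysicsParams.default().phi.reshape(-1)
        assert design_row("TT", q=0.0) @ phi == pytest.approx(0.037, abs=1e-12)


class TestInvertNaive:
    def test_residual_vanishes_on_composed_data(self, rng):
        """Noiseless symmetric compose -> residual at machine precision."""
        seqs = all_kmers(4)
        A = design_matrix(seqs, 0.0)
        for _ in range(5):
            half = rng.uniform(0, 0.03, 16).reshape(4, 4)
            phi = (0.5 * (half + half.T)).reshape(-1)
            mu = A @ phi
            res = invert_naive(seqs, mu, tie_pairs=True)
            assert res.residual < 1e-10
            np.testing.assert_allclose(res.phi, phi, atol=1e-12)

    def test_exact_recovery_of_tied_yields(self):
        """Symmetric yields are identified exactly by the tied inversion."""
        seqs = all_kmers(4)
        phi = PhotophysicsParams.default().phi.reshape(-1)
        mu = design_matrix(seqs, 0.0) @ phi
        res = invert_naive(seqs, mu, tie_pairs=True)
        np.testing.assert_allclose(res.phi, phi, atol=1e-12)

    def test_directional_design_is_gauge_deficient(self):
        """phi_XY -> phi_XY + c_X - c_Y telescopes to zero: rank error."""
        seqs = all_kmers(4)
        mu = design_matrix(seqs, 0.0) @ _phi_vec(TT=0.02)
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            invert_naive(seqs, mu, tie_pairs=False)

    def test_negative_gt_yield_on_quench_generated_data(self):
        """The no-quench model goes negative on G-adjacent dimers."""
        seqs = all_kmers(4)
        phi = PhotophysicsParams.default().phi.reshape(-1)
        q = 0.5
        ref = "GGGG"
        mu = (
            design_matrix(seqs, q, context="pool") @ phi
            - design_row(ref, q, context="pool") @ phi
            + design_row(ref, q, context="nearest") @ phi
        )
        res = invert_naive(seqs, mu, context="nearest", tie_pairs=True)
        assert res.tied_yield("GT") < 0
        assert res.tied_yield("TT") > 0.015

    def test_unbiased_under_noise(self, rng):
        """20% Gaussian noise on mu leaves phi_TT unbiased over replicates."""
        seqs = all_kmers(4)
        phi = PhotophysicsParams.default().phi.reshape(-1)
        A = design_matrix(seqs, 0.0)
        mu = A @ phi
        est = []
        for _ in range(200):
            noisy = mu * (1 + 0.2 * rng.standard_normal(mu.size))
            est.append(invert_naive(seqs, noisy, tie_pairs=True).yield_of("TT"))
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 0.021) < 3 * se + 1e-4


class TestInvertQuench:
    def test_nested_limit_matches_naive(self):
        """Data generated without quenching: q-hat ~ 0, phi as in naive."""
        seqs = all_kmers(4)
        phi = PhotophysicsParams.default().phi.reshape(-1)
        mu = design_matrix(seqs, 0.0) @ phi
        quench = invert_quench(seqs, mu, tie_pairs=True)
        naive = invert_naive(seqs, mu, tie_pairs=True)
        assert quench.q == pytest.approx(0.0, abs=0.02)
        np.testing.assert_allclose(quench.phi, naive.phi, atol=2e-4)

    def test_exact_recovery_with_reference_differencing(self):
        seqs = all_kmers(4)
        phi = PhotophysicsParams.default().phi.reshape(-1)
        q = 0.5
        ref = "GGGG"
        mu = (
            design_matrix(seqs, q, context="pool") @ phi
            - design_row(ref, q, context="pool") @ phi
            + design_row(ref, q, context="nearest") @ phi
        )
        res = invert_quench(seqs, mu, reference=ref, context="pool", tie_pairs=True)
        assert res.q == pytest.approx(0.5, abs=0.01)
        np.testing.assert_allclose(res.phi, phi, atol=1e-6)

    def test_quench_model_beats_naive_on_quench_data(self, rng):
        """Paired residual comparison over 20 noisy replicates."""
        seqs = all_kmers(4)
        phi = PhotophysicsParams.default().phi.reshape(-1)
        mu = design_matrix(seqs, 0.5, context="nearest") @ phi
        wins = 0
        for _ in range(20):
            noisy = mu + 2e-4 * rng.standard_normal(mu.size)
            r_q = invert_quench(seqs, noisy, tie_pairs=True).residual
            r_n = invert_naive(seqs, noisy, tie_pairs=True).residual
            wins += r_q < r_n
        assert wins == 20

    def test_flat_profile_warns_unidentifiable(self):
        seqs = all_kmers(4)
        mu = np.zeros(len(seqs))
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = invert_quench(seqs, mu, tie_pairs=True)
        assert not res.q_identifiable


@pytest.fixture(scope="module")
def fitted():
    """Moderate-depth simulation inverted with the curve-level model."""
    params = PhotophysicsParams.default()
    pool = PoolSpec(depth=300_000, bias_sigma=0.5)
    schedule = DoseSchedule.log_spaced(12, 250.0)
    table = simulate_counts(pool, params, schedule, seed=71)
    rft = relative_frequencies(marginalize(table, 4))
    res = fit_pool_model(rft, weights=table.counts[:, 0].astype(float))
    return params, res


class TestFitPoolModel:
    def test_recovers_pyrimidine_yields(self, fitted):
        params, res = fitted
        assert res.tied_yield("TT") == pytest.approx(0.021, abs=0.003)
        assert res.tied_yield("CT") == pytest.approx(0.011, abs=0.002)
        assert res.tied_yield("CC") == pytest.approx(0.006, abs=0.0015)

    def test_recovers_quench_factor(self, fitted):
        _, res = fitted
        assert res.q == pytest.approx(0.5, abs=0.1)

    def test_purine_dimers_stay_below_sensitivity_floor(self, fitted):
        """Yields simulated at zero come back below ~0.5e-3."""
        _, res = fitted
        for d in ("GT", "GC", "GA", "TA", "CA", "GG"):
            assert abs(res.tied_yield(d)) < 5e-4

    def test_estimator_wrapper_round_trip(self):
        seqs = all_kmers(4)
        phi = PhotophysicsParams.default().phi.reshape(-1)
        mu = design_matrix(seqs, 0.3) @ phi
        est = DimerYieldEstimator(model="quench", context="nearest", tie_pairs=True)
        est.fit(seqs, mu)
        np.testing.assert_allclose(est.predict(seqs), mu, atol=5e-5)
        assert est.q_ == pytest.approx(0.3, abs=0.02)


def test_fit_functional_offsets_show_mixture_flattening():
    """Fitted coefficients of flank mixtures understate the initial slope.

    Over a finite dose range a mixture of exponentials settles toward its
    slowest components, so the model-implied offset (fitted minus initial
    slope) is negative for fast heterogeneous classes and near zero for a
    homogeneous slow one.
    """
    from uvpool import fit_functional_offsets

    params = PhotophysicsParams.default()
    doses = np.concatenate([[0.0], np.geomspace(2.0, 250.0, 11)])
    seqs = ("TTTT", "CTTC", "AAAA")
    stderr = np.full((len(seqs), doses.size), 0.02)
    offsets = fit_functional_offsets(
        seqs, params.phi.reshape(-1), params.q, doses, stderr, reference="GGGG"
    )
    by_seq = dict(zip(seqs, offsets))
    assert by_seq["TTTT"] < -0.002  # strongly heterogeneous, fast
    assert abs(by_seq["AAAA"]) < 0.002  # nearly homogeneous hazard


def test_predicted_hazard_matches_row_product():
    phi = PhotophysicsParams.default().phi.reshape(-1)
    for seq in ("TT", "GGGG", "ACGT"):
        assert predicted_hazard(seq, phi, 0.4) == pytest.approx(
            design_row(seq, 0.4) @ phi
        )
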