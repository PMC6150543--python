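"""Transition-matrix construction: entry formulas, conservation, collapses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyomc.chain_models import (
    DEFAULT_C_GLOBAL,
    DEFAULT_D,
    ChainParams,
    InvalidParameterError,
    ScoreTable,
    build_basic,
    build_drift,
    build_duplication,
    build_inactivation,
    build_scored,
    karyotype_survival,
    load_score_table,
    survival_factor,
)


def unit_params(**kw):
    """Parameters with no score effect (C = mu = 1)."""
    return ChainParams(**{"C": 1.0, "mu": 1.0, **kw})


class TestBasic:
    def test_matches_printed_block_n8(self):
        # the 8x8 sub-stochastic block: diag 1-ip, off-diagonals ip/2,
        # boundary leaks p/2 (state 1) and 4p (state 8)
        p = 0.004
        ch = build_basic(unit_params(N=8, p=p))
        assert ch.T[1, 0] == pytest.approx(p)  # printed "p" in row 2
        assert ch.T[6, 7] == pytest.approx(7 * p / 2)
        assert ch.T[3, 3] == pytest.approx(1 - 4 * p)
        assert ch.death_mass[0] == pytest.approx(p / 2)
        assert ch.death_mass[7] == pytest.approx(4 * p)
        for i in range(1, 9):
            for j in range(1, 9):
                expected = (
                    1 - i * p if i == j else (i * p / 2 if abs(i - j) == 1 else 0.0)
                )
                assert ch.T[i - 1, j - 1] == pytest.approx(expected, abs=1e-15)

    def test_no_missegregation_is_identity(self):
        ch = build_basic(unit_params(N=3, p=0.0))
        assert np.array_equal(ch.T, np.eye(3))
        assert np.all(ch.death_mass == 0)

    def test_explicit_n3_matrix(self):
        ch = build_basic(unit_params(N=3, p=0.1))
        expected = np.array([[0.9, 0.05, 0], [0.1, 0.8, 0.1], [0, 0.15, 0.7]])
        np.testing.assert_allclose(ch.T, expected, atol=1e-15)
        np.testing.assert_allclose(ch.death_mass, [0.05, 0, 0.15], atol=1e-15)

    def test_rejects_p_beyond_linearized_range(self):
        with pytest.raises(InvalidParameterError, match="state"):
            build_basic(unit_params(N=8, p=0.2))


class TestDrift:
    def test_single_state(self):
        assert build_drift(1).T == pytest.approx(np.array([[-1.0]]))

    def test_n2_entries(self):
        np.testing.assert_allclose(
            build_drift(2).T, [[-1.0, 0.5], [1.0, -2.0]], atol=1e-15
        )

    @pytest.mark.parametrize("N", [1, 2, 5, 8, 16, 32])
    @pytest.mark.parametrize("p", [0.0, 1e-4, 0.01])
    def test_basic_equals_identity_plus_p_drift(self, N, p):
        M = build_basic(unit_params(N=N, p=p)).T
        J = build_drift(N).T
        np.testing.assert_allclose(M, np.eye(N) + p * J, atol=1e-15)


class TestSurvival:
    def test_scoreless_factor_is_one(self):
        params = unit_params(N=8, p=0.001)
        assert all(survival_factor(params, i) == 1.0 for i in range(1, 9))

    def test_mu_from_published_score(self):
        # chromosome 7: the largest oncogenic score
        assert math.exp(DEFAULT_D * 3.039521587) == pytest.approx(
            1.001187547, abs=1e-9
        )

    def test_even_constant_split(self):
        params = ChainParams(N=8, p=0.001, mu=1.0)
        assert survival_factor(params, 2) == pytest.approx(
            math.exp(DEFAULT_C_GLOBAL / 23), rel=1e-12
        )

    def test_zero_scores_give_global_constant(self, score_table):
        flat = ScoreTable.from_scores([0.0] * 23)
        for ploidy in (1, 2, 4):
            assert karyotype_survival(flat, [ploidy] * 23) == pytest.approx(
                math.exp(DEFAULT_C_GLOBAL), rel=1e-12
            )

    def test_diploid_survival_direct_exponential(self, score_table):
        expected = math.exp(
            score_table.c + 2 * score_table.d * sum(score_table.scores)
        )
        assert karyotype_survival(score_table, [2] * 23) == pytest.approx(
            expected, rel=1e-12
        )

    def test_factorization_over_chromosomes(self, score_table, rng):
        # Q_surv = prod_k q_k(n_k) with any split of c summing to c; the
        # identity needs mu_k = exp(d s_k) exactly, not the 9-decimal print
        import warnings

        exact = ScoreTable.from_scores(score_table.scores)
        C = exact.c_split
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for _ in range(100):
                karyotype = rng.integers(1, 9, size=23)
                product = 1.0
                for mu, n_k in zip(exact.mu, karyotype):
                    params = ChainParams(N=8, p=0.001, mu=mu, C=C)
                    product *= survival_factor(params, int(n_k))
                assert product == pytest.approx(
                    karyotype_survival(exact, karyotype), rel=1e-12
                )

    def test_warns_when_factor_exceeds_one(self):
        with pytest.warns(UserWarning, match="product chain"):
            ChainParams(N=8, p=0.001, mu=1.001, C=1.0)


class TestScored:
    def test_reduces_to_basic_without_scores(self):
        params = unit_params(N=8, p=0.0025)
        basic, scored = build_basic(params), build_scored(params)
        np.testing.assert_array_equal(basic.T, scored.T)
        # death is recomputed as 1 - q * rowsum, so only float-ulp equality
        np.testing.assert_allclose(basic.death_mass, scored.death_mass, atol=1e-15)

    def test_entrywise_formula(self):
        p, mu, C = 0.0025, 1.0004, 0.99
        ch = build_scored(ChainParams(N=8, p=p, mu=mu, C=C))
        for i in range(1, 9):
            q = C * mu**i
            assert ch.T[i - 1, i - 1] == pytest.approx((1 - i * p) * q, rel=1e-14)
            if i < 8:
                assert ch.T[i - 1, i] == pytest.approx(i * p * q / 2, rel=1e-14)

    def test_n2_hand_product(self):
        p, mu = 0.01, 1.0004
        ch = build_scored(unit_params(N=2, p=p, mu=mu))
        D = np.diag([mu, mu**2])
        M = np.array([[1 - p, p / 2], [p, 1 - 2 * p]])
        np.testing.assert_allclose(ch.T, D @ M, rtol=1e-14)

    @pytest.mark.parametrize("mu", [0.9994, 1.0, 1.0012])
    @pytest.mark.parametrize("C", [0.9, 1.0])
    def test_equals_diagonal_times_basic(self, mu, C):
        params = ChainParams(N=8, p=0.0025, mu=mu, C=C)
        D = np.diag([C * mu**i for i in range(1, 9)])
        np.testing.assert_allclose(
            build_scored(params).T, D @ build_basic(params).T, rtol=1e-14
        )


class TestDuplication:
    def test_zero_rate_collapses(self):
        params = unit_params(N=8, p=0.0025, p_gd=0.0)
        np.testing.assert_array_equal(
            build_duplication(params).T, build_basic(params).T
        )
        params2 = ChainParams(N=8, p=0.0025, mu=1.0004, C=0.99, p_gd=0.0)
        np.testing.assert_array_equal(
            build_duplication(params2, scored=True).T, build_scored(params2).T
        )

    def test_doubling_transition_and_diagonal(self):
        p, pgd = 0.0025, 0.001
        ch = build_duplication(unit_params(N=8, p=p, p_gd=pgd))
        base = build_basic(unit_params(N=8, p=p))
        assert ch.T[2, 5] == pytest.approx(pgd / 2)  # 3 -> 6
        assert ch.T[2, 2] == pytest.approx(base.T[2, 2] - pgd)

    def test_lethal_duplication_above_cap(self):
        # from 5 copies, 2i = 10 > 8: the duplicated daughter dies too, so
        # the whole p_gd event mass lands on the dead state
        p, pgd = 0.0025, 0.001
        ch = build_duplication(unit_params(N=8, p=p, p_gd=pgd))
        base = build_basic(unit_params(N=8, p=p))
        assert ch.death_mass[4] == pytest.approx(base.death_mass[4] + pgd)
        assert ch.death_mass[2] == pytest.approx(base.death_mass[2] + pgd / 2)

    def test_per_state_rates(self):
        pgd = np.array([0.0] * 2 + [0.01] * 6)  # higher rate at >= 3 copies
        ch = build_duplication(unit_params(N=8, p=0.0025, p_gd=pgd))
        assert ch.T[0, 1] == pytest.approx(0.0025 / 2)  # no gd from state 1
        assert ch.T[2, 5] == pytest.approx(0.005)
        assert ch.T[3, 7] == pytest.approx(0.005)

    def test_rejects_oversized_rates(self):
        with pytest.raises(InvalidParameterError, match="negative"):
            build_duplication(unit_params(N=8, p=0.12, p_gd=0.05))


class TestInactivation:
    def test_absorbing_states_without_events(self):
        ch = build_inactivation(unit_params(N=8, p=0.0, m_r=0.0))
        assert ch.states[:2] == ["sigma", "tau"]
        assert ch.T[0, 0] == pytest.approx(1.0)
        assert ch.T[1, 1] == pytest.approx(1.0)

    def test_printed_entries(self):
        p, m_r, N = 0.001, 1e-6, 8
        ch = build_inactivation(unit_params(N=N, p=p, m_r=m_r))
        q2 = 1.0
        no46 = (1 - p) ** 46
        assert ch.T[0, 0] == pytest.approx((no46 - 2 * m_r) * q2, rel=1e-14)
        assert ch.T[0, 1] == pytest.approx(2 * m_r * q2, rel=1e-14)
        assert ch.T[1, 0] == 0.0
        assert ch.T[1, 1] == pytest.approx((no46 - m_r) * q2, rel=1e-14)
        assert ch.T[1, 2] == pytest.approx(p / 2 * q2, rel=1e-14)
        assert ch.T[1, 3] == pytest.approx(m_r * q2, rel=1e-14)
        assert np.all(ch.T[0, 2:] == 0)
        assert np.all(ch.T[2:, :2] == 0)
        assert np.all(ch.T[1, 4:] == 0)
        # row sums follow from the listed entries
        assert ch.T[0].sum() == pytest.approx(no46 * q2, rel=1e-14)
        assert ch.T[1].sum() == pytest.approx((no46 + p / 2) * q2, rel=1e-14)

    def test_copy_number_block_is_scored(self):
        params = ChainParams(N=8, p=0.001, mu=1.0004, C=0.99, m_r=1e-5)
        ch = build_inactivation(params)
        np.testing.assert_array_equal(ch.T[2:, 2:], build_scored(params).T)

    def test_rejects_mutation_rate_above_survival(self):
        with pytest.raises(InvalidParameterError):
            build_inactivation(unit_params(N=8, p=0.05, m_r=0.3))


@settings(max_examples=60, deadline=None)
@given(
    N=st.integers(1, 12),
    p_frac=st.floats(0.0, 1.0),
    mu=st.floats(0.999, 1.002),
    C=st.floats(0.5, 1.0),
    pgd_frac=st.floats(0.0, 0.5),
    m_r=st.floats(0.0, 1e-3),
)
def test_row_conservation_everywhere(N, p_frac, mu, C, pgd_frac, m_r):
    """Every builder keeps row sum of T + death mass = 1 exactly."""
    p = p_frac / N * 0.999
    pgd = pgd_frac * (1 - N * p)
    # the sigma state requires (1-p)^46 >= 2*m_r to stay sub-stochastic
    m_r = min(m_r, 0.49 * (1 - p) ** 46)
    # keep q(i) = C*mu^i a probability so death mass stays nonnegative
    C = min(C, 1.0 / mu**N, 1.0 / mu)
    for ch in (
        build_basic(ChainParams(N=N, p=p, mu=1.0, C=1.0)),
        build_scored(ChainParams(N=N, p=p, mu=mu, C=C)),
        build_duplication(ChainParams(N=N, p=p, mu=1.0, C=1.0, p_gd=pgd)),
        build_duplication(ChainParams(N=N, p=p, mu=mu, C=C, p_gd=pgd), scored=True),
        build_inactivation(ChainParams(N=N, p=p, mu=mu, C=C, m_r=m_r)),
    ):
        np.testing.assert_allclose(
            ch.T.sum(axis=1) + ch.death_mass, 1.0, atol=1e-14
        )
        assert np.all(ch.T >= 0)
        assert np.all(ch.death_mass >= -1e-15)


def test_extensions_collapse_to_basic():
    params = unit_params(N=6, p=0.01, p_gd=0.0, m_r=0.0)
    base = build_basic(params)
    np.testing.assert_array_equal(build_scored(params).T, base.T)
    np.testing.assert_array_equal(build_duplication(params).T, base.T)
    ax = build_inactivation(params)
    np.testing.assert_array_equal(ax.T[2:, 2:], base.T)


class TestScoreTable:
    def test_builtin_rows(self, score_table):
        assert len(score_table) == 23
        assert score_table.score_for(7) == pytest.approx(3.039521587)
        assert score_table.mu_for(7) == pytest.approx(1.001187547, abs=1e-9)
        assert score_table.score_for(23) == 0.0
        assert score_table.mu_for(23) == 1.0

    def test_mu_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ScoreTable((1,), (1.0,), (2.0,))

    def test_missing_row_reported(self, tmp_path, score_table):
        rows = [
            f"{k}\t{s}\t{m}"
            for k, s, m in zip(
                score_table.chromosomes, score_table.scores, score_table.mu
            )
            if k != 15
        ]
        path = tmp_path / "scores.tsv"
        path.write_text("chromosome\tscore\tmu\n" + "\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="15"):
            load_score_table(path)

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "chromosome\tscore\tmu\n1\t0\t1\n1\t0\t1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_score_table(path)

    def test_wrong_columns_rejected(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("chrom\tscore\n1\t0\n")
        with pytest.raises(ValueError, match="columns"):
            load_score_table(path)
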