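"""Set-level permutation statistics, covariate regression, surrogates."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats as ss

from kurafit import (
    MeasureStack,
    Regressor,
    SetLevelTest,
    TimeCourseSet,
    ValidationError,
    analytic_phase,
    bonferroni_report,
    correlate_couplings,
    group_set_test,
    nonzero_set_test,
    phase_randomized_surrogates,
    phase_synchrony,
    regress_out_covariate,
    set_level_test,
    surrogate_set_test,
)
from kurafit.setstats import (
    _positions,
    _ranksum_columns,
    _signrank_columns,
    _spearman_columns,
)

from conftest import DT, make_noise_stack


def stack_from_vectors(V, r, symmetric=False, measure="K"):
    """Place per-coupling column vectors into an (s, r, r) stack."""
    s = V.shape[0]
    tensor = np.zeros((s, r, r))
    ii, jj = _positions(r, symmetric)
    tensor[:, ii, jj] = V
    if symmetric:
        tensor[:, jj, ii] = V
    return MeasureStack(
        tensor=tensor,
        measure=measure,
        subject_ids=[f"s{i:02d}" for i in range(s)],
        symmetric=symmetric,
    )


class TestRegressorContracts:
    def test_constant_score_rejected(self):
        with pytest.raises(ValidationError):
            Regressor(values=np.ones(10), kind="score")

    def test_group_must_be_binary(self):
        with pytest.raises(ValidationError):
            Regressor(values=np.array([0, 1, 2.0]), kind="group")


class TestSpearmanEngine:
    def test_matches_scipy_at_large_n(self, rng):
        V = rng.standard_normal((24, 50))
        score = rng.uniform(0, 30, 24)
        rho, p, _ = _spearman_columns(V, score, "bidirectional", None)
        for k in range(50):
            expect = ss.spearmanr(V[:, k], score)
            assert rho[k] == pytest.approx(expect.statistic, abs=1e-12)
            assert p[k] == pytest.approx(expect.pvalue, abs=1e-12)

    def test_one_sided_p_matches_scipy_alternative(self, rng):
        V = rng.standard_normal((20, 10))
        score = rng.uniform(0, 1, 20)
        for direction, alt in [("positive", "greater"), ("negative", "less")]:
            _, p, _ = _spearman_columns(V, score, direction, None)
            for k in range(10):
                expect = ss.spearmanr(V[:, k], score, alternative=alt).pvalue
                assert p[k] == pytest.approx(expect, abs=1e-12)

    def test_exact_small_n_matches_enumeration_oracle(self, rng):
        n = 6
        V = rng.standard_normal((n, 4))
        score = rng.uniform(0, 1, n)
        _, p, _ = _spearman_columns(V, score, "bidirectional", None)
        ry = ss.rankdata(score)
        for k in range(4):
            rx = ss.rankdata(V[:, k])
            obs = np.corrcoef(rx, ry)[0, 1]
            null = [
                np.corrcoef(rx, ry[list(perm)])[0, 1]
                for perm in permutations(range(n))
            ]
            oracle = np.mean(np.abs(null) >= abs(obs) - 1e-12)
            assert p[k] == pytest.approx(oracle, abs=1e-12)

    def test_outlier_exclusion_matches_manual_removal(self, rng):
        V = rng.standard_normal((24, 1))
        V[0, 0] = 25.0  # gross outlier
        score = rng.uniform(0, 30, 24)
        rho, p, n = _spearman_columns(V, score, "bidirectional", 2.0)
        assert n[0] == 23
        expect = ss.spearmanr(V[1:, 0], score[1:])
        assert rho[0] == pytest.approx(expect.statistic, abs=1e-12)
        assert p[0] == pytest.approx(expect.pvalue, abs=1e-12)


class TestCorrelateCouplings:
    def test_perfect_monotone_coupling(self, rng):
        s, r = 24, 5
        score = Regressor(rng.uniform(0, 30, s))
        V = np.tile(score.values[:, None], (1, r * (r - 1)))
        stack = stack_from_vectors(V, r)
        rho, p = correlate_couplings(stack, score, direction="positive",
                                     outlier_sd=None)
        off = ~np.eye(r, dtype=bool)
        np.testing.assert_allclose(rho[off], 1.0, atol=1e-12)
        assert np.all(p[off] < 1e-10)
        assert np.all(np.isnan(np.diag(rho)))

    def test_constant_score_rejected(self, rng):
        stack = make_noise_stack(rng, s=10, r=4)
        with pytest.raises(ValidationError):
            correlate_couplings(stack, Regressor(np.ones(10), kind="covariate"))

    def test_noisy_monotone_matches_rank_correlation_oracle(self, rng):
        s, r = 24, 5
        score = rng.uniform(0, 30, s)
        V = score[:, None] + (score.std() / 2.0) * rng.standard_normal((s, r * (r - 1)))
        stack = stack_from_vectors(V, r)
        rho, _ = correlate_couplings(stack, Regressor(score), outlier_sd=None)
        ii, jj = _positions(r, False)
        ry = ss.rankdata(score)
        for k, (i, j) in enumerate(zip(ii, jj)):
            oracle = np.corrcoef(ss.rankdata(V[:, k]), ry)[0, 1]
            assert abs(rho[i, j] - oracle) < 0.15
            assert rho[i, j] == pytest.approx(oracle, abs=1e-12)


class TestSetLevelTest:
    def test_deterministic_given_seed(self, rng):
        stack = make_noise_stack(rng, s=12, r=6)
        score = Regressor(rng.uniform(0, 30, 12))
        a = set_level_test(stack, score, n_perm=120, seed=9)
        b = set_level_test(stack, score, n_perm=120, seed=9)
        assert a.p_set == b.p_set
        np.testing.assert_array_equal(a.null_set_sizes, b.null_set_sizes)
        assert a.null_set_sizes.size == 120
        assert 0.0 < a.p_set <= 1.0

    def test_injected_dependence_detected_and_recovered(self, rng):
        # 40 of 380 couplings made monotone in the score: the set-level test
        # must reject and flag most injected positions
        s, r = 24, 20
        score = rng.uniform(0, 30, s)
        m = r * (r - 1)
        V = rng.standard_normal((s, m))
        injected = rng.choice(m, size=40, replace=False)
        z = (score - score.mean()) / score.std()
        V[:, injected] = z[:, None] + 0.15 * rng.standard_normal((s, 40))
        stack = stack_from_vectors(V, r)
        res = set_level_test(stack, Regressor(score), n_perm=200, seed=5)
        assert res.p_set < 0.05
        ii, jj = _positions(r, False)
        flagged = {(i, j) for i, j in res.significant_couplings}
        truth = {(int(ii[k]), int(jj[k])) for k in injected}
        assert len(flagged & truth) >= 30

    def test_permuted_score_behaves_as_null(self, rng):
        s, r = 24, 10
        score = rng.uniform(0, 30, s)
        p_sets = []
        for rep in range(30):
            stack = make_noise_stack(rng, s=s, r=r)
            shuffled = Regressor(rng.permutation(score))
            res = set_level_test(stack, shuffled, n_perm=100,
                                 seed=int(rng.integers(2**31)))
            p_sets.append(res.p_set)
        p_sets = np.array(p_sets)
        # roughly uniform: mass on both sides, few extreme rejections
        assert np.mean(p_sets < 0.5) == pytest.approx(0.5, abs=0.35)
        assert np.mean(p_sets < 0.05) < 0.25

    def test_symmetric_stack_counts_upper_triangle_only(self, rng):
        s, r = 12, 6
        stack = make_noise_stack(rng, s=s, r=r, symmetric=True, measure="PS")
        score = Regressor(rng.uniform(0, 1, s))
        res = set_level_test(stack, score, n_perm=100, seed=2)
        bound = r * (r - 1) // 2
        assert res.observed_set_size <= bound
        assert np.all(res.null_set_sizes <= bound)
        # reported couplings live in the upper triangle
        assert all(i < j for i, j in res.significant_couplings) or not res.significant_couplings

    def test_effect_magnitude_monotonically_lowers_p(self, rng):
        # signs of the injected dependencies are mixed, as in the simulator's
        # pattern: same-signed mass would leak into the within-subject
        # permutation null and break monotonicity
        s, r = 24, 8
        score = rng.uniform(0, 30, s)
        z = (score - score.mean()) / score.std()
        signs = np.resize([1.0, -1.0], 20)
        mean_p = []
        for effect in (0.0, 0.6, 1.5):
            ps = []
            for rep in range(4):
                V = rng.standard_normal((s, r * (r - 1)))
                V[:, :20] += effect * z[:, None] * signs[None, :]
                stack = stack_from_vectors(V, r)
                res = set_level_test(stack, Regressor(score), n_perm=100,
                                     seed=100 + rep)
                ps.append(res.p_set)
            mean_p.append(np.mean(ps))
        assert mean_p[0] > mean_p[2]
        assert mean_p[1] >= mean_p[2]

    def test_model_front_end_equivalent(self, rng):
        stack = make_noise_stack(rng, s=12, r=5)
        score = Regressor(rng.uniform(0, 30, 12))
        direct = set_level_test(stack, score, n_perm=100, seed=4)
        via_model = SetLevelTest(stack, score).fit(n_perm=100, seed=4)
        assert direct.p_set == via_model.p_set


class TestGroupSetTest:
    def test_identical_groups_not_significant(self, rng):
        large = 0
        for rep in range(10):
            stack = make_noise_stack(rng, s=12, r=6)
            res = group_set_test(stack, stack, n_perm=100,
                                 seed=int(rng.integers(2**31)))
            large += res.p_set > 0.2
        assert large >= 9

    def test_shifted_couplings_detected(self, rng):
        s, r = 24, 20
        m = r * (r - 1)
        Va = rng.standard_normal((s, m))
        Vb = rng.standard_normal((s, m))
        Vb[:, :50] += 2.0  # 2 pooled SDs
        a = stack_from_vectors(Va, r)
        b = stack_from_vectors(Vb, r)
        res = group_set_test(a, b, n_perm=150, seed=3)
        assert res.p_set < 0.05

    def test_per_coupling_p_matches_scipy_ranksums(self, rng):
        Va = rng.standard_normal((15, 12))
        Vb = rng.standard_normal((18, 12)) + 0.4
        _, p, _ = _ranksum_columns(Va, Vb, "bidirectional", None)
        for k in range(12):
            expect = ss.ranksums(Va[:, k], Vb[:, k]).pvalue
            assert p[k] == pytest.approx(expect, abs=1e-12)

    def test_mismatched_stacks_rejected(self, rng):
        a = make_noise_stack(rng, s=10, r=5)
        b = make_noise_stack(rng, s=10, r=6)
        with pytest.raises(ValidationError):
            group_set_test(a, b, seed=1)


class TestNonzeroSetTest:
    def test_symmetric_about_zero_not_significant(self, rng):
        stack = make_noise_stack(rng, s=20, r=8)
        res = nonzero_set_test(stack, n_perm=100, seed=6)
        assert res.p_set > 0.05

    def test_shifted_mean_detected(self, rng):
        s, r = 24, 20
        m = r * (r - 1)
        V = rng.standard_normal((s, m))
        V[:, :60] += 0.5
        stack = stack_from_vectors(V, r)
        res = nonzero_set_test(stack, n_perm=100, seed=8)
        assert res.p_set < 0.05

    def test_per_coupling_p_matches_scipy_wilcoxon(self, rng):
        V = rng.standard_normal((20, 10)) + 0.3
        _, p, _ = _signrank_columns(V, "bidirectional", None)
        for k in range(10):
            expect = ss.wilcoxon(V[:, k], method="approx", correction=False).pvalue
            assert p[k] == pytest.approx(expect, abs=1e-12)


class TestRegressOutCovariate:
    def test_linear_coupling_becomes_constant(self, rng):
        s, r = 20, 4
        cov = rng.uniform(20, 70, s)
        tensor = np.zeros((s, r, r))
        tensor[:, 0, 1] = 3.0 + 0.5 * cov
        stack = MeasureStack(tensor=tensor, measure="K",
                             subject_ids=[str(i) for i in range(s)], symmetric=False)
        out = regress_out_covariate(stack, Regressor(cov, name="age", kind="covariate"))
        np.testing.assert_allclose(out.tensor[:, 0, 1],
                                   np.mean(3.0 + 0.5 * cov), atol=1e-10)

    def test_orthogonal_covariate_is_identity(self, rng):
        s = 24
        stack = make_noise_stack(rng, s=s, r=4)
        cov = rng.standard_normal(s)
        ii, jj = _positions(4, False)
        V = stack.tensor[:, ii, jj]
        # orthogonalise every coupling against [1, cov]
        X = np.column_stack([np.ones(s), cov])
        V_orth = V - X @ np.linalg.lstsq(X, V, rcond=None)[0] + V.mean(axis=0)
        stack.tensor[:, ii, jj] = V_orth
        out = regress_out_covariate(stack, Regressor(cov, kind="covariate"))
        np.testing.assert_allclose(out.tensor, stack.tensor, atol=1e-10)

    def test_residuals_uncorrelated_with_covariate(self, rng):
        s = 24
        stack = make_noise_stack(rng, s=s, r=5)
        cov = rng.uniform(0, 10, s)
        out = regress_out_covariate(stack, Regressor(cov, kind="covariate"))
        ii, jj = _positions(5, False)
        V = out.tensor[:, ii, jj]
        centred = V - V.mean(axis=0)
        corr = (cov - cov.mean()) @ centred
        assert np.max(np.abs(corr) / (np.linalg.norm(cov - cov.mean())
                                      * np.linalg.norm(centred, axis=0))) < 1e-10

    def test_constant_covariate_warns_and_returns_copy(self, rng):
        stack = make_noise_stack(rng, s=10, r=4)
        with pytest.warns(UserWarning, match="constant covariate"):
            out = regress_out_covariate(
                stack, Regressor(np.full(10, 3.0), kind="covariate")
            )
        np.testing.assert_array_equal(out.tensor, stack.tensor)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,factor,significant",
        [(0.002, 6, True), (0.04, 6, False), (0.04, 1, True), (0.012, 3, True)],
    )
    def test_threshold_decisions(self, p, factor, significant):
        (row,) = bonferroni_report([("test", p)], factor)
        assert row["significant"] is significant
        assert row["p_adjusted"] == pytest.approx(min(1.0, p * factor))

    def test_factor_one_is_identity(self):
        rows = bonferroni_report([("a", 0.3), ("b", 0.04)], 1)
        assert [r["p_adjusted"] for r in rows] == [0.3, 0.04]


class TestPhaseRandomizedSurrogates:
    def test_amplitude_spectrum_preserved_and_real(self, rng):
        tc = TimeCourseSet(data=rng.standard_normal((3, 301)), dt=DT)
        (surr,) = phase_randomized_surrogates(tc, 1, seed=0)
        assert np.isrealobj(surr.data)
        mag_orig = np.abs(np.fft.rfft(tc.data, axis=1))
        mag_surr = np.abs(np.fft.rfft(surr.data, axis=1))
        np.testing.assert_allclose(mag_surr, mag_orig, rtol=1e-8)

    def test_even_length_nyquist_bin_handled(self, rng):
        tc = TimeCourseSet(data=rng.standard_normal((2, 300)), dt=DT)
        (surr,) = phase_randomized_surrogates(tc, 1, seed=1)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(surr.data, axis=1)),
            np.abs(np.fft.rfft(tc.data, axis=1)),
            rtol=1e-8,
        )

    def test_constant_series_maps_to_itself(self):
        tc = TimeCourseSet(data=np.full((2, 64), 7.5), dt=DT)
        (surr,) = phase_randomized_surrogates(tc, 1, seed=2)
        np.testing.assert_allclose(surr.data, 7.5, atol=1e-10)

    def test_phase_locking_destroyed(self, rng):
        # two strongly locked sinusoids: surrogate PS averages to ~0
        t = np.arange(300) * DT
        x = np.cos(2 * np.pi * 0.0625 * t) + 0.05 * rng.standard_normal(300)
        data = np.vstack([x, np.roll(x, 1)])
        tc = TimeCourseSet(data=data, dt=DT)
        ps_vals = []
        for surr in phase_randomized_surrogates(tc, 100, seed=3):
            aps = analytic_phase(surr, (0.05, 0.075))
            ps_vals.append(phase_synchrony(aps).values[0, 1])
        assert abs(np.mean(ps_vals)) < 0.1

    def test_surrogate_set_test_single_draw_is_degenerate(self, rng):
        s, r = 8, 4
        cohort = [
            TimeCourseSet(data=rng.standard_normal((r, 40)), dt=DT,
                          subject_id=f"s{i}")
            for i in range(s)
        ]
        score = Regressor(rng.uniform(0, 1, s))

        def builder(tcs):
            from kurafit import partial_correlation, stack_cohort
            return stack_cohort([partial_correlation(tc, band=None) for tc in tcs])

        res = surrogate_set_test(builder, cohort, score, n_surrogates=1, seed=4)
        # with the add-one correction a single surrogate yields p in {1/2, 1}
        assert res["p"] in (0.5, 1.0)
        assert res["surrogate_set_sizes"].size == 1
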