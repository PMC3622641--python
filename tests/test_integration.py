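"""Score normalization and linear / rank-based integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqgsea.integration import (
    LINEAR,
    RANK_GLB,
    RANK_SP,
    ScoreSet,
    integrate,
    integrate_linear,
    integrate_rank,
    normalize_scores,
)


def _score_set(rng, G=30, P=12, kind="DE"):
    return ScoreSet(s_obs=rng.gamma(2, 1, size=G), T=rng.gamma(2, 1, size=(G, P)), kind=kind)


class TestNormalize:
    def test_self_division_gives_one(self):
        ss = ScoreSet(s_obs=np.array([3.0]), T=np.full((1, 5), 3.0), kind="DE")
        out = normalize_scores(ss)
        assert out.s_obs[0] == 1.0

    def test_zero_mean_gene_normalized_to_zero(self):
        ss = ScoreSet(s_obs=np.array([0.0, 2.0]),
                      T=np.array([[0.0, 0.0], [2.0, 2.0]]), kind="DS")
        out = normalize_scores(ss)
        assert out.s_obs[0] == 0.0
        assert (out.T[0] == 0.0).all()

    def test_permutation_row_means_are_one(self, rng):
        out = normalize_scores(_score_set(rng))
        np.testing.assert_allclose(out.T.mean(axis=1), 1.0, atol=1e-12)

    def test_empty_permutation_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_scores(ScoreSet(s_obs=np.ones(2), T=np.ones((2, 0)), kind="DE"))


class TestLinear:
    def test_arithmetic(self):
        de = ScoreSet(s_obs=np.array([2.0]), T=np.ones((1, 3)), kind="DE")
        ds = ScoreSet(s_obs=np.array([1.0]), T=np.ones((1, 3)), kind="DS")
        out = integrate_linear(de, ds, 0.5)
        assert out.s_obs[0] == pytest.approx(1.5)

    @pytest.mark.parametrize("alpha", [-0.1, 1.1])
    def test_alpha_out_of_range_rejected(self, alpha, rng):
        with pytest.raises(ValueError, match="alpha"):
            integrate_linear(_score_set(rng), _score_set(rng, kind="DS"), alpha)

    def test_elementwise_oracle(self, rng):
        de, ds = _score_set(rng), _score_set(rng, kind="DS")
        for alpha in (0.0, 0.3, 0.7, 1.0):
            out = integrate_linear(de, ds, alpha)
            expected = np.array(
                [alpha * a + (1 - alpha) * b for a, b in zip(de.s_obs, ds.s_obs)]
            )
            np.testing.assert_allclose(out.s_obs, expected, rtol=1e-15)


class TestRank:
    def test_arithmetic(self):
        # ranks 2 and 1 for the DE/DS scores 3 and 1:
        # (0.5*2*3 + 0.5*1*1) / (0.5*2 + 0.5*1) = 3.5/1.5
        de = ScoreSet(s_obs=np.array([3.0, 1.0]), T=np.ones((2, 2)), kind="DE")
        ds = ScoreSet(s_obs=np.array([1.0, 3.0]), T=np.ones((2, 2)), kind="DS")
        out = integrate_rank(de, ds, 0.5, RANK_GLB)
        assert out.s_obs[0] == pytest.approx(3.5 / 1.5)

    def test_elementwise_oracle_both_variants(self, rng):
        from scipy.stats import rankdata

        de, ds = _score_set(rng), _score_set(rng, kind="DS")
        for variant in (RANK_SP, RANK_GLB):
            for alpha in (0.25, 0.5, 0.9):
                out = integrate_rank(de, ds, alpha, variant)
                g_de = rankdata(de.s_obs)
                g_ds = rankdata(ds.s_obs)
                exp_obs = np.array(
                    [
                        (alpha * gd * a + (1 - alpha) * gs * b)
                        / (alpha * gd + (1 - alpha) * gs)
                        for a, b, gd, gs in zip(de.s_obs, ds.s_obs, g_de, g_ds)
                    ]
                )
                np.testing.assert_allclose(out.s_obs, exp_obs, rtol=1e-12)
                # permutation columns: per-gene oracle with the variant's ranks
                for p in (0, out.s_perm.shape[1] - 1):
                    if variant == RANK_GLB:
                        rd, rs = g_de, g_ds
                    else:
                        rd = rankdata(de.T[:, p])
                        rs = rankdata(ds.T[:, p])
                    exp = (alpha * rd * de.T[:, p] + (1 - alpha) * rs * ds.T[:, p]) / (
                        alpha * rd + (1 - alpha) * rs
                    )
                    np.testing.assert_allclose(out.s_perm[:, p], exp, rtol=1e-12)

    def test_variant_name_validated(self, rng):
        with pytest.raises(ValueError, match="variant"):
            integrate_rank(_score_set(rng), _score_set(rng, kind="DS"), 0.5, "bogus")


class TestDegeneracyAndMonotonicity:
    @pytest.mark.parametrize("strategy", [LINEAR, RANK_SP, RANK_GLB])
    def test_alpha_extremes_reproduce_single_scores_exactly(self, strategy, rng):
        de, ds = _score_set(rng), _score_set(rng, kind="DS")
        at1 = integrate(de, ds, 1.0, strategy)
        np.testing.assert_array_equal(at1.s_obs, de.s_obs)
        np.testing.assert_array_equal(at1.s_perm, de.T)
        at0 = integrate(de, ds, 0.0, strategy)
        np.testing.assert_array_equal(at0.s_obs, ds.s_obs)
        np.testing.assert_array_equal(at0.s_perm, ds.T)

    @given(
        st.floats(min_value=0.05, max_value=1.0),
        st.floats(min_value=0.0, max_value=10.0),
        st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_linear_monotone_in_de_score(self, alpha, base, bump):
        """Raising one gene's normalized DE score never lowers its linear
        integrated score for any alpha > 0."""
        rng = np.random.default_rng(7)
        G = 10
        de_obs = rng.gamma(2, 1, size=G)
        ds_obs = rng.gamma(2, 1, size=G)
        T = np.ones((G, 2))
        lo = de_obs.copy()
        lo[0] = base
        hi = de_obs.copy()
        hi[0] = base + bump
        s_lo = integrate(ScoreSet(lo, T, "DE"), ScoreSet(ds_obs, T, "DS"),
                         alpha, LINEAR).s_obs[0]
        s_hi = integrate(ScoreSet(hi, T, "DE"), ScoreSet(ds_obs, T, "DS"),
                         alpha, LINEAR).s_obs[0]
        assert s_hi >= s_lo - 1e-12

    @given(st.floats(min_value=0.05, max_value=1.0),
           st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rank_monotone_at_fixed_rank(self, alpha, bump):
        """For the rank strategy the same monotonicity holds whenever the
        gene's DE rank is unchanged (here: the gene is top-ranked before
        and after the bump).  A rank jump can legitimately shift weight
        toward the smaller of the two scores, so only the fixed-rank case
        is a theorem."""
        rng = np.random.default_rng(9)
        G = 10
        de_obs = rng.gamma(2, 1, size=G)
        de_obs[0] = de_obs.max() + 1.0  # top-ranked, stays top after bump
        ds_obs = rng.gamma(2, 1, size=G)
        T = np.ones((G, 2))
        hi = de_obs.copy()
        hi[0] += bump
        for variant in (RANK_SP, RANK_GLB):
            s_lo = integrate(ScoreSet(de_obs, T, "DE"), ScoreSet(ds_obs, T, "DS"),
                             alpha, variant).s_obs[0]
            s_hi = integrate(ScoreSet(hi, T, "DE"), ScoreSet(ds_obs, T, "DS"),
                             alpha, variant).s_obs[0]
            assert s_hi >= s_lo - 1e-12
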