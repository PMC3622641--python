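"""Enrichment score, permutation machinery, significance and the weight scan."""

import numpy as np
import pandas as pd
import pytest

import seqgsea as sg
from seqgsea.gsea_engine import (
    GeneSet,
    GeneSetCollection,
    enrichment_score,
    enrichment_scores_matrix,
    generate_label_permutations,
    read_gmt,
    saturation_analysis,
    significance,
    significant_sets,
    weight_scan,
    write_gmt,
)


def es_bruteforce(scores, members, weight_exp):
    """Independent running-sum oracle: plain Python, explicit loop."""
    n = len(scores)
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    n_hit = sum(members)
    n_r = sum(abs(scores[i]) ** weight_exp for i in order if members[i])
    run, best = 0.0, -float("inf")
    for i in order:
        if members[i]:
            run += abs(scores[i]) ** weight_exp / n_r
        else:
            run -= 1.0 / (n - n_hit)
        best = max(best, run)
    return best


class TestEnrichmentScore:
    def test_single_top_gene_set(self):
        # scores [3,2,1], set = {top}: running sum (1, 0.5, 0), ES = 1
        es = enrichment_score(np.array([3.0, 2.0, 1.0]), np.array([True, False, False]))
        assert es == pytest.approx(1.0)

    def test_top_half_with_zero_tail_reaches_one(self):
        scores = np.array([5.0, 4.0, 3.0, 0.0, 0.0, 0.0])
        members = np.array([True, True, True, False, False, False])
        assert enrichment_score(scores, members) == pytest.approx(1.0)

    @pytest.mark.parametrize("weight_exp", [0.0, 1.0])
    def test_oracle_equivalence_on_random_instances(self, weight_exp, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            scores = rng.gamma(1.5, 1.0, size=n)
            k = int(rng.integers(1, n))
            members = np.zeros(n, dtype=bool)
            members[rng.choice(n, size=k, replace=False)] = True
            expected = es_bruteforce(list(scores), list(members), weight_exp)
            got = enrichment_score(scores, members, weight_exp)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_matrix_form_matches_scalar_form(self, rng):
        G, C, S = 40, 7, 6
        cols = rng.gamma(2, 1, size=(G, C))
        membership = rng.random((S, G)) < 0.3
        membership[:, 0] = True  # guarantee non-empty
        es = enrichment_scores_matrix(cols, membership)
        for s_i in range(S):
            for c in range(C):
                assert es[s_i, c] == pytest.approx(
                    enrichment_score(cols[:, c], membership[s_i]), abs=1e-12
                )

    def test_empty_and_full_sets_rejected(self):
        scores = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="zero intersection"):
            enrichment_score(scores, np.array([False, False]))
        with pytest.raises(ValueError, match="whole gene list"):
            enrichment_score(scores, np.array([True, True]))

    def test_all_zero_member_scores_give_zero_es(self):
        scores = np.array([3.0, 2.0, 0.0, 0.0])
        members = np.array([False, False, True, True])
        assert enrichment_score(scores, members) == 0.0


class TestLabelPermutations:
    def test_requested_count_and_group_sizes(self):
        rng = np.random.default_rng(0)
        masks = generate_label_permutations(12, 5, 50, rng)
        assert masks.shape == (50, 12)
        assert (masks.sum(axis=1) == 5).all()

    def test_small_design_enumerates_all(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="distinct label assignments"):
            masks = generate_label_permutations(6, 3, 100, rng)
        assert masks.shape == (20, 6)  # C(6,3)
        assert len({tuple(m) for m in masks}) == 20

    def test_sampling_without_replacement_gives_distinct_shuffles(self):
        rng = np.random.default_rng(1)
        masks = generate_label_permutations(10, 5, 200, rng)
        assert len({tuple(m) for m in masks}) == 200

    def test_determinism_under_fixed_seed(self, small_dataset):
        cd, _, _ = small_dataset
        a = sg.compute_scores(cd, n_perm=15, seed=42)
        b = sg.compute_scores(cd, n_perm=15, seed=42)
        np.testing.assert_array_equal(a.label_masks, b.label_masks)
        np.testing.assert_array_equal(a.de.T, b.de.T)
        np.testing.assert_array_equal(a.ds.T, b.ds.T)


class TestSignificance:
    def test_add_one_estimator_extremes(self):
        perm = np.arange(1, 1000, dtype=float)[None, :] / 1000  # 999 perms, all < obs
        res = significance(np.array([2.0]), perm, ["s"], np.array([10]))
        assert res["p_emp"][0] == pytest.approx(1 / 1000)

    def test_median_observed_gives_half(self):
        perm = np.linspace(0.1, 2.0, 999)[None, :]
        obs = np.array([np.median(perm)])
        res = significance(obs, perm, ["s"], np.array([10]))
        assert res["p_emp"][0] == pytest.approx(0.5, abs=0.01)

    def test_fdr_matches_hand_computed_pooled_ratio(self):
        # 3 sets x 4 permutations, chosen so NES values are easy to pool
        obs = np.array([2.0, 1.0, 0.5])
        perm = np.array(
            [
                [1.0, 1.0, 1.0, 1.0],  # mean-positive 1 -> NES 2.0
                [0.5, 1.5, 1.0, 1.0],  # mean 1          -> NES 1.0
                [1.0, 1.0, 0.5, 1.5],  # mean 1          -> NES 0.5
            ]
        )
        res = significance(obs, perm, ["a", "b", "c"], np.array([5, 5, 5]))
        nes = res["NES"].values
        pooled = (perm / 1.0).ravel()  # all means are 1
        for i, row in res.iterrows():
            frac_pool = np.mean(pooled >= nes[i])
            frac_obs = np.mean(nes >= nes[i])
            assert row["FDR"] == pytest.approx(min(1.0, frac_pool / frac_obs))

    def test_fdr_monotone_in_nes(self, small_scored, small_dataset):
        _, _, collection = small_dataset
        res = sg.run_enrichment(small_scored, collection, alpha=0.5)
        ok = res[res["flag"] == "ok"].sort_values("NES", ascending=False)
        fdr = ok["FDR"].values
        assert (np.diff(fdr) >= -1e-12).all()

    def test_all_zero_permutations_flagged(self):
        res = significance(np.array([1.0]), np.zeros((1, 10)), ["s"], np.array([5]))
        assert res["flag"][0] == "NES-undefined"
        assert np.isnan(res["NES"][0])


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        coll = GeneSetCollection(
            [
                GeneSet("SET1", "first", frozenset({"g1", "g2", "g3"})),
                GeneSet("SET2", "second", frozenset({"g2", "g4"})),
            ]
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, str(path))
        back = read_gmt(str(path))
        assert {(s.name, s.members) for s in back} == {(s.name, s.members) for s in coll}

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("NAME\tdesc-only\n")
        with pytest.raises(ValueError, match=":1"):
            read_gmt(str(path))

    def test_restrict_applies_size_bounds(self):
        coll = GeneSetCollection(
            [
                GeneSet("BIG", "", frozenset(f"g{i}" for i in range(10))),
                GeneSet("TINY", "", frozenset({"g0"})),
            ]
        )
        kept = coll.restrict([f"g{i}" for i in range(10)], min_size=5, max_size=1000)
        assert [s.name for s in kept] == ["BIG"]


class TestScanAndSaturation:
    def test_scan_extremes_equal_single_score_runs(self, small_scored, small_dataset):
        """alpha=1 column of the scan reproduces a DE-only enrichment run and
        alpha=0 a DS-only run, set for set."""
        _, _, collection = small_dataset
        scan = weight_scan(small_scored, collection, alphas=(0.0, 1.0))
        de_only = sg.run_enrichment(small_scored, collection, alpha=1.0)
        sub = scan[np.isclose(scan["alpha"], 1.0)].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            sub[["set_name", "ES", "NES", "p_emp", "FDR"]],
            de_only[["set_name", "ES", "NES", "p_emp", "FDR"]],
        )

    def test_duplicate_alphas_deduplicated(self, small_scored, small_dataset):
        _, _, collection = small_dataset
        with pytest.warns(UserWarning, match="duplicate alpha"):
            scan = weight_scan(small_scored, collection, alphas=(0.5, 0.5))
        assert sorted(set(scan["alpha"])) == [0.5]

    def test_saturation_curve_monotone_and_cumulative(self, small_scored, small_dataset):
        _, _, collection = small_dataset
        alphas = (0.0, 0.5, 1.0)
        scan = weight_scan(small_scored, collection, alphas=alphas)
        sat = saturation_analysis(scan, weight_order=(1.0, 0.0, 0.5))
        counts = sat["cumulative_unique_sets"].values
        assert (np.diff(counts) >= 0).all()
        assert counts[0] == len(significant_sets(scan, "Linear", 1.0))
        assert counts[-1] == len(sg.gsea_engine.scan_union(scan, "Linear"))

    def test_missing_weight_rejected(self, small_scored, small_dataset):
        _, _, collection = small_dataset
        scan = weight_scan(small_scored, collection, alphas=(0.0, 1.0))
        with pytest.raises(ValueError, match="not present"):
            saturation_analysis(scan, weight_order=(1.0, 0.3))
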