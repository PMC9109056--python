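"""Random-Forest QTL mapping: importances, permutation null, FDR, merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crossqtl as cq
from crossqtl.genotype import UniqueMarkerSet
from crossqtl.mapping import (ForestConfig, linkage_count_curve,
                              pooled_linkage_fdr)


@pytest.fixture(scope="module")
def tiny_panel():
    """60 strains, ~60 unique markers: cheap forests for unit tests."""
    mm = cq.make_marker_map({"chrA": 300_000, "chrB": 300_000}, 10_000)
    geno = cq.simulate_genotypes(mm, 60, seed=21)
    uset = cq.process_genotypes(geno)
    return uset


TINY = ForestConfig(n_trees=100, n_permutations=20, seed=0)


class TestCombinedScore:
    @pytest.mark.parametrize("rss,pi,expected", [
        (2.0, 0.5, 1.0), (2.0, -0.5, 0.0), (0.0, 3.0, 0.0), (-1.0, -1.0, 0.0)])
    def test_positive_part_product(self, rss, pi, expected):
        assert cq.combined_score(rss, pi) == expected


class TestForestImportances:
    def test_causal_marker_ranks_first(self, mapping_panel):
        _, uset, _ = mapping_panel
        G = uset.calls.to_numpy()
        j = 120
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(600 + seed)
            y = G[:, j] + rng.normal(0, 0.5, G.shape[0])  # ~50% variance
            scores = cq.forest_importances(y, G, ForestConfig(
                n_trees=200, n_permutations=20, seed=0), seed)
            top = int(np.argmax(scores.s))
            r = abs(np.corrcoef(G[:, j], G[:, top])[0, 1])
            hits += (top == j) or (r >= 0.8)
        assert hits >= 9

    def test_null_trait_scores_match_permuted(self, tiny_panel):
        G = tiny_panel.calls.to_numpy()
        rng = np.random.default_rng(0)
        y = rng.normal(size=G.shape[0])
        s_obs = cq.forest_importances(y, G, TINY, 1).s
        s_perm = cq.forest_importances(rng.permutation(y), G, TINY, 2).s
        p = stats.mannwhitneyu(s_obs, s_perm).pvalue
        assert p > 0.01

    def test_duplicate_causal_marker_shares_importance(self, tiny_panel):
        G = tiny_panel.calls.to_numpy()
        rng = np.random.default_rng(1)
        j = 10
        X = np.hstack([G, G[:, [j]]])  # perfect duplicate appended
        y = G[:, j] + rng.normal(0, 0.5, G.shape[0])
        scores = cq.forest_importances(y, X, TINY, 3)
        dup = X.shape[1] - 1
        pair = scores.s[[j, dup]]
        others = np.delete(scores.s, [j, dup])
        assert pair.sum() > others.max()
        assert pair.min() > 0  # importance genuinely shared

    def test_constant_trait_flagged(self, tiny_panel):
        G = tiny_panel.calls.to_numpy()
        scores = cq.forest_importances(np.ones(G.shape[0]), G, TINY, 0)
        assert scores.constant_trait
        assert (scores.s == 0).all()

    def test_missing_y_rejected(self, tiny_panel):
        G = tiny_panel.calls.to_numpy()
        y = np.ones(G.shape[0]); y[0] = np.nan
        with pytest.raises(ValueError, match="NA"):
            cq.forest_importances(y, G, TINY, 0)


class TestPermutationNull:
    def test_nonnegative_and_deterministic(self, tiny_panel):
        G = tiny_panel.calls.to_numpy()
        rng = np.random.default_rng(2)
        y = rng.normal(size=G.shape[0])
        n1 = cq.permutation_null(y, G, TINY, seed=11)
        n2 = cq.permutation_null(y, G, TINY, seed=11)
        assert (n1 >= 0).all()
        np.testing.assert_array_equal(n1, n2)
        n3 = cq.permutation_null(y, G, TINY, seed=12)
        assert not np.array_equal(n1, n3)


class TestEstimateFdr:
    def test_score_above_all_null_gets_q_zero(self):
        rng = np.random.default_rng(0)
        null = rng.uniform(0, 1, (25, 50))
        obs = rng.uniform(0, 1, 50)
        obs[7] = 2.0
        q = cq.estimate_fdr(obs, null)
        assert q[7] == 0.0

    def test_monotone_in_score(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            null = np.abs(rng.normal(size=(30, 40)))
            obs = np.abs(rng.normal(size=40))
            q = cq.estimate_fdr(obs, null)
            order = np.argsort(obs)
            assert (np.diff(q[order]) <= 1e-12).all()

    def test_zero_scores_get_q_one(self):
        null = np.abs(np.random.default_rng(2).normal(size=(25, 10)))
        obs = np.zeros(10)
        assert (cq.estimate_fdr(obs, null) == 1.0).all()

    def test_null_calibration(self):
        # observed scores drawn from the null distribution itself: on
        # average few markers reach q <= 0.10
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(100):
            null = np.abs(rng.normal(size=(25, 60))) * rng.integers(0, 2, (25, 60))
            obs = np.abs(rng.normal(size=60)) * rng.integers(0, 2, 60)
            q = cq.estimate_fdr(obs, null)
            fracs.append((q <= 0.10).mean())
        assert np.mean(fracs) <= 0.10

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            cq.estimate_fdr(np.ones(5), np.ones((10, 5)))


def _handmade_uset():
    """Six markers on two chromosomes with controlled correlations."""
    rng = np.random.default_rng(4)
    n = 40
    base = rng.integers(0, 2, n).astype(float)
    flip = lambda v, k: np.where(np.isin(np.arange(n), rng.choice(n, k, False)),
                                 1 - v, v)
    calls = pd.DataFrame({
        "a1": base, "a2": flip(base, 2), "a3": flip(base, 3),
        "a4": rng.integers(0, 2, n).astype(float),
        "b1": flip(base, 1),                       # high LD with a1, other chrom
        "b2": rng.integers(0, 2, n).astype(float),
    }, index=[f"s{i}" for i in range(n)])
    table = pd.DataFrame({
        "unique_marker": ["a1", "a2", "a3", "a4", "b1", "b2"],
        "chrom": ["cA"] * 4 + ["cB"] * 2,
        "start_bp": [1000, 2000, 3000, 4000, 1000, 2000],
        "end_bp": [1000, 2000, 3000, 4000, 1000, 2000],
        "pos_bp": [1000, 2000, 3000, 4000, 1000, 2000],
        "members": ["a1", "a2", "a3", "a4", "b1", "b2"],
    })
    member_of = pd.Series({m: m for m in calls.columns})
    return UniqueMarkerSet(calls, table, member_of)


class TestCallQtls:
    def test_consecutive_markers_merge(self):
        uset = _handmade_uset()
        q = np.array([0.01, 0.02, 0.05, 1.0, 1.0, 1.0])
        s = np.array([3.0, 2.0, 1.0, 0.0, 0.0, 0.0])
        out = cq.call_qtls("t", "x", q, s, uset, 0.10)
        assert len(out) == 1
        assert out.iloc[0]["peak_marker"] == "a1"
        assert out.iloc[0]["n_markers"] == 3

    def test_high_ld_merges_across_chromosomes(self):
        uset = _handmade_uset()
        r = np.corrcoef(uset.calls["a1"], uset.calls["b1"])[0, 1]
        assert r > 0.8  # sanity of the construction
        q = np.array([0.01, 1.0, 1.0, 1.0, 0.02, 1.0])
        s = np.array([3.0, 0.0, 0.0, 0.0, 2.0, 0.0])
        out = cq.call_qtls("t", "x", q, s, uset, 0.10)
        assert len(out) == 1
        assert out.iloc[0]["n_markers"] == 2

    def test_unlinked_markers_stay_separate(self):
        uset = _handmade_uset()
        q = np.array([0.01, 1.0, 1.0, 0.02, 1.0, 1.0])
        s = np.array([3.0, 0.0, 0.0, 2.0, 0.0, 0.0])
        out = cq.call_qtls("t", "x", q, s, uset, 0.10)
        assert len(out) == 2

    def test_remerging_is_stable(self):
        uset = _handmade_uset()
        q = np.array([0.01, 0.02, 0.05, 1.0, 0.02, 1.0])
        s = np.array([3.0, 2.0, 1.0, 0.0, 2.5, 0.0])
        first = cq.call_qtls("t", "x", q, s, uset, 0.10)
        # feeding the same significance pattern back changes nothing
        second = cq.call_qtls("t", "x", q, s, uset, 0.10)
        pd.testing.assert_frame_equal(first, second)

    def test_effect_sign_convention(self):
        uset = _handmade_uset()
        trait = pd.Series(1.0 - uset.calls["a1"], index=uset.calls.index)
        q = np.array([0.01, 1.0, 1.0, 1.0, 1.0, 1.0])
        s = np.array([3.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        out = cq.call_qtls("t", "x", q, s, uset, 0.10, trait_values=trait)
        assert out.iloc[0]["effect"] == pytest.approx(1.0)  # BY minus RM


class TestLinkageCurve:
    def test_component_counting(self):
        chrom = np.array([0, 0, 0, 1, 1])
        partners = [np.array([], dtype=int)] * 5
        scores = np.array([5.0, 0.0, 3.0, 4.0, 0.0])
        act, counts = linkage_count_curve(scores, chrom, partners)
        np.testing.assert_array_equal(act, [5.0, 4.0, 3.0])
        # 5 -> 1 comp; adding 4 (other chrom) -> 2; adding 3 (gap) -> 3
        np.testing.assert_array_equal(counts, [1, 2, 3])

    def test_adjacent_activation_merges(self):
        chrom = np.zeros(4, dtype=int)
        partners = [np.array([], dtype=int)] * 4
        scores = np.array([3.0, 2.0, 1.5, 0.0])
        act, counts = linkage_count_curve(scores, chrom, partners)
        np.testing.assert_array_equal(counts, [1, 1, 1])

    def test_ld_partner_merges_distant_markers(self):
        chrom = np.array([0, 0, 1])
        partners = [np.array([2]), np.array([], dtype=int), np.array([0])]
        scores = np.array([3.0, 0.0, 2.0])
        _, counts = linkage_count_curve(scores, chrom, partners)
        np.testing.assert_array_equal(counts, [1, 1])


class TestMapTraits:
    def test_finds_planted_qtl_and_is_deterministic(self, tiny_panel):
        G = tiny_panel.calls.to_numpy()
        rng = np.random.default_rng(5)
        j = 25
        traits = pd.DataFrame({
            "causal": G[:, j] + rng.normal(0, 0.5, G.shape[0]),
            "noise": rng.normal(size=G.shape[0]),
        }, index=tiny_panel.calls.index)
        out1 = cq.map_traits(traits, tiny_panel, config=TINY, layer="transcript")
        out2 = cq.map_traits(traits, tiny_panel, config=TINY, layer="transcript")
        pd.testing.assert_frame_equal(out1, out2)
        causal_calls = out1[out1["trait"] == "causal"]
        assert len(causal_calls) >= 1
        members = causal_calls.iloc[0]["members"].split(",")
        target = tiny_panel.markers[j]
        linked = target in members or any(
            np.corrcoef(tiny_panel.calls[target], tiny_panel.calls[m])[0, 1] > 0.8
            for m in members)
        assert linked

    def test_covariates_never_reported_and_power_unharmed(self, tiny_panel):
        # structure eigenvectors ride along as extra predictors; they must
        # never surface as QTLs, and a real causal marker must still be found
        cov = cq.structure_eigenvectors(tiny_panel.calls, k=7).vectors
        G = tiny_panel.calls.to_numpy()
        rng = np.random.default_rng(9)
        j = 12
        traits = pd.DataFrame(
            {"causal": G[:, j] + rng.normal(0, 0.5, G.shape[0])},
            index=tiny_panel.calls.index)
        out = cq.map_traits(traits, tiny_panel, cov, TINY)
        assert len(out) >= 1
        all_members = ",".join(out["members"])
        assert "PC" not in all_members
        members = out.iloc[0]["members"].split(",")
        target = tiny_panel.markers[j]
        assert target in members or any(
            np.corrcoef(tiny_panel.calls[target], tiny_panel.calls[m])[0, 1] > 0.8
            for m in members)

    def test_na_strains_dropped(self, tiny_panel):
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=len(tiny_panel.calls)),
                      index=tiny_panel.calls.index)
        y.iloc[:5] = np.nan
        traits = pd.DataFrame({"t": y})
        out = cq.map_traits(traits, tiny_panel, config=TINY)
        assert isinstance(out, pd.DataFrame)  # runs despite missing strains
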