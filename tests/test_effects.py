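"""Effect sizes, transmission classes, local/distant calls, hotspots, SNP context."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crossqtl as cq
from crossqtl.effects import GeneModel, TRANSMISSION_THRESHOLD


class TestAlleleEffect:
    def test_mean_difference(self):
        trait = np.array([2.0, 4.0, 1.0, 3.0])
        geno = np.array([0.0, 0.0, 1.0, 1.0])
        assert cq.allele_effect(trait, geno) == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        trait = np.array([1.0, 2.0, 1.0, 2.0])
        geno = np.array([0.0, 0.0, 1.0, 1.0])
        assert cq.allele_effect(trait, geno) == pytest.approx(0.0)

    def test_antisymmetric_under_allele_swap(self):
        rng = np.random.default_rng(0)
        trait = rng.normal(size=30)
        geno = rng.integers(0, 2, 30).astype(float)
        assert cq.allele_effect(trait, geno) == pytest.approx(
            -cq.allele_effect(trait, 1 - geno))

    def test_empty_group_signals(self):
        with pytest.raises(ValueError):
            cq.allele_effect(np.ones(4), np.zeros(4))


class TestClassifyTransmission:
    @pytest.mark.parametrize("ee,ep,expected", [
        (1.0, 1.0, "similar"),
        (1.0, 0.2, "buffered"),
        (-1.0, -1.5, "enhanced"),
        (0.15, 0.0, "similar"),     # delta exactly 0.15: boundary is similar
        (1.0, 1.15, "similar"),
        (-1.0, -0.2, "buffered"),   # sign-aware: |E_p| < |E_e|
    ])
    def test_examples(self, ee, ep, expected):
        assert cq.classify_transmission(ee, ep) == expected

    def test_zero_transcript_effect_unclassifiable(self):
        with pytest.raises(ValueError):
            cq.classify_transmission(0.0, 1.0)

    def test_grid_matches_brute_force(self):
        # exhaustive oracle over the effect plane including the boundaries
        grid = np.round(np.arange(-2.0, 2.0001, 0.05), 10)
        for ee in grid:
            for ep in grid:
                if ee == 0:
                    continue
                delta = np.sign(ee) * (ee - ep)
                if delta > TRANSMISSION_THRESHOLD:
                    expected = "buffered"
                elif delta < -TRANSMISSION_THRESHOLD:
                    expected = "enhanced"
                else:
                    expected = "similar"
                assert cq.classify_transmission(float(ee), float(ep)) == expected


class TestPoissonThreshold:
    def test_zero_lambda(self):
        assert cq.poisson_threshold(0.0, 0.01) == 0

    def test_lambda_two(self):
        # exact CDF: P(X<=5)=0.9834, P(X<=6)=0.9955
        assert cq.poisson_threshold(2.0, 0.01) == 6

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_matches_exact_cdf_oracle(self, lam, alpha):
        # independent oracle via scipy's exact Poisson CDF
        k = 0
        while stats.poisson.cdf(k, lam) < 1 - alpha:
            k += 1
        assert cq.poisson_threshold(lam, alpha) == k

    def test_monotone_in_lambda(self):
        ks = [cq.poisson_threshold(l, 0.01) for l in np.linspace(0.1, 30, 40)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))


class TestHotspots:
    def _qtls(self, positions, chrom="chrA", layer="transcript"):
        return pd.DataFrame({
            "trait": [f"t{i}" for i in range(len(positions))],
            "layer": layer, "chrom": chrom, "peak_pos_bp": positions})

    def test_uniform_qtls_give_no_hotspots(self):
        rng = np.random.default_rng(0)
        # 100 QTLs over 100 bins (lambda = 1)
        chroms = {"chrA": 2_000_000, "chrB": 2_000_000}
        pos = rng.integers(1, 2_000_000, 100)
        q = pd.DataFrame({"trait": [f"t{i}" for i in range(100)],
                          "layer": "transcript",
                          "chrom": rng.choice(["chrA", "chrB"], 100),
                          "peak_pos_bp": pos})
        bins, hot = cq.detect_hotspots(q, chroms, bin_bp=40_000)
        assert hot.empty

    def test_loaded_bin_flagged_and_counts_conserved(self):
        pos = list(np.linspace(50_000, 1_900_000, 50).astype(int))  # background
        pos += [105_000] * 50  # hotspot bin [80001, 120000]
        q = self._qtls(pos)
        bins, hot = cq.detect_hotspots(q, {"chrA": 2_000_000}, bin_bp=40_000)
        assert len(hot) == 1
        assert hot.iloc[0]["start_bp"] <= 105_000 <= hot.iloc[0]["end_bp"]
        assert bins["count_transcript"].sum() == len(q)

    def test_adjacent_hotspot_bins_merge(self):
        pos = [105_000] * 30 + [125_000] * 30  # two consecutive loaded bins
        q = self._qtls(pos)
        _, hot = cq.detect_hotspots(q, {"chrA": 2_000_000}, bin_bp=40_000)
        assert len(hot) == 1
        assert hot.iloc[0]["n_qtls"] == 60

    def test_terminal_bin_absorbs_remainder(self):
        from crossqtl.effects import _genome_bins
        bins = _genome_bins({"chrA": 90_000}, 40_000)
        assert len(bins) == 2
        assert bins.iloc[-1]["end_bp"] == 90_000  # last bin spans 50 kb

    def test_shuffled_positions_rarely_flagged(self, mapping_panel):
        geno, uset, _ = mapping_panel
        rng = np.random.default_rng(1)
        chroms = {c: 760_000 for c in "ABCD"}
        chroms = {f"chr{c}": v for c, v in chroms.items()}
        n_flagged, n_bins = 0, 0
        for rep in range(20):
            pos = rng.integers(1, 760_000, 60)
            q = pd.DataFrame({"trait": [f"t{i}" for i in range(60)],
                              "layer": "x",
                              "chrom": rng.choice(list(chroms), 60),
                              "peak_pos_bp": pos})
            bins, _ = cq.detect_hotspots(q, chroms, bin_bp=40_000)
            n_flagged += bins["hotspot_x"].sum()
            n_bins += len(bins)
        assert n_flagged / n_bins <= 0.011  # alpha = 0.01 on average


class TestLocalDistant:
    def test_qtl_containing_flank_is_local(self, collapsed):
        tab = collapsed.table
        gene_chrom = tab.iloc[5]["chrom"]
        gene_pos = int(tab.iloc[5]["pos_bp"]) + 100
        flank = tab.iloc[5]["unique_marker"]
        assert cq.classify_local_distant([flank], gene_chrom, gene_pos, collapsed)

    def test_uncorrelated_far_qtl_is_distant(self, collapsed):
        tab = collapsed.table
        chra = tab[tab["chrom"] == "chrA"]
        chrb = tab[tab["chrom"] == "chrB"]
        gene_pos = int(chra.iloc[2]["pos_bp"])
        # pick a chrB marker with low correlation to the chrA flanks
        calls = collapsed.calls
        flanks = [chra.iloc[2]["unique_marker"], chra.iloc[3]["unique_marker"]]
        for m in chrb["unique_marker"]:
            r = max(abs(np.corrcoef(calls[m], calls[f])[0, 1]) for f in flanks)
            if r < 0.3:
                assert not cq.classify_local_distant([m], "chrA", gene_pos, collapsed)
                return
        pytest.skip("no weakly correlated marker found")


class TestTransmissionSlope:
    def test_identity_line(self):
        pairs = pd.DataFrame({"e_transcript": [0.5, 1.0, -1.0, 2.0],
                              "e_protein": [0.5, 1.0, -1.0, 2.0]})
        slope, se = cq.transmission_slope(pairs)
        assert slope == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_flat_response(self):
        pairs = pd.DataFrame({"e_transcript": [0.5, 1.0, -1.0, 2.0],
                              "e_protein": [0.0, 0.0, 0.0, 0.0]})
        slope, _ = cq.transmission_slope(pairs)
        assert slope == pytest.approx(0.0)

    def test_recovers_simulated_transmission(self):
        rng = np.random.default_rng(2)
        ee = rng.normal(0, 1, 100)
        ep = 0.7 * ee + rng.normal(0, 0.2, 100)
        pairs = pd.DataFrame({"e_transcript": ee, "e_protein": ep,
                              "local": rng.integers(0, 2, 100).astype(bool)})
        for subset in ("local", "distant"):
            slope, se = cq.transmission_slope(pairs, subset)
            assert abs(slope - 0.7) < 2 * se + 1e-9


class TestSnpContext:
    def test_missense_distance(self):
        assert cq.missense_distance(100, [90, 150]) == 10
        assert cq.missense_distance(90, [90, 150]) == 0
        rng = np.random.default_rng(0)
        site = 250
        poly = rng.integers(1, 500, 20)
        assert cq.missense_distance(site, poly) == min(abs(site - p) for p in poly)
        with pytest.raises(ValueError):
            cq.missense_distance(10, [])

    def _gene(self, **kw):
        defaults = dict(gene="g", chrom="chrA", strand="+", cds=(10_000, 10_899),
                        utr5=(9_800, 9_999), utr3=(10_900, 11_100))
        defaults.update(kw)
        return GeneModel(**defaults)

    def test_region_membership(self):
        gene = self._gene()
        counts = cq.count_region_snps(gene, [10_050, 9_900, 11_000, 8_500, 12_000])
        assert counts["cds"] == 1
        assert counts["utr5"] == 1
        assert counts["utr3"] == 1
        assert counts["upstream"] == 1   # 8500 within 2 kb of UTR5 start
        assert counts["downstream"] == 1

    def test_far_upstream_not_counted(self):
        gene = self._gene()
        counts = cq.count_region_snps(gene, [9_800 - 2_500])
        assert sum(counts.values()) == 0

    def test_same_codon_snps_collapse(self):
        gene = self._gene(missense_positions=frozenset({10_000, 10_001, 10_030}))
        counts = cq.count_region_snps(gene, [10_000, 10_001, 10_030])
        assert counts["aa_changes"] == 2  # first two share a codon
        assert counts["cds"] == 3

    def test_indel_gene_rejected(self):
        gene = self._gene(has_indel=True)
        with pytest.raises(ValueError, match="indel"):
            cq.count_region_snps(gene, [10_050])


class TestProteinOnly:
    def test_overlapping_eqtl_blocks_protein_only(self, collapsed):
        pt = pd.DataFrame({"trait": ["p1"], "members": [collapsed.markers[0]]})
        eq = pd.DataFrame({"trait": ["e1"], "members": [collapsed.markers[0]]})
        gene_of = pd.Series({"p1": "g", "e1": "g"})
        flags = cq.annotate_protein_only(pt, eq, collapsed, gene_of)
        assert not flags.iloc[0]

    def test_lone_ptqtl_is_protein_only(self, collapsed):
        pt = pd.DataFrame({"trait": ["p1"], "members": [collapsed.markers[0]]})
        eq = pd.DataFrame({"trait": [], "members": []})
        gene_of = pd.Series({"p1": "g"})
        flags = cq.annotate_protein_only(pt, eq, collapsed, gene_of)
        assert flags.iloc[0]

    def test_linked_eqtl_blocks_protein_only(self, collapsed):
        # adjacent unique markers are typically in high LD
        calls = collapsed.calls
        m0, m1 = collapsed.markers[0], collapsed.markers[1]
        r = np.corrcoef(calls[m0], calls[m1])[0, 1]
        if r <= 0.8:
            pytest.skip("adjacent markers not in high LD in this panel")
        pt = pd.DataFrame({"trait": ["p1"], "members": [m0]})
        eq = pd.DataFrame({"trait": ["e1"], "members": [m1]})
        gene_of = pd.Series({"p1": "g", "e1": "g"})
        assert not cq.annotate_protein_only(pt, eq, collapsed, gene_of).iloc[0]
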