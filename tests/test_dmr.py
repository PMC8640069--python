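import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from siccaomics.dmr import (
    dmr_scan,
    enrichment_score,
    eqtm_scan,
    leading_edge_profile,
    rank_cpgs,
    region_spans,
)
from siccaomics.io import MolecularMatrix, RegionSet


def brute_force_es(scores, members, p=1.0):
    """Independent walk of the weighted KS running sum, in exact rational
    arithmetic so |peak| == |trough| ties are decided exactly (positive
    extremum wins, the documented convention)."""
    from fractions import Fraction

    members = set(members)
    weights = {i: Fraction(abs(float(scores[i]))) for i in members}
    total = sum(weights.values())
    miss = Fraction(1, len(scores) - len(members))
    run, best, best_abs = Fraction(0), Fraction(0), Fraction(0)
    for i in range(len(scores)):
        if i in members:
            run += weights[i] / total
        else:
            run -= miss
        if abs(run) > best_abs or (abs(run) == best_abs and run > best):
            best_abs, best = abs(run), run
    return float(best)


class TestRanking:
    def test_descending_by_statistic(self):
        t = pd.DataFrame({"feature_id": ["a", "b"], "statistic": [-1.0, 3.0]})
        ranked = rank_cpgs(t)
        assert list(ranked.cpg) == ["b", "a"]

    def test_ties_broken_lexicographically(self):
        t = pd.DataFrame({"feature_id": ["z", "a", "m"], "statistic": [1.0, 1.0, 1.0]})
        assert list(rank_cpgs(t).cpg) == ["a", "m", "z"]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"feature_id": [f"c{i}" for i in range(20)],
                          "statistic": rng.normal(size=20)})
        shuffled = t.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(rank_cpgs(t), rank_cpgs(shuffled))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rank_cpgs(pd.DataFrame({"feature_id": [], "statistic": []}))


class TestEnrichmentScore:
    def test_all_members_lead_the_list(self):
        es, le = enrichment_score([3, 2, 1, -1, -2], [0, 1])
        assert es == pytest.approx(1.0)
        assert set(le) == {0, 1}

    def test_split_members_extremum_at_top(self):
        es, le = enrichment_score([3, 2, 1, -1, -2], [0, 4])
        assert es == pytest.approx(0.6)
        assert set(le) == {0}

    def test_all_positions_rejected(self):
        with pytest.raises(ValueError, match="whole ranked list"):
            enrichment_score([3, 2, 1], [0, 1, 2])

    def test_zero_member_scores_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            enrichment_score([3, 1, 0.0, -2], [2])

    def test_matches_brute_force_on_all_subsets_up_to_n8(self):
        rng = np.random.default_rng(5)
        for N in range(2, 9):
            scores = np.sort(rng.normal(size=N))[::-1]
            scores[scores == 0] = 0.1
            for k in range(1, N):
                for members in itertools.combinations(range(N), k):
                    if all(scores[list(members)] == 0):
                        continue
                    es, _ = enrichment_score(scores, members)
                    assert es == pytest.approx(
                        brute_force_es(scores, members), abs=1e-12
                    ), (scores, members)

    def test_antisymmetric_under_score_negation(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            N = 12
            scores = np.sort(rng.normal(size=N))[::-1]
            members = rng.choice(N, size=4, replace=False)
            es, _ = enrichment_score(scores, members)
            # negate and reverse the ranking; members map to mirrored positions
            es_neg, _ = enrichment_score(-scores[::-1], N - 1 - members)
            assert es_neg == pytest.approx(-es, abs=1e-12)


def _dmp_table(scores):
    return pd.DataFrame({"feature_id": [f"cg{i:03d}" for i in range(len(scores))],
                         "statistic": scores})


class TestDmrScan:
    def test_top_loaded_region_reaches_minimal_p(self):
        rng = np.random.default_rng(7)
        scores = np.sort(rng.normal(size=2000))[::-1]
        table = _dmp_table(scores)
        ranked = rank_cpgs(table)
        top = list(ranked.cpg[:10])
        regions = [RegionSet("hot", "promoter", top)]
        res = dmr_scan(table, regions, n_perm=999, seed=1)
        assert res.p_perm.iloc[0] == pytest.approx(1 / 1000)
        assert res.direction.iloc[0] == "hyper"
        assert set(res.leading_edge.iloc[0].split(",")) <= set(top)

    def test_seed_reproducible_and_small_regions_skipped(self):
        rng = np.random.default_rng(8)
        table = _dmp_table(rng.normal(size=300))
        regions = [
            RegionSet("r1", "promoter", [f"cg{i:03d}" for i in range(40, 48)]),
            RegionSet("tiny", "CGI", ["cg001", "cg002"]),  # < 5 members
        ]
        a = dmr_scan(table, regions, n_perm=199, seed=3)
        b = dmr_scan(table, regions, n_perm=199, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert "tiny" not in set(a.region_id)

    def test_null_region_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        table = _dmp_table(rng.normal(size=500))
        regions = [RegionSet(f"r{j}", "promoter",
                             list(rng.choice([f"cg{i:03d}" for i in range(500)], 8,
                                             replace=False)))
                   for j in range(40)]
        res = dmr_scan(table, regions, n_perm=199, seed=4)
        assert stats.kstest(res.p_perm, "uniform").pvalue > 0.01

    def test_minimal_p_scales_with_permutations(self):
        rng = np.random.default_rng(10)
        scores = np.sort(rng.normal(size=400))[::-1]
        table = _dmp_table(scores)
        ranked = rank_cpgs(table)
        regions = [RegionSet("hot", "promoter", list(ranked.cpg[:8]))]
        p1 = dmr_scan(table, regions, n_perm=199, seed=5).p_perm.iloc[0]
        p2 = dmr_scan(table, regions, n_perm=399, seed=5).p_perm.iloc[0]
        assert p1 == pytest.approx(1 / 200) and p2 == pytest.approx(1 / 400)


class TestLeadingEdgeProfile:
    def _meth(self):
        values = pd.DataFrame([[0.2, 0.6], [0.4, 0.8]], index=["cg1", "cg2"],
                              columns=["s1", "s2"])
        return MolecularMatrix(values, "methylation")

    def test_single_cpg_is_identity(self):
        prof = leading_edge_profile(self._meth(), ["cg1"])
        assert list(prof) == [0.2, 0.6]

    def test_two_cpgs_average(self):
        prof = leading_edge_profile(self._meth(), ["cg1", "cg2"])
        assert list(prof) == pytest.approx([0.3, 0.7])

    def test_random_fixture_matches_numpy_mean(self):
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(rng.random((6, 5)),
                            index=[f"cg{i}" for i in range(6)],
                            columns=[f"s{j}" for j in range(5)])
        m = MolecularMatrix(vals, "methylation")
        edge = ["cg0", "cg3", "cg5"]
        assert leading_edge_profile(m, edge).to_numpy() == pytest.approx(
            vals.loc[edge].to_numpy().mean(axis=0))

    def test_absent_cpg_rejected(self):
        with pytest.raises(KeyError):
            leading_edge_profile(self._meth(), ["cgX"])


class TestEqtm:
    def _inputs(self, y):
        samples = [f"s{i}" for i in range(len(y))]
        profiles = pd.DataFrame([np.linspace(0.2, 0.8, len(y))], index=["r1"],
                                columns=samples)
        expr = pd.DataFrame([y], index=["g1"], columns=samples)
        genes = pd.DataFrame({"feature_id": ["g1"], "chrom": ["chr1"], "pos": [1400]})
        regions = pd.DataFrame({"region_id": ["r1"], "chrom": ["chr1"],
                                "start": [2000], "end": [2600]})
        return profiles, expr, genes, regions

    def test_perfect_correlation(self):
        x = np.linspace(0.2, 0.8, 6)
        res = eqtm_scan(*self._inputs(10 * x + 1))
        assert res.pearson_r.iloc[0] == pytest.approx(1.0)
        res_neg = eqtm_scan(*self._inputs(-3 * x))
        assert res_neg.pearson_r.iloc[0] == pytest.approx(-1.0)

    def test_three_point_pearson_value(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 7.0])
        r = stats.pearsonr(x, y).statistic
        assert r == pytest.approx(0.99339927, abs=1e-6)
        profiles = pd.DataFrame([x / 10], index=["r1"], columns=["a", "b", "c"])
        expr = pd.DataFrame([y], index=["g1"], columns=["a", "b", "c"])
        genes = pd.DataFrame({"feature_id": ["g1"], "chrom": ["chr1"], "pos": [1000]})
        regions = pd.DataFrame({"region_id": ["r1"], "chrom": ["chr1"],
                                "start": [900], "end": [1100]})
        res = eqtm_scan(profiles, expr, genes, regions)
        assert res.pearson_r.iloc[0] == pytest.approx(r, abs=1e-12)

    def test_affine_invariance(self):
        x = np.linspace(0.1, 0.9, 8)
        rng = np.random.default_rng(12)
        y = rng.normal(size=8)
        r1 = eqtm_scan(*self._inputs(y)).pearson_r.iloc[0]
        r2 = eqtm_scan(*self._inputs(3.5 * y + 11)).pearson_r.iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_window_pairing_inclusive(self):
        profiles, expr, genes, regions = self._inputs(np.arange(5.0))
        genes.loc[0, "pos"] = 2000 - 1500  # exactly at window edge
        assert len(eqtm_scan(profiles, expr, genes, regions, window=1500)) == 1
        genes.loc[0, "pos"] = 2000 - 1501
        assert len(eqtm_scan(profiles, expr, genes, regions, window=1500)) == 0

    def test_zero_variance_flagged(self):
        profiles, expr, genes, regions = self._inputs(np.ones(5))
        res = eqtm_scan(profiles, expr, genes, regions)
        assert res.degenerate.iloc[0] and np.isnan(res.pearson_r.iloc[0])


class TestPlantedRegionRecovery:
    def test_subtle_region_found_without_single_cpg_hits(self):
        """A coordinated 8-CpG shift is detected as a region while every
        member stays below the single-CpG Bonferroni bar."""
        from siccaomics.ewas import bonferroni_threshold, run_dmp_scan
        from siccaomics.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_cases=30, n_controls=30, n_cpgs=2000, n_genes=50,
                               n_snps=10, n_dmr_regions=1, dmr_delta_beta=0.05,
                               n_regions=40, seed=5)
        cohort = simulate_cohort(cfg)
        dmp = run_dmp_scan(cohort.methylation, cohort.sheet)
        members = cohort.truth.dmr_regions["DMR000"]["members"]
        th = bonferroni_threshold(0.05, cfg.n_cpgs)
        assert (dmp.set_index("feature_id").loc[members, "p"] >= th).all()
        res = dmr_scan(dmp, cohort.regions, n_perm=999, seed=5)
        row = res[res.region_id == "DMR000"].iloc[0]
        assert row.p_fdr < 0.05
        assert row.direction == "hyper"

    def test_region_profile_correlates_with_companion_gene(self, tmp_path):
        from siccaomics.diffexpr import vst_matrix
        from siccaomics.ewas import run_dmp_scan
        from siccaomics.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_cases=100, n_controls=100, n_cpgs=500, n_genes=100,
                               n_snps=10, n_dmr_regions=1, dmr_delta_beta=0.05,
                               n_regions=10, seed=6)
        cohort = simulate_cohort(cfg)
        info = cohort.truth.dmr_regions["DMR000"]
        prof = leading_edge_profile(cohort.methylation, info["members"])
        profiles = pd.DataFrame({"DMR000": prof}).T
        vst = vst_matrix(cohort.expression)
        spans = region_spans(cohort.regions, cohort.cpg_annotation)
        res = eqtm_scan(profiles, vst.values, cohort.gene_annotation, spans)
        row = res[(res.region_id == "DMR000") & (res.gene_id == info["gene"])]
        assert len(row) == 1
        assert abs(row.pearson_r.iloc[0]) > 0.6
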