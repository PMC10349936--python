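import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tfredist import enrichment as en
from tfredist import synthetic_data as syn


def brute_force_es(ranked, weights, gene_set, exponent):
    """Independent loop implementation of the weighted KS running sum."""
    N = len(ranked)
    hits = [g in gene_set.genes for g in ranked]
    S = sum(hits)
    denom = sum(abs(w) ** exponent for w, h in zip(weights, hits) if h)
    run, cur, best = [], 0.0, 0.0
    for g, w, h in zip(ranked, weights, hits):
        if h:
            cur += abs(w) ** exponent / denom
        else:
            cur -= 1.0 / (N - S)
        run.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best, run


class TestGeneSets:
    def test_regulon_halves_must_be_disjoint(self):
        with pytest.raises(ValueError):
            en.Regulon(
                en.GeneSet("a", {"g1", "g2"}),
                en.GeneSet("b", {"g2", "g3"}),
            )

    def test_gmt_round_trip(self, tmp_path):
        sets = [en.GeneSet("s1", {"a", "b"}), en.GeneSet("s2", {"c"})]
        en.write_gmt(sets, tmp_path / "x.gmt")
        back = en.read_gmt(tmp_path / "x.gmt")
        assert {s.name: s.genes for s in back} == {s.name: s.genes for s in sets}


class TestFisherOra:
    def test_hits_equal_universe_p_one(self):
        uni = {"a", "b", "c"}
        res = en.fisher_ora(en.GeneSet("h", uni), uni, [en.GeneSet("s", uni)])
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_hand_hypergeometric_example(self):
        """Table (8,2;2,8): p = sum_{k>=8} C(10,k) C(10,10-k) / C(20,10)."""
        universe = [f"g{i}" for i in range(20)]
        set_genes = set(universe[:10])
        hits = set(universe[:8]) | set(universe[10:12])
        res = en.fisher_ora(en.GeneSet("h", hits), universe, [en.GeneSet("s", set_genes)])
        expected = sum(
            math.comb(10, k) * math.comb(10, 10 - k) for k in range(8, 11)
        ) / math.comb(20, 10)
        assert res["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_disjoint_hits_p_near_one(self):
        universe = [f"g{i}" for i in range(200)]
        res = en.fisher_ora(
            en.GeneSet("h", set(universe[:10])),
            universe,
            [en.GeneSet("s", set(universe[100:110]))],
        )
        assert res["pvalue"].iloc[0] >= 0.95

    def test_matches_exhaustive_enumeration_small_margins(self):
        """Property: p equals the brute-force hypergeometric tail sum for
        random tables with margins <= 30."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            N = int(rng.integers(8, 30))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            set_genes = set(rng.choice(universe, K, replace=False))
            hits = set(rng.choice(universe, n, replace=False))
            k = len(hits & set_genes)
            res = en.fisher_ora(
                en.GeneSet("h", hits), universe, [en.GeneSet("s", set_genes)]
            )
            brute = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert res["pvalue"].iloc[0] == pytest.approx(brute, rel=1e-9)


class TestGseaEs:
    def test_single_member_first_exponent_zero(self):
        genes = [f"g{i}" for i in range(10)]
        es, _ = en.gsea_es(genes, np.ones(10), en.GeneSet("s", {"g0"}), exponent=0)
        assert es == pytest.approx(1.0)

    def test_single_member_last_exponent_zero(self):
        """With the hit ranked last, the running sum walks down by
        1/(N - |S|) = 1/9 over nine misses, so the extreme pre-hit
        deviation is exactly -1."""
        genes = [f"g{i}" for i in range(10)]
        es, run = en.gsea_es(genes, np.ones(10), en.GeneSet("s", {"g9"}), exponent=0)
        assert es == pytest.approx(-1.0)
        assert run[-1] == pytest.approx(0.0, abs=1e-12)

    def test_reversal_negates_es_at_exponent_zero(self):
        rng = np.random.default_rng(32)
        genes = [f"g{i}" for i in range(60)]
        for _ in range(20):
            members = set(rng.choice(genes, 8, replace=False))
            w = rng.normal(0, 1, 60)
            es_f, _ = en.gsea_es(genes, w, en.GeneSet("s", members), exponent=0)
            es_r, _ = en.gsea_es(genes[::-1], w[::-1], en.GeneSet("s", members), exponent=0)
            assert es_f == pytest.approx(-es_r, abs=1e-9)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(33)
        genes = [f"g{i}" for i in range(80)]
        for expo in (0.0, 1.0):
            members = set(rng.choice(genes, 12, replace=False))
            w = np.sort(rng.normal(0, 2, 80))[::-1]
            es, run = en.gsea_es(genes, w, en.GeneSet("s", members), exponent=expo)
            es_b, run_b = brute_force_es(genes, w, en.GeneSet("s", members), expo)
            assert es == pytest.approx(es_b, abs=1e-9)
            assert np.allclose(run, run_b, atol=1e-9)

    def test_bounds_and_return_to_zero(self):
        rng = np.random.default_rng(34)
        genes = [f"g{i}" for i in range(100)]
        for _ in range(30):
            members = set(rng.choice(genes, int(rng.integers(2, 40)), replace=False))
            w = rng.normal(0, 1, 100)
            es, run = en.gsea_es(genes, w, en.GeneSet("s", members))
            assert -1 <= es <= 1
            assert abs(run[-1]) < 1e-9

    def test_vectorized_positions_kernel_matches_public_es(self):
        rng = np.random.default_rng(35)
        genes = [f"g{i}" for i in range(70)]
        w = np.sort(rng.normal(0, 1, 70))[::-1]
        for _ in range(30):
            members = sorted(rng.choice(70, 9, replace=False))
            gs = en.GeneSet("s", {genes[i] for i in members})
            es, _ = en.gsea_es(genes, w, gs, exponent=1)
            es_vec = en._es_from_positions(
                np.array([members]), np.abs(w), 70
            )[0]
            assert es == pytest.approx(es_vec, abs=1e-12)

    def test_empty_or_full_set_rejected(self):
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError):
            en.gsea_es(genes, np.ones(3), en.GeneSet("s", set()))
        with pytest.raises(ValueError):
            en.gsea_es(genes, np.ones(3), en.GeneSet("s", set(genes)))


class TestPermutationP:
    def test_determinism(self):
        rng = np.random.default_rng(36)
        genes = [f"g{i}" for i in range(100)]
        w = np.sort(rng.normal(0, 1, 100))[::-1]
        gs = en.GeneSet("s", set(genes[:10]))
        r1 = en.gsea_permutation_p(genes, w, gs, n_perm=200, seed=5)
        r2 = en.gsea_permutation_p(genes, w, gs, n_perm=200, seed=5)
        assert r1 == r2

    def test_planted_top_set_minimum_p(self):
        genes = [f"g{i}" for i in range(300)]
        w = np.linspace(3, -3, 300)
        gs = en.GeneSet("s", set(genes[:15]))
        es, p = en.gsea_permutation_p(genes, w, gs, n_perm=200, seed=6)
        assert es > 0.9
        assert p <= 2 / 200

    def test_null_p_roughly_uniform(self):
        """Random sets on a random ranking give approximately uniform
        permutation p-values (KS tolerance)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(37)
        genes = [f"g{i}" for i in range(150)]
        ps = []
        for i in range(150):
            w = np.sort(rng.normal(0, 1, 150))[::-1]
            members = set(rng.choice(genes, 10, replace=False))
            _, p = en.gsea_permutation_p(
                genes,
                w,
                en.GeneSet("s", members),
                n_perm=200,
                seed=int(rng.integers(2**31)),
            )
            ps.append(p)
        # 1% KS critical value for n = 150 is ~0.133
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.13


class TestCohortRanking:
    def test_flat_patient_all_zero_tiebreak_by_id(self):
        expr = pd.DataFrame(
            np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
            index=["gB", "gA"],
            columns=["p1", "p2", "p3"],
        )
        order, weights, _ = en.cohort_zscore_rank(expr, "p2")
        assert np.allclose(weights, 0.0)
        assert order == ["gA", "gB"]

    def test_outlier_gene_ranked_first(self):
        rng = np.random.default_rng(38)
        expr = pd.DataFrame(rng.normal(0, 1, (20, 10)), index=[f"g{i}" for i in range(20)], columns=[f"p{i}" for i in range(10)])
        mu, sd = expr.loc["g7"].mean(), expr.loc["g7"].std(ddof=0)
        expr.loc["g7", "p3"] = mu + 10 * sd
        order, weights, _ = en.cohort_zscore_rank(expr, "p3")
        # the outlier inflates the cohort sd it is scaled by, so its own
        # z lands below the 10-sd perturbation but far above every other gene
        assert order[0] == "g7" and weights[0] > 2.5

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(39)
        expr = pd.DataFrame(rng.normal(0, 1, (15, 8)), index=[f"g{i}" for i in range(15)], columns=[f"p{i}" for i in range(8)])
        o1, w1, _ = en.cohort_zscore_rank(expr, "p0")
        expr2 = expr.copy()
        expr2.loc["g3"] += 100.0
        o2, w2, _ = en.cohort_zscore_rank(expr2, "p0")
        assert o1 == o2 and np.allclose(w1, w2)

    def test_too_few_patients_rejected(self):
        expr = pd.DataFrame(np.ones((4, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            en.cohort_zscore_rank(expr, "a")


class TestPatientActivity:
    def test_des_tracks_latent_activity(self):
        cfg = syn.SimulationConfig(seed=41)
        c = syn.simulate_cohort(cfg)
        act = en.patient_activity(c.expression, c.regulon, n_perm=250, seed=2)
        merged = act.set_index("patient_id").join(c.truth.patients)
        rho = spearmanr(merged["dES"], merged["activity"]).statistic
        assert abs(rho) >= 0.8

    def test_classification_rule_instantiated(self):
        """A patient whose depletion-up genes sit at the bottom of the
        ranking and depletion-down genes at the top is classed high."""
        rng = np.random.default_rng(42)
        n_genes, n_pat = 200, 20
        genes = [f"g{i}" for i in range(n_genes)]
        expr = pd.DataFrame(rng.normal(0, 1, (n_genes, n_pat)), index=genes, columns=[f"p{i}" for i in range(n_pat)])
        up, down = set(genes[:20]), set(genes[20:40])
        expr.loc[sorted(up), "p0"] -= 5.0
        expr.loc[sorted(down), "p0"] += 5.0
        reg = en.Regulon(en.GeneSet("up", up), en.GeneSet("down", down))
        act = en.patient_activity(expr, reg, n_perm=200, seed=3)
        assert act.set_index("patient_id").loc["p0", "class"] == "high"
        # and the mirror image is classed low
        expr.loc[sorted(up), "p1"] += 5.0
        expr.loc[sorted(down), "p1"] -= 5.0
        act = en.patient_activity(expr, reg, n_perm=200, seed=3)
        assert act.set_index("patient_id").loc["p1", "class"] == "low"

    def test_null_cohort_mostly_intermediate(self):
        inter_frac = []
        for s in range(5):
            cfg = syn.SimulationConfig(seed=300 + s)
            cfg.cohort.beta = 0.0
            cfg.cohort.gamma = 0.0
            cfg.cohort.n_patients = 60
            c = syn.simulate_cohort(cfg)
            act = en.patient_activity(c.expression, c.regulon, n_perm=200, seed=s)
            inter_frac.append((act["class"] == "intermediate").mean())
        assert np.mean(inter_frac) >= 0.8

    def test_des_antisymmetric_under_half_swap(self):
        cfg = syn.SimulationConfig(seed=43)
        cfg.cohort.n_patients = 25
        c = syn.simulate_cohort(cfg)
        act = en.patient_activity(c.expression, c.regulon, n_perm=150, seed=4)
        swapped = en.Regulon(
            activated=en.GeneSet("down", c.regulon.repressed.genes),
            repressed=en.GeneSet("up", c.regulon.activated.genes),
        )
        act_sw = en.patient_activity(c.expression, swapped, n_perm=150, seed=4)
        a = act.set_index("patient_id")["dES"]
        b = act_sw.set_index("patient_id")["dES"]
        assert np.allclose(a, -b.loc[a.index], atol=1e-12)

    def test_every_patient_exactly_one_class(self):
        cfg = syn.SimulationConfig(seed=44)
        cfg.cohort.n_patients = 30
        c = syn.simulate_cohort(cfg)
        act = en.patient_activity(c.expression, c.regulon, n_perm=150, seed=5)
        assert len(act) == 30
        assert act["class"].isin(["high", "intermediate", "low"]).all()

    def test_small_overlap_rejected(self):
        cfg = syn.SimulationConfig(seed=45)
        cfg.cohort.n_patients = 10
        c = syn.simulate_cohort(cfg)
        reg = en.Regulon(en.GeneSet("up", {"cg_1"}), en.GeneSet("down", {"cg_2"}))
        with pytest.raises(ValueError, match="overlap"):
            en.patient_activity(c.expression, reg, n_perm=150)
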