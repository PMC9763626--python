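"""Transforms, PLS-DA VIP, differential calling, classification, trees."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qkmgwas.metabolites import (
    MetaboliteMatrix,
    classify_inducible_constitutive,
    differential_call,
    four_group_fc,
    log2_transform,
    minmax_normalize,
    nj_from_distance,
    pca_scores,
    plsda_vip,
    sample_nj_tree,
    simple_matching_distance,
    spearman_matrix,
)
from qkmgwas.simulate import SimConfig, simulate_cohort, simulate_genotypes, simulate_metabolites


def make_matrix(ab, conditions, groups, accessions=None):
    n = ab.shape[0]
    ids = [f"s{i}" for i in range(n)]
    ab = pd.DataFrame(ab, index=ids,
                      columns=[f"m{j}" for j in range(ab.shape[1])])
    meta = pd.DataFrame({
        "accession": accessions or ids,
        "condition": conditions, "group": groups}, index=ids)
    return MetaboliteMatrix(ab, meta)


class TestTransforms:
    def test_log2_and_minmax(self):
        M = pd.DataFrame({"a": [2.0, 8.0]})
        assert list(log2_transform(M)["a"]) == [1.0, 3.0]
        assert list(minmax_normalize(M)["a"]) == [0.0, 1.0]

    def test_constant_feature_maps_to_zero(self):
        M = pd.DataFrame({"a": [5.0, 5.0, 5.0]})
        assert (minmax_normalize(M)["a"] == 0).all()

    def test_minmax_bounds(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.lognormal(size=(20, 5)))
        out = minmax_normalize(M).to_numpy()
        assert out.min() >= 0 and out.max() <= 1

    def test_log2_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log2_transform(pd.DataFrame({"a": [1.0, 0.0]}))


class TestVip:
    def test_square_sum_conservation(self):
        rng = np.random.default_rng(1)
        for p in (10, 50):
            X = rng.normal(size=(30, p))
            classes = np.array([0] * 15 + [1] * 15)
            vip = plsda_vip(X, classes)
            assert np.sum(vip ** 2) == pytest.approx(p, rel=1e-6)

    def test_informative_feature_has_max_vip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 51), scale=0.5)
        classes = np.array([0] * 20 + [1] * 20)
        X[:20, 0] += 3.0
        vip = plsda_vip(X, classes)
        assert np.argmax(vip) == 0
        assert vip[0] > 1.0

    def test_single_component_formula_collapse(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(24, 8))
        classes = np.array([0, 1] * 12)
        vip = plsda_vip(X, classes, n_components=1)
        # re-derive w1 from the NIPALS definition: w ~ X' y (autoscaled)
        y = np.where(classes == np.unique(classes)[0], -1.0, 1.0)
        Xc = X - X.mean(axis=0)
        Xs = Xc / Xc.std(axis=0, ddof=1)
        w = Xs.T @ y
        w = w / np.linalg.norm(w)
        expected = np.sqrt(8) * np.abs(w)
        assert np.allclose(vip, expected, rtol=1e-8)

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 12))
        X[:15, 3] += 2.0
        classes = np.array([0] * 15 + [1] * 15)
        vip = plsda_vip(X, classes)
        perm = rng.permutation(12)
        vip_p = plsda_vip(X[:, perm], classes)
        assert np.allclose(vip[perm], vip_p, rtol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            plsda_vip(np.zeros((6, 3)), np.zeros(6))


class TestDifferentialCall:
    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(5)
        block = rng.lognormal(mean=3, size=(6, 10))
        ab = np.vstack([block, block])
        M = make_matrix(ab, ["CK"] * 6 + ["DS"] * 6, ["intermediate"] * 12)
        res = differential_call(M, M.select(condition="CK"),
                                M.select(condition="DS"))
        assert np.allclose(res["fc"], 1.0)
        assert (res["call"] == "ns").all()

    def test_planted_induction_called_up(self):
        rng = np.random.default_rng(6)
        base = rng.normal(10, 0.2, size=(80, 20))
        ab = 2.0 ** base
        ab[40:, 0] *= 2.0  # 2x induced feature
        M = make_matrix(ab, ["CK"] * 40 + ["DS"] * 40, ["intermediate"] * 80)
        res = differential_call(M, M.select(condition="CK"),
                                M.select(condition="DS"))
        assert res.iloc[0]["call"] == "up"
        assert res.iloc[0]["fc"] == pytest.approx(2.0, rel=0.1)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(7)
        ab = rng.lognormal(3, 0.5, size=(20, 15))
        ab[:10, 2] *= 3.0
        M = make_matrix(ab, ["CK"] * 10 + ["DS"] * 10, ["intermediate"] * 20)
        fwd = differential_call(M, M.select(condition="CK"),
                                M.select(condition="DS"))
        rev = differential_call(M, M.select(condition="DS"),
                                M.select(condition="CK"))
        assert np.allclose(fwd["fc"], 1 / rev["fc"], rtol=1e-10)
        assert np.allclose(fwd["p_raw"], rev["p_raw"], rtol=1e-9)
        swapped = {"up": "down", "down": "up", "ns": "ns"}
        assert (fwd["call"].map(swapped) == rev["call"]).to_numpy().all()

    def test_null_features_false_call_budget(self):
        # 1000 pure-noise features across 20 seeds: BH keeps false calls
        # at or below ~0.05 * 1000 per seed on average; observe <= 75 total
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ab = rng.lognormal(3, 0.3, size=(20, 50))
            M = make_matrix(ab, ["CK"] * 10 + ["DS"] * 10,
                            ["intermediate"] * 20)
            res = differential_call(M, M.select(condition="CK"),
                                    M.select(condition="DS"))
            total += int((res["call"] != "ns").sum())
        assert total <= 75


class TestFourGroup:
    def build(self, seed=8, const_feature=False):
        rng = np.random.default_rng(seed)
        n_per = 10
        ab = rng.lognormal(3, 0.05, size=(4 * n_per, 12))
        conditions = (["CK"] * n_per + ["DS"] * n_per) * 2
        groups = ["R"] * (2 * n_per) + ["S"] * (2 * n_per)
        if const_feature:
            ab[: 2 * n_per, 0] *= 2.0  # R = 2 x S in both conditions
        return make_matrix(ab, conditions, groups)

    def test_identical_cells_unit_fc(self):
        ab = np.full((8, 5), 7.0)
        M = make_matrix(ab, ["CK", "DS"] * 4,
                        ["R", "R", "R", "R", "S", "S", "S", "S"])
        fc, tests = four_group_fc(M)
        assert np.allclose(fc.to_numpy(), 1.0)
        assert all(p == 1.0 or np.isnan(p) for p in tests.values())

    def test_constitutive_feature_pattern(self):
        fc, _ = four_group_fc(self.build(const_feature=True))
        row = fc.iloc[0]
        assert row["R_CK/S_CK"] == pytest.approx(2.0, rel=0.1)
        assert row["R_DS/S_DS"] == pytest.approx(2.0, rel=0.1)
        assert row["R_DS/R_CK"] == pytest.approx(1.0, abs=0.1)

    def test_shifted_distributions_detected(self):
        # constitutive |log2FC| magnitudes shifted up by 0.5 SD across
        # 300 features: the pooled Wilcoxon contrast flags it (p < 0.001
        # in >= 90% of seeds)
        hits = 0
        n_feat, sigma = 300, 0.4
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            a = np.abs(rng.normal(0, sigma, n_feat))       # induction
            c = np.abs(rng.normal(0, sigma, n_feat)) + 0.5 * sigma
            sa = rng.choice([-1, 1], n_feat)
            sc = rng.choice([-1, 1], n_feat)
            base = 2.0 ** rng.normal(10, 1, n_feat)
            cells = {
                ("S", "CK"): base,
                ("S", "DS"): base * 2.0 ** (sa * a),
                ("R", "CK"): base * 2.0 ** (sc * c),
                ("R", "DS"): base * 2.0 ** (sc * c + sa * a),
            }
            rows, conds, grps = [], [], []
            for (g, cond), mean in cells.items():
                for rep in range(3):
                    rows.append(mean * 2.0 ** rng.normal(0, 0.01, n_feat))
                    conds.append(cond)
                    grps.append(g)
            M = make_matrix(np.vstack(rows), conds, grps)
            _, tests = four_group_fc(M)
            hits += tests["constitutive vs induced (pooled)"] < 0.001
        assert hits >= 9

    def test_missing_cell_rejected(self):
        ab = np.full((4, 3), 2.0)
        M = make_matrix(ab, ["CK"] * 4, ["R", "R", "S", "S"])
        with pytest.raises(ValueError, match="empty"):
            four_group_fc(M)


class TestClassification:
    def calls(self, features, called):
        df = pd.DataFrame({"call": ["ns"] * len(features)}, index=features)
        for f, c in called.items():
            df.loc[f, "call"] = c
        return df

    def test_rule_application(self):
        feats = ["a", "b", "c", "d"]
        diff_all = self.calls(feats, {"a": "up", "d": "up"})
        diff_ck = self.calls(feats, {"b": "up", "d": "up"})
        diff_ds = self.calls(feats, {"b": "up", "d": "up"})
        labels = classify_inducible_constitutive(diff_all, diff_ck, diff_ds)
        assert labels["a"] == "inducible"
        assert labels["b"] == "constitutive_differential"
        assert labels["c"] == "neither"
        assert labels["d"] == "both"

    def test_direction_must_agree_for_constitutive(self):
        feats = ["a"]
        diff_all = self.calls(feats, {})
        diff_ck = self.calls(feats, {"a": "up"})
        diff_ds = self.calls(feats, {"a": "down"})
        labels = classify_inducible_constitutive(diff_all, diff_ck, diff_ds)
        assert labels["a"] == "neither"

    def test_labels_partition_features(self):
        rng = np.random.default_rng(9)
        feats = [f"m{i}" for i in range(50)]
        opts = ["up", "down", "ns"]
        diff_all = self.calls(feats, {f: rng.choice(opts) for f in feats})
        diff_ck = self.calls(feats, {f: rng.choice(opts) for f in feats})
        diff_ds = self.calls(feats, {f: rng.choice(opts) for f in feats})
        labels = classify_inducible_constitutive(diff_all, diff_ck, diff_ds)
        assert set(labels.unique()) <= {"inducible",
                                        "constitutive_differential",
                                        "both", "neither"}
        assert len(labels) == 50

    def test_simulated_recovery_low_noise(self):
        # 10 planted inducible + 10 constitutive features; >= 18/20 labelled
        # correctly at low noise
        n_met = 40
        lfc = np.zeros(n_met)
        lfc[:10] = 1.5          # inducible
        const = np.zeros(n_met)
        const[10:20] = 1.5      # constitutive R-vs-S
        cfg = SimConfig(n_accessions=246, n_snps=60, n_metabolites=n_met,
                        induction_log2fc=lfc, constitutive_log2fc=const,
                        h2_mean=0.05, metabolite_noise_sd=0.3,
                        causal_dsi_effect=2.0, liability_noise_sd=0.3,
                        missing_rate=0.0, seed=77)
        _, _, dsi, ck, ds, _ = simulate_cohort(cfg)
        all_ab = pd.concat([ck.abundances, ds.abundances])
        all_meta = pd.concat([ck.sample_meta, ds.sample_meta])
        M = MetaboliteMatrix(all_ab, all_meta)
        diff_all = differential_call(M, M.select(condition="CK"),
                                     M.select(condition="DS"))
        diff_ck = differential_call(M, M.select(condition="CK", group="S"),
                                    M.select(condition="CK", group="R"))
        diff_ds = differential_call(M, M.select(condition="DS", group="S"),
                                    M.select(condition="DS", group="R"))
        labels = classify_inducible_constitutive(diff_all, diff_ck, diff_ds)
        correct = sum(labels.iloc[j] == "inducible" for j in range(10))
        correct += sum(labels.iloc[j] == "constitutive_differential"
                       for j in range(10, 20))
        assert correct >= 18


class TestCorrelationAndTrees:
    def test_spearman_monotone_and_negation(self):
        x = np.arange(10, dtype=float)
        M = pd.DataFrame({"a": x, "b": np.exp(x), "c": -x})
        rho, _ = spearman_matrix(M)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(10)
        M = pd.DataFrame(rng.normal(size=(10, 6)))
        rho, _ = spearman_matrix(M)
        for i in range(6):
            for j in range(6):
                ri = stats.rankdata(M.iloc[:, i])
                rj = stats.rankdata(M.iloc[:, j])
                assert rho.iloc[i, j] == pytest.approx(
                    np.corrcoef(ri, rj)[0, 1], rel=1e-10)

    def test_constant_feature_is_na(self):
        M = pd.DataFrame({"a": np.arange(6.0), "b": np.ones(6)})
        rho, _ = spearman_matrix(M)
        assert rho["b"].isna().all()

    def test_identical_samples_zero_distance(self):
        rng = np.random.default_rng(11)
        row = rng.normal(size=12)
        M = pd.DataFrame([row, row, rng.normal(size=12),
                          rng.normal(size=12)],
                         index=["a", "b", "c", "d"])
        D = simple_matching_distance(M)
        assert D.loc["a", "b"] == 0.0
        newick = sample_nj_tree(M)
        for name in "abcd":
            assert name in newick

    def test_nj_recovers_additive_tree(self):
        # 5-taxon additive ((A:2,B:3):1,(C:1,D:4):2,E:5) distances
        D = pd.DataFrame(
            [[0, 5, 6, 9, 8],
             [5, 0, 7, 10, 9],
             [6, 7, 0, 5, 8],
             [9, 10, 8, 0, 11],
             [8, 9, 8, 11, 0]],
            index=list("ABCDE"), columns=list("ABCDE"), dtype=float)
        # rebuild exact additive distances from the generating tree
        bl = {"A": 2, "B": 3, "C": 1, "D": 4, "E": 5}
        paths = {
            ("A", "B"): bl["A"] + bl["B"],
            ("A", "C"): bl["A"] + 1 + 2 + bl["C"],
            ("A", "D"): bl["A"] + 1 + 2 + bl["D"],
            ("A", "E"): bl["A"] + 1 + bl["E"],
            ("B", "C"): bl["B"] + 1 + 2 + bl["C"],
            ("B", "D"): bl["B"] + 1 + 2 + bl["D"],
            ("B", "E"): bl["B"] + 1 + bl["E"],
            ("C", "D"): bl["C"] + bl["D"],
            ("C", "E"): bl["C"] + 2 + bl["E"],
            ("D", "E"): bl["D"] + 2 + bl["E"],
        }
        for (i, j), d in paths.items():
            D.loc[i, j] = D.loc[j, i] = float(d)
        newick = nj_from_distance(D)
        import skbio
        tree = skbio.TreeNode.read([newick])
        # topology: A-B form a clade (vs C,D,E) and C-D form a clade
        dist = {(i, j): tree.find(i).distance(tree.find(j))
                for (i, j) in paths}
        for pair, d in paths.items():
            assert dist[pair] == pytest.approx(d, abs=1e-10)

    def test_nj_three_point_on_ultrametric(self):
        # ultrametric distances: three-point condition must be respected
        D = pd.DataFrame(
            [[0, 2, 8, 8],
             [2, 0, 8, 8],
             [8, 8, 0, 4],
             [8, 8, 4, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float)
        newick = nj_from_distance(D)
        import skbio
        tree = skbio.TreeNode.read([newick])
        d = {(i, j): tree.find(i).distance(tree.find(j))
             for i in "abcd" for j in "abcd" if i < j}
        for (i, j), v in d.items():
            assert v == pytest.approx(D.loc[i, j], abs=1e-10)

    def test_too_few_samples_rejected(self):
        M = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 4)))
        with pytest.raises(ValueError):
            sample_nj_tree(M)


class TestPca:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(12)
        row = rng.normal(size=6)
        M = pd.DataFrame([row, row, rng.normal(size=6), rng.normal(size=6)])
        scores, _ = pca_scores(M)
        assert np.allclose(scores.iloc[0], scores.iloc[1])

    def test_rank_one_explains_everything(self):
        u = np.arange(5, dtype=float)[:, None]
        v = np.array([1.0, 2.0, 3.0])[None, :]
        M = pd.DataFrame(u @ v)
        _, evr = pca_scores(M, 2)
        assert evr[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(13)
        M = pd.DataFrame(rng.normal(size=(8, 5)))
        scores, evr = pca_scores(M, 3)
        Xc = M.to_numpy() - M.to_numpy().mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        oracle = Xc @ V[:, :3]
        for k in range(3):
            assert (np.allclose(scores.iloc[:, k], oracle[:, k], atol=1e-8)
                    or np.allclose(scores.iloc[:, k], -oracle[:, k],
                                   atol=1e-8))
        assert np.allclose(evr, w[:3] / w.sum(), rtol=1e-10)
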