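import numpy as np
import pandas as pd
import pytest

import oracles
from rectomics.selection import (
    RankingConfig,
    affinity_propagation_select,
    apply_minmax,
    correlation_prune,
    feature_auc,
    fit_minmax,
    mrmr_rank,
    overfitting_point,
    stability_ranking,
)
from rectomics.synthetic import TabularSpec, generate_feature_table


class TestMinMax:
    def test_midpoint_maps_to_half(self):
        table = pd.DataFrame({"f": [2.0, 6.0, 10.0]})
        params = fit_minmax(table, ["f"])
        out = apply_minmax(params, table)
        assert list(out["f"]) == [0.0, 0.5, 1.0]

    def test_validation_rows_extrapolate_unclipped(self):
        constr = pd.DataFrame({"f": [2.0, 10.0]})
        params = fit_minmax(constr, ["f"])
        out = apply_minmax(params, pd.DataFrame({"f": [12.0]}))
        assert out["f"].iloc[0] == pytest.approx(1.25)

    def test_constant_feature_maps_to_zero(self):
        constr = pd.DataFrame({"f": [3.0, 3.0, 3.0]})
        out = apply_minmax(fit_minmax(constr, ["f"]), constr)
        assert (out["f"] == 0.0).all()


class TestFeatureAUC:
    def test_perfect_separation(self):
        assert feature_auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_folding_makes_direction_irrelevant(self):
        v = np.array([1, 2, 3, 4.0])
        assert feature_auc(v, np.array([0, 1, 0, 1])) == pytest.approx(0.75)
        assert feature_auc(v, np.array([1, 1, 0, 0])) == 1.0  # reversed direction

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(6, 20)
            v = rng.integers(0, 5, size=n).astype(float)  # ties on purpose
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            folded = max(oracles.pairwise_auc(v, y), 1 - oracles.pairwise_auc(v, y))
            assert feature_auc(v, y) == pytest.approx(folded)

    def test_invariant_under_minmax_scaling(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        scaled = (v - v.min()) / (v.max() - v.min())
        assert feature_auc(v, y) == pytest.approx(feature_auc(scaled, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            feature_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestCorrelationPrune:
    def test_duplicate_drops_lower_auc_member(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        kept = correlation_prune(table, {"a": 0.8, "b": 0.6, "c": 0.55}, 0.85)
        assert kept == ["a", "c"]

    def test_equal_auc_drops_lexicographically_later(self):
        x = np.random.default_rng(3).normal(size=30)
        table = pd.DataFrame({"beta": x, "alpha": x})
        kept = correlation_prune(table, {"alpha": 0.7, "beta": 0.7}, 0.85)
        assert kept == ["alpha"]

    def test_independent_features_all_retained(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        kept = correlation_prune(table, {"a": 0.9, "b": 0.8, "c": 0.7}, 0.85)
        assert kept == ["a", "b", "c"]

    def test_chain_resolution(self):
        # A~B and B~C tied at r ~ 0.866, A~C at exactly 0.5; AUC A > B > C:
        # B is removed first, leaving A and C (their pair is below threshold)
        rng = np.random.default_rng(5)
        n = 50
        u1 = rng.normal(size=n)
        u1 = (u1 - u1.mean()) / np.linalg.norm(u1 - u1.mean())
        v = rng.normal(size=n)
        v = v - v.mean()
        u2 = v - (u1 @ v) * u1
        u2 /= np.linalg.norm(u2)
        a = u1
        c = 0.5 * u1 + np.sqrt(0.75) * u2  # exact sample correlation 0.5 with A
        b = a + c  # exact r(A,B) = r(B,C) = 1.5/sqrt(3) ~ 0.866
        table = pd.DataFrame({"A": a, "B": b, "C": c})
        corr = table.corr().abs()
        assert corr.loc["A", "B"] == pytest.approx(corr.loc["B", "C"])
        assert corr.loc["A", "B"] > 0.85 > corr.loc["A", "C"]
        kept = correlation_prune(table, {"A": 0.9, "B": 0.8, "C": 0.7}, 0.85)
        assert kept == ["A", "C"]


class TestStabilityRanking:
    def test_strong_feature_always_selected(self):
        rng = np.random.default_rng(6)
        n = 60
        y = np.repeat([0, 1], n // 2)
        table = pd.DataFrame(rng.normal(size=(n, 20)),
                             columns=[f"n{i}" for i in range(20)])
        table["signal"] = rng.normal(size=n) + 2.0 * y  # d = 2
        res = stability_ranking(table, y, RankingConfig(rng_seed=0))
        assert res.selection_counts["signal"] == 100
        assert res.ordered_features[0] == "signal"

    def test_duplicate_pair_counts_split(self):
        """At most one member of an exact duplicate pair survives each
        resample, so their counts sum to ~the number of resamples."""
        rng = np.random.default_rng(7)
        n = 60
        y = np.repeat([0, 1], n // 2)
        sig = rng.normal(size=n) + 1.5 * y
        table = pd.DataFrame({
            "sig_a": sig, "sig_b": 0.95 * sig + 0.05 * rng.normal(size=n),
            "noise": rng.normal(size=n),
        })
        res = stability_ranking(table, y, RankingConfig(rng_seed=0, min_selections=1))
        total = res.selection_counts["sig_a"] + res.selection_counts["sig_b"]
        assert 95 <= total <= 105

    def test_single_resample_reduces_to_one_prune_pass(self):
        rng = np.random.default_rng(8)
        n = 40
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=n) + y
        table = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=n)})
        cfg = RankingConfig(resamples=1, min_selections=1, resample_fraction=1.0, rng_seed=0)
        res = stability_ranking(table, y, cfg)
        aucs = {f: feature_auc(table[f].to_numpy(), y) for f in table.columns}
        expected = set(correlation_prune(table, aucs, 0.85))
        assert set(res.ordered_features) == expected

    def test_seeded_runs_are_bit_reproducible(self):
        table, y, _ = generate_feature_table(TabularSpec(n_cases=40, rng_seed=3))
        r1 = stability_ranking(table, y, RankingConfig(rng_seed=5, min_selections=50))
        r2 = stability_ranking(table, y, RankingConfig(rng_seed=5, min_selections=50))
        assert r1.ordered_features == r2.ordered_features
        assert r1.selection_counts == r2.selection_counts

    def test_no_survivor_raises_actionable_error(self):
        rng = np.random.default_rng(9)
        y = np.tile([0, 1], 15)
        shared = rng.normal(size=30)
        # strongly redundant noise pair: each resample prunes one member at
        # random, so neither can be selected in (almost) every resample
        table = pd.DataFrame({
            "a": shared + 0.3 * rng.normal(size=30),
            "b": shared + 0.3 * rng.normal(size=30),
        })
        with pytest.raises(ValueError, match="relaxing"):
            stability_ranking(table, y, RankingConfig(rng_seed=0, min_selections=98))


class TestOverfittingPoint:
    @staticmethod
    def _factory():
        from sklearn.svm import SVC

        return lambda: SVC(kernel="linear", C=1.0)

    def _split(self, seed=0, n=48, p=8, d=1.2):
        rng = np.random.default_rng(seed)
        y = np.tile([0, 1], n // 2)
        x = rng.normal(size=(n, p))
        x[:, 0] += d * y
        x[:, 1] += 0.8 * d * y
        cols = [f"f{i}" for i in range(p)]
        table = pd.DataFrame(x, columns=cols)
        return table.iloc[: n // 2], y[: n // 2], table.iloc[n // 2:], y[n // 2:], cols

    def test_curves_cover_all_sizes(self):
        tr, ytr, te, yte, cols = self._split()
        chosen, curves = overfitting_point(cols, self._factory(), tr, ytr, te, yte, seed=0)
        assert [c[0] for c in curves] == list(range(1, len(cols) + 1))
        assert 1 <= chosen <= len(cols)

    def test_stated_rule_on_synthetic_curves(self):
        from rectomics.selection import choose_overfitting_size

        # train (.80,.85,.90), test (.75,.78,.70): stop at the .78 point
        assert choose_overfitting_size([0.80, 0.85, 0.90], [0.75, 0.78, 0.70]) == 2
        # monotone increasing test curve: no overfitting point, take them all
        assert choose_overfitting_size([0.7, 0.8, 0.9], [0.6, 0.7, 0.8]) == 3
        # all equal: tie resolves to the smallest size
        assert choose_overfitting_size([0.8] * 4, [0.7] * 4) == 1

    def test_all_equal_accuracies_choose_smallest(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 12)
        # pure noise: test accuracy flat-ish; tie rule -> small k
        table = pd.DataFrame(np.zeros((24, 4)), columns=list("abcd"))
        chosen, curves = overfitting_point(
            list("abcd"), self._factory(), table, y, table, y, seed=0
        )
        tests = [c[2] for c in curves]
        assert chosen == int(np.argmax(tests)) + 1 == 1


class TestAffinityPropagation:
    def _blocks(self, seed, n=80, blocks=3, per_block=5, r=0.95):
        rng = np.random.default_rng(seed)
        cols = {}
        membership = {}
        for b in range(blocks):
            shared = rng.normal(size=n)
            for j in range(per_block):
                name = f"b{b}_f{j}"
                cols[name] = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.normal(size=n)
                membership[name] = b
        return pd.DataFrame(cols), membership

    def test_three_blocks_one_exemplar_each(self):
        hits = 0
        for seed in range(10):
            table, membership = self._blocks(seed)
            res = affinity_propagation_select(table)
            blocks_hit = {membership[f] for f in res.ordered_features}
            if len(res.ordered_features) == 3 and blocks_hit == {0, 1, 2}:
                hits += 1
        assert hits >= 9  # >= 90% of seeds

    def test_matches_sklearn_reference(self):
        """Independent cross-check: sklearn's affinity propagation finds the
        same exemplar features on well-separated block data."""
        from sklearn.cluster import AffinityPropagation

        table, _ = self._blocks(42)
        res = affinity_propagation_select(table)
        x = table.to_numpy()
        z = (x - x.mean(0)) / x.std(0)
        ref = AffinityPropagation(damping=0.7, max_iter=500, convergence_iter=30,
                                  random_state=0).fit(z.T)
        ref_names = {table.columns[i] for i in ref.cluster_centers_indices_}
        assert set(res.ordered_features) == ref_names

    def test_two_orthogonal_features_stay_separate(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({"u": rng.normal(size=60), "v": rng.normal(size=60)})
        res = affinity_propagation_select(table)
        assert set(res.ordered_features) == {"u", "v"}

    def test_deterministic(self):
        table, _ = self._blocks(1)
        a = affinity_propagation_select(table)
        b = affinity_propagation_select(table)
        assert a.ordered_features == b.ordered_features


class TestMRMR:
    def test_single_feature_ranks_first(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 20)
        table = pd.DataFrame({"only": rng.normal(size=40) + y})
        res = mrmr_rank(table, y)
        assert res.ordered_features == ["only"]

    def test_copy_of_top_feature_is_demoted(self):
        """An exact copy of the selected top feature collapses its quotient
        and ranks below an independent, weaker informative feature."""
        rng = np.random.default_rng(13)
        n = 400
        y = np.repeat([0, 1], n // 2)
        strong = rng.normal(size=n) + 2.0 * y
        weak = rng.normal(size=n) + 0.8 * y
        table = pd.DataFrame({"strong": strong, "copy": strong.copy(), "weak": weak})
        res = mrmr_rank(table, y)
        order = res.ordered_features
        assert order[0] in ("strong", "copy")  # the twins tie on relevance
        loser = "copy" if order[0] == "strong" else "strong"
        assert order.index("weak") < order.index(loser)

    def test_uninformative_feature_ranks_last(self):
        rng = np.random.default_rng(14)
        n = 300
        y = np.repeat([0, 1], n // 2)
        table = pd.DataFrame({
            "inf1": rng.normal(size=n) + 1.5 * y,
            "inf2": rng.normal(size=n) + 1.0 * y,
            "dead": rng.normal(size=n),
        })
        res = mrmr_rank(table, y)
        assert res.ordered_features[-1] == "dead"
        assert res.per_feature_auc["dead"] < 0.05  # relevance MI near zero

    def test_deterministic_full_ordering(self):
        table, y, _ = generate_feature_table(TabularSpec(n_cases=50, rng_seed=2))
        assert mrmr_rank(table, y).ordered_features == mrmr_rank(table, y).ordered_features
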