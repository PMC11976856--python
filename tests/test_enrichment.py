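import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanopotency.enrichment import (
    GeneSetCollection,
    cluster_nes,
    compute_protein_fold_change,
    enrichment_score,
    gsea_preranked,
    overrepresentation_test,
)
from nanopotency.synthetic import generate_protein_matrix, make_gene_sets


def brute_force_es(scores, hit_flags, weight):
    """Independent oracle: literal walk of the ranked list.

    Returns (es, running) with the same tie rule as the spec of the
    operation under test: the sign whose extremum has the larger magnitude
    wins, positive on an exact tie.
    """
    n = len(scores)
    n_hit = sum(hit_flags)
    denom_hit = sum(abs(s) ** weight if weight != 0 else 1.0
                    for s, h in zip(scores, hit_flags) if h)
    running = []
    total = 0.0
    for s, h in zip(scores, hit_flags):
        if h:
            w = abs(s) ** weight if weight != 0 else 1.0
            total += w / denom_hit
        else:
            total -= 1.0 / (n - n_hit)
        running.append(total)
    mx, mn = max(running), min(running)
    if max(mx, 0.0) >= max(-mn, 0.0) - 1e-12:  # positive wins near-ties
        es = mx if mx > 0 else 0.0
    else:
        es = mn
    return es, running


def ranked_frame(scores, ids=None):
    ids = ids or [f"P{i}" for i in range(len(scores))]
    return pd.DataFrame({"protein": ids, "score": scores})


class TestEnrichmentScore:
    def test_top_ranked_singleton_weight_zero(self):
        ranked = ranked_frame([4.0, 3.0, 2.0, 1.0])
        es, _, leading = enrichment_score(ranked, {"P0"}, weight=0)
        assert es == pytest.approx(1.0)
        assert leading == ("P0",)

    def test_bottom_ranked_singleton_weight_zero(self):
        ranked = ranked_frame([4.0, 3.0, 2.0, 1.0])
        es, _, leading = enrichment_score(ranked, {"P3"}, weight=0)
        assert es == pytest.approx(-1.0)
        assert leading == ("P3",)

    def test_hand_enumerated_weighted_example(self):
        ranked = ranked_frame([3.0, 2.0, 1.0, 0.5])
        es, running, leading = enrichment_score(ranked, {"P0", "P2"}, weight=1)
        assert np.allclose(running, [0.75, 0.25, 0.5, 0.0])
        assert es == pytest.approx(0.75)
        assert leading == ("P0",)

    def test_es_in_unit_interval(self, rng):
        scores = np.sort(rng.normal(size=30))[::-1]
        ranked = ranked_frame(list(scores))
        for k in (1, 5, 15, 29):
            members = {f"P{i}" for i in rng.choice(30, size=k, replace=False)}
            es, _, _ = enrichment_score(ranked, members)
            assert -1.0 <= es <= 1.0

    def test_antisymmetry_under_score_negation(self, rng):
        scores = np.sort(rng.normal(size=20))[::-1]
        ranked = ranked_frame(list(scores))
        neg = ranked_frame(list(-scores[::-1]), ids=[f"P{i}" for i in range(19, -1, -1)])
        members = {"P2", "P7", "P11"}
        es_pos, _, _ = enrichment_score(ranked, members)
        es_neg, _, _ = enrichment_score(neg, members)
        assert es_neg == pytest.approx(-es_pos, abs=1e-12)

    def test_weight_zero_is_ks_statistic(self, rng):
        scores = np.sort(rng.normal(size=15))[::-1]
        ranked = ranked_frame(list(scores))
        members = {"P1", "P4", "P9", "P12"}
        es, _, _ = enrichment_score(ranked, members, weight=0)
        hits = np.array([i in (1, 4, 9, 12) for i in range(15)])
        cdf_hit = np.cumsum(hits) / hits.sum()
        cdf_miss = np.cumsum(~hits) / (~hits).sum()
        diffs = cdf_hit - cdf_miss
        expected = diffs[np.argmax(np.abs(diffs))]
        assert es == pytest.approx(expected, abs=1e-12)

    def test_no_overlap_or_full_overlap_raise(self):
        ranked = ranked_frame([3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"X"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"P0", "P1", "P2"})

    @given(
        st.integers(4, 10),
        st.randoms(use_true_random=False),
        st.sampled_from([0.0, 0.5, 1.0, 2.0]),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_on_random_instances(self, n, rnd, weight):
        # scores kept away from 0: a zero-score hit has no defined weighted
        # increment (the implementation raises for all-zero hit weights)
        scores = sorted(
            ((1 if rnd.random() < 0.5 else -1) * rnd.uniform(0.01, 3)
             for _ in range(n)),
            reverse=True,
        )
        k = rnd.randint(1, n - 1)
        idx = sorted(rnd.sample(range(n), k))
        members = {f"P{i}" for i in idx}
        ranked = ranked_frame(scores)
        es, running, _ = enrichment_score(ranked, members, weight=weight)
        es_bf, running_bf = brute_force_es(
            scores, [i in idx for i in range(n)], weight)
        assert np.allclose(running, running_bf, atol=1e-12)
        assert es == pytest.approx(es_bf, abs=1e-12)


class TestComputeProteinFoldChange:
    def test_equal_conditions_give_unit_scores(self):
        mat = pd.DataFrame(np.ones((5, 3)), index=[f"P{i}" for i in range(5)])
        ranked = compute_protein_fold_change(mat, mat.copy())
        assert np.allclose(ranked["score"], 1.0)

    def test_doubled_protein_ranks_first(self):
        control = pd.DataFrame(np.full((4, 3), 10.0),
                               index=[f"P{i}" for i in range(4)])
        treated = control.copy()
        treated.loc["P2"] = 20.0
        ranked = compute_protein_fold_change(treated, control)
        assert ranked.iloc[0]["protein"] == "P2"
        assert ranked.iloc[0]["score"] == pytest.approx(2.0)

    def test_min_obs_filter_drops_sparse_protein(self):
        idx = [f"P{i}" for i in range(3)]
        treated = pd.DataFrame(np.full((3, 3), 10.0), index=idx)
        treated.loc["P1", :] = [10.0, np.nan, np.nan]
        control = pd.DataFrame(np.full((3, 3), 10.0), index=idx)
        ranked = compute_protein_fold_change(treated, control, min_obs=2)
        assert "P1" not in set(ranked["protein"])
        assert len(ranked) == 2

    def test_ties_broken_by_id(self):
        mat = pd.DataFrame(np.ones((3, 2)), index=["b", "a", "c"])
        ranked = compute_protein_fold_change(mat, mat.copy())
        assert list(ranked["protein"]) == ["a", "b", "c"]

    def test_disjoint_universes_raise(self):
        a = pd.DataFrame(np.ones((2, 2)), index=["x", "y"])
        b = pd.DataFrame(np.ones((2, 2)), index=["u", "v"])
        with pytest.raises(ValueError, match="no proteins"):
            compute_protein_fold_change(a, b)


class TestGseaPreranked:
    def test_reproducible_given_seed(self, rng):
        scores = np.sort(rng.normal(size=50))[::-1]
        ranked = ranked_frame(list(scores))
        sets = GeneSetCollection({"S1": frozenset({"P1", "P5", "P9"}),
                                  "S2": frozenset({"P40", "P44", "P48"})})
        a = gsea_preranked(ranked, sets, n_perm=200, seed=7)
        b = gsea_preranked(ranked, sets, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_set_detected(self):
        sets = make_gene_sets(150, n_sets=6, set_size=10, seed=3)
        treated, control = generate_protein_matrix(
            150, sets, {"SET002": 2.0}, n_reps=3, seed=5)
        ranked = compute_protein_fold_change(treated, control)
        res = gsea_preranked(ranked, sets, n_perm=500, seed=11)
        row = res.set_index("set").loc["SET002"]
        assert row["nes"] > 1.5
        assert row["fdr_q"] < 0.05

    def test_sign_consistency_and_leading_edge_membership(self, rng):
        scores = np.sort(rng.normal(size=60))[::-1]
        ranked = ranked_frame(list(scores))
        sets = make_gene_sets(60, n_sets=5, set_size=8, seed=2, prefix="P_SET")
        # remap synthetic ids (P%05d) onto this universe's P%d ids
        remapped = GeneSetCollection({
            name: frozenset(f"P{int(m[1:])}" for m in members)
            for name, members in sets.items()
        })
        res = gsea_preranked(ranked, remapped, n_perm=100, seed=0)
        for _, row in res.iterrows():
            assert np.sign(row["nes"]) == np.sign(row["es"]) or row["es"] == 0
            leading = set(row["leading_edge"].split(",")) if row["leading_edge"] else set()
            assert leading <= remapped[row["set"]]

    def test_no_overlap_set_skipped_with_warning(self, rng):
        ranked = ranked_frame([3.0, 2.0, 1.0, 0.5])
        sets = GeneSetCollection({"GOOD": frozenset({"P0", "P2"}),
                                  "NOPE": frozenset({"X1", "X2"})})
        with pytest.warns(UserWarning, match="no overlap"):
            res = gsea_preranked(ranked, sets, n_perm=100, seed=0)
        assert set(res["set"]) == {"GOOD"}

    def test_n_perm_floor(self):
        ranked = ranked_frame([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="n_perm"):
            gsea_preranked(ranked, GeneSetCollection({"S": frozenset({"P0"})}),
                           n_perm=10, seed=0)


class TestClusterNes:
    def test_identical_rows_merge_first_at_zero(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, -2.0]],
            index=["r0", "r1", "r2"], columns=list("abc"))
        # correlation distance: r0 and r1 are perfectly correlated
        res = cluster_nes(mat, axis="rows")
        first = res.row_tree.merges[0]
        assert {first[0], first[1]} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_three_leaf_hand_dendrogram(self):
        # build rows with correlation distances d01=0, d02=d12=0.5
        base = np.array([1.0, 2.0, 3.0, 4.0])
        other = np.array([1.0, 3.0, 2.0, 4.0])  # corr(base, other) = 0.8
        # want d = 0.5 => corr 0.5; mix: corr of (a*base + b*orth) tunable
        x = (base - base.mean()) / base.std()
        e = other - other.mean()
        e = e - x * (e @ x) / (x @ x)
        e = e / np.sqrt((e**2).mean())
        y = 0.5 * x + np.sqrt(1 - 0.25) * e  # corr(x, y) = 0.5 exactly
        mat = pd.DataFrame([x, x * 2 + 1, y], index=["r0", "r1", "r2"])
        res = cluster_nes(mat, axis="rows", distance="correlation",
                          linkage="average")
        merges = res.row_tree.merges
        assert {merges[0][0], merges[0][1]} == {0, 1}
        assert merges[0][2] == pytest.approx(0.0, abs=1e-10)
        assert merges[1][2] == pytest.approx(0.5, abs=1e-10)
        assert res.row_tree.leaf_order == ("r0", "r1", "r2")

    def test_permutation_equivariance(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 8)),
                           index=[f"r{i}" for i in range(6)])
        res = cluster_nes(mat, axis="rows")
        perm = [3, 0, 5, 1, 4, 2]
        res_p = cluster_nes(mat.iloc[perm], axis="rows")

        def merge_leafsets(tree):
            n = len(tree.labels)
            sets = {i: frozenset([tree.labels[i]]) for i in range(n)}
            out = []
            for t, (a, b, h) in enumerate(tree.merges):
                sets[n + t] = sets[a] | sets[b]
                out.append((sets[n + t], round(h, 10)))
            return sorted(out, key=lambda x: (x[1], sorted(x[0])))

        assert merge_leafsets(res.row_tree) == merge_leafsets(res_p.row_tree)

    def test_merge_heights_non_decreasing(self, rng):
        for linkage in ("average", "complete"):
            mat = pd.DataFrame(rng.normal(size=(8, 10)))
            res = cluster_nes(mat, axis="rows", distance="euclidean",
                              linkage=linkage)
            heights = [m[2] for m in res.row_tree.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_pairwise_complete_with_missing(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, np.nan],
                            [1.0, 2.0, 3.0, 4.0],
                            [4.0, 3.0, 2.0, 1.0]])
        res = cluster_nes(mat, axis="rows")
        assert res.row_tree is not None

    def test_all_missing_row_raises(self):
        mat = pd.DataFrame([[np.nan] * 3, [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
                           index=["bad", "ok1", "ok2"])
        with pytest.raises(ValueError, match="bad"):
            cluster_nes(mat, axis="rows")

    def test_both_axes_and_newick_export(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 5)),
                           index=[f"r{i}" for i in range(4)],
                           columns=[f"c{j}" for j in range(5)])
        res = cluster_nes(mat, axis="both", distance="euclidean")
        assert res.row_tree.newick.endswith(";")
        assert res.col_tree.newick.endswith(";")
        assert sorted(res.matrix.index) == sorted(mat.index)
        assert sorted(res.matrix.columns) == sorted(mat.columns)


class TestOverrepresentation:
    def test_closed_form_hypergeometric(self):
        ids = [f"P{i}" for i in range(10)]
        # selection: P0..P3 (fold change 2, p tiny); set = P0..P4
        scores = ranked_frame([2.0] * 4 + [1.0] * 6, ids=ids)
        pvals = {i: 0.001 for i in ids}
        sets = GeneSetCollection({"S": frozenset(ids[:5])})
        res = overrepresentation_test(scores, pvals, sets)
        row = res.iloc[0]
        assert row["overlap"] == 4
        assert row["p_hypergeom"] == pytest.approx(5 / 210, abs=1e-12)
        assert row["identified"]

    def test_overlap_equal_expected_gives_zero_z(self):
        ids = [f"P{i}" for i in range(10)]
        # 4 selected out of 10; set of 5 -> expected overlap 2
        fc = [2.0, 2.0, 1.0, 1.0, 1.0, 2.0, 2.0, 1.0, 1.0, 1.0]
        scores = ranked_frame(fc, ids=ids)
        pvals = {i: 0.001 for i in ids}
        sets = GeneSetCollection({"S": frozenset(ids[:5])})  # overlap = 2
        res = overrepresentation_test(scores, pvals, sets)
        assert res.iloc[0]["z"] == pytest.approx(0.0, abs=1e-12)

    def test_threshold_definition(self):
        scores = ranked_frame([1.6, 1.4], ids=["hi", "lo"])
        pvals = {"hi": 0.01, "lo": 0.01}
        sets = GeneSetCollection({"S": frozenset({"hi"})})
        res = overrepresentation_test(scores, pvals, sets)
        assert res.iloc[0]["n_selected"] == 1
        assert res.iloc[0]["overlap"] == 1

    def test_downregulation_selected_via_reciprocal_cutoff(self):
        scores = ranked_frame([1.0, 0.5], ids=["flat", "down"])
        pvals = {"flat": 0.5, "down": 0.001}
        sets = GeneSetCollection({"S": frozenset({"down"})})
        res = overrepresentation_test(scores, pvals, sets)
        assert res.iloc[0]["n_selected"] == 1
        assert res.iloc[0]["overlap"] == 1

    def test_empty_selection_flagged_not_raised(self):
        scores = ranked_frame([1.0, 1.1], ids=["a", "b"])
        pvals = {"a": 0.9, "b": 0.9}
        sets = GeneSetCollection({"S": frozenset({"a"})})
        with pytest.warns(UserWarning, match="no proteins pass"):
            res = overrepresentation_test(scores, pvals, sets)
        assert (res["overlap"] == 0).all()
        assert not res["identified"].any()
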