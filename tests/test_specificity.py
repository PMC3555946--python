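"""Profile merging, specificity scores, permutation FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import isletmir as im


def naive_single_linkage(dist, height):
    """Exhaustive single-linkage agglomeration: repeatedly join the closest
    pair of clusters (min over cross-pairs) while the gap is < height."""
    clusters = [{i} for i in range(len(dist))]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = min(dist[i][j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        if best[0] >= height:
            break
        _, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    return sorted(frozenset(c) for c in clusters)


def _panel(values, tissues=None):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"m{i}" for i in range(arr.shape[0])],
        columns=tissues or [f"t{j}" for j in range(arr.shape[1])],
    )


class TestFilterMinExpression:
    def test_boundary(self):
        panel = _panel([[999, 0], [500, 500], [1200, 0]])
        out = im.filter_min_expression(panel)
        assert list(out.index) == ["m1", "m2"]

    def test_empty_result_then_scores_refuse(self):
        panel = _panel([[10, 20]])
        out = im.filter_min_expression(panel)
        assert out.empty
        merged = im.ProfileSet(profiles=out, provenance={})
        scores = im.specificity_scores(merged)
        assert scores.empty


class TestProfileCorrelation:
    def test_duplicated_profile_perfect(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.standard_normal(30) * 2)
        panel = _panel(np.column_stack([x, x, np.exp(rng.standard_normal(30))]))
        corr = im.profile_correlation(panel)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_antiproportional_minus_one(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        panel = _panel(np.column_stack([x, x[::-1]]))
        corr = im.profile_correlation(panel)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_three_tissue_hand_check(self):
        vals = np.array(
            [[1, 2, 10], [4, 5, 2], [16, 17, 80], [64, 60, 3], [256, 270, 7]],
            dtype=float,
        )
        panel = _panel(vals)
        corr = im.profile_correlation(panel)
        logs = np.log2(vals)
        for i, j in itertools.combinations(range(3), 2):
            rho = spearmanr(logs[:, i], logs[:, j]).statistic
            assert corr.iloc[i, j] == pytest.approx(rho)

    def test_pairwise_complete_ignores_zeros(self):
        panel = _panel([[2, 4], [8, 16], [0, 5], [32, 64]])
        corr = im.profile_correlation(panel)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_profile_fails(self):
        panel = _panel([[1, 3], [1, 9], [1, 27], [1, 81]])
        with pytest.raises(ValueError, match="undefined"):
            im.profile_correlation(panel)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            im.profile_correlation(_panel([[1], [2]]))


class TestMergeSimilarProfiles:
    def test_all_distant_identity(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        panel = _panel(np.ones((4, 3)), tissues=list("abc"))
        ps = im.merge_similar_profiles(corr, panel)
        assert len(ps.profiles.columns) == 3

    def test_duplicates_merge_to_mean(self):
        rng = np.random.default_rng(1)
        x = np.exp(2 * rng.standard_normal(40))
        y = np.exp(2 * rng.standard_normal(40))
        panel = _panel(np.column_stack([x, x * 1.001, y]), tissues=["a", "b", "c"])
        corr = im.profile_correlation(panel)
        ps = im.merge_similar_profiles(corr, panel)
        assert ps.provenance["a+b"] == ["a", "b"]
        assert np.allclose(
            ps.profiles["a+b"], (panel["a"] + panel["b"]) / 2
        )

    def test_synthetic_near_duplicate_pair_merges(self, panel_sim, merged_scores):
        profile_set, _ = merged_scores
        a, b = panel_sim.duplicate_pair
        merged_name = next(
            name for name, members in profile_set.provenance.items() if a in members
        )
        assert b in profile_set.provenance[merged_name]
        # and nothing else joined the twins
        assert sorted(profile_set.provenance[merged_name]) == sorted([a, b])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_single_linkage(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(3, 7))
        corr = pd.DataFrame(
            np.corrcoef(rng.standard_normal((n, 50))),
            index=[f"t{i}" for i in range(n)],
            columns=[f"t{i}" for i in range(n)],
        )
        panel = _panel(np.exp(rng.standard_normal((20, n))),
                       tissues=list(corr.columns))
        height = float(rng.uniform(0.1, 1.5))
        ps = im.merge_similar_profiles(corr, panel, height=height)
        got = sorted(
            frozenset(list(corr.columns).index(t) for t in members)
            for members in ps.provenance.values()
        )
        dist = squareform(pdist(corr.values)).tolist()
        assert got == naive_single_linkage(dist, height)

    def test_merging_monotone_in_height(self):
        rng = np.random.default_rng(9)
        corr = pd.DataFrame(np.corrcoef(rng.standard_normal((6, 30))))
        corr.index = corr.columns = [f"t{i}" for i in range(6)]
        panel = _panel(np.exp(rng.standard_normal((15, 6))),
                       tissues=list(corr.columns))
        sizes = [
            len(im.merge_similar_profiles(corr, panel, height=h).profiles.columns)
            for h in (0.05, 0.25, 0.8, 1.5)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestSpecificityScores:
    def test_direct_formula(self):
        ps = im.ProfileSet(profiles=_panel([[10, 30, 60]]), provenance={})
        scores = im.specificity_scores(ps)
        assert scores.iloc[0].tolist() == pytest.approx([0.1, 0.3, 0.6])

    def test_all_in_one_profile(self):
        scores = im.specificity_scores(_panel([[0, 0, 50]]))
        assert scores.iloc[0].tolist() == [0.0, 0.0, 1.0]

    def test_zero_row_undefined(self):
        scores = im.specificity_scores(_panel([[0, 0, 0], [1, 1, 2]]))
        assert scores.iloc[0].isna().all()
        assert scores.iloc[1].sum() == pytest.approx(1.0)

    def test_rows_sum_to_one(self, merged_scores):
        _, scores = merged_scores
        sums = scores.dropna().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_profile_rescaling_changes_scores_but_mirna_rescaling_not_rowwise(self):
        """Scores are invariant to rescaling a whole miRNA row, but NOT to
        rescaling one profile column (the declared asymmetry)."""
        base = _panel([[10, 30, 60], [5, 5, 10]])
        s0 = im.specificity_scores(base)
        row_scaled = base.copy()
        row_scaled.iloc[0] = base.iloc[0] * 7
        assert np.allclose(im.specificity_scores(row_scaled), s0)
        col_scaled = base.copy()
        col_scaled["t0"] = base["t0"] * 7
        assert not np.allclose(im.specificity_scores(col_scaled), s0)


class TestCallSpecific:
    def test_strict_cutoff(self):
        table = _panel([[0.5, 0.5], [0.51, 0.49]], tissues=["a", "b"])
        assert im.call_specific(table) == [("m1", "a")]

    def test_at_most_one_call_per_mirna(self, merged_scores):
        _, scores = merged_scores
        calls = im.call_specific(scores)
        mirnas = [m for m, _ in calls]
        assert len(mirnas) == len(set(mirnas))


class TestPermutationFdr:
    def _dominant_panel(self, rng, n_rows, n_tissues, ref_rows=None):
        """Rows with one dominant entry; its position is uniform unless a
        reference placement is forced."""
        scores = np.full((n_rows, n_tissues), 0.05)
        pos = (
            rng.integers(0, n_tissues, n_rows)
            if ref_rows is None
            else np.zeros(n_rows, dtype=int)
        )
        for i in range(n_rows):
            scores[i] = 0.1 / (n_tissues - 1)
            scores[i, pos[i]] = 0.9
        return _panel(scores, tissues=[f"t{j}" for j in range(n_tissues)])

    def test_exchangeable_panel_fdr_near_one(self):
        rng = np.random.default_rng(42)
        n_rows, T = 240, 8
        table = self._dominant_panel(rng, n_rows, T)
        rep = im.permutation_fdr(table, reference="t0", n_permutations=5000, seed=0)
        # observed ~ Binomial(240, 1/8); FDR should be 1 within 3 sd
        sd = np.sqrt(n_rows * (1 / T) * (1 - 1 / T))
        lo = (n_rows / T) / (n_rows / T + 3 * sd)
        hi = (n_rows / T) / max(n_rows / T - 3 * sd, 1)
        assert lo < rep.fdr < hi

    def test_strongly_planted_panel_fdr_below_point_two(self):
        rng = np.random.default_rng(43)
        T = 8
        planted = self._dominant_panel(rng, 12, T, ref_rows=True)  # all in t0
        spread = _panel(
            rng.dirichlet(np.full(T, 5.0), size=90),
            tissues=[f"t{j}" for j in range(T)],
        )
        spread.index = [f"n{i}" for i in range(90)]
        table = pd.concat([planted, spread])
        rep = im.permutation_fdr(table, reference="t0", n_permutations=5000, seed=1)
        assert rep.n_observed == 12
        assert rep.fdr < 0.2

    def test_deterministic(self, merged_scores):
        _, scores = merged_scores
        ref = scores.columns[0]
        a = im.permutation_fdr(scores, ref, n_permutations=500, seed=7)
        b = im.permutation_fdr(scores, ref, n_permutations=500, seed=7)
        assert a == b

    def test_zero_observed_fdr_undefined(self):
        table = _panel([[0.3, 0.3, 0.4]] * 5)
        rep = im.permutation_fdr(table, reference="t0", n_permutations=200, seed=0)
        assert rep.n_observed == 0
        assert rep.fdr is None

    def test_too_few_permutations_rejected(self, merged_scores):
        _, scores = merged_scores
        with pytest.raises(ValueError):
            im.permutation_fdr(scores, scores.columns[0], n_permutations=50)
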