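import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryocomp.errors import DegenerateInputError
from cryocomp.io_formats import GeneCountMatrix
from cryocomp.orthogroup_shift import (
    NormalizationConfig,
    ShiftConfig,
    normalize_counts,
    pca_scores,
    per_species_shift_counts,
    rank_shifts,
    species_correlation,
    trimmed_stats,
    ward_cluster,
    welch_t_scores,
)

from conftest import normalized_from


class TestTrimmedStats:
    @pytest.mark.parametrize(
        "values, trim, mean, sd",
        [
            ([1, 2, 3, 4, 100], 0.25, 3.0, 1.0),  # k=1 per tail, kept [2,3,4]
            ([5, 5, 5, 5], 0.25, 5.0, 0.0),
            ([1, 2], 0.25, 1.5, 0.7071067811865476),  # k=0, two-point sample SD
        ],
    )
    def test_hand_computed_examples(self, values, trim, mean, sd):
        m, s = trimmed_stats(values, trim)
        assert m == pytest.approx(mean, abs=1e-12)
        assert s == pytest.approx(sd, abs=1e-12)

    def test_fewer_than_two_kept_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            trimmed_stats([1, 2, 3], 0.4)  # k=1 per tail leaves 1 value

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40),
        st.floats(0, 0.49),
    )
    def test_matches_direct_sort_and_slice_oracle(self, values, trim):
        n = len(values)
        k = int(np.floor(trim * n))
        kept = sorted(values)[k : n - k]
        if len(kept) < 2:
            return
        m, s = trimmed_stats(values, trim)
        assert m == pytest.approx(np.mean(kept), rel=1e-9, abs=1e-9)
        assert s == pytest.approx(np.std(kept, ddof=1), rel=1e-9, abs=1e-9)


class TestNormalizeCounts:
    def test_hand_computed_midmean_scores(self):
        counts = pd.DataFrame([[2, 4, 6, 8]], index=["OG1"], columns=list("abcd"))
        norm = normalize_counts(GeneCountMatrix(counts))
        expected = np.array([-3, -1, 1, 3]) / np.sqrt(2)  # kept [4,6]: mean 5, sd sqrt2
        np.testing.assert_allclose(norm.scores.loc["OG1"], expected, atol=1e-12)

    def test_zero_sd_policy_zeros(self):
        counts = pd.DataFrame([[3, 3, 3, 3]], index=["OG1"], columns=list("abcd"))
        norm = normalize_counts(GeneCountMatrix(counts))
        assert (norm.scores.loc["OG1"] == 0).all()

    def test_zero_sd_policy_drop(self):
        counts = pd.DataFrame(
            [[3, 3, 3, 3], [1, 2, 3, 4]], index=["OG1", "OG2"], columns=list("abcd")
        )
        norm = normalize_counts(
            GeneCountMatrix(counts), NormalizationConfig(zero_sd_policy="drop")
        )
        assert norm.dropped_orthogroups == ["OG1"]
        assert norm.orthogroup_ids == ["OG2"]

    def test_scale_invariance(self):
        base = pd.DataFrame([[1, 2, 5, 9]], index=["OG1"], columns=list("abcd"))
        scaled = base * 10
        n1 = normalize_counts(GeneCountMatrix(base))
        n2 = normalize_counts(GeneCountMatrix(scaled))
        np.testing.assert_allclose(n1.scores, n2.scores, atol=1e-12)

    def test_shift_invariance(self):
        base = pd.DataFrame([[1, 2, 5, 9]], index=["OG1"], columns=list("abcd"))
        n1 = normalize_counts(GeneCountMatrix(base))
        n2 = normalize_counts(GeneCountMatrix(base + 7))
        np.testing.assert_allclose(n1.scores, n2.scores, atol=1e-12)


class TestWelchT:
    groups = {"p1": "p", "p2": "p", "b1": "b", "b2": "b"}

    def _normalized(self):
        return normalized_from(
            {"p1": [2.0], "p2": [0.0], "b1": [0.0], "b2": [-2.0]}, ["OG1"]
        )

    def test_welch_hand_example(self):
        s = welch_t_scores(self._normalized(), self.groups, "p")
        assert s.loc["OG1", "t"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_paper_literal_hand_example(self):
        s = welch_t_scores(
            self._normalized(), self.groups, "p", ShiftConfig(t_formula="paper_literal")
        )
        assert s.loc["OG1", "t"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_welch(self, rng):
        from scipy import stats

        scores = pd.DataFrame(
            rng.normal(size=(30, 6)),
            index=[f"OG{i}" for i in range(30)],
            columns=["p1", "p2", "p3", "b1", "b2", "b3"],
        )
        groups = {c: c[0] for c in scores.columns}
        norm = normalized_from({c: scores[c].tolist() for c in scores.columns}, list(scores.index))
        ours = welch_t_scores(norm, groups, "p")
        for og in scores.index:
            ref = stats.ttest_ind(
                scores.loc[og, ["p1", "p2", "p3"]],
                scores.loc[og, ["b1", "b2", "b3"]],
                equal_var=False,
            ).statistic
            assert ours.loc[og, "t"] == pytest.approx(ref, rel=1e-9)

    def test_antisymmetry_under_label_swap(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(20, 5)),
            index=[f"OG{i}" for i in range(20)],
            columns=["p1", "p2", "b1", "b2", "b3"],
        )
        norm = normalized_from({c: scores[c].tolist() for c in scores.columns}, list(scores.index))
        groups = {c: c[0] for c in scores.columns}
        t_p = welch_t_scores(norm, groups, "p")["t"]
        t_b = welch_t_scores(norm, groups, "b")["t"]
        np.testing.assert_allclose(t_p, -t_b, atol=1e-12)

    def test_both_sds_zero(self):
        norm = normalized_from(
            {"p1": [1.0, 1.0], "p2": [1.0, 1.0], "b1": [1.0, 0.0], "b2": [1.0, 0.0]},
            ["OG_equal", "OG_diff"],
        )
        s = welch_t_scores(norm, self.groups, "p")
        assert s.loc["OG_equal", "t"] == 0.0
        assert s.loc["OG_diff", "t"] == np.inf

    def test_unknown_focal_group_is_error(self):
        with pytest.raises(ValueError, match="unknown focal group"):
            welch_t_scores(self._normalized(), self.groups, "nope")


class TestRankShifts:
    def _scores(self, t: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame({"t": pd.Series(t)})

    def test_extremes_selected(self):
        s = self._scores({"OG1": 2.0, "OG2": -1.0, "OG3": 0.5, "OG4": -3.0})
        expanded, contracted = rank_shifts(s, ShiftConfig(top_n=1))
        assert expanded == ["OG1"]
        assert contracted == ["OG4"]

    def test_all_equal_breaks_ties_lexicographically(self):
        s = self._scores({f"OG{i}": 1.0 for i in range(6)})
        expanded, contracted = rank_shifts(s, ShiftConfig(top_n=2))
        assert expanded == ["OG0", "OG1"]
        assert set(expanded).isdisjoint(contracted)

    def test_lists_disjoint_and_cover_extremes(self):
        s = self._scores({"OG1": 2.0, "OG2": -1.0, "OG3": 0.5, "OG4": -3.0})
        expanded, contracted = rank_shifts(s, ShiftConfig(top_n=2))
        assert set(expanded) == {"OG1", "OG3"}
        assert set(contracted) == {"OG4", "OG2"}

    def test_too_few_orthogroups_is_error(self):
        s = self._scores({"OG1": 1.0, "OG2": 2.0})
        with pytest.raises(ValueError):
            rank_shifts(s, ShiftConfig(top_n=2))


class TestPerSpeciesShiftCounts:
    def test_strict_threshold_counting(self):
        norm = normalized_from(
            {"sp": [0.8, -0.9, 0.5], "other": [0.0, 0.0, 0.0]}, ["a", "b", "c"]
        )
        counts = per_species_shift_counts(norm)
        assert tuple(counts.loc["sp"]) == (1, 1)
        assert tuple(counts.loc["other"]) == (0, 0)

    def test_exact_threshold_counted_in_neither(self):
        norm = normalized_from({"sp": [0.75, -0.75], "o": [0.0, 0.0]}, ["a", "b"])
        counts = per_species_shift_counts(norm)
        assert tuple(counts.loc["sp"]) == (0, 0)


class TestSpeciesCorrelation:
    def test_identical_and_negated_columns(self):
        norm = normalized_from(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [-1.0, -2.0, -3.0]},
            ["x", "y", "z"],
        )
        corr, flagged = species_correlation(norm)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert flagged == []

    def test_collinear_columns_all_unit_correlation(self):
        norm = normalized_from(
            {"a": [1.0, 2.0], "b": [2.0, 4.0], "c": [3.0, 6.0]}, ["x", "y"]
        )
        corr, _ = species_correlation(norm)
        off = corr.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-12)

    def test_matches_brute_force_pearson(self, rng):
        cols = {f"s{i}": rng.normal(size=10).tolist() for i in range(5)}
        norm = normalized_from(cols, [f"og{i}" for i in range(10)])
        corr, _ = species_correlation(norm)
        for a in cols:
            for b in cols:
                x, y = np.array(cols[a]), np.array(cols[b])
                r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert corr.loc[a, b] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_species_flagged_with_zero_correlation(self):
        norm = normalized_from({"a": [1.0, 2.0], "flat": [3.0, 3.0]}, ["x", "y"])
        corr, flagged = species_correlation(norm)
        assert flagged == ["flat"]
        assert corr.loc["a", "flat"] == 0.0
        assert corr.loc["flat", "flat"] == 1.0

    def test_unknown_subset_is_error(self):
        norm = normalized_from({"a": [1.0, 2.0], "b": [2.0, 1.0]}, ["x", "y"])
        with pytest.raises(ValueError):
            species_correlation(norm, orthogroup_subset=["nope", "x"])


def _block_corr(n_a: int, n_b: int, within: float = 0.95, between: float = -0.5):
    labels = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    corr = np.full((n_a + n_b, n_a + n_b), between)
    corr[:n_a, :n_a] = within
    corr[n_a:, n_a:] = within
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=labels, columns=labels)


class TestWardCluster:
    def test_well_separated_blocks_recovered(self):
        corr = _block_corr(4, 3)
        _, clusters = ward_cluster(corr, n_clusters=2)
        a = {clusters[f"A{i}"] for i in range(4)}
        b = {clusters[f"B{i}"] for i in range(3)}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_singleton_clusters(self):
        corr = _block_corr(2, 2)
        _, clusters = ward_cluster(corr, n_clusters=4)
        assert len(set(clusters.values())) == 4

    def test_permutation_invariance(self, rng):
        corr = _block_corr(3, 3)
        perm = list(rng.permutation(corr.index))
        _, c1 = ward_cluster(corr, 2)
        _, c2 = ward_cluster(corr.loc[perm, perm], 2)
        # same partition up to relabeling
        pairs1 = {frozenset([a, b]) for a in corr.index for b in corr.index if c1[a] == c1[b]}
        pairs2 = {frozenset([a, b]) for a in corr.index for b in corr.index if c2[a] == c2[b]}
        assert pairs1 == pairs2

    def test_merge_heights_non_decreasing(self):
        corr = _block_corr(4, 4)
        z, _ = ward_cluster(corr, 2)
        heights = z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_asymmetric_input_is_error(self):
        corr = _block_corr(2, 2)
        corr.iloc[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            ward_cluster(corr, 2)


class TestPcaScores:
    def test_identity_correlation_gives_equal_fractions(self):
        corr = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        _, explained = pca_scores(corr, n_components=4)
        # centered identity has a flat spectrum on the n-1 non-null directions
        np.testing.assert_allclose(explained, 0.25, atol=1e-10)

    def test_rank_one_structure_explained_by_first_component(self):
        # two near-identical row patterns per block (diagonal spikes aside):
        # centered profiles lie essentially on one line
        corr = _block_corr(3, 3)
        _, explained = pca_scores(corr, n_components=2)
        assert explained[0] > 0.99

    def test_constant_matrix_has_no_explained_variance(self):
        corr = _block_corr(3, 3, within=1.0, between=1.0)  # all r = 1
        _, explained = pca_scores(corr, n_components=2)
        np.testing.assert_allclose(explained, 0.0, atol=1e-12)

    def test_fractions_sorted_descending_and_sum_le_one(self, rng):
        x = rng.normal(size=(30, 6))
        corr = pd.DataFrame(np.corrcoef(x, rowvar=False),
                            index=list("abcdef"), columns=list("abcdef"))
        _, explained = pca_scores(corr, n_components=5)
        assert (np.diff(explained) <= 1e-12).all()
        assert explained.sum() <= 1.0 + 1e-9

    def test_sign_convention_largest_loading_positive(self):
        corr = _block_corr(3, 3)
        scores, _ = pca_scores(corr, n_components=2)
        assert scores.shape == (6, 2)
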