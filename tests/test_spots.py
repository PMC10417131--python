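"""Spot detection, profiles, ROC, ternary simplex, wTO, contamination split."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import somscape as sc
from somscape.spot_modules import sort_samples_by_spot


def flat_map(h=20, w=20, value=0.0):
    return np.full((h, w), value)


class TestDetectSpots:
    def test_single_elevated_block(self):
        m = flat_map()
        m[5:8, 5:8] = 1.0
        spots = sc.detect_spots(m, threshold_percentile=90)
        assert len(spots) == 1
        assert spots.spots[0].n_pixels == 9
        assert spots.labels == ["A"]

    def test_two_blocks_ordered_by_peak(self):
        m = flat_map()
        m[2:5, 2:5] = 1.0
        m[12:15, 12:15] = 2.0
        spots = sc.detect_spots(m, threshold_percentile=90)
        assert spots.labels == ["A", "B"]
        assert spots["A"].peak_value == 2.0  # brighter block gets the first label
        assert {s.n_pixels for s in spots} == {9}

    def test_min_pixels_filters_small_components(self):
        m = flat_map()
        m[0, 0:2] = 5.0
        spots = sc.detect_spots(m, threshold_percentile=98, min_pixels=4)
        assert len(spots) == 0

    def test_too_high_threshold_gives_empty_collection(self):
        spots = sc.detect_spots(flat_map(value=1.0), threshold_percentile=99.9)
        assert len(spots) == 0

    def test_merged_twin_peaks_are_split(self):
        # two peaks joined by a shallow bridge above threshold
        m = flat_map()
        m[10, 2:18] = 0.6
        m[9:12, 3:6] = 1.0
        m[9:12, 14:17] = 0.95
        split = sc.detect_spots(m, threshold_percentile=90, split_merged=True)
        merged = sc.detect_spots(m, threshold_percentile=90, split_merged=False)
        assert len(merged) == 1
        assert len(split) == 2

    def test_diagonal_contact_is_one_component(self):
        m = flat_map()
        m[3:5, 3:5] = 1.0
        m[5:7, 5:7] = 1.0  # touches only diagonally at (4,4)-(5,5)
        spots = sc.detect_spots(m, threshold_percentile=95, min_pixels=4, split_merged=False)
        assert len(spots) == 1


class TestSpotExpression:
    def test_single_pixel_equals_metagene_profile(self, small_fit):
        prof = sc.spot_expression(small_fit, [7])
        np.testing.assert_allclose(prof.to_numpy(), small_fit.prototypes.iloc[7].to_numpy())

    def test_two_pixel_hand_mean(self, small_fit):
        prof = sc.spot_expression(small_fit, [3, 10])
        expected = (small_fit.prototypes.iloc[3] + small_fit.prototypes.iloc[10]) / 2
        np.testing.assert_allclose(prof.to_numpy(), expected.to_numpy())

    def test_whole_grid_equals_prototype_column_means(self, small_fit):
        prof = sc.spot_expression(small_fit, np.arange(small_fit.n_metagenes))
        np.testing.assert_allclose(
            prof.to_numpy(), small_fit.prototypes.to_numpy().mean(axis=0)
        )

    def test_out_of_grid_pixels_rejected(self, small_fit):
        with pytest.raises(IndexError):
            sc.spot_expression(small_fit, [10_000])

    def test_sorting_helper_orders_within_subtype(self, small_spots, small_cohort):
        profiles = small_spots.profiles()
        spot = small_spots.labels[0]
        order = sort_samples_by_spot(profiles, spot, small_cohort["subtypes"])
        assert sorted(order) == sorted(profiles.columns)
        values = profiles.loc[spot]
        subtypes = small_cohort["subtypes"]
        for g in subtypes.unique():
            within = [s for s in order if subtypes[s] == g]
            assert (np.diff(values[within].to_numpy()) >= 0).all()


class TestCountSampleSpots:
    def test_flat_portrait_counts_zero(self):
        assert sc.count_sample_spots(flat_map()) == 0

    def test_two_blobs_count_two(self):
        m = flat_map()
        m[2:5, 2:5] = 1.0
        m[12:16, 12:16] = 1.5
        assert sc.count_sample_spots(m, threshold_percentile=90) == 2

    def test_percentile_threshold_is_shift_invariant(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(20, 20))
        m[5:9, 5:9] += 4.0
        assert sc.count_sample_spots(m, 95) == sc.count_sample_spots(m + 17.3, 95)

    def test_planted_subtype_samples_show_one_to_three_spots(self, small_fit):
        counts = [
            sc.count_sample_spots(small_fit.portrait(s), threshold_percentile=95)
            for s in small_fit.samples
        ]
        assert np.median(counts) <= 3 and max(counts) >= 1


class TestSpotAUC:
    def test_perfect_separation(self):
        prof = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        labels = pd.Series(["pos", "pos", "neg"], index=list("abc"))
        assert sc.spot_auc(prof, labels, "pos") == 1.0

    def test_hand_computed_half(self):
        # +: {2, 0}, -: {1}: one concordant of two pairs
        prof = pd.Series([2.0, 0.0, 1.0], index=list("abc"))
        labels = pd.Series(["pos", "pos", "neg"], index=list("abc"))
        assert sc.spot_auc(prof, labels, "pos") == 0.5

    def test_underexpression_marker_reported_below_half(self):
        prof = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        labels = pd.Series(["pos", "pos", "neg", "neg"], index=list("abcd"))
        assert sc.spot_auc(prof, labels, "pos") == 0.0

    def test_single_class_rejected(self):
        prof = pd.Series([1.0, 2.0], index=list("ab"))
        labels = pd.Series(["pos", "pos"], index=list("ab"))
        with pytest.raises(ValueError, match="both classes"):
            sc.spot_auc(prof, labels, "pos")

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            scores = rng.integers(0, 6, size=30).astype(float)  # ties on purpose
            labels = rng.random(30) < 0.4
            prof = pd.Series(scores, index=[f"s{i}" for i in range(30)])
            lab = pd.Series(np.where(labels, "pos", "neg"), index=prof.index)
            pos, neg = scores[labels], scores[~labels]
            if len(pos) == 0 or len(neg) == 0:
                continue
            concordant = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert sc.spot_auc(prof, lab, "pos") == pytest.approx(
                concordant / (len(pos) * len(neg))
            )


class TestTernary:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((1, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
            ((2, 0, 0), (1, 0, 0)),
            ((-1, 1, 1), (0, 0.5, 0.5)),
            ((0, 0, 0), (1 / 3, 1 / 3, 1 / 3)),
        ],
    )
    def test_examples(self, triple, expected):
        np.testing.assert_allclose(sc.ternary_coordinates(triple), expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.tuples(
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
        )
    )
    def test_property_simplex(self, triple):
        coords = sc.ternary_coordinates(triple)
        assert coords.sum() == pytest.approx(1.0)
        assert (coords >= 0).all()

    def test_matrix_input(self):
        out = sc.ternary_coordinates([[1, 1, 0], [0, 0, 4]])
        np.testing.assert_allclose(out, [[0.5, 0.5, 0], [0, 0, 1]])


def wto_brute_force(profiles: pd.DataFrame) -> np.ndarray:
    """Independent direct evaluation of the signed wTO formula."""
    a = np.corrcoef(profiles.to_numpy())
    np.fill_diagonal(a, 0.0)
    n = len(a)
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, k] * a[k, j] for k in range(n))
            k_i = sum(abs(a[i, k]) for k in range(n) if k != i)
            k_j = sum(abs(a[j, k]) for k in range(n) if k != j)
            w[i, j] = (shared + a[i, j]) / (min(k_i, k_j) + 1 - abs(a[i, j]))
    return w


class TestWTO:
    def test_perfectly_correlated_pair(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]], index=["A", "B"]
        )
        w = sc.wto_matrix(profiles)
        assert w.loc["A", "B"] == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        profiles = pd.DataFrame(rng.normal(size=(5, 40)), index=list("ABCDE"))
        w = sc.wto_matrix(profiles)
        np.testing.assert_allclose(w.to_numpy(), wto_brute_force(profiles), atol=1e-10)
        np.testing.assert_allclose(w.to_numpy(), w.to_numpy().T, atol=1e-12)

    def test_anticorrelation_stays_negative(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=30)
        profiles = pd.DataFrame(
            [base, -base + rng.normal(0, 0.05, 30), rng.normal(size=30)],
            index=["up", "down", "noise"],
        )
        w = sc.wto_matrix(profiles)
        assert w.loc["up", "down"] < -0.5

    def test_constant_profile_names_offender(self):
        profiles = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            sc.wto_matrix(profiles)

    def test_needs_two_spots(self):
        with pytest.raises(ValueError, match="at least 2"):
            sc.wto_matrix(pd.DataFrame([[1.0, 2.0]], index=["A"]))


class TestContaminationSplit:
    def test_bimodal_fixture(self):
        prof = pd.Series([-1.0, -1.0, -1.0, 2.0, 2.0], index=list("abcde"))
        labels, frac = sc.contamination_split(prof)
        assert frac == pytest.approx(0.4)
        assert set(labels[labels == "high"].index) == {"d", "e"}

    def test_constant_profile_degenerates_to_low(self):
        prof = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            labels, frac = sc.contamination_split(prof)
        assert frac == 0.0 and (labels == "low").all()

    def test_monotone_affine_invariance(self):
        rng = np.random.default_rng(4)
        prof = pd.Series(
            np.concatenate([rng.normal(0, 0.3, 30), rng.normal(3, 0.3, 12)]),
            index=[f"s{i}" for i in range(42)],
        )
        l1, f1 = sc.contamination_split(prof)
        l2, f2 = sc.contamination_split(prof * 2.5 + 7.0)
        assert f1 == f2
        assert (l1 == l2).all()

    def test_recovers_planted_contamination_fraction(self, small_spots, small_cohort):
        truth = small_cohort["truth"]
        # find the detected spot best matching planted module F
        f_genes = set(truth.module_genes("F"))
        best = max(small_spots, key=lambda s: len(f_genes & set(s.genes)))
        labels, frac = sc.contamination_split(best.profile)
        info = truth.sample_info
        expected = ((info["contaminated"]) | (info["subtype"] == "LIV")).mean()
        assert abs(frac - expected) < 0.15

    def test_two_samples_minimum(self):
        with pytest.raises(ValueError, match="2 samples"):
            sc.contamination_split(pd.Series([1.0], index=["a"]))


class TestCollection:
    def test_gmt_round_trip_and_membership(self, small_spots, tmp_path):
        from somscape.geneset_analysis import parse_gmt

        path = tmp_path / "spots.gmt"
        small_spots.to_gmt(path)
        back = parse_gmt(path)
        for spot in small_spots:
            if spot.genes:
                assert back[spot.label] == set(spot.genes)
        table = small_spots.membership_table()
        assert set(table["spot"]) == set(small_spots.labels)
        assert len(table) == sum(s.n_pixels for s in small_spots)
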