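"""HR maps, ΔHR scores, risk splits, patient heterogeneity."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import somscape as sc
from somscape.prognostics import (
    HRMap,
    PrognosticModel,
    _cox_binary_efron,
    patient_heterogeneity,
)
from somscape.synthetic_cohort import attach_survival

from conftest import scaled_design


class TestCoxSolver:
    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(0)
        n = 120
        x = (rng.random((n, 12)) < rng.uniform(0.25, 0.75, 12)).astype(float)
        time = rng.exponential(20, n).round(1)  # rounding forces tied event times
        time = np.where(x[:, 0] == 1, time * 0.5, time)
        event = rng.random(n) < 0.7
        beta, se, conv = _cox_binary_efron(x, time, event)
        assert conv.all()
        for j in range(12):
            df = pd.DataFrame({"t": time, "e": event.astype(int), "x": x[:, j]})
            cph = CoxPHFitter().fit(df, "t", "e")
            assert beta[j] == pytest.approx(cph.params_["x"], abs=1e-3)
            assert se[j] == pytest.approx(cph.standard_errors_["x"], abs=1e-3)

    def test_monotone_likelihood_reported_unconverged(self):
        # all events in the x=1 arm and none in x=0: beta diverges
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])
        beta, se, conv = _cox_binary_efron(x, time, event)
        assert not conv[0]
        assert np.isnan(beta[0])


class TestHRMap:
    def test_masking_small_groups(self, small_fit, small_survival):
        hrm = sc.hr_map(small_fit, small_survival, min_group_size=5)
        n = len(small_fit.samples)
        n_high = hrm.n_high.ravel()
        mask = hrm.mask.ravel()
        small = (n_high < 5) | (n - n_high < 5)
        assert mask[small].all()
        assert np.isnan(hrm.hr.ravel()[mask]).all()
        assert (hrm.hr.ravel()[~mask] > 0).all()

    def test_threshold_modes_differ(self, small_fit, small_survival):
        lo = sc.hr_map(small_fit, small_survival, "gt-mean")
        hi = sc.hr_map(small_fit, small_survival, "gt-1sd")
        assert (hi.n_high <= lo.n_high).all()
        with pytest.raises(ValueError, match="threshold mode"):
            sc.hr_map(small_fit, small_survival, "gt-2sd")

    def test_all_censored_rejected(self, small_fit, small_survival):
        surv = small_survival.copy()
        surv["event"] = 0
        with pytest.raises(ValueError, match="censored"):
            sc.hr_map(small_fit, surv)

    def test_missing_samples_rejected(self, small_fit, small_survival):
        with pytest.raises(ValueError, match="missing samples"):
            sc.hr_map(small_fit, small_survival.iloc[:-3])

    def test_risk_module_pixels_double_hazard(self):
        """Pixels hosting a module that doubles the hazard show HR ~ 2."""
        medians = []
        for seed in range(10):
            design = scaled_design(
                seed=seed, n_samples=150,
                survival_betas={"A": float(np.log(2)) / 1.2},  # beta*act = log 2
            )
            matrix, truth, _ = sc.generate_cohort(design)
            som = sc.SOMPortrayal(sc.centralize(matrix), grid=(15, 15), epochs=15, seed=0).fit()
            surv = attach_survival(truth, seed=900 + seed)
            hrm = sc.hr_map(som, surv)
            a_px = np.unique(som.gene_assignments()[truth.module_genes("A")])
            vals = hrm.hr.ravel()[a_px]
            medians.append(np.nanmedian(vals))
        assert 1.6 <= float(np.median(medians)) <= 2.5


class TestExtremeMetagenes:
    def make_map(self, small_fit, values):
        hr = np.full(small_fit.n_metagenes, np.nan)
        mask = np.ones(small_fit.n_metagenes, dtype=bool)
        for pixel, value in values.items():
            hr[pixel] = value
            mask[pixel] = False
        shape = (small_fit.height, small_fit.width)
        return HRMap(
            hr=hr.reshape(shape), se_log=np.full(shape, np.nan),
            n_high=np.zeros(shape, dtype=int), mask=mask.reshape(shape),
            threshold_mode="gt-mean", min_group_size=5,
        )

    def test_argmax_argmin_and_tie_rule(self, small_fit):
        hrm = self.make_map(small_fit, {5: 0.5, 17: 1.0, 30: 2.0, 31: 2.0})
        skel = sc.extreme_metagenes(hrm, small_fit, min_genes=1)
        assert skel.max_pixel == 30  # tie resolves to the lower linear index
        assert skel.min_pixel == 5

    def test_padding_stops_exactly_at_minimum(self, small_fit):
        hrm = self.make_map(small_fit, {45: 2.0, 200: 0.5})
        skel = sc.extreme_metagenes(hrm, small_fit, min_genes=25)
        base = len(small_fit.genes_of_pixels([45]))
        if base < 25:
            assert len(skel.max_genes) == 25
        else:
            assert len(skel.max_genes) == base
        assert set(small_fit.genes_of_pixels([45])) <= set(skel.max_genes)

    def test_fully_masked_rejected(self, small_fit):
        hrm = self.make_map(small_fit, {})
        with pytest.raises(ValueError, match="masked"):
            sc.extreme_metagenes(hrm, small_fit)


class TestDeltaHR:
    def test_identical_lists_score_zero(self, small_cohort):
        cen = small_cohort["centralized"]
        genes = cen.genes[:10]
        score = sc.delta_hr_score(cen, max_genes=genes, min_genes=list(genes))
        np.testing.assert_allclose(score.to_numpy(), 0.0, atol=1e-12)

    def test_hand_value_and_linearity(self):
        df = pd.DataFrame(
            {"S1": [1.0, 1.0, -1.0, -1.0], "S2": [0.5, 0.5, 0.5, 0.5]},
            index=["a", "b", "c", "d"],
        )
        m = sc.ExpressionMatrix(df, scale="centralized")
        score = sc.delta_hr_score(m, max_genes=["a", "b"], min_genes=["c", "d"])
        assert score["S1"] == pytest.approx(2.0)
        assert score["S2"] == pytest.approx(0.0)
        shifted = m.values.copy()
        shifted.loc[["a", "b"]] += 0.7
        score2 = sc.delta_hr_score(
            sc.ExpressionMatrix(shifted, scale="centralized"),
            max_genes=["a", "b"], min_genes=["c", "d"],
        )
        np.testing.assert_allclose(score2.to_numpy(), score.to_numpy() + 0.7)

    def test_swapping_lists_negates_exactly(self, small_cohort):
        cen = small_cohort["centralized"]
        a, b = cen.genes[:15], cen.genes[20:40]
        fwd = sc.delta_hr_score(cen, max_genes=a, min_genes=b)
        rev = sc.delta_hr_score(cen, max_genes=b, min_genes=a)
        np.testing.assert_array_equal(fwd.to_numpy(), -rev.to_numpy())

    def test_empty_or_absent_lists_rejected(self, small_cohort):
        cen = small_cohort["centralized"]
        with pytest.raises(ValueError, match="nonempty"):
            sc.delta_hr_score(cen, max_genes=[], min_genes=cen.genes[:3])
        with pytest.raises(ValueError, match="absent"):
            sc.delta_hr_score(cen, max_genes=["ghost"], min_genes=cen.genes[:3])


class TestRiskSplit:
    def test_group_sizes_quarter_of_hundred(self, small_cohort):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=100), index=[f"s{i}" for i in range(100)])
        surv = pd.DataFrame(
            {"sample": scores.index, "os_time": rng.exponential(10, 100) + 0.1,
             "event": rng.integers(0, 2, 100)}
        )
        split = sc.split_risk_groups(scores, surv, percentile=25)
        assert (split.labels == "high").sum() == 25
        assert (split.labels == "low").sum() == 25

    def test_identical_survival_gives_zero_statistic(self):
        scores = pd.Series(np.arange(20, dtype=float), index=[f"s{i}" for i in range(20)])
        surv = pd.DataFrame(
            {"sample": scores.index,
             "os_time": np.tile([5.0, 8.0, 11.0, 14.0, 17.0], 4),
             "event": np.tile([1, 0, 1, 1, 0], 4)}
        )
        split = sc.split_risk_groups(scores, surv, percentile=25)
        assert split.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert split.p_value == pytest.approx(1.0)

    def test_percentile_bounds(self, small_cohort, small_survival):
        scores = pd.Series(
            np.arange(len(small_survival), dtype=float),
            index=small_survival["sample"],
        )
        with pytest.raises(ValueError, match="percentile"):
            sc.split_risk_groups(scores, small_survival, percentile=60)
        with pytest.raises(ValueError, match="too small"):
            sc.split_risk_groups(scores.iloc[:4], small_survival.iloc[:4], percentile=25)

    def test_deterministic_tie_break_by_sample_id(self):
        scores = pd.Series([1.0] * 8, index=[f"s{i}" for i in range(8)])
        surv = pd.DataFrame(
            {"sample": scores.index, "os_time": np.arange(1.0, 9.0), "event": 1}
        )
        s1 = sc.split_risk_groups(scores, surv, percentile=25)
        s2 = sc.split_risk_groups(scores.sample(frac=1, random_state=3), surv, percentile=25)
        assert (s1.labels.sort_index() == s2.labels.sort_index()).all()


class TestPatientHeterogeneity:
    def test_hand_values(self):
        scores = pd.Series([1.0, 3.0, 4.0, 4.0], index=list("abcd"))
        patients = pd.Series(["p1", "p1", "p2", "p2"], index=list("abcd"))
        table, summary = patient_heterogeneity(scores, patients)
        assert table.loc["p1", "mean"] == pytest.approx(2.0)
        assert table.loc["p1", "sd"] == pytest.approx(np.sqrt(2.0))
        assert table.loc["p2", "sd"] == pytest.approx(0.0)
        assert summary["range_of_patient_means"] == pytest.approx(2.0)

    def test_singleton_patient_sd_missing(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        patients = pd.Series(["p1", "p2", "p2"], index=list("abc"))
        table, summary = patient_heterogeneity(scores, patients)
        assert np.isnan(table.loc["p1", "sd"])
        assert summary["n_multi_lesion_patients"] == 1

    def test_ranked_ascending(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        patients = pd.Series([f"p{i % 10}" for i in range(30)], index=scores.index)
        table, _ = patient_heterogeneity(scores, patients)
        assert (np.diff(table["mean"].to_numpy()) >= 0).all()


class TestPrognosticModel:
    def test_end_to_end_discriminates_planted_risk(self, small_fit, small_cohort, small_survival):
        fitted = PrognosticModel(
            small_fit, small_cohort["centralized"], small_survival
        ).fit()
        truth = small_cohort["truth"]
        # ΔHR should separate the high-hazard subtype (module A / LMS1)
        scores = fitted.scores
        lms1 = truth.sample_info["subtype"] == "LMS1"
        auc = sc.spot_auc(scores, truth.sample_info["subtype"], "LMS1")
        assert auc > 0.8
        text = fitted.summary()
        assert "maxHR pixel" in text
        split = fitted.split_risk_groups(25)
        assert split.p_value < 0.05

    def test_spot_variant_uses_given_gene_lists(self, small_fit, small_cohort, small_survival, small_spots):
        truth = small_cohort["truth"]
        a = [g for g in small_spots.spots[0].genes][:20] or small_cohort["centralized"].genes[:20]
        e = small_cohort["centralized"].genes[-20:]
        fitted = PrognosticModel(
            small_fit, small_cohort["centralized"], small_survival
        ).fit(spot_gene_lists=(a, e))
        expected = sc.delta_hr_score(
            small_cohort["centralized"], max_genes=list(a), min_genes=list(e)
        )
        np.testing.assert_array_equal(fitted.scores.to_numpy(), expected.to_numpy())

    def test_heterogeneity_from_survival_patient_column(self, small_fit, small_cohort, small_survival):
        fitted = PrognosticModel(
            small_fit, small_cohort["centralized"], small_survival
        ).fit()
        table, summary = fitted.patient_heterogeneity()
        assert summary["n_patients"] == small_cohort["truth"].sample_info["patient"].nunique()
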