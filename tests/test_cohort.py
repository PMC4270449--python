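"""Cohort-level predictive value, correspondence analysis, group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import csaeeg as c


@pytest.fixture(scope="module")
def ref_cohort():
    return c.reference_cohort(seed=0)


class TestConfusion:
    def test_identity_prediction_is_perfect(self):
        labels = ["MCI-DLB"] * 5 + ["MCI-NC"] * 3 + ["MCI-AD"] * 4
        s = c.confusion(labels, labels)
        assert all(v == 100.0 for v in s.per_class_correct.values())
        assert s.overall_correct == 100.0

    def test_clinical_feature_table_reproduced(self, ref_cohort):
        s = c.confusion(ref_cohort["group"], c.clinical_predictor(ref_cohort))
        assert s.matrix.loc["MCI-DLB"].tolist() == [15, 0, 5]
        assert s.matrix.loc["MCI-NC"].tolist() == [2, 0, 6]
        assert s.matrix.loc["MCI-AD"].tolist() == [2, 0, 12]
        assert s.overall_correct == pytest.approx(100 * 27 / 42)
        rep = s.report()
        assert rep.loc["overall_pct", "correct_pct"] == 64.3
        assert rep.loc["overall_pct", "MCI-DLB"] == 45.2
        assert rep.loc["overall_pct", "MCI-AD"] == 54.8

    def test_random_labels_match_recount_oracle(self):
        rng = np.random.default_rng(0)
        classes = c.cohort.OUTCOME_CLASSES
        obs = rng.choice(classes, size=1000)
        pred = rng.choice(classes, size=1000)
        s = c.confusion(obs, pred)
        for o in classes:  # independent counting pass
            for p in classes:
                assert s.matrix.loc[o, p] == int(
                    sum(1 for a, b in zip(obs, pred) if a == o and b == p)
                )
        assert s.matrix.values.sum() == 1000
        # row sums equal observed class sizes regardless of the predictor
        for o in classes:
            assert s.matrix.loc[o].sum() == int((obs == o).sum())

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            c.confusion(["MCI-DLB"], ["bogus"])

    def test_permutation_invariance(self, ref_cohort):
        pred = c.eeg_predictor(ref_cohort)
        s1 = c.confusion(ref_cohort["group"], pred)
        perm = np.random.default_rng(1).permutation(len(ref_cohort))
        s2 = c.confusion(ref_cohort["group"].to_numpy()[perm], pred.to_numpy()[perm])
        assert s1.matrix.equals(s2.matrix)


class TestPredictors:
    def test_eeg_predictor_never_predicts_nonconversion(self, ref_cohort):
        s = c.confusion(ref_cohort["group"], c.eeg_predictor(ref_cohort))
        assert (s.matrix["MCI-NC"] == 0).all()

    def test_all_stable_alpha_predicts_ad(self):
        df = pd.DataFrame({"pattern": ["1"] * 7, "group": ["MCI-AD"] * 7})
        assert (c.eeg_predictor(df) == "MCI-AD").all()

    def test_eeg_predictor_per_class(self, ref_cohort):
        s = c.confusion(ref_cohort["group"], c.eeg_predictor(ref_cohort))
        assert s.per_class_correct["MCI-DLB"] == 100.0
        assert s.per_class_correct["MCI-AD"] == pytest.approx(100 * 13 / 14)
        assert s.per_class_correct["MCI-NC"] == 0.0

    def test_unflagged_cohort_predicts_ad(self):
        df = pd.DataFrame({"group": ["MCI-AD", "MCI-DLB"],
                           "has_dlb_feature": [False, False]})
        assert (c.clinical_predictor(df) == "MCI-AD").all()

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            c.clinical_predictor(pd.DataFrame({"group": ["MCI-AD"]}))
        with pytest.raises(ValueError):
            c.eeg_predictor(pd.DataFrame({"pattern": [None], "group": ["MCI-AD"]}))


class TestAbnormalConversion:
    def test_reference_rate(self, ref_cohort):
        rate = c.abnormal_eeg_conversion_rate(ref_cohort)
        assert ref_cohort["abnormal"].sum() == 24
        assert rate == pytest.approx(20 / 24)

    def test_all_normal_cohort_undefined(self):
        df = pd.DataFrame({"group": ["MCI-AD"] * 3, "abnormal": [False] * 3})
        with pytest.raises(ZeroDivisionError):
            c.abnormal_eeg_conversion_rate(df)

    def test_large_synthetic_cohort_matches_recount(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "group": rng.choice(c.cohort.OUTCOME_CLASSES, size=1000),
            "abnormal": rng.random(1000) < 0.4,
        })
        expected = ((df["group"] == "MCI-DLB") & df["abnormal"]).sum() / df["abnormal"].sum()
        assert c.abnormal_eeg_conversion_rate(df) == pytest.approx(expected)


def _ca_oracle(tab):
    """Textbook CA: chi-square residual SVD in principal coordinates."""
    x = np.asarray(tab, dtype=float)
    n = x.sum()
    p = x / n
    r, col = p.sum(1), p.sum(0)
    s = np.diag(1 / np.sqrt(r)) @ (p - np.outer(r, col)) @ np.diag(1 / np.sqrt(col))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    return np.diag(1 / np.sqrt(r)) @ u * sig, np.diag(1 / np.sqrt(col)) @ vt.T * sig, sig


class TestCorrespondenceAnalysis:
    def test_independent_table_has_zero_inertia(self):
        tab = pd.DataFrame(np.outer([10, 20], [3, 7]), dtype=float)
        res = c.correspondence_analysis(tab)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.row_coords.values, 0, atol=1e-8)

    def test_inertia_equals_chi2_over_n(self):
        rng = np.random.default_rng(7)
        tab = pd.DataFrame(rng.integers(1, 40, size=(4, 3)))
        res = c.correspondence_analysis(tab)
        chi2 = stats.chi2_contingency(tab.values, correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / tab.values.sum(), abs=1e-10)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(11)
        tab = pd.DataFrame(rng.integers(1, 40, size=(4, 3)))
        res = c.correspondence_analysis(tab)
        f, g, sig = _ca_oracle(tab)
        for k in range(2):  # coordinates agree up to axis sign
            ours_f, ours_g = res.row_coords.values[:, k], res.col_coords.values[:, k]
            same = np.allclose(ours_f, f[:, k], atol=1e-8) and np.allclose(ours_g, g[:, k], atol=1e-8)
            flip = np.allclose(ours_f, -f[:, k], atol=1e-8) and np.allclose(ours_g, -g[:, k], atol=1e-8)
            assert same or flip

    def test_zero_margin_dropped_with_warning(self):
        tab = pd.DataFrame([[5, 0, 3], [2, 0, 8], [0, 0, 0]],
                           index=["a", "b", "c"], columns=["x", "y", "z"])
        with pytest.warns(UserWarning):
            res = c.correspondence_analysis(tab)
        assert list(res.row_coords.index) == ["a", "b"]
        assert list(res.col_coords.index) == ["x", "z"]

    def test_pattern_outcome_geometry(self, ref_cohort):
        """Stable alpha sits nearest the AD converters; unstable alpha
        nearest the DLB converters."""
        tab = c.pattern_outcome_table(ref_cohort)
        res = c.correspondence_analysis(tab)

        def nearest(row):
            d = ((res.col_coords - res.row_coords.loc[row]) ** 2).sum(axis=1)
            return d.idxmin()

        assert nearest("1") == "MCI-AD"
        assert nearest("1plus+2") == "MCI-DLB"


class TestGroupStats:
    def test_identical_groups_not_significant(self):
        vals = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0],
                "c": [1.0, 2.0, 3.0, 4.0]}
        res = c.group_compare(vals)
        assert res["anova"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert all(p["p_bonferroni"] == 1.0 for p in res["pairwise"].values())

    def test_statistics_match_reference_implementations(self):
        rng = np.random.default_rng(5)
        vals = {g: rng.normal(loc=i, size=20) for i, g in enumerate("abc")}
        res = c.group_compare(vals)
        f, p = stats.f_oneway(*vals.values())
        h, pk = stats.kruskal(*vals.values())
        assert res["anova"]["F"] == pytest.approx(f, abs=1e-10)
        assert res["kruskal"]["H"] == pytest.approx(h, abs=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            c.group_compare({"a": [1.0]})
        with pytest.raises(ValueError):
            c.group_compare({"a": [1.0], "b": [1.0, 2.0]})

    def test_monotone_spearman(self):
        x = [1, 2, 3, 4, 5]
        assert c.spearman(x, [10, 20, 30, 40, 50])["rho"] == pytest.approx(1.0)
        # cross-check: Pearson correlation of the ranks
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=30), rng.normal(size=30)
        manual = stats.pearsonr(stats.rankdata(a), stats.rankdata(b))[0]
        assert c.spearman(a, b)["rho"] == pytest.approx(manual, abs=1e-12)

    def test_fisher_wrapper(self):
        res = c.fisher_2x2([[8, 2], [1, 5]])
        odds, p = stats.fisher_exact([[8, 2], [1, 5]])
        assert res["p"] == pytest.approx(p)
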