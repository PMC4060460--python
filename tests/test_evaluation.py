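import numpy as np
import pandas as pd
import pytest

from fuzzyrules import (
    CLASSES,
    PipelineConfig,
    bootstrap_validation,
    compute_metrics,
    confusion,
    cross_center,
    evaluate_on,
    fit_study_group,
    loocv,
)
from fuzzyrules.evaluation import _refit_subset

from oracles import tally_confusion


def series_pair(pairs):
    """pairs: list of (true, predicted, count) -> (pred, truth) Series."""
    truth, pred = [], []
    for t, p, k in pairs:
        truth += [t] * k
        pred += [p] * k
    idx = [f"s{i}" for i in range(len(truth))]
    return pd.Series(pred, index=idx), pd.Series(truth, index=idx)


# Multi-center assessment fixture: per-class prediction tallies of six
# center-to-center tests (CG 10/10/0, OA 10/10/6, RA 13/10/10 cohorts).
BERLIN_TO_JENA = [
    ("CG", "CG", 6), ("CG", "OA", 1), ("CG", "RA", 3),
    ("OA", "OA", 9), ("OA", "RA", 1),
    ("RA", "RA", 12), ("RA", "OA", 1),
]
SIX_TESTS = {
    ("Jena", "Berlin"): [("CG", "CG", 10), ("OA", "OA", 4), ("OA", "CG", 6),
                         ("RA", "RA", 10)],
    ("Jena", "Leipzig"): [("OA", "OA", 6), ("RA", "RA", 10)],
    ("Berlin", "Jena"): BERLIN_TO_JENA,
    ("Berlin", "Leipzig"): [("OA", "OA", 5), ("OA", "RA", 1), ("RA", "RA", 10)],
    ("Leipzig", "Jena"): [("OA", "OA", 10), ("RA", "RA", 12), ("RA", "OA", 1)],
    ("Leipzig", "Berlin"): [("OA", "OA", 10), ("RA", "RA", 9), ("RA", "OA", 1)],
}
EXPECTED_COLUMNS = {
    ("Jena", "Berlin"): (100, 40, 100, 100, 100, 80),
    ("Jena", "Leipzig"): (100, 100, 100, 100, None, 100),
    ("Berlin", "Jena"): (92.3, 90, 80, 91.3, 60, 81.8),
    ("Berlin", "Leipzig"): (100, 83.3, 83.3, 100, None, 93.8),
    # 22 hits of 23 samples = 95.65..., i.e. 95.7 at one decimal
    ("Leipzig", "Jena"): (92.3, 100, 100, 92.3, None, 95.7),
    ("Leipzig", "Berlin"): (90, 100, 100, 90, None, 95),
}


class TestConfusion:
    def test_identity_predictions(self):
        pred, truth = series_pair([(c, c, 1) for c in CLASSES])
        cm = confusion(pred, truth)
        assert cm.hits == 3 and cm.errors == 0
        np.testing.assert_array_equal(np.diag(cm.table.loc[list(CLASSES), list(CLASSES)]), 1)

    def test_reconstructed_cross_center_matrix(self):
        pred, truth = series_pair(BERLIN_TO_JENA)
        cm = confusion(pred, truth)
        assert cm.hits == 27 and cm.errors == 6 and cm.n == 33
        assert [cm.hits_for(c) for c in CLASSES] == [6, 9, 12]
        # column sums equal true class sizes
        assert list(cm.table.sum(axis=0)) == [10, 10, 13]

    def test_matches_independent_tally(self):
        rng = np.random.default_rng(0)
        pred = pd.Series(rng.choice(CLASSES, 100), index=range(100))
        truth = pd.Series(rng.choice(CLASSES, 100), index=range(100))
        cm = confusion(pred, truth)
        tally = tally_confusion(pred, truth, CLASSES)
        for p in CLASSES:
            for t in CLASSES:
                assert cm.cell(p, t) == tally.get((p, t), 0)
        assert cm.hits + cm.errors == cm.n == 100

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown true label"):
            confusion(pd.Series(["CG"]), pd.Series(["XX"]))


class TestMetrics:
    def test_identity_matrix_gives_all_hundred(self):
        pred, truth = series_pair([(c, c, 4) for c in CLASSES])
        m = compute_metrics(confusion(pred, truth))
        assert all(v == 100.0 for v in m.rounded().values())

    @pytest.mark.parametrize("pair", list(SIX_TESTS))
    def test_assessment_columns_from_reconstructed_matrices(self, pair):
        """Each cross-center confusion matrix reconstructed from the
        per-class hit/error tallies reproduces its full printed metric
        column (one-decimal rounding)."""
        pred, truth = series_pair(SIX_TESTS[pair])
        m = compute_metrics(confusion(pred, truth)).rounded()
        exp = EXPECTED_COLUMNS[pair]
        got = (m["sensitivity_RA"], m["sensitivity_OA"], m["specificity_RA"],
               m["specificity_OA"], m["overall_specificity"], m["accuracy"])
        want = tuple("n.a." if v is None else float(v) for v in exp)
        assert got == want

    def test_no_control_cohort_uses_reduced_formulas(self):
        """Without CG samples, FP_RA is the OA samples called RA and
        overall specificity is undefined (n.a.)."""
        pred, truth = series_pair([("OA", "OA", 5), ("OA", "RA", 1), ("RA", "RA", 10)])
        m = compute_metrics(confusion(pred, truth))
        assert m.specificity_RA == pytest.approx(100 * 5 / 6)
        assert m.overall_specificity is None

    def test_mean_metrics_across_six_tests(self):
        """Averaging the (full-precision) per-test metrics and rounding
        reproduces the summary means: 96 / 86 / 94 / 96 / 91."""
        cols = []
        for pairs in SIX_TESTS.values():
            pred, truth = series_pair(pairs)
            cols.append(compute_metrics(confusion(pred, truth)))
        mean = lambda name: float(np.round(np.mean(
            [getattr(c, name) for c in cols if getattr(c, name) is not None]), 0))
        assert mean("sensitivity_RA") == 96
        assert mean("sensitivity_OA") == 86
        assert mean("specificity_RA") == 94
        assert mean("specificity_OA") == 96
        assert mean("accuracy") == 91

    def test_accuracy_equals_hits_over_n(self):
        rng = np.random.default_rng(1)
        pred = pd.Series(rng.choice(CLASSES, 60))
        truth = pd.Series(rng.choice(CLASSES, 60))
        cm = confusion(pred, truth)
        m = compute_metrics(cm)
        assert m.accuracy == pytest.approx(100 * cm.hits / cm.n)

    def test_zero_denominator_reported_undefined(self):
        pred, truth = series_pair([("RA", "RA", 5)])  # no CG, no OA samples
        m = compute_metrics(confusion(pred, truth))
        assert m.sensitivity_OA is None and m.overall_specificity is None

    def test_sample_order_irrelevant(self):
        pred, truth = series_pair(BERLIN_TO_JENA)
        perm = np.random.default_rng(2).permutation(pred.index)
        a = compute_metrics(confusion(pred, truth)).as_dict()
        b = compute_metrics(confusion(pred[perm], truth[perm])).as_dict()
        assert a == b


class TestCrossCenter:
    def test_train_equals_test_is_training_reapplication(self, small_trained):
        clf, pp, _ = small_trained
        rep = cross_center(pp[0], [pp[0]], clf=clf)
        assert rep.outcomes[0].cm.errors == 0
        assert rep.outcomes[0].metrics.accuracy == 100.0

    def test_uncovered_class_samples_are_excluded(self, table2_cohort):
        """A classifier trained without controls is evaluated only on the
        OA/RA samples of the test cohorts."""
        pp, _ = table2_cohort
        clf = fit_study_group(pp[2])  # 0/6/10 cohort
        if clf.rule_system_.r_max("CG") == 0:
            out = evaluate_on(clf, pp[0])
            assert out.n_test == 23 and out.n_excluded == 10
            assert out.metrics.overall_specificity is None

    def test_summary_means_equal_independent_averaging(self, small_trained):
        clf, pp, _ = small_trained
        rep = cross_center(pp[0], pp[1:], clf=clf)
        summ = rep.summary()
        for name in ("accuracy", "sensitivity_RA"):
            vals = [getattr(o.metrics, name) for o in rep.outcomes
                    if getattr(o.metrics, name) is not None]
            assert summ.loc[name, "mean"] == pytest.approx(sum(vals) / len(vals))


@pytest.fixture(scope="module")
def tiny_ds():
    from conftest import make_cohort_spec
    from fuzzyrules import generate_cohorts, preprocess

    datasets, _ = generate_cohorts(make_cohort_spec(n_genes=120))
    return preprocess(datasets[1])  # 10/10/10


class TestInternalValidation:

    def test_loocv_zero_error_on_separated_cohort(self, tiny_ds):
        out = loocv(tiny_ds)
        assert out["errors"] == 0
        assert out["error_rate"] == 0.0

    def test_degenerate_bootstrap_resample_matches_training_reapplication(self, tiny_ds):
        """Refitting on the original index multiset reproduces the training
        re-application predictions exactly."""
        cfg = PipelineConfig()
        full = fit_study_group(tiny_ds, cfg)
        clf = _refit_subset(tiny_ds, tiny_ds.sample_ids, cfg, full.alpha_)
        a = full.predict(tiny_ds.values.T)
        b = clf.predict(tiny_ds.values.T)
        np.testing.assert_array_equal(a, b)

    def test_bootstrap_oob_error_small_on_separated_cohort(self, tiny_ds):
        out = bootstrap_validation(tiny_ds, B=8, seed=0)
        assert out["oob_error_rate"] <= 0.1
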