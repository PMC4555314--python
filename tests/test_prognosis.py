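"""Eligibility filtering, temporal representations, metrics and the benchmark."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_profile, make_snapshot
from icfmon.prognosis import (
    CohortSpec,
    ConfusionMatrix,
    attribute_importance,
    benchmark,
    default_learners,
    evaluate,
    features_full_series,
    features_previous_state,
    select_cohort,
)

SPEC = CohortSpec(target_code="b152", label_year=2013, min_series_length=3)


def profile_with_series(pid, series, target="b152", **demo):
    """series: {year: qualifier-or-None-or-dict-of-codes}."""
    snapshots = {}
    for year, val in series.items():
        if isinstance(val, dict):
            codes = {c: v for c, v in val.items() if v is not None}
            snap = make_snapshot(pid, year, **codes) if codes else make_snapshot(pid, year, d920=0)
        elif val is None:
            snap = make_snapshot(pid, year, d920=0)  # evaluated, target missing
        else:
            snap = make_snapshot(pid, year, **{target: val})
        snapshots[year] = snap
    return make_profile(person_id=pid, snapshots=snapshots, **demo)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


def test_short_series_excluded():
    p = profile_with_series("P1", {2011: 1, 2012: 2})
    assert select_cohort([p], SPEC) == []


def test_missing_label_year_target_excluded():
    p = profile_with_series("P1", {2011: 1, 2012: 2, 2013: None})
    assert select_cohort([p], SPEC) == []


def test_sentinel_label_excluded():
    p = profile_with_series("P1", {2011: 1, 2012: 2, 2013: 8})
    assert select_cohort([p], SPEC) == []


def test_complete_series_included():
    p = profile_with_series("P1", {2011: 1, 2012: 2, 2013: 2})
    assert select_cohort([p], SPEC) == [p]


def test_select_cohort_monotone_in_min_length():
    cohort = [
        profile_with_series(f"P{n}", {y: 1 for y in range(2013 - n + 1, 2014)})
        for n in range(2, 7)
    ]
    sizes = [
        len(select_cohort(cohort, CohortSpec("b152", 2013, min_series_length=k)))
        for k in range(2, 8)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_min_series_length_must_allow_a_predictor_year():
    with pytest.raises(ValueError):
        CohortSpec("b152", 2013, min_series_length=1)


# ---------------------------------------------------------------------------
# temporal representations
# ---------------------------------------------------------------------------


def test_full_series_feature_counting():
    # 3 codes observed over 2 predictor years -> 5 demographic + 6 temporal
    series = {
        2011: {"b152": 1, "d550": 2, "b1641": 0},
        2012: {"b152": 2, "d550": 2, "b1641": 1},
        2013: {"b152": 2},
    }
    p = profile_with_series("P1", series)
    fm = features_full_series([p], SPEC)
    demographic = [c for c in fm.X.columns if c not in fm.temporal]
    assert sorted(demographic) == ["age", "disease", "gender", "origin", "years_from_diagnosis"]
    assert len(fm.temporal) == 6
    assert fm.X.loc["P1", "d550 2011"] == 2.0
    assert fm.y.loc["P1"] == 2


def test_full_series_never_uses_label_year_values():
    p = profile_with_series("P1", {2011: 1, 2012: 3, 2013: 4})
    fm = features_full_series([p], SPEC)
    assert not any(col.endswith("2013") for col in fm.temporal)


def test_all_missing_temporal_row_retained():
    rich = profile_with_series("P1", {2011: {"b152": 1, "d550": 0}, 2012: 1, 2013: 2})
    sparse = profile_with_series(
        "P2", {2011: {"d920": 0}, 2012: {"d920": 0}, 2013: 3}
    )
    fm = features_full_series([rich, sparse], SPEC)
    assert "P2" in fm.X.index
    b152_cols = [c for c in fm.temporal if c.startswith("b152")]
    assert fm.X.loc["P2", b152_cols].isna().all()


def test_previous_state_takes_most_recent_ordered_value():
    p = profile_with_series("P1", {2010: 1, 2011: None, 2012: 3, 2013: 2})
    fm = features_previous_state([p], SPEC)
    assert fm.X.loc["P1", "b152 prev"] == 3.0


def test_previous_state_constant_series():
    p = profile_with_series("P1", {2011: 2, 2012: 2, 2013: 2})
    fm = features_previous_state([p], SPEC)
    assert fm.X.loc["P1", "b152 prev"] == 2.0


def test_previous_state_missing_marker_when_no_prelabel_value():
    p = profile_with_series("P1", {2011: None, 2012: None, 2013: 2})
    q = profile_with_series("P2", {2011: 1, 2012: 1, 2013: 1})
    fm = features_previous_state([p, q], SPEC)
    assert np.isnan(fm.X.loc["P1", "b152 prev"])


def test_previous_state_uses_only_information_available_to_full_series():
    rng = np.random.default_rng(3)
    cohort = []
    for i in range(30):
        series = {}
        for year in (2010, 2011, 2012):
            series[year] = int(rng.integers(0, 5)) if rng.random() > 0.4 else None
        series[2013] = int(rng.integers(0, 5))
        cohort.append(profile_with_series(f"P{i}", series))
    eligible = select_cohort(cohort, SPEC)
    full = features_full_series(eligible, SPEC)
    prev = features_previous_state(eligible, SPEC)
    for pid in prev.X.index:
        v = prev.X.loc[pid, "b152 prev"]
        if np.isnan(v):
            continue
        year_cols = [c for c in full.temporal if c.startswith("b152 ")]
        observed = full.X.loc[pid, year_cols].dropna()
        assert v == observed.iloc[-1]  # last non-missing pre-label value


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_perfect_binary_classifier():
    cm = ConfusionMatrix.from_binary_counts(tp=5, fp=0, fn=0, tn=5)
    assert evaluate(cm, average="binary") == pytest.approx(
        {"accuracy": 1.0, "precision": 1.0, "recall": 1.0, "specificity": 1.0}
    )


def test_binary_formulas_verbatim():
    cm = ConfusionMatrix.from_binary_counts(tp=2, fp=1, fn=1, tn=6)
    got = evaluate(cm, average="binary")
    assert got == pytest.approx(
        {"accuracy": 0.8, "precision": 2 / 3, "recall": 2 / 3, "specificity": 6 / 7}
    )


def test_diagonal_multiclass_table_is_perfect():
    cm = ConfusionMatrix(labels=(0, 1, 2), table=np.diag([3, 3, 3]))
    assert evaluate(cm)["accuracy"] == 1.0
    assert evaluate(cm)["recall"] == 1.0


def test_zero_denominator_flagged_as_zero():
    # nothing predicted positive -> precision denominator 0
    cm = ConfusionMatrix.from_binary_counts(tp=0, fp=0, fn=3, tn=7)
    with pytest.warns(UserWarning, match="zero denominator"):
        got = evaluate(cm, average="binary")
    assert got["precision"] == 0.0


def _random_tables(n, seed, kmax=5):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        k = int(rng.integers(2, kmax + 1))
        table = rng.integers(0, 10, size=(k, k))
        if table.sum() == 0:
            table[0, 0] = 1
        yield ConfusionMatrix(labels=tuple(range(k)), table=table)


def test_evaluate_matches_brute_force_counting():
    """Support-weighted one-vs-rest ratios recomputed by cell enumeration."""
    for cm in _random_tables(400, seed=5):
        got = evaluate(cm)
        k, total = len(cm.labels), cm.table.sum()
        exp = {"precision": 0.0, "recall": 0.0, "specificity": 0.0}
        for i in range(k):
            tp = cm.table[i, i]
            fp = sum(cm.table[r, i] for r in range(k) if r != i)
            fn = sum(cm.table[i, c] for c in range(k) if c != i)
            tn = total - tp - fp - fn
            support = tp + fn
            w = support / total
            exp["precision"] += w * (tp / (tp + fp) if tp + fp else 0.0)
            exp["recall"] += w * (tp / (tp + fn) if tp + fn else 0.0)
            exp["specificity"] += w * (tn / (tn + fp) if tn + fp else 0.0)
        assert got["accuracy"] == pytest.approx(np.trace(cm.table) / total)
        for m in ("precision", "recall", "specificity"):
            assert got[m] == pytest.approx(exp[m])


def test_weighted_recall_equals_accuracy_identity():
    for cm in _random_tables(400, seed=6):
        got = evaluate(cm)
        assert got["recall"] == pytest.approx(got["accuracy"])


def test_metrics_within_unit_interval():
    for cm in _random_tables(100, seed=7):
        for m, v in evaluate(cm).items():
            assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------


def _signal_cohort(n=160, seed=0):
    """Label equals the previous state exactly (deterministic signal)."""
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        prev = int(rng.integers(0, 5))
        series = {2011: int(rng.integers(0, 5)), 2012: prev, 2013: prev}
        cohort.append(profile_with_series(f"P{i}", series))
    return select_cohort(cohort, SPEC)


def test_decision_tree_recovers_planted_deterministic_signal():
    eligible = _signal_cohort()
    fm = features_previous_state(eligible, SPEC)
    report = benchmark(fm, learners={"J48": default_learners(0)["J48"]},
                       seed=0, n_splits=5)
    assert report.table.accuracy.iloc[0] >= 0.9


def test_benchmark_is_deterministic_given_seed():
    eligible = _signal_cohort()
    fm = features_previous_state(eligible, SPEC)
    r1 = benchmark(fm, seed=3, n_splits=4)
    r2 = benchmark(fm, seed=3, n_splits=4)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_learners_share_folds_so_totals_agree():
    eligible = _signal_cohort()
    fm = features_previous_state(eligible, SPEC)
    report = benchmark(fm, seed=1, n_splits=4)
    totals = {cm.total for cm in report.confusions.values()}
    assert totals == {len(fm.y)}


def test_single_class_input_is_explicit_error():
    cohort = [
        profile_with_series(f"P{i}", {2011: 1, 2012: 1, 2013: 2}) for i in range(10)
    ]
    fm = features_previous_state(select_cohort(cohort, SPEC), SPEC)
    with pytest.raises(ValueError, match="single label class"):
        benchmark(fm, seed=0)


def test_report_has_table_shape_and_metadata():
    eligible = _signal_cohort()
    fms = [features_full_series(eligible, SPEC), features_previous_state(eligible, SPEC)]
    report = benchmark(fms, seed=2, n_splits=4)
    assert list(report.table.columns) == [
        "representation", "learner", "accuracy", "precision", "recall", "specificity"
    ]
    assert set(report.table.representation) == {"full time-series", "previous state"}
    assert set(report.table.learner) == set(default_learners(2))
    assert ((report.table[["accuracy", "precision", "recall", "specificity"]] >= 0).all().all())
    assert ((report.table[["accuracy", "precision", "recall", "specificity"]] <= 1).all().all())
    assert report.metadata["seed"] == 2
    assert report.metadata["protocol"].startswith("stratified")


# ---------------------------------------------------------------------------
# attribute importance
# ---------------------------------------------------------------------------


def test_label_copying_feature_dominates_importance():
    eligible = _signal_cohort(n=200, seed=4)
    fm = features_previous_state(eligible, SPEC)
    ranked = attribute_importance(fm, seed=0, top=10)
    assert ranked[0][0] == "b152 prev"
    assert ranked[0][1] > 50.0


def test_importances_sum_to_100_and_descend():
    eligible = _signal_cohort(n=120, seed=5)
    fm = features_previous_state(eligible, SPEC)
    ranked = attribute_importance(fm, seed=0, top=10)
    values = [v for _, v in ranked]
    assert sum(values) == pytest.approx(100.0)
    assert values == sorted(values, reverse=True)
    assert all(v >= 0 for v in values)


def test_requesting_more_features_than_exist():
    eligible = _signal_cohort(n=80, seed=6)
    fm = features_previous_state(eligible, SPEC)
    ranked = attribute_importance(fm, seed=0, top=50)
    assert len(ranked) == len(fm.X.columns)


def test_pure_noise_importances_are_spread_out():
    rng = np.random.default_rng(8)
    cohort = []
    for i in range(150):
        series = {
            year: {
                "b152": int(rng.integers(0, 5)),
                "d550": int(rng.integers(0, 5)),
                "d920": int(rng.integers(0, 5)),
                "b1641": int(rng.integers(0, 5)),
            }
            for year in (2011, 2012, 2013)
        }
        cohort.append(
            profile_with_series(
                f"P{i}", series,
                age=float(rng.integers(17, 90)),
                years_from_diagnosis=float(rng.integers(2, 40)),
            )
        )
    fm = features_previous_state(select_cohort(cohort, SPEC), SPEC)
    ranked = attribute_importance(fm, seed=0, top=10)
    assert ranked[0][1] < 40.0  # no single feature should dominate pure noise
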