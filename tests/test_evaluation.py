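import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taxatext.annotator import AnnotationHit, AnnotationResult
from taxatext.errors import UndefinedKappaError, UsageError
from taxatext.evaluation import (
    ConfusionCounts,
    GoldAnnotationSet,
    GoldAssociationSet,
    compare_associations,
    compare_uri_annotations,
    compute_metrics,
    error_category_report,
    f1_from_pr,
    fleiss_kappa,
    load_gold_annotations,
    metrics_report,
    relative_improvement,
    render_report,
    round_half_up,
    save_gold_annotations,
)


def _res(oid, uris):
    return AnnotationResult(oid, [AnnotationHit(f"k{i}", u, i)
                                  for i, u in enumerate(sorted(uris))])


# ---------------------------------------------------------------- metrics

@pytest.mark.parametrize("counts,expected", [
    # published per-species association rows that are internally consistent
    ((9, 2, 2), (0.818, 0.818, 0.818)),      # shark
    ((30, 2, 4), (0.938, 0.882, 0.909)),     # lion
    ((1, 0, 0), (1.000, 1.000, 1.000)),      # cactus
    ((510, 560, 24), (0.477, 0.955, 0.636)),  # baseline totals
    ((0, 0, 0), (0, 0, 0)),                  # degenerate convention
])
def test_compute_metrics_matches_published_rows(counts, expected):
    tp, fp, fn = counts
    m = compute_metrics(ConfusionCounts(tp, fp, fn))
    got = (round_half_up(m.precision), round_half_up(m.recall),
           round_half_up(m.f1))
    assert got == expected


@pytest.mark.parametrize("p,r,f1", [
    (0.889, 1, 0.941),   # URI workflow overall
    (0.523, 1, 0.687),   # tube worm
    (0.961, 1, 0.980),   # lion URI row
    (0.844, 0.930, 0.885),  # association workflow
    (1, 1, 1),
    (0, 0, 0),
])
def test_f1_is_harmonic_mean_of_printed_pairs(p, r, f1):
    assert round_half_up(f1_from_pr(p, r)) == f1


def test_f1_rejects_out_of_range_inputs():
    with pytest.raises(UsageError):
        f1_from_pr(1.2, 0.5)


@given(st.floats(0, 1), st.floats(0, 1))
def test_f1_bounded_by_precision_and_recall(p, r):
    f1 = f1_from_pr(p, r)
    assert 0 <= f1 <= 1
    if p > 0 and r > 0:
        assert min(p, r) <= f1 + 1e-12
        assert f1 <= max(p, r) + 1e-12


@given(st.floats(0, 1))
def test_f1_of_equal_precision_recall_is_that_value(p):
    assert f1_from_pr(p, p) == pytest.approx(p)


def test_relative_improvement():
    assert round_half_up(relative_improvement(0.885, 0.636), 2) == 0.39
    assert relative_improvement(0.7, 0.7) == 0
    assert relative_improvement(0.6, 0.3) == pytest.approx(1.0)
    with pytest.raises(UsageError):
        relative_improvement(0.5, 0.0)


# ------------------------------------------------------- URI comparison

def test_compare_uri_annotations_identity_and_set_arithmetic():
    gold = GoldAnnotationSet(uris={"O1": {"U1", "U2"}, "O2": {"U2", "U3"}})
    pred = {"O1": _res("O1", {"U1", "U2"}), "O2": _res("O2", {"U1", "U2"})}
    per, total = compare_uri_annotations(pred, gold)
    assert per["O1"] == ConfusionCounts(2, 0, 0, 0)
    assert per["O2"] == ConfusionCounts(1, 1, 1, 0)
    assert total == ConfusionCounts(3, 1, 1, 0)


def test_compare_uri_annotations_swapping_pred_and_gold_swaps_fp_fn():
    gold = GoldAnnotationSet(uris={"O1": {"U1", "U2"}})
    pred = {"O1": _res("O1", {"U2", "U3"})}
    _, fwd = compare_uri_annotations(pred, gold)
    swapped_gold = GoldAnnotationSet(uris={"O1": {"U2", "U3"}})
    swapped_pred = {"O1": _res("O1", {"U1", "U2"})}
    _, rev = compare_uri_annotations(swapped_pred, swapped_gold)
    assert (fwd.tp, fwd.fp, fwd.fn) == (rev.tp, rev.fn, rev.fp)


def test_compare_uri_micro_total_is_sum_over_objects():
    rng = np.random.default_rng(0)
    uris = [f"U{i}" for i in range(8)]
    gold = GoldAnnotationSet()
    pred = {}
    for i in range(20):
        oid = f"O{i:02d}"
        gold.uris[oid] = set(rng.choice(uris, rng.integers(0, 5), replace=False))
        pred[oid] = _res(oid, set(rng.choice(uris, rng.integers(0, 5),
                                             replace=False)))
    per, total = compare_uri_annotations(pred, gold)
    hand = ConfusionCounts()
    for oid in pred:
        p, g = pred[oid].unique_uris, gold.uris[oid]
        hand = hand + ConfusionCounts(len(p & g), len(p - g), len(g - p), 0)
    assert total == hand


def test_gold_annotations_round_trip_with_error_categories(tmp_path):
    gold = GoldAnnotationSet(
        uris={"O1": {"U1"}, "O2": set()},
        expected_fps=[("O1", "U9", "negation"), ("O2", "U8", "word_part")])
    p = tmp_path / "gold.tsv"
    save_gold_annotations(gold, p)
    back = load_gold_annotations(p)
    assert back.uris == gold.uris
    assert sorted(back.expected_fps) == sorted(gold.expected_fps)


def test_error_category_report_counts_fired_traps():
    gold = GoldAnnotationSet(
        uris={"O1": set(), "O2": set()},
        expected_fps=[("O1", "U1", "negation"), ("O2", "U2", "homonym"),
                      ("O2", "U3", "homonym")])
    pred = {"O1": _res("O1", {"U1"}), "O2": _res("O2", {"U2"})}
    df = error_category_report(pred, gold)
    assert df.loc["negation", "fired"] == 1
    assert df.loc["homonym", "planted"] == 2
    assert df.loc["homonym", "fired"] == 1
    assert df.loc["TOTAL", "planted"] == 3


# ------------------------------------------------ association comparison

def test_compare_associations_counts():
    universe = [("A", "B"), ("A", "C"), ("B", "A"), ("C", "A")]
    gold = GoldAssociationSet({("A", "B")})
    assert compare_associations({("A", "B")}, gold, universe) == \
        ConfusionCounts(1, 0, 0, 3)
    assert compare_associations({("A", "B")},
                                GoldAssociationSet({("A", "C")}), universe) == \
        ConfusionCounts(0, 1, 1, 2)


def test_compare_associations_requires_covering_universe():
    with pytest.raises(UsageError):
        compare_associations({("A", "B")}, GoldAssociationSet({("A", "C")}),
                             [("A", "B")])


# ------------------------------------------------------------- kappa

def test_fleiss_kappa_perfect_agreement_is_one():
    m = [[3, 0], [0, 3], [3, 0], [0, 3], [3, 0]]
    assert fleiss_kappa(m) == pytest.approx(1.0)


def test_fleiss_kappa_single_category_is_undefined():
    with pytest.raises(UndefinedKappaError):
        fleiss_kappa([[3, 0], [3, 0]])


def test_fleiss_kappa_matches_hand_computed_oracle():
    # 5 items x 3 raters x 2 categories, worked by hand:
    # P̄ = 3/5, P̄e = 113/225, κ = (22/225)/(112/225) = 11/56
    m = [[3, 0], [2, 1], [1, 2], [0, 3], [2, 1]]
    assert fleiss_kappa(m) == pytest.approx(11 / 56)


def test_fleiss_kappa_agrees_with_statsmodels():
    from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa
    rng = np.random.default_rng(1)
    counts = rng.multinomial(4, [0.5, 0.3, 0.2], size=12)
    assert fleiss_kappa(counts) == pytest.approx(sm_kappa(counts))


def test_fleiss_kappa_invariant_under_row_and_column_permutation():
    m = np.array([[3, 0, 1], [2, 1, 1], [1, 2, 1], [0, 3, 1], [2, 1, 1]])
    base = fleiss_kappa(m)
    assert fleiss_kappa(m[::-1]) == pytest.approx(base)
    assert fleiss_kappa(m[:, [2, 0, 1]]) == pytest.approx(base)


def test_fleiss_kappa_rejects_ragged_or_single_rater():
    with pytest.raises(UsageError):
        fleiss_kappa([[2, 1], [1, 1]])
    with pytest.raises(UsageError):
        fleiss_kappa([[1, 0], [0, 1]])


# ------------------------------------------------------------- report

def test_metrics_report_matches_published_association_table():
    from taxatext.refdata import ASSOC_WORKFLOW_COUNTS, reference_confusion_counts
    report = metrics_report(reference_confusion_counts(ASSOC_WORKFLOW_COUNTS))
    assert report.loc["Apis mellifera", "precision"] == 0.809
    assert report.loc["Harrisia simpsonii", ["precision", "recall", "f1"]].tolist() \
        == [1.000, 1.000, 1.000]
    assert report.loc["Carcharodon carcharias", "f1"] == 0.818
    assert report.loc["TOTAL", "tp"] == 494
    assert report.loc["TOTAL", "precision"] == 0.844
    # blank metrics where nothing was assigned or expected
    assert np.isnan(report.loc["Hypnum fauriei", "f1"])


def test_metrics_report_total_row_is_micro_average():
    per_unit = {"a": ConfusionCounts(3, 1, 2, 0), "b": ConfusionCounts(5, 0, 1, 2)}
    report = metrics_report(per_unit)
    summed = compute_metrics(ConfusionCounts(8, 1, 3, 2))
    assert report.loc["TOTAL", "precision"] == round_half_up(summed.precision)
    assert report.loc["TOTAL", "recall"] == round_half_up(summed.recall)
    assert report.loc["TOTAL", "f1"] == round_half_up(summed.f1)


def test_metrics_report_empty_mapping_is_total_only_zeros():
    report = metrics_report({})
    assert list(report.index) == ["TOTAL"]
    assert report.loc["TOTAL"].tolist() == [0, 0, 0, 0, 0, 0, 0]


def test_render_report_blanks_nan_cells():
    text = render_report(metrics_report({"x": ConfusionCounts(0, 0, 0, 5)}))
    assert "nan" not in text.lower()
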