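"""Strict/relaxed metrics, macro report, CIs, and the error analyses."""

import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iduqa import (
    QueryGroup,
    SpanPrediction,
    confidence_interval,
    evaluate,
    null_note_detection,
    quartile_bin_analysis,
    ratio_distribution,
    recall_interval_table,
    relaxed_prf,
    strict_f1,
)
from iduqa.annotate import GoldAnswer, QASample
from iduqa.evaluation import RECALL_INTERVALS, SampleScore

_words = st.lists(st.sampled_from("a b c d e f idu ivdu no history of".split()),
                  min_size=0, max_size=8).map(" ".join)


# ---------------------------------------------------------------------------
# strict and relaxed metrics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pred,gold,expected",
    [
        ("no history of idu", "no history of idu", 1),
        ("history of idu", "no history of idu", 0),
        ("", "", 1),
        ("No history of idu", "no history of idu", 0),  # raw char equality
    ],
)
def test_strict_contract(pred, gold, expected):
    assert strict_f1(pred, gold) == expected


def test_strict_with_normalizer():
    assert strict_f1("No IDU", "no idu", normalizer=str.lower) == 1


def test_relaxed_hand_counts():
    p, r, f = relaxed_prf("history of idu", "no history of idu")
    assert p == 1.0 and r == 0.75
    assert f == pytest.approx(2 * 1.0 * 0.75 / 1.75)


def test_relaxed_edge_cases():
    assert relaxed_prf("", "") == (1.0, 1.0, 1.0)
    assert relaxed_prf("", "idu") == (0.0, 0.0, 0.0)
    assert relaxed_prf("x y", "p q") == (0.0, 0.0, 0.0)
    assert relaxed_prf("same text", "same text") == (1.0, 1.0, 1.0)


@settings(derandomize=True, max_examples=300)
@given(_words, _words)
def test_precision_recall_symmetry(a, b):
    assert relaxed_prf(a, b)[0] == relaxed_prf(b, a)[1]


@settings(derandomize=True, max_examples=300)
@given(_words, _words)
def test_strict_implies_relaxed_perfect(a, b):
    if strict_f1(a, b):
        assert relaxed_prf(a, b) == (1.0, 1.0, 1.0)


def test_relaxed_agrees_with_pairing_oracle():
    """Brute-force pair-and-remove token counting on random string pairs."""
    vocab = "no history of idu ivdu meth heroin daily last use denies pt".split()
    rng = random.Random(11)
    for _ in range(1000):
        a = " ".join(rng.choices(vocab, k=rng.randint(0, 10)))
        b = " ".join(rng.choices(vocab, k=rng.randint(0, 10)))
        at, bt = a.split(), b.split()
        pool = list(bt)
        tp = 0
        for tok in at:
            if tok in pool:
                pool.remove(tok)
                tp += 1
        if not at and not bt:
            expected = (1.0, 1.0, 1.0)
        elif not at or not bt:
            expected = (0.0, 0.0, 0.0)
        else:
            prec, rec = tp / len(at), tp / len(bt)
            f1 = 0.0 if tp == 0 else 2 * prec * rec / (prec + rec)
            expected = (prec, rec, f1)
        assert relaxed_prf(a, b) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def _gold(sample_id, context, answers, group=QueryGroup.existence, q="q?"):
    return QASample(sample_id, "p", "n", context,  q,
                    [GoldAnswer("n", context.find(a), context.find(a) + len(a), a)
                     for a in answers], split="test", group=group)


def _pred(sample_id, text):
    return SpanPrediction(sample_id, 0, len(text), text, 1.0)


def test_macro_is_mean_of_sample_scores():
    gold = [_gold("a", "x y. no idu.", ["no idu"]),
            _gold("b", "x y. no idu.", ["no idu"])]
    preds = [_pred("a", "no idu"), _pred("b", "something else")]
    report, scores = evaluate(preds, gold, compute_ci=False)
    assert report.macro_strict_f1 == 50.0
    assert report.n_samples == 2


def test_all_correct_scores_hundred():
    gold = [_gold(str(i), "ctx with no idu.", ["no idu"]) for i in range(4)]
    preds = [_pred(str(i), "no idu") for i in range(4)]
    report, _ = evaluate(preds, gold, compute_ci=False)
    assert (report.macro_strict_f1, report.macro_relaxed_f1,
            report.macro_precision, report.macro_recall) == (100.0,) * 4


def test_order_invariance():
    gold = [_gold(str(i), "a b no idu.", ["no idu"]) for i in range(6)]
    preds = [_pred(str(i), "no idu" if i % 2 else "b") for i in range(6)]
    r1, _ = evaluate(preds, gold, compute_ci=False)
    r2, _ = evaluate(list(reversed(preds)), list(reversed(gold)), compute_ci=False)
    assert r1 == r2


def test_multi_gold_scores_best_match():
    gold = [_gold("a", "has h/o ivdu. last used iv meth 2 years ago.",
                  ["has h/o ivdu", "last used iv meth 2 years ago"])]
    preds = [_pred("a", "last used iv meth 2 years ago")]
    report, scores = evaluate(preds, gold, compute_ci=False)
    assert report.macro_strict_f1 == 100.0


def test_missing_prediction_scored_empty_with_warning():
    gold = [_gold("a", "no idu here.", ["no idu"])]
    with pytest.warns(UserWarning, match="no prediction"):
        report, scores = evaluate([], gold, compute_ci=False)
    assert report.macro_strict_f1 == 0.0
    assert scores[0].pred_len_tokens == 0


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def test_ci_degenerate_data():
    assert confidence_interval([0.8] * 50) == (0.8, 0.8)


def test_ci_contains_mean_and_seeded():
    rng = np.random.default_rng(3)
    scores = rng.random(200).tolist()
    lo, hi = confidence_interval(scores, seed=1)
    assert lo <= float(np.mean(scores)) <= hi
    assert confidence_interval(scores, seed=1) == (lo, hi)


def test_ci_narrows_with_sample_size():
    rng = np.random.default_rng(5)
    big = rng.binomial(1, 0.6, size=1000).astype(float).tolist()
    small = big[:100]
    lo_b, hi_b = confidence_interval(big, seed=2)
    lo_s, hi_s = confidence_interval(small, seed=2)
    assert (hi_b - lo_b) < (hi_s - lo_s)


def test_ci_bad_level_rejected():
    with pytest.raises(ValueError):
        confidence_interval([0.1, 0.2], level=1.5)


# ---------------------------------------------------------------------------
# binned analyses
# ---------------------------------------------------------------------------

def _score(i, strict, recall, pred_len=3, gold_len=4, ctx_len=100, q_len=8):
    f1 = recall  # adequate stand-in for table tests
    return SampleScore(str(i), strict, recall, recall, f1, pred_len, gold_len,
                       ctx_len, q_len, QueryGroup.existence)


def test_quartile_bins_uniform_lengths():
    scores = [_score(i, 1, 1.0, ctx_len=i + 1) for i in range(100)]
    table = quartile_bin_analysis(scores, "context_len")
    assert list(table["n"]) == [25, 25, 25, 25]
    assert table["n"].sum() == 100
    assert (table["macro_strict_f1"] == 100.0).all()


def test_quartile_bins_conserve_counts():
    rng = random.Random(2)
    scores = [_score(i, rng.randint(0, 1), rng.random(),
                     gold_len=rng.randint(1, 40)) for i in range(57)]
    table = quartile_bin_analysis(scores, "gold_answer_len")
    assert table["n"].sum() == 57


def test_quartile_bins_small_input_single_bin():
    with pytest.warns(UserWarning, match="single bin"):
        table = quartile_bin_analysis([_score(0, 1, 1.0)], "question_len")
    assert len(table) == 1


def test_quartile_bins_unknown_key():
    with pytest.raises(ValueError):
        quartile_bin_analysis([_score(0, 1, 1.0)], "note_type")


def test_recall_table_shape_and_placement():
    table = recall_interval_table([_score(0, 0, 1.0)])
    assert list(table["recall_interval"]) == [r[0] for r in RECALL_INTERVALS]
    assert len(table) == 12
    assert table.loc[table["recall_interval"] == "(99-100]", "pct"].item() == 100.0
    t0 = recall_interval_table([_score(0, 0, 0.0)])
    assert t0.loc[t0["recall_interval"] == "0", "pct"].item() == 100.0


def test_recall_table_conserves_percentages():
    rng = random.Random(8)
    scores = [_score(i, rng.randint(0, 1), rng.random()) for i in range(200)]
    table = recall_interval_table(scores)
    assert table["pct"].sum() == pytest.approx(100.0)
    assert table["n"].sum() == sum(1 for s in scores if s.strict_f1 == 0)


def test_recall_table_empty_subset_all_zero():
    table = recall_interval_table([_score(0, 1, 1.0)])
    assert (table["pct"] == 0.0).all()


def test_ratio_distribution_bounds_and_coincidence():
    scores = [_score(i, 0, 1.0, pred_len=10, gold_len=10, ctx_len=50)
              for i in range(5)]
    out = ratio_distribution(scores)
    assert out["n"] == 5
    assert np.all(out["pred_ratios_pct"] > 0) and np.all(out["pred_ratios_pct"] <= 100)
    assert np.allclose(out["pred_ratios_pct"], out["gold_ratios_pct"])


def test_ratio_full_context_prediction_is_hundred_percent():
    scores = [_score(0, 0, 1.0, pred_len=50, gold_len=5, ctx_len=50)]
    out = ratio_distribution(scores)
    assert out["pred_ratios_pct"][0] == 100.0


def test_null_note_detection_rates():
    all_empty = [SpanPrediction(str(i), None, None, "", 0.5) for i in range(4)]
    assert null_note_detection(all_empty)[0] == 1.0
    half = all_empty[:2] + [SpanPrediction("x", 0, 5, "empty", 1.0),
                            SpanPrediction("y", 0, 1, ".", 1.0)]
    rate, tally = null_note_detection(half)
    assert rate == 0.5
    assert tally == Counter({"empty": 1, ".": 1})
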