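"""Strict and relaxed span metrics, macro averaging, CIs, and error analyses.

Strict matching is character-by-character equality of predicted and gold
answers, giving a per-sample score of 0 or 1 (no normalization by default).
Relaxed matching counts whitespace tokens: TP is the multiset intersection of
prediction and gold tokens, FP the prediction-only count, FN the gold-only
count, with precision TP/(TP+FP), recall TP/(TP+FN) and F1 their harmonic
mean. Macro scores are per-sample means reported as percentages.

The error-analysis suite mirrors the published analyses: bootstrap 95%
confidence intervals, quartile bins over context/question/answer length,
a 12-interval recall table over non-strict-match samples, answer-to-context
length-ratio distributions, and empty-answer detection on keyword-free notes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotate import QASample
from .engine import SpanPrediction
from .lexicon import QueryGroup

__all__ = [
    "SampleScore",
    "EvalReport",
    "strict_f1",
    "relaxed_prf",
    "evaluate",
    "confidence_interval",
    "quartile_bin_analysis",
    "recall_interval_table",
    "ratio_distribution",
    "null_note_detection",
]


@dataclass
class SampleScore:
    """Per-sample strict/relaxed scores plus the lengths used in binning."""

    sample_id: str
    strict_f1: int
    relaxed_precision: float
    relaxed_recall: float
    relaxed_f1: float
    pred_len_tokens: int
    gold_len_tokens: int
    context_len_tokens: int
    question_len_tokens: int
    group: QueryGroup | None = None


@dataclass
class EvalReport:
    """Macro-averaged scores (percentages) with optional 95% CIs."""

    macro_strict_f1: float
    macro_relaxed_f1: float
    macro_precision: float
    macro_recall: float
    n_samples: int
    ci_95: dict[str, tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        d = {
            "macro_strict_f1": self.macro_strict_f1,
            "macro_relaxed_f1": self.macro_relaxed_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "n_samples": self.n_samples,
        }
        if self.ci_95 is not None:
            d["ci_95"] = {k: list(v) for k, v in self.ci_95.items()}
        return d


def strict_f1(
    pred: str, gold: str, normalizer: Callable[[str], str] | None = None
) -> int:
    """1 iff the prediction matches the gold answer character by character.

    ``normalizer`` (off by default) is applied to both strings first for
    callers who want, e.g., case-insensitive matching.
    """
    if normalizer is not None:
        pred, gold = normalizer(pred), normalizer(gold)
    return int(pred == gold)


def relaxed_prf(pred: str, gold: str) -> tuple[float, float, float]:
    """Token-overlap (precision, recall, F1) between prediction and gold.

    Tokens are whitespace delimited and counted as multisets. Two empty
    strings agree perfectly; an empty prediction against a non-empty gold
    (or vice versa) scores zero.
    """
    p_tok, g_tok = pred.split(), gold.split()
    if not p_tok and not g_tok:
        return 1.0, 1.0, 1.0
    if not p_tok or not g_tok:
        return 0.0, 0.0, 0.0
    tp = sum((Counter(p_tok) & Counter(g_tok)).values())
    precision = tp / len(p_tok)
    recall = tp / len(g_tok)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _score_one(
    pred_text: str,
    gold_texts: Sequence[str],
    normalizer: Callable[[str], str] | None,
) -> tuple[int, float, float, float, str]:
    """Score against the gold answer maximizing relaxed F1 (SQuAD convention)."""
    golds = list(gold_texts) if gold_texts else [""]
    best = None
    for g in golds:
        prf = relaxed_prf(pred_text, g)
        if best is None or prf[2] > best[1][2]:
            best = (g, prf)
    gold, (precision, recall, f1) = best  # type: ignore[misc]
    strict = max(strict_f1(pred_text, g, normalizer) for g in golds)
    if strict:
        precision = recall = f1 = 1.0
        gold = next(g for g in golds if strict_f1(pred_text, g, normalizer))
    return strict, precision, recall, f1, gold


def evaluate(
    predictions: Sequence[SpanPrediction],
    gold_samples: Sequence[QASample],
    normalizer: Callable[[str], str] | None = None,
    compute_ci: bool = True,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[EvalReport, list[SampleScore]]:
    """Score predictions against gold samples and macro-average.

    Samples with several gold answers score against the one maximizing
    relaxed F1. A sample without a prediction is scored as an empty string
    with a warning. The report is invariant to sample order.
    """
    pred_by_id = {p.sample_id: p for p in predictions}
    scores: list[SampleScore] = []
    for sample in gold_samples:
        pred = pred_by_id.get(sample.sample_id)
        if pred is None:
            warnings.warn(f"no prediction for sample {sample.sample_id}; scoring ''")
            pred_text = ""
        else:
            pred_text = pred.text
        strict, precision, recall, f1, gold = _score_one(
            pred_text, [a.text for a in sample.answers], normalizer
        )
        scores.append(
            SampleScore(
                sample_id=sample.sample_id,
                strict_f1=strict,
                relaxed_precision=precision,
                relaxed_recall=recall,
                relaxed_f1=f1,
                pred_len_tokens=len(pred_text.split()),
                gold_len_tokens=len(gold.split()),
                context_len_tokens=len(sample.context.split()),
                question_len_tokens=len(sample.question.split()),
                group=sample.group,
            )
        )
    scores.sort(key=lambda s: s.sample_id)

    def macro(values: list[float]) -> float:
        return float(np.mean(values)) * 100 if values else 0.0

    metric_values = {
        "strict_f1": [float(s.strict_f1) for s in scores],
        "relaxed_f1": [s.relaxed_f1 for s in scores],
        "precision": [s.relaxed_precision for s in scores],
        "recall": [s.relaxed_recall for s in scores],
    }
    ci = None
    if compute_ci and scores:
        ci = {
            name: tuple(
                100 * b
                for b in confidence_interval(vals, seed=seed, n_boot=n_boot)
            )
            for name, vals in metric_values.items()
        }
    report = EvalReport(
        macro_strict_f1=macro(metric_values["strict_f1"]),
        macro_relaxed_f1=macro(metric_values["relaxed_f1"]),
        macro_precision=macro(metric_values["precision"]),
        macro_recall=macro(metric_values["recall"]),
        n_samples=len(scores),
        ci_95=ci,
    )
    return report, scores


def confidence_interval(
    scores: Sequence[float],
    level: float = 0.95,
    method: str = "bootstrap",
    seed: int = 0,
    n_boot: int = 10_000,
) -> tuple[float, float]:
    """Confidence interval for the mean of per-sample scores.

    Default is the seeded percentile bootstrap; ``method="normal"`` gives the
    normal approximation. Degenerate (constant) data yields a zero-width
    interval at the mean.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("scores must be non-empty")
    if np.all(arr == arr[0]):
        v = float(arr[0])
        return v, v
    mean = float(arr.mean())
    if method == "normal":
        from math import sqrt

        se = float(arr.std(ddof=1)) / sqrt(arr.size)
        # two-sided normal quantile via the inverse error function
        from statistics import NormalDist

        z = NormalDist().inv_cdf(0.5 + level / 2)
        return mean - z * se, mean + z * se
    if method != "bootstrap":
        raise ValueError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(seed)
    means = np.empty(n_boot)
    batch = max(1, min(n_boot, 50_000_000 // max(arr.size, 1)))
    done = 0
    while done < n_boot:
        k = min(batch, n_boot - done)
        idx = rng.integers(0, arr.size, size=(k, arr.size))
        means[done : done + k] = arr[idx].mean(axis=1)
        done += k
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


_BIN_KEYS = {
    "context_len": "context_len_tokens",
    "question_len": "question_len_tokens",
    "gold_answer_len": "gold_len_tokens",
}


def quartile_bin_analysis(scores: Sequence[SampleScore], key: str) -> pd.DataFrame:
    """Macro metrics in four quartile bins of a length variable.

    ``key`` is one of ``context_len``, ``question_len``, ``gold_answer_len``.
    Bins split at the empirical 25/50/75 percentiles; bin counts sum to the
    sample count. With fewer than 4 samples a single bin is returned.
    """
    if key not in _BIN_KEYS:
        raise ValueError(f"key must be one of {sorted(_BIN_KEYS)}, got {key!r}")
    attr = _BIN_KEYS[key]
    lengths = np.array([getattr(s, attr) for s in scores], dtype=float)
    if lengths.size < 4:
        warnings.warn("fewer than 4 samples; returning a single bin")
        bins = np.zeros(lengths.size, dtype=int)
        n_bins = 1
    else:
        qs = np.percentile(lengths, [25, 50, 75])
        bins = np.searchsorted(qs, lengths, side="left")
        n_bins = 4
    rows = []
    for b in range(n_bins):
        members = [s for s, g in zip(scores, bins) if g == b]
        lens = lengths[bins == b]
        rows.append(
            {
                "bin": b + 1,
                "min_len": float(lens.min()) if lens.size else np.nan,
                "max_len": float(lens.max()) if lens.size else np.nan,
                "n": len(members),
                "macro_strict_f1": 100 * float(np.mean([s.strict_f1 for s in members])) if members else np.nan,
                "macro_relaxed_f1": 100 * float(np.mean([s.relaxed_f1 for s in members])) if members else np.nan,
                "macro_precision": 100 * float(np.mean([s.relaxed_precision for s in members])) if members else np.nan,
                "macro_recall": 100 * float(np.mean([s.relaxed_recall for s in members])) if members else np.nan,
            }
        )
    return pd.DataFrame(rows)


#: Recall-interval bounds, upper-inclusive, plus the exact-zero row.
RECALL_INTERVALS: list[tuple[str, float, float]] = [
    ("(99-100]", 0.99, 1.00),
    ("(90-99]", 0.90, 0.99),
    ("(80-90]", 0.80, 0.90),
    ("(70-80]", 0.70, 0.80),
    ("(60-70]", 0.60, 0.70),
    ("(50-60]", 0.50, 0.60),
    ("(40-50]", 0.40, 0.50),
    ("(30-40]", 0.30, 0.40),
    ("(20-30]", 0.20, 0.30),
    ("(10-20]", 0.10, 0.20),
    ("(0-10]", 0.00, 0.10),
    ("0", 0.0, 0.0),
]


def recall_interval_table(scores: Sequence[SampleScore]) -> pd.DataFrame:
    """Recall distribution of non-strict-match samples over 12 fixed intervals.

    Each cell is the percentage of samples with strict F1 = 0 whose relaxed
    recall falls in the interval; rows sum to 100% of that subset (all-zero
    table when the subset is empty).
    """
    subset = [s for s in scores if s.strict_f1 == 0]
    n = len(subset)
    rows = []
    for label, lo, hi in RECALL_INTERVALS:
        if label == "0":
            count = sum(1 for s in subset if s.relaxed_recall == 0.0)
        else:
            count = sum(1 for s in subset if lo < s.relaxed_recall <= hi)
        rows.append(
            {"recall_interval": label, "n": count,
             "pct": 100 * count / n if n else 0.0}
        )
    return pd.DataFrame(rows)


def ratio_distribution(scores: Sequence[SampleScore]) -> dict:
    """Answer/context length-ratio distributions (percent).

    Restricted to samples where relaxed recall is 1 but the strict match
    failed — the cases where a full-overlap prediction might simply be the
    whole context. Returns both ratio samples plus summary quantiles.
    """
    subset = [
        s
        for s in scores
        if s.relaxed_recall == 1.0 and s.strict_f1 == 0 and s.context_len_tokens > 0
    ]
    pred_ratios = np.array(
        [100 * s.pred_len_tokens / s.context_len_tokens for s in subset]
    )
    gold_ratios = np.array(
        [100 * s.gold_len_tokens / s.context_len_tokens for s in subset]
    )
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    summary = pd.DataFrame(
        {
            "quantile": qs,
            "pred_ratio_pct": np.quantile(pred_ratios, qs) if subset else [np.nan] * 5,
            "gold_ratio_pct": np.quantile(gold_ratios, qs) if subset else [np.nan] * 5,
        }
    )
    return {
        "n": len(subset),
        "pred_ratios_pct": pred_ratios,
        "gold_ratios_pct": gold_ratios,
        "summary": summary,
    }


def null_note_detection(
    predictions: Sequence[SpanPrediction],
) -> tuple[float, Counter]:
    """Empty-answer detection on keyword-free notes.

    Returns the fraction of predictions equal to the empty string and a tally
    of the literal non-empty mispredictions.
    """
    if not predictions:
        return 0.0, Counter()
    empty = sum(1 for p in predictions if p.text == "")
    mispredictions = Counter(p.text for p in predictions if p.text != "")
    return empty / len(predictions), mispredictions
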