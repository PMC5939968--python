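"""Benchmark scoring: precision of top-L/5 long-range predictions,
replicate averaging, per-case geometric-mean score, method ranking and
paired Wilcoxon significance.

The per-case score is computed in a fixed order: for each predictor the
precision is averaged over alignment replicates first, then the
geometric mean is taken across predictors.  Methods are ranked by the
arithmetic mean of per-case scores; note this is not the geometric mean
of the per-predictor mean columns.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .contact_truth import ColumnMap, ContactSet, DEFAULT_MIN_SEP
from .dca_predictor import PredictionList
from .errors import DegenerateInputError, PairingError
from .formats_io import Msa

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CaseScore:
    """Per-test-case scores: per-predictor replicate precisions, their
    means, and the combined geometric-mean score."""

    case_id: str
    per_predictor: dict[str, tuple[tuple[float, ...], float]]
    conttest_score: float


@dataclass(frozen=True)
class MethodSummary:
    """One alignment method's scores over a set of test cases."""

    method_name: str
    case_scores: tuple[CaseScore, ...]
    mean_conttest: float


def precision_top_l5(
    predictions: PredictionList,
    truth: ContactSet,
    L: int,
    min_sep: int = DEFAULT_MIN_SEP,
    fraction: float = 0.2,
) -> float:
    """Precision of the top k = floor(L * fraction) long-range predictions.

    Predictions are filtered to sequence separation j - i >= min_sep,
    ranked by score (ties broken by (i, j) lexicographic order), and the
    top k compared against the true contact set.  If fewer than k
    long-range predictions exist, the missing ones count as wrong.
    """
    k = max(1, math.floor(L * fraction))
    long_range = [e for e in predictions.entries if e[1] - e[0] >= min_sep]
    if not long_range:
        raise DegenerateInputError(
            "no long-range predictions to score (separation filter removed all)"
        )
    if len(long_range) < k:
        warnings.warn(
            f"only {len(long_range)} long-range predictions for k={k}; "
            "missing predictions count as incorrect"
        )
    taken = long_range[:k]  # entries are already sorted with the tie-break
    hits = sum(1 for i, j, _ in taken if (i, j) in truth.pairs)
    return hits / k


def conttest_score(mean_precisions: Sequence[float]) -> float:
    """Geometric mean of per-predictor mean precisions; 0 if any is 0."""
    if len(mean_precisions) == 0:
        raise DegenerateInputError("no precisions to combine")
    for p in mean_precisions:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"precision {p} outside [0, 1]")
    if any(p == 0.0 for p in mean_precisions):
        return 0.0
    return float(np.exp(np.mean(np.log(mean_precisions))))


Predictor = Callable[[Msa, ColumnMap], PredictionList]


def score_case(
    msa_replicates: Sequence[Msa],
    truth: ContactSet,
    column_maps: Sequence[ColumnMap],
    predictors: Mapping[str, Predictor],
    case_id: str = "case",
    min_sep: int = DEFAULT_MIN_SEP,
    fraction: float = 0.2,
) -> CaseScore:
    """Score one test case: replicate-mean precision per predictor, then
    geometric mean across predictors.

    ``column_maps`` holds one map per replicate (row shuffles share a
    map, but re-aligned replicates may not).  A replicate that fails
    with a degenerate-input error is dropped; the case fails only if all
    replicates fail for some predictor.
    """
    if not msa_replicates:
        raise DegenerateInputError("no replicates")
    if not predictors:
        raise DegenerateInputError("no predictors")
    if len(column_maps) != len(msa_replicates):
        raise ValueError("need one column map per replicate")
    per_predictor: dict[str, tuple[tuple[float, ...], float]] = {}
    for name, fn in predictors.items():
        precisions: list[float] = []
        errors: list[Exception] = []
        for msa, cmap in zip(msa_replicates, column_maps):
            try:
                preds = fn(msa, cmap)
                precisions.append(
                    precision_top_l5(
                        preds, truth, truth.L, min_sep=min_sep, fraction=fraction
                    )
                )
            except DegenerateInputError as exc:
                errors.append(exc)
        if not precisions:
            raise DegenerateInputError(
                f"predictor {name!r} failed on all replicates: {errors[-1]}"
            )
        per_predictor[name] = (tuple(precisions), float(np.mean(precisions)))
    score = conttest_score([mean for _, mean in per_predictor.values()])
    return CaseScore(
        case_id=case_id, per_predictor=per_predictor, conttest_score=score
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic via the subset-sum
    distribution of the ranks (handles tied, i.e. half-integer, ranks)."""
    # doubling makes average ranks integral
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    paired_scores: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired scores; returns (W+, p).

    Zero differences are dropped (Wilcoxon's original rule); tied
    absolute differences receive average ranks.  The null distribution
    is exact (full subset-sum enumeration) for up to 25 effective pairs
    and a normal approximation with tie correction and continuity
    correction beyond that.  The p-value is two-sided.
    """
    if len(paired_scores) == 0:
        raise DegenerateInputError("no pairs")
    diffs = np.array([a - b for a, b in paired_scores], dtype=float)
    diffs = diffs[diffs != 0.0]
    n = len(diffs)
    if n == 0:
        warnings.warn("all differences are zero; returning p = 1.0")
        return 0.0, 1.0
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= 25:
        return w_plus, _exact_signed_rank_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # variance with tie correction
    tie_term = 0.0
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


#: Base significance levels marked in ranked tables, Bonferroni-divided
#: by the number of tests: '*', '**', '***'.
SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


def summarize_methods(
    per_method: Mapping[str, Sequence[CaseScore]],
    alpha_levels: Sequence[float] = SIGNIFICANCE_LEVELS,
    n_tests: int | None = None,
) -> list[dict]:
    """Rank methods by mean score and test consecutive pairs.

    All methods must share the same case-id set (paired design).
    Returns a list of row dicts sorted by ``mean_conttest`` descending;
    each row except the last carries the Wilcoxon p-value against the
    next-ranked method and a significance mark at the Bonferroni-
    corrected levels ('NS' if not significant at the loosest level).
    """
    if not per_method:
        raise DegenerateInputError("no methods to summarize")
    case_sets = {
        name: frozenset(cs.case_id for cs in scores)
        for name, scores in per_method.items()
    }
    ref = next(iter(case_sets.values()))
    for name, ids in case_sets.items():
        if ids != ref:
            missing = sorted(ref ^ ids)
            raise PairingError(
                f"method {name!r} case ids differ from the rest: {missing[:10]}"
            )
    summaries = []
    for name, scores in per_method.items():
        scores = sorted(scores, key=lambda cs: cs.case_id)
        mean = float(np.mean([cs.conttest_score for cs in scores]))
        summaries.append(
            MethodSummary(
                method_name=name, case_scores=tuple(scores), mean_conttest=mean
            )
        )
    summaries.sort(key=lambda m: (-m.mean_conttest, m.method_name))
    if n_tests is None:
        n_tests = max(1, len(summaries) - 1)
    rows = []
    for rank, summary in enumerate(summaries):
        row = {
            "rank": rank + 1,
            "method": summary.method_name,
            "mean_conttest": summary.mean_conttest,
            "p_vs_next": None,
            "mark": "",
        }
        if rank + 1 < len(summaries):
            nxt = summaries[rank + 1]
            pairs = [
                (a.conttest_score, b.conttest_score)
                for a, b in zip(summary.case_scores, nxt.case_scores)
            ]
            _, p = wilcoxon_signed_rank(pairs)
            row["p_vs_next"] = p
            mark = "NS"
            stars = 0
            for level in sorted(alpha_levels, reverse=True):
                if p < level / n_tests:
                    stars += 1
            if stars:
                mark = "*" * stars
            row["mark"] = mark
        rows.append(row)
    return rows


def format_ranked_table(rows: list[dict]) -> str:
    """Plain-text ranked table of method summaries."""
    lines = [f"{'method':<32}{'mean score':>12}  vs next"]
    for row in rows:
        tail = ""
        if row["p_vs_next"] is not None:
            tail = f"p={row['p_vs_next']:.3g} {row['mark']}"
        lines.append(f"{row['method']:<32}{row['mean_conttest']:>12.4f}  {tail}")
    return "\n".join(lines)
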