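"""Scoring, agreement, bootstrap confidence intervals, and model comparison.

Predicted spans are scored against gold annotations with span-overlap
precision/recall/F1 computed over word-token index sets (character
granularity is a config option).  When a note has no gold section and the
model asserts absence, the pair scores P = R = F1 = 1 (a correct
rejection); an alternative policy excludes such pairs from averaging.

Uncertainty follows the multi-run bootstrap protocol: each inference run is
bootstrapped over notes (n_boot resamples, the note being the independent
sampling unit), resample means are pooled across runs, and the 95% CI is
the 2.5/97.5 percentile interval.  Models are compared with a Friedman test
over paired blocks and post-hoc pairwise Wilcoxon signed-rank tests under a
Bonferroni-adjusted alpha.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .anchoring import tokenize_words
from .models import (
    AnchoredPrediction,
    AnnotatedNote,
    ClinicalNote,
    NotesectError,
    ReferenceError_,
    SectionLabel,
    SectionSpan,
)

# ---------------------------------------------------------------------------
# per-section overlap metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricRecord:
    note_id: str
    label: SectionLabel
    precision: float
    recall: float
    f1: float
    gold_present: bool
    pred_present: bool


def _covered_units(span: Optional[SectionSpan], note: ClinicalNote, granularity: str) -> set[int]:
    if span is None:
        return set()
    span.validate_against(note)
    if granularity == "char":
        return set(range(span.start_char, span.end_char))
    if granularity != "word":
        raise ValueError(f"unknown granularity {granularity!r}")
    return {
        i
        for i, t in enumerate(tokenize_words(note.text))
        if t.start_char < span.end_char and t.end_char > span.start_char
    }


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def span_overlap_metrics(
    gold: Optional[SectionSpan],
    pred: Optional[SectionSpan],
    note: ClinicalNote,
    granularity: str = "word",
    label: Optional[SectionLabel] = None,
) -> MetricRecord:
    """Precision/recall/F1 of a predicted span against gold.

    Both absent scores 1/1/1 (correct rejection); presence mismatches score
    zero on all three.
    """
    if label is None:
        label = gold.label if gold is not None else (pred.label if pred is not None else SectionLabel.RCH)
    if gold is None and pred is None:
        p = r = 1.0
    elif gold is None or pred is None:
        p = r = 0.0
    else:
        g = _covered_units(gold, note, granularity)
        q = _covered_units(pred, note, granularity)
        inter = len(g & q)
        p = inter / len(q) if q else 0.0
        r = inter / len(g) if g else 0.0
    return MetricRecord(
        note_id=note.note_id,
        label=label,
        precision=p,
        recall=r,
        f1=_f1(p, r),
        gold_present=gold is not None,
        pred_present=pred is not None,
    )


def evaluate_predictions(
    corpus: list[AnnotatedNote],
    predictions: Mapping[str, Mapping[SectionLabel, AnchoredPrediction]],
    granularity: str = "word",
) -> list["ScoredSection"]:
    """Score each (note, label) pair; missing prediction entries count as absent."""
    scored: list[ScoredSection] = []
    known = {ann.note.note_id for ann in corpus}
    for nid in predictions:
        if nid not in known:
            raise ReferenceError_(f"predictions reference unknown note_id {nid!r}")
    for ann in corpus:
        by_label = predictions.get(ann.note.note_id, {})
        for label in SectionLabel:
            gold = ann.spans.get(label)
            pred_obj = by_label.get(label)
            pred_span = pred_obj.span if pred_obj is not None else None
            rec = span_overlap_metrics(gold, pred_span, ann.note, granularity, label=label)
            scored.append(ScoredSection(ann.note, label, gold, pred_span, rec))
    return scored


@dataclass(frozen=True)
class ScoredSection:
    note: ClinicalNote
    label: SectionLabel
    gold: Optional[SectionSpan]
    pred: Optional[SectionSpan]
    metrics: MetricRecord


def corpus_metrics(
    records: Sequence[MetricRecord], absent_policy: str = "credit"
) -> dict[str, dict[str, float]]:
    """Unweighted per-label and overall means of precision, recall, F1.

    absent_policy="exclude" drops correct rejections (gold and prediction
    both absent) from the averages.
    """
    if not records:
        raise NotesectError("no metric records to aggregate")
    if absent_policy not in ("credit", "exclude"):
        raise ValueError(f"unknown absent_policy {absent_policy!r}")
    if absent_policy == "exclude":
        records = [r for r in records if r.gold_present or r.pred_present]
        if not records:
            raise NotesectError("all records are correct rejections; nothing to average")
    out: dict[str, dict[str, float]] = {}
    groups: dict[str, list[MetricRecord]] = {"overall": list(records)}
    for label in SectionLabel:
        groups[label.value] = [r for r in records if r.label is label]
    for name, recs in groups.items():
        if not recs:
            continue
        out[name] = {
            "precision": float(np.mean([r.precision for r in recs])),
            "recall": float(np.mean([r.recall for r in recs])),
            "f1": float(np.mean([r.f1 for r in recs])),
            "n": len(recs),
        }
    return out


# ---------------------------------------------------------------------------
# inter-annotator agreement and adjudication
# ---------------------------------------------------------------------------


class Resolution(str, Enum):
    UNION_ADOPTED = "union_adopted"
    NEEDS_ADJUDICATION = "needs_adjudication"


@dataclass(frozen=True)
class AgreementRecord:
    note_id: str
    label: SectionLabel
    jaccard: float
    resolution: Resolution


def jaccard_index(a: Optional[SectionSpan], b: Optional[SectionSpan]) -> float:
    """Jaccard index of two spans over their character-offset sets.

    Both absent → 1.0 (vacuous agreement); exactly one absent → 0.0.
    """
    if a is None and b is None:
        return 1.0
    if a is None or b is None:
        return 0.0
    inter = max(0, min(a.end_char, b.end_char) - max(a.start_char, b.start_char))
    union = (a.end_char - a.start_char) + (b.end_char - b.start_char) - inter
    return inter / union


def adjudicate(
    a: AnnotatedNote, b: AnnotatedNote, agreement_threshold: float = 0.80
) -> tuple[dict[SectionLabel, AgreementRecord], AnnotatedNote]:
    """Merge two annotators' spans per the union rule.

    Labels whose Jaccard strictly exceeds the threshold adopt the union
    span [min(starts), max(ends)); others are flagged for group
    adjudication and excluded from the merged note.
    """
    if a.note.note_id != b.note.note_id:
        raise ReferenceError_(
            f"annotations refer to different notes: {a.note.note_id!r} vs {b.note.note_id!r}"
        )
    records: dict[SectionLabel, AgreementRecord] = {}
    merged_spans: dict[SectionLabel, SectionSpan] = {}
    for label in SectionLabel:
        sa, sb = a.spans.get(label), b.spans.get(label)
        ji = jaccard_index(sa, sb)
        if ji > agreement_threshold:
            resolution = Resolution.UNION_ADOPTED
            if sa is not None or sb is not None:
                present = [s for s in (sa, sb) if s is not None]
                merged_spans[label] = SectionSpan(
                    label,
                    min(s.start_char for s in present),
                    max(s.end_char for s in present),
                )
        else:
            resolution = Resolution.NEEDS_ADJUDICATION
        records[label] = AgreementRecord(a.note.note_id, label, ji, resolution)
    merged = AnnotatedNote(note=a.note, spans=merged_spans, annotator_id="union")
    return records, merged


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapResult:
    metric_name: str
    label: str
    samples: tuple[float, ...]
    mean: float
    ci_low: float
    ci_high: float


_METRICS = ("precision", "recall", "f1")


def bootstrap_metrics(
    per_run_records: Sequence[tuple[int, Sequence[MetricRecord]]],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, dict[str, BootstrapResult]]:
    """Multi-run note-level bootstrap of mean metrics.

    For each run, draw ``n_boot`` resamples of notes with replacement and
    record the mean of each metric per label over the resample; pool all
    runs' resample means (3 runs × 1000 → 3000 samples) and take the 95%
    percentile interval.  Deterministic given ``seed``: run ``r`` uses the
    stream ``default_rng((seed, r))`` so identical resample indices pair
    across models evaluated on the same corpus.
    """
    if not per_run_records:
        raise NotesectError("no runs supplied")
    note_sets = [tuple(sorted({r.note_id for r in recs})) for _, recs in per_run_records]
    if any(not recs for _, recs in per_run_records):
        raise NotesectError("a run has no records")
    if len(set(note_sets)) != 1:
        raise NotesectError("all runs must cover the same note set")
    note_ids = list(note_sets[0])
    n_notes = len(note_ids)
    labels = [lab.value for lab in SectionLabel] + ["overall"]

    # per run: (n_notes, n_labels, n_metrics) array of per-note mean metrics
    pooled: dict[str, dict[str, list[float]]] = {m: {g: [] for g in labels} for m in _METRICS}
    for run_index, recs in per_run_records:
        by_note: dict[str, dict[str, list[MetricRecord]]] = {
            nid: {g: [] for g in labels} for nid in note_ids
        }
        for r in recs:
            by_note[r.note_id][r.label.value].append(r)
            by_note[r.note_id]["overall"].append(r)
        arr = np.full((n_notes, len(labels), len(_METRICS)), np.nan)
        for i, nid in enumerate(note_ids):
            for g_idx, g in enumerate(labels):
                rs = by_note[nid][g]
                if rs:
                    for m_idx, m in enumerate(_METRICS):
                        arr[i, g_idx, m_idx] = float(np.mean([getattr(r, m) for r in rs]))
        rng = np.random.default_rng((seed, run_index))
        idx = rng.integers(0, n_notes, size=(n_boot, n_notes))
        for b in range(n_boot):
            sample = arr[idx[b]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # label absent from resample
                means = np.nanmean(sample, axis=0)
            for g_idx, g in enumerate(labels):
                for m_idx, m in enumerate(_METRICS):
                    pooled[m][g].append(float(means[g_idx, m_idx]))

    out: dict[str, dict[str, BootstrapResult]] = {}
    for m in _METRICS:
        out[m] = {}
        for g in labels:
            samples = np.array(pooled[m][g])
            lo, hi = np.percentile(samples, [2.5, 97.5])
            # clamp: summation order can push the mean a ULP outside a degenerate interval
            mean = float(min(max(samples.mean(), lo), hi))
            out[m][g] = BootstrapResult(
                metric_name=m,
                label=g,
                samples=tuple(samples.tolist()),
                mean=mean,
                ci_low=float(lo),
                ci_high=float(hi),
            )
    return out


# ---------------------------------------------------------------------------
# Friedman + Wilcoxon model comparison
# ---------------------------------------------------------------------------


def _friedman_statistic(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-squared statistic; matrix is models × blocks."""
    k, n = matrix.shape
    ranks = np.apply_along_axis(sps.rankdata, 0, matrix)  # midranks within block
    rank_sums = ranks.sum(axis=1)
    ssbn = float((rank_sums**2).sum())
    chisq = 12.0 / (n * k * (k + 1)) * ssbn - 3 * n * (k + 1)
    ties = 0.0
    for j in range(n):
        _, counts = np.unique(matrix[:, j], return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0  # every block fully tied
    return chisq / c


def friedman_test(
    metric_matrix: Sequence[Sequence[float]] | np.ndarray,
    method: str = "approx",
) -> tuple[float, float]:
    """Friedman rank test for k paired models over n blocks.

    ``metric_matrix`` is models × blocks; blocks must be paired across
    models (same bootstrap resample index and run).  ``method="approx"``
    uses the chi-squared approximation with k−1 degrees of freedom;
    ``method="exact"`` enumerates all within-block permutations of the
    observed values (feasible only for small matrices) and returns the
    permutation p-value of the tie-corrected statistic.
    """
    matrix = np.asarray(metric_matrix, dtype=float)
    if matrix.ndim != 2:
        raise NotesectError("metric matrix must be 2-D (models × blocks)")
    k, n = matrix.shape
    if k < 2 or n < 2:
        raise NotesectError("need at least 2 models and 2 blocks")
    stat = _friedman_statistic(matrix)
    if method == "approx":
        p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
        return stat, p
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    total = math.factorial(k) ** n
    if total > 2_000_000:
        raise NotesectError(f"exact Friedman infeasible: {total} permutations")
    perms = list(itertools.permutations(range(k)))
    count = 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.empty_like(matrix)
        for j, perm in enumerate(combo):
            permuted[:, j] = matrix[list(perm), j]
        if _friedman_statistic(permuted) >= stat - 1e-12:
            count += 1
    return stat, count / total


@dataclass(frozen=True)
class PairwiseTest:
    model_a: str
    model_b: str
    statistic: float
    p_value: float
    significant_at_adjusted_alpha: bool
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    friedman_statistic: float
    friedman_p: float
    pairwise: tuple[PairwiseTest, ...]
    adjusted_alpha: float


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied magnitudes get midranks.  The exact
    null distribution (dynamic programming over doubled ranks) is used for
    n ≤ 25 retained pairs, else a normal approximation with tie correction
    and continuity correction.  Returns (W+, p, degenerate); a pair whose
    differences are all zero is degenerate with p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, True
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # exact distribution over 2^n sign assignments, ranks doubled to integers
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = float(counts[: w2 + 1].sum())
        p_ge = float(counts[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = n * (n + 1) / 4.0
        tie_sum = 0.0
        _, cnts = np.unique(np.abs(d), return_counts=True)
        tie_sum = float((cnts**3 - cnts).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_sum / 48.0
        diff = w_plus - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(var) if var > 0 else 0.0
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z)))) if var > 0 else 1.0
    return w_plus, p, False


def pairwise_wilcoxon(
    metric_matrix: Sequence[Sequence[float]] | np.ndarray,
    global_alpha: float = 0.05,
    model_names: Optional[Sequence[str]] = None,
    friedman_method: str = "approx",
) -> ComparisonResult:
    """Friedman omnibus test plus Bonferroni-corrected pairwise Wilcoxon tests."""
    matrix = np.asarray(metric_matrix, dtype=float)
    if matrix.ndim != 2:
        raise NotesectError("metric matrix must be 2-D (models × blocks)")
    k = matrix.shape[0]
    names = list(model_names) if model_names is not None else [f"model{i}" for i in range(k)]
    if len(names) != k:
        raise NotesectError("model_names length must match the number of models")
    stat, p = friedman_test(matrix, method=friedman_method)
    pairs = list(itertools.combinations(range(k), 2))
    adjusted_alpha = global_alpha / len(pairs)
    results = []
    for i, j in pairs:
        w, pw, degenerate = wilcoxon_signed_rank(matrix[i], matrix[j])
        results.append(
            PairwiseTest(
                model_a=names[i],
                model_b=names[j],
                statistic=w,
                p_value=pw,
                significant_at_adjusted_alpha=bool(pw < adjusted_alpha),
                degenerate=degenerate,
            )
        )
    return ComparisonResult(
        friedman_statistic=stat,
        friedman_p=p,
        pairwise=tuple(results),
        adjusted_alpha=adjusted_alpha,
    )


# ---------------------------------------------------------------------------
# error classification
# ---------------------------------------------------------------------------


class ErrorClass(str, Enum):
    OK = "ok"
    OVERPREDICTION = "overprediction"
    UNDERPREDICTION = "underprediction"
    SHIFT = "shift"
    MISSED = "missed"
    SPURIOUS = "spurious"


def classify_error(scored: ScoredSection, f1_gate: float = 0.8) -> ErrorClass:
    """Classify one scored section; sections at or above the F1 gate are ok."""
    m = scored.metrics
    if m.f1 >= f1_gate:
        return ErrorClass.OK
    if m.gold_present and not m.pred_present:
        return ErrorClass.MISSED
    if m.pred_present and not m.gold_present:
        return ErrorClass.SPURIOUS
    gold, pred = scored.gold, scored.pred
    assert gold is not None and pred is not None
    contains = pred.start_char <= gold.start_char and pred.end_char >= gold.end_char
    contained = gold.start_char <= pred.start_char and gold.end_char >= pred.end_char
    if contains and not contained:
        return ErrorClass.OVERPREDICTION
    if contained and not contains:
        return ErrorClass.UNDERPREDICTION
    if m.precision < m.recall:
        return ErrorClass.OVERPREDICTION
    if m.recall < m.precision:
        return ErrorClass.UNDERPREDICTION
    return ErrorClass.SHIFT


def classify_errors(
    scored: Iterable[ScoredSection], f1_gate: float = 0.8
) -> list[tuple[str, SectionLabel, ErrorClass]]:
    return [(s.note.note_id, s.label, classify_error(s, f1_gate)) for s in scored]
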