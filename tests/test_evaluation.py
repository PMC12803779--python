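"""Scoring, agreement, bootstrap, and nonparametric comparison."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import notesect as ns
from notesect.evaluation import (
    ErrorClass,
    MetricRecord,
    Resolution,
    ScoredSection,
    adjudicate,
    bootstrap_metrics,
    classify_error,
    corpus_metrics,
    friedman_test,
    jaccard_index,
    pairwise_wilcoxon,
    span_overlap_metrics,
    wilcoxon_signed_rank,
)
from notesect.models import AnnotatedNote, ClinicalNote, SectionLabel, SectionSpan

RCH = SectionLabel.RCH
AP = SectionLabel.AP


def note_of_words(n_words, note_id="n"):
    return ClinicalNote(note_id=note_id, patient_id="p",
                        text=" ".join(f"w{i}" for i in range(n_words)))


def word_span(note, label, first, last):
    """Span covering word indices [first, last] inclusive."""
    toks = ns.tokenize_words(note.text)
    return SectionSpan(label, toks[first].start_char, toks[last].end_char)


class TestOverlapMetrics:
    def test_exact_match_scores_one(self):
        note = note_of_words(30)
        g = word_span(note, RCH, 5, 20)
        m = span_overlap_metrics(g, g, note)
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_disjoint_scores_zero(self):
        note = note_of_words(30)
        m = span_overlap_metrics(word_span(note, RCH, 0, 5),
                                 word_span(note, RCH, 10, 20), note)
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_half_covered_gold_token_counts(self):
        note = note_of_words(40)
        gold = word_span(note, RCH, 10, 29)   # 20 tokens
        pred = word_span(note, RCH, 10, 19)   # 10 tokens, all inside gold
        m = span_overlap_metrics(gold, pred, note)
        assert m.precision == 1.0
        assert m.recall == 0.5
        assert m.f1 == pytest.approx(2 / 3)

    def test_absence_conventions(self):
        note = note_of_words(10)
        span = word_span(note, AP, 0, 4)
        both = span_overlap_metrics(None, None, note, label=AP)
        assert (both.precision, both.recall, both.f1) == (1.0, 1.0, 1.0)
        fp = span_overlap_metrics(None, span, note)
        fn = span_overlap_metrics(span, None, note)
        assert (fp.precision, fp.recall) == (0.0, 0.0)
        assert (fn.precision, fn.recall) == (0.0, 0.0)

    def test_char_granularity_differs_from_word(self):
        note = ClinicalNote(note_id="n", patient_id="p", text="aa bbbbbbbb cc")
        gold = SectionSpan(RCH, 0, 14)
        pred = SectionSpan(RCH, 3, 11)  # the long middle token only
        word = span_overlap_metrics(gold, pred, note, "word")
        char = span_overlap_metrics(gold, pred, note, "char")
        assert word.recall == pytest.approx(1 / 3)
        assert char.recall == pytest.approx(8 / 14)

    def test_f1_harmonic_identity_on_random_records(self):
        rng = np.random.default_rng(4)
        note = note_of_words(50)
        for _ in range(50):
            a, b = sorted(rng.integers(0, 49, size=2))
            c, d = sorted(rng.integers(0, 49, size=2))
            m = span_overlap_metrics(word_span(note, RCH, a, b + 1),
                                     word_span(note, RCH, c, d + 1), note)
            assert 0 <= m.precision <= 1 and 0 <= m.recall <= 1
            if m.precision + m.recall > 0:
                expected = 2 * m.precision * m.recall / (m.precision + m.recall)
                assert m.f1 == pytest.approx(expected)
            else:
                assert m.f1 == 0.0


class TestCorpusMetrics:
    def _rec(self, f1, label=RCH, gold=True, pred=True, nid="n"):
        return MetricRecord(nid, label, f1, f1, f1, gold, pred)

    def test_mean_of_constant_records(self):
        recs = [self._rec(1.0, nid=f"n{i}") for i in range(5)]
        assert corpus_metrics(recs)["overall"]["f1"] == 1.0

    def test_mean_of_mixed_records(self):
        recs = [self._rec(0.0, nid="a"), self._rec(1.0, nid="b")]
        assert corpus_metrics(recs)["overall"]["f1"] == 0.5

    def test_matches_arithmetic_on_random_records(self):
        rng = np.random.default_rng(1)
        vals = rng.random(100)
        recs = [self._rec(float(v), nid=f"n{i}") for i, v in enumerate(vals)]
        assert corpus_metrics(recs)["overall"]["f1"] == pytest.approx(float(vals.mean()))

    def test_exclude_policy_drops_correct_rejections(self):
        recs = [self._rec(1.0, gold=False, pred=False, nid="a"), self._rec(0.5, nid="b")]
        assert corpus_metrics(recs, "credit")["overall"]["f1"] == 0.75
        assert corpus_metrics(recs, "exclude")["overall"]["f1"] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ns.NotesectError):
            corpus_metrics([])


class TestJaccardAndAdjudication:
    def test_identical_spans(self):
        s = SectionSpan(RCH, 0, 10)
        assert jaccard_index(s, s) == 1.0

    def test_disjoint_spans(self):
        assert jaccard_index(SectionSpan(RCH, 0, 10), SectionSpan(RCH, 20, 30)) == 0.0

    def test_interval_arithmetic_case(self):
        assert jaccard_index(SectionSpan(RCH, 0, 100), SectionSpan(RCH, 50, 150)) == pytest.approx(1 / 3)

    def test_absence_conventions(self):
        s = SectionSpan(RCH, 0, 10)
        assert jaccard_index(None, None) == 1.0
        assert jaccard_index(s, None) == 0.0

    def _pair(self, span_a, span_b, n_chars=200):
        note = ClinicalNote(note_id="n", patient_id="p", text="x" * n_chars)
        a = AnnotatedNote(note=note, spans={RCH: span_a} if span_a else {}, annotator_id="A")
        b = AnnotatedNote(note=note, spans={RCH: span_b} if span_b else {}, annotator_id="B")
        return a, b

    def test_identical_annotations_union_adopted(self):
        s = SectionSpan(RCH, 0, 100)
        records, merged = adjudicate(*self._pair(s, s))
        assert records[RCH].resolution is Resolution.UNION_ADOPTED
        assert merged.spans[RCH] == s

    def test_low_agreement_flags_adjudication(self):
        records, merged = adjudicate(*self._pair(SectionSpan(RCH, 0, 100), SectionSpan(RCH, 50, 150)))
        assert records[RCH].jaccard == pytest.approx(1 / 3)
        assert records[RCH].resolution is Resolution.NEEDS_ADJUDICATION
        assert RCH not in merged.spans

    def test_union_is_min_max_envelope(self):
        records, merged = adjudicate(
            *self._pair(SectionSpan(RCH, 0, 100), SectionSpan(RCH, 50, 150)),
            agreement_threshold=0.3,
        )
        assert records[RCH].resolution is Resolution.UNION_ADOPTED
        assert (merged.spans[RCH].start_char, merged.spans[RCH].end_char) == (0, 150)

    def test_mismatched_notes_rejected(self):
        a, _ = self._pair(SectionSpan(RCH, 0, 10), None)
        other = AnnotatedNote(
            note=ClinicalNote(note_id="other", patient_id="p", text="x" * 50), spans={})
        with pytest.raises(ns.NotesectError):
            adjudicate(a, other)


class TestBootstrap:
    def _records(self, f1_by_note, label=RCH):
        return [MetricRecord(nid, label, f, f, f, True, True) for nid, f in f1_by_note.items()]

    def test_sample_count_is_runs_times_nboot(self):
        recs = self._records({f"n{i}": 0.5 + 0.01 * i for i in range(10)})
        runs = [(r, recs) for r in range(3)]
        out = bootstrap_metrics(runs, n_boot=50, seed=0)
        assert len(out["f1"]["RCH"].samples) == 150

    def test_zero_variance_degenerate_ci(self):
        recs = self._records({f"n{i}": 0.7 for i in range(8)})
        out = bootstrap_metrics([(0, recs)], n_boot=100, seed=1)
        res = out["f1"]["RCH"]
        assert res.mean == res.ci_low == res.ci_high == pytest.approx(0.7)

    def test_seed_reproducibility_bit_exact(self):
        rng = np.random.default_rng(2)
        recs = self._records({f"n{i}": float(v) for i, v in enumerate(rng.random(20))})
        recs += self._records({f"n{i}": float(v) for i, v in enumerate(rng.random(20))}, label=AP)
        runs = [(r, recs) for r in range(2)]
        a = bootstrap_metrics(runs, n_boot=200, seed=7)
        b = bootstrap_metrics(runs, n_boot=200, seed=7)
        assert a == b

    def test_ci_width_shrinks_with_corpus_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (50, 500):
            recs = self._records({f"n{i}": float(v) for i, v in enumerate(rng.beta(8, 2, size=n))})
            out = bootstrap_metrics([(0, recs)], n_boot=300, seed=5)
            res = out["f1"]["RCH"]
            widths.append(res.ci_high - res.ci_low)
        assert widths[1] < widths[0]

    def test_mismatched_note_sets_rejected(self):
        r1 = self._records({"a": 0.5, "b": 0.6})
        r2 = self._records({"a": 0.5, "c": 0.6})
        with pytest.raises(ns.NotesectError):
            bootstrap_metrics([(0, r1), (1, r2)], n_boot=10, seed=0)


# --------------------------------------------------------------------------
# nonparametric comparison, with exhaustive-null oracles
# --------------------------------------------------------------------------


def oracle_friedman_perm_p(matrix):
    """Exhaustive within-block rank-permutation null, coded independently."""
    matrix = np.asarray(matrix, dtype=float)
    k, n = matrix.shape

    def stat(m):
        ranks = np.empty_like(m)
        for j in range(n):
            ranks[:, j] = sps.rankdata(m[:, j])
        rj = ranks.sum(axis=1)
        q = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3 * n * (k + 1)
        ties = sum(float((c**3 - c).sum())
                   for c in (np.unique(m[:, j], return_counts=True)[1] for j in range(n)))
        corr = 1.0 - ties / (n * k * (k * k - 1))
        return 0.0 if corr <= 0 else q / corr

    observed = stat(matrix)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        m = np.stack([matrix[list(p), j] for j, p in enumerate(combo)], axis=1)
        total += 1
        if stat(m) >= observed - 1e-12:
            count += 1
    return observed, count / total


def oracle_wilcoxon_exact_p(diffs):
    """Two-sided p by brute enumeration of all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, bit in zip(ranks, bits) if bit)
          for bits in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestFriedman:
    def test_all_models_identical_gives_p_one(self):
        matrix = np.ones((3, 6))
        stat, p = friedman_test(matrix)
        assert stat == 0.0 and p == 1.0

    def test_two_model_dominance_closed_form(self):
        # A beats B in every block: rank sums are n and 2n, statistic = n for k=2
        n = 6
        matrix = np.vstack([np.full(n, 0.9), np.full(n, 0.1)])
        stat, _ = friedman_test(matrix)
        k = 2
        rank_sums = np.array([2.0 * n, 1.0 * n])
        expected = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3 * n * (k + 1)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(n)

    def test_approx_statistic_matches_scipy(self):
        rng = np.random.default_rng(8)
        matrix = rng.random((4, 12))
        stat, p = friedman_test(matrix)
        ref_stat, ref_p = sps.friedmanchisquare(*matrix)
        assert stat == pytest.approx(ref_stat)
        assert p == pytest.approx(ref_p)

    def test_exact_p_matches_permutation_oracle(self):
        matrix = np.array([
            [0.81, 0.74, 0.90, 0.62],
            [0.55, 0.71, 0.68, 0.50],
            [0.60, 0.80, 0.41, 0.33],
        ])
        stat, p = friedman_test(matrix, method="exact")
        o_stat, o_p = oracle_friedman_perm_p(matrix)
        assert stat == pytest.approx(o_stat, abs=1e-9)
        assert p == pytest.approx(o_p, abs=1e-9)

    def test_ragged_matrix_rejected(self):
        with pytest.raises(Exception):
            friedman_test([[1.0, 2.0], [1.0]])


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        w, p, degenerate = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert degenerate and p == 1.0

    def test_exact_p_matches_sign_flip_enumeration(self):
        x = np.array([0.91, 0.72, 0.85, 0.60, 0.78, 0.95, 0.66, 0.83])
        y = np.array([0.85, 0.74, 0.70, 0.55, 0.80, 0.88, 0.61, 0.79])
        w, p, _ = wilcoxon_signed_rank(x, y)
        w_o, p_o = oracle_wilcoxon_exact_p(x - y)
        assert w == pytest.approx(w_o)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_exact_p_matches_scipy_without_ties(self):
        rng = np.random.default_rng(9)
        x = rng.random(12)
        y = x + rng.normal(0.1, 0.2, size=12)
        w, p, _ = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, zero_method="wilcox", mode="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(10)
        x = rng.random(60)
        y = x + rng.normal(0.05, 0.1, size=60)
        _, p, _ = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, zero_method="wilcox", mode="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestPairwiseComparison:
    def test_bonferroni_alpha_for_five_models(self):
        rng = np.random.default_rng(11)
        matrix = rng.random((5, 8))
        result = pairwise_wilcoxon(matrix, global_alpha=0.05)
        assert len(result.pairwise) == 10
        assert result.adjusted_alpha == pytest.approx(0.005)

    def test_clearly_separated_models_flagged_significant(self):
        n = 30
        rng = np.random.default_rng(12)
        base = rng.random(n) * 0.1
        matrix = np.vstack([base + 0.8, base + 0.1])
        result = pairwise_wilcoxon(matrix, global_alpha=0.05)
        assert result.pairwise[0].significant_at_adjusted_alpha


class TestErrorClassification:
    def _scored(self, note, gold, pred):
        m = span_overlap_metrics(gold, pred, note, label=RCH)
        return ScoredSection(note, RCH, gold, pred, m)

    def test_exact_match_ok(self):
        note = note_of_words(30)
        g = word_span(note, RCH, 5, 20)
        assert classify_error(self._scored(note, g, g)) is ErrorClass.OK

    def test_strict_containment_is_overprediction(self):
        note = note_of_words(40)
        gold = word_span(note, RCH, 15, 20)
        pred = word_span(note, RCH, 5, 35)
        assert classify_error(self._scored(note, gold, pred)) is ErrorClass.OVERPREDICTION

    def test_half_gold_is_underprediction(self):
        note = note_of_words(40)
        gold = word_span(note, RCH, 10, 29)
        pred = word_span(note, RCH, 10, 19)
        s = self._scored(note, gold, pred)
        assert s.metrics.recall < s.metrics.precision
        assert classify_error(s) is ErrorClass.UNDERPREDICTION

    def test_missed_and_spurious(self):
        note = note_of_words(20)
        g = word_span(note, RCH, 0, 10)
        assert classify_error(self._scored(note, g, None)) is ErrorClass.MISSED
        assert classify_error(self._scored(note, None, g)) is ErrorClass.SPURIOUS

    def test_offset_overlap_with_equal_pr_is_shift(self):
        note = note_of_words(40)
        gold = word_span(note, RCH, 10, 19)
        pred = word_span(note, RCH, 15, 24)  # same length, partial overlap
        s = self._scored(note, gold, pred)
        assert s.metrics.precision == s.metrics.recall
        assert classify_error(s) is ErrorClass.SHIFT
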