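"""Fuzzy 5-gram span anchoring.

A generative backend proposes the first five and last five words of each
target section.  This module locates those word n-grams in the source note
with a sliding window over whitespace tokens, scoring each window by
normalized Levenshtein similarity ``1 - d / max(|a|, |b|)``, and extracts
the enclosed character span.  Generated text rarely reproduces the source
verbatim, so an exact-window short-circuit is tried first and fuzzy scoring
is the fallback; windows scoring at or above the policy threshold
(default 0.80) are considered valid anchors.

All matching is case-folded and whitespace-collapsed by default, but the
returned offsets always refer to the raw note text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .models import (
    AnchoredPrediction,
    ClinicalNote,
    NotesectError,
    PredictionStatus,
    SectionLabel,
    SectionSpan,
)

_WORD_RE = re.compile(r"\S+")


@dataclass(frozen=True)
class WordToken:
    """A maximal run of non-whitespace characters with raw-text offsets."""

    text: str
    start_char: int
    end_char: int


@dataclass(frozen=True)
class AnchorMatch:
    window_start_token: int
    score: float
    start_char: int
    end_char: int


@dataclass(frozen=True)
class MatchPolicy:
    """Knobs of the anchoring algorithm.

    threshold
        Minimum similarity for a valid anchor.  The boundary is inclusive
        (a score of exactly 0.80 is valid); set ``strict_threshold`` for
        strict-inequality semantics.
    window_size
        Anchor n-gram length in words.  Queries shorter than this are
        matched against equally short windows, so a three-word section can
        still anchor exactly.
    """

    threshold: float = 0.80
    window_size: int = 5
    normalize_case: bool = True
    collapse_whitespace: bool = True
    strict_threshold: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


def tokenize_words(text: str) -> list[WordToken]:
    """Split text into maximal non-whitespace runs with raw offsets."""
    return [WordToken(m.group(), m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character insert/delete/substitute edits."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    try:
        return edlib.align(a, b)["editDistance"]
    except (ValueError, MemoryError):
        # edlib maps at most 256 distinct symbols; fall back to plain DP
        return _levenshtein_dp(a, b)


def _levenshtein_dp(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity ``1 - d / max(|a|, |b|)`` in [0, 1]."""
    if not a and not b:
        raise NotesectError("similarity of two empty strings is undefined")
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def _normalize(s: str, policy: MatchPolicy) -> str:
    if policy.collapse_whitespace:
        s = " ".join(s.split())
    if policy.normalize_case:
        s = s.casefold()
    return s


def _window_text(tokens: Sequence[WordToken], start: int, size: int, policy: MatchPolicy) -> str:
    words = [t.text for t in tokens[start : start + size]]
    text = " ".join(words)
    return text.casefold() if policy.normalize_case else text


def find_anchor(
    tokens: Sequence[WordToken],
    query: str,
    policy: MatchPolicy = MatchPolicy(),
    search_from: int = 0,
) -> Optional[AnchorMatch]:
    """Locate ``query`` in the token stream by sliding-window fuzzy matching.

    Exact window equality is tried first (earliest match wins, score 1.0).
    Otherwise every window from ``search_from`` onward is scored — including
    tail windows shorter than the window size — and the best-scoring window
    passing the threshold is returned, earliest on ties.  Returns ``None``
    when no window qualifies; absence is a value, not an error.
    """
    if not query or not query.strip():
        raise NotesectError("anchor query must be non-empty")
    if not (0 <= search_from <= len(tokens)):
        raise NotesectError(f"search_from {search_from} out of range")

    q_norm = _normalize(query, policy)
    q_words = q_norm.split(" ")
    size = min(policy.window_size, len(q_words))
    n = len(tokens)

    def result(idx: int, score: float) -> AnchorMatch:
        last = min(idx + size, n) - 1
        return AnchorMatch(
            window_start_token=idx,
            score=score,
            start_char=tokens[idx].start_char,
            end_char=tokens[last].end_char,
        )

    # exact short-circuit: earliest window equal to the normalized query
    for i in range(search_from, n - size + 1):
        if _window_text(tokens, i, size, policy) == q_norm:
            return result(i, 1.0)

    best_idx: Optional[int] = None
    best_score = -1.0
    for i in range(search_from, n):
        w = _window_text(tokens, i, size, policy)
        if not w:
            continue
        s = similarity(q_norm, w)
        if s > best_score:
            best_idx, best_score = i, s
    if best_idx is None:
        return None
    passes = best_score > policy.threshold if policy.strict_threshold else best_score >= policy.threshold
    if not passes:
        return None
    return result(best_idx, best_score)


def extract_span(
    note: ClinicalNote,
    label: SectionLabel,
    first_words: str,
    last_words: str,
    policy: MatchPolicy = MatchPolicy(),
) -> AnchoredPrediction:
    """Anchor generated boundary words in the note and extract the span.

    The start anchor is searched over the whole note; the end anchor only at
    or after the start anchor's window, so extracted spans are never
    inverted.  Failures are encoded in the prediction status rather than
    raised.
    """
    tokens = tokenize_words(note.text)
    if not tokens:
        raise NotesectError(f"note {note.note_id!r} has no tokens")

    start = find_anchor(tokens, first_words, policy, search_from=0)
    if start is None:
        return AnchoredPrediction(label=label, status=PredictionStatus.NO_START_MATCH)
    end = find_anchor(tokens, last_words, policy, search_from=start.window_start_token)
    if end is None:
        return AnchoredPrediction(
            label=label, status=PredictionStatus.NO_END_MATCH, start_score=start.score
        )
    span = SectionSpan(label, start.start_char, end.end_char)
    return AnchoredPrediction(
        label=label,
        status=PredictionStatus.MATCHED,
        span=span,
        start_score=start.score,
        end_score=end.score,
    )


def anchor_output(
    note: ClinicalNote,
    sections: dict[SectionLabel, Optional[tuple[str, str]]],
    policy: MatchPolicy = MatchPolicy(),
) -> dict[SectionLabel, AnchoredPrediction]:
    """Anchor one backend output (per-label first/last word pairs) for a note."""
    preds: dict[SectionLabel, AnchoredPrediction] = {}
    for label in SectionLabel:
        pair = sections.get(label)
        if pair is None:
            preds[label] = AnchoredPrediction(label=label, status=PredictionStatus.SECTION_ABSENT)
        else:
            preds[label] = extract_span(note, label, pair[0], pair[1], policy)
    return preds
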