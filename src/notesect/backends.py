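"""Section-proposal backends.

A backend takes a note and emits, per section label, the first five and the
last five whitespace words of the span it believes is that section (or
asserts absence).  The anchoring module then locates those words in the
source text.  Three backends ship here:

* a mock oracle that reads gold spans and optionally corrupts its output
  (character edits, boundary shifts, false absences) — the test harness for
  the fuzzy matcher, since generative models rarely reproduce source text
  verbatim;
* a rule-based header scanner, a lightweight baseline in the spirit of
  terminology-rule sectioners;
* interface stubs for external LLM services, which share the contract but
  perform no inference.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from string import ascii_lowercase
from typing import Callable, Optional

import numpy as np

from .anchoring import tokenize_words
from .models import (
    AnnotatedNote,
    ClinicalNote,
    NotesectError,
    SectionLabel,
    slice_section,
)

Pair = tuple[str, str]


@dataclass(frozen=True)
class GenerationOutput:
    """Per-label (first_words, last_words) proposals from one backend run.

    An absent entry (None) means the backend asserts the section does not
    occur in the note.  Word strings are whitespace-normalized and at most
    five words long (shorter only when the proposed span itself is shorter).
    """

    sections: dict[SectionLabel, Optional[Pair]]
    model_name: str = "unknown"
    run_index: int = 0


@dataclass(frozen=True)
class PromptSpec:
    template: str = (
        "You are given a clinical progress note. For each requested section, "
        "return the FIRST FIVE words and the LAST FIVE words of that section "
        "exactly as they appear in the note, or the word ABSENT if the note "
        "contains no such section. Requested sections: {labels}.\n\n"
        "NOTE:\n{note_text}\n"
    )
    max_context_tokens: int = 8192


@dataclass(frozen=True)
class CorruptionConfig:
    """Controlled degradation of the mock oracle's output.

    char_edit_rate is the expected number of single-character edits applied
    per emitted 5-gram (edit counts are Poisson); shift_words displaces the
    true boundary by that many note words before emitting; drop_section_prob
    is the chance of wrongly asserting absence.  All zeros → exact output.
    """

    seed: int = 0
    char_edit_rate: float = 0.0
    drop_section_prob: float = 0.0
    shift_words: int = 0

    def __post_init__(self) -> None:
        if self.char_edit_rate < 0:
            raise NotesectError("char_edit_rate must be >= 0")
        if not (0.0 <= self.drop_section_prob <= 1.0):
            raise NotesectError("drop_section_prob must lie in [0, 1]")


def build_prompt(spec: PromptSpec, note: ClinicalNote, labels: list[SectionLabel]) -> str:
    """Render the unified prompt for one note; deterministic."""
    if not note.text:
        raise NotesectError("note text must be non-empty")
    if not labels:
        raise NotesectError("at least one section label must be requested")
    rendered = spec.template.format(
        labels=", ".join(lab.value for lab in labels), note_text=note.text
    )
    n_tokens = len(rendered.split())
    if n_tokens > spec.max_context_tokens:
        raise NotesectError(
            f"prompt of {n_tokens} whitespace tokens exceeds context window "
            f"of {spec.max_context_tokens}"
        )
    return rendered


def _note_rng(config: CorruptionConfig, note_id: str, run_index: int) -> np.random.Generator:
    # stable per-note stream: same (seed, note, run) → same corruption
    h = zlib.crc32(f"{note_id}|{run_index}".encode())
    return np.random.default_rng((config.seed, h))


def _apply_char_edits(rng: np.random.Generator, s: str, rate: float) -> str:
    n_edits = int(rng.poisson(rate))
    chars = list(s)
    for _ in range(n_edits):
        if not chars:
            chars = [str(ascii_lowercase[rng.integers(26)])]
            continue
        op = rng.integers(3)
        pos = int(rng.integers(len(chars)))
        c = str(ascii_lowercase[rng.integers(26)])
        if op == 0:
            chars[pos] = c
        elif op == 1:
            chars.insert(pos, c)
        else:
            del chars[pos]
    return "".join(chars)


def mock_oracle_generate(
    annotated: AnnotatedNote,
    corruption: CorruptionConfig = CorruptionConfig(),
    run_index: int = 0,
) -> GenerationOutput:
    """Emit the true boundary 5-grams of each gold span, then corrupt them.

    Corruption order per section: boundary shift, character edits, drop.
    Deterministic given (corruption.seed, note_id, run_index).
    """
    rng = _note_rng(corruption, annotated.note.note_id, run_index)
    note_tokens = tokenize_words(annotated.note.text)
    sections: dict[SectionLabel, Optional[Pair]] = {}
    for label in SectionLabel:
        gold = annotated.spans.get(label)
        if gold is None:
            sections[label] = None
            continue
        if corruption.shift_words == 0:
            words = slice_section(annotated.note, gold).split()
            first = words[:5]
            last = words[-5:]
        else:
            # word indices of the span inside the full note token stream
            idxs = [
                i for i, t in enumerate(note_tokens)
                if t.start_char >= gold.start_char and t.end_char <= gold.end_char
            ]
            lo = max(0, idxs[0] + corruption.shift_words)
            hi = min(len(note_tokens) - 1, idxs[-1] + corruption.shift_words)
            if lo > hi:
                lo = hi
            first = [t.text for t in note_tokens[lo : lo + 5]]
            last = [t.text for t in note_tokens[max(lo, hi - 4) : hi + 1]]
        first_s = " ".join(first)
        last_s = " ".join(last)
        if corruption.char_edit_rate > 0:
            first_s = _apply_char_edits(rng, first_s, corruption.char_edit_rate)
            last_s = _apply_char_edits(rng, last_s, corruption.char_edit_rate)
        if corruption.drop_section_prob > 0 and rng.random() < corruption.drop_section_prob:
            sections[label] = None
            continue
        sections[label] = (first_s, last_s) if first_s.strip() and last_s.strip() else None
    return GenerationOutput(sections=sections, model_name="mock-oracle", run_index=run_index)


DEFAULT_HEADER_LEXICON: dict[SectionLabel, list[str]] = {
    SectionLabel.RCH: [
        "hpi",
        "history of present illness",
        "interval history",
        "recent history",
        "hx of present illness",
    ],
    SectionLabel.AP: [
        "a/p",
        "a&p",
        "assessment and plan",
        "assessment & plan",
        "impression and plan",
    ],
}


# non-target headers that terminate a section run (exam block, signature, ...)
DEFAULT_STOP_HEADERS: list[str] = [
    "physical exam",
    "review of systems",
    "signature",
]


def rule_based_generate(
    note: ClinicalNote,
    header_lexicon: Optional[dict[SectionLabel, list[str]]] = None,
    stop_headers: Optional[list[str]] = None,
    run_index: int = 0,
) -> GenerationOutput:
    """Header-lexicon baseline: first case-insensitive header match per label;
    the section runs to the next recognized header (of any label, or a
    stop header such as an exam block), or to the end of the note."""
    lexicon = header_lexicon if header_lexicon is not None else DEFAULT_HEADER_LEXICON
    stops = stop_headers if stop_headers is not None else DEFAULT_STOP_HEADERS
    for label in SectionLabel:
        if not lexicon.get(label):
            raise NotesectError(f"header lexicon for {label.value} is empty")
    tokens = tokenize_words(note.text)
    norm = [t.text.casefold() for t in tokens]

    def match_at(i: int, pattern: str) -> int:
        """Token count consumed if pattern (word seq, optional ':') starts at i, else 0."""
        pwords = pattern.split()
        m = len(pwords)
        if i + m > len(tokens):
            return 0
        for j, pw in enumerate(pwords):
            tok = norm[i + j]
            if j == m - 1:
                if tok not in (pw, pw + ":"):
                    return 0
            elif tok != pw:
                return 0
        return m

    hits: dict[SectionLabel, int] = {}
    boundaries: list[int] = []
    for i in range(len(tokens)):
        matched = False
        for label in SectionLabel:
            if any(match_at(i, p) for p in lexicon[label]):
                boundaries.append(i)
                hits.setdefault(label, i)
                matched = True
                break
        if not matched and any(match_at(i, p) for p in stops):
            boundaries.append(i)

    sections: dict[SectionLabel, Optional[Pair]] = {}
    for label in SectionLabel:
        if label not in hits:
            sections[label] = None
            continue
        start = hits[label]
        nxt = [b for b in boundaries if b > start]
        end = min(nxt) if nxt else len(tokens)
        run = [t.text for t in tokens[start:end]]
        sections[label] = (" ".join(run[:5]), " ".join(run[-5:]))
    return GenerationOutput(sections=sections, model_name="rule-header", run_index=run_index)


class ExternalBackendStub:
    """Placeholder adapter for a remote or local LLM inference service.

    Shares the backend contract but performs no inference; calling it
    raises.  Subclass and implement ``generate`` to integrate a real
    service (function-calling API, local inference server, ...).
    """

    def __init__(self, name: str):
        self.name = name

    def generate(self, note: ClinicalNote, run_index: int = 0) -> GenerationOutput:
        raise NotImplementedError(
            f"backend stub {self.name!r} has no inference engine attached"
        )


BackendFn = Callable[..., GenerationOutput]

BACKEND_REGISTRY: dict[str, str] = {
    "mock": "mock oracle over gold spans (requires annotated corpus)",
    "rule": "rule-based header lexicon baseline",
}


def generate_for_corpus(
    corpus: list[AnnotatedNote],
    backend: str = "mock",
    corruption: CorruptionConfig = CorruptionConfig(),
    run_index: int = 0,
) -> dict[str, GenerationOutput]:
    """Run a registered backend over a corpus; returns note_id → output."""
    outputs: dict[str, GenerationOutput] = {}
    for ann in corpus:
        if backend == "mock":
            outputs[ann.note.note_id] = mock_oracle_generate(ann, corruption, run_index)
        elif backend == "rule":
            outputs[ann.note.note_id] = rule_based_generate(ann.note, run_index=run_index)
        elif backend.startswith("stub:"):
            outputs[ann.note.note_id] = ExternalBackendStub(backend[5:]).generate(ann.note, run_index)
        else:
            raise NotesectError(f"unknown backend {backend!r}")
    return outputs
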