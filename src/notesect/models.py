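"""Core data types for clinical notes, section spans, and predictions.

Offsets are 0-based, half-open, and always refer to the *raw* note text:
any normalization (case folding, whitespace collapsing) used during fuzzy
matching is transient, so gold annotations survive write→read round trips
bit-exactly.  JSONL is the single interchange dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional


class NotesectError(Exception):
    """Base class for all package errors."""


class ParseError(NotesectError):
    """A JSONL line could not be parsed."""


class ValidationError(NotesectError):
    """A record violates a structural invariant."""


class ReferenceError_(NotesectError):
    """A record references an unknown note."""


class ProviderType(str, Enum):
    PHYSICIAN = "physician"
    NURSE_PRACTITIONER = "nurse_practitioner"
    PHYSICIAN_ASSISTANT = "physician_assistant"


class Group(str, Enum):
    BREAST = "breast"
    GI = "gi"
    NEURO = "neuro"
    EXTERNAL = "external"


class SectionLabel(str, Enum):
    """The two section labels: recent clinical history and assessment & plan."""

    RCH = "RCH"
    AP = "AP"


class PredictionStatus(str, Enum):
    MATCHED = "matched"
    NO_START_MATCH = "no_start_match"
    NO_END_MATCH = "no_end_match"
    SECTION_ABSENT = "section_absent"


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    text: str
    provider_type: ProviderType = ProviderType.PHYSICIAN
    group: Group = Group.BREAST


@dataclass(frozen=True)
class SectionSpan:
    """A labeled character interval [start_char, end_char) over a note."""

    label: SectionLabel
    start_char: int
    end_char: int

    def __post_init__(self) -> None:
        if self.start_char < 0 or self.end_char <= self.start_char:
            raise ValidationError(
                f"invalid span [{self.start_char}, {self.end_char}) for label {self.label.value}"
            )

    def validate_against(self, note: ClinicalNote) -> None:
        if self.end_char > len(note.text):
            raise ValidationError(
                f"span [{self.start_char}, {self.end_char}) out of bounds for "
                f"note {note.note_id!r} of length {len(note.text)}"
            )


@dataclass
class AnnotatedNote:
    note: ClinicalNote
    spans: dict[SectionLabel, SectionSpan] = field(default_factory=dict)
    annotator_id: str = ""

    def __post_init__(self) -> None:
        for label, span in self.spans.items():
            if span.label is not label:
                raise ValidationError(
                    f"span labeled {span.label.value} stored under key {label.value} "
                    f"in note {self.note.note_id!r}"
                )
            span.validate_against(self.note)


@dataclass(frozen=True)
class AnchoredPrediction:
    """A span recovered from generated boundary words by fuzzy anchoring.

    ``span`` is present iff ``status`` is ``matched``; the two scores are
    the normalized Levenshtein similarities of the start/end anchors.
    """

    label: SectionLabel
    status: PredictionStatus
    span: Optional[SectionSpan] = None
    start_score: Optional[float] = None
    end_score: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.span is not None) != (self.status is PredictionStatus.MATCHED):
            raise ValidationError(
                f"span present iff status=matched violated (status={self.status.value})"
            )


def slice_section(note: ClinicalNote, span: SectionSpan) -> str:
    """Return the section text ``note.text[start_char:end_char]``."""
    span.validate_against(note)
    return note.text[span.start_char : span.end_char]


# ---------------------------------------------------------------------------
# JSONL readers / writers
# ---------------------------------------------------------------------------

def _note_from_obj(obj: dict, lineno: int) -> AnnotatedNote:
    try:
        note = ClinicalNote(
            note_id=obj["note_id"],
            patient_id=obj["patient_id"],
            text=obj["text"],
            provider_type=ProviderType(obj.get("provider_type", "physician")),
            group=Group(obj.get("group", "breast")),
        )
        spans: dict[SectionLabel, SectionSpan] = {}
        for s in obj.get("spans", []):
            label = SectionLabel(s["label"])
            spans[label] = SectionSpan(label, int(s["start_char"]), int(s["end_char"]))
            if "text_check" in s:
                got = note.text[s["start_char"] : s["end_char"]]
                if got != s["text_check"]:
                    raise ValidationError(
                        f"span slice mismatch for note {note.note_id!r}, label {label.value}"
                    )
        return AnnotatedNote(note=note, spans=spans, annotator_id=obj.get("annotator_id", ""))
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"malformed record at line {lineno}: {exc}") from exc


def read_annotated_corpus(path: str | Path, dialect: str = "jsonl") -> list[AnnotatedNote]:
    """Read an annotated corpus from a JSONL file, validating every span."""
    if dialect != "jsonl":
        raise ValueError(f"unsupported dialect {dialect!r}")
    corpus: list[AnnotatedNote] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"malformed line {lineno}: {exc}") from exc
            corpus.append(_note_from_obj(obj, lineno))
    return corpus


def _annotated_to_obj(ann: AnnotatedNote) -> dict:
    return {
        "note_id": ann.note.note_id,
        "patient_id": ann.note.patient_id,
        "text": ann.note.text,
        "provider_type": ann.note.provider_type.value,
        "group": ann.note.group.value,
        "spans": [
            {"label": label.value, "start_char": s.start_char, "end_char": s.end_char}
            for label, s in sorted(ann.spans.items(), key=lambda kv: kv[0].value)
        ],
        "annotator_id": ann.annotator_id,
    }


def write_annotated_corpus(corpus: Iterable[AnnotatedNote], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in corpus:
            fh.write(json.dumps(_annotated_to_obj(ann), ensure_ascii=False) + "\n")


def write_predictions(
    predictions: Mapping[str, Mapping[SectionLabel, AnchoredPrediction]] | Iterable[tuple[str, AnchoredPrediction]],
    path: str | Path,
    known_note_ids: Optional[set[str]] = None,
) -> None:
    """Write predictions keyed by note_id to JSONL, one (note_id, label) per line.

    Field order is fixed so equal inputs produce byte-identical files.
    """
    if isinstance(predictions, Mapping):
        items = [
            (nid, pred)
            for nid, by_label in predictions.items()
            for _, pred in sorted(by_label.items(), key=lambda kv: kv[0].value)
        ]
    else:
        items = list(predictions)
    with open(path, "w", encoding="utf-8") as fh:
        for note_id, pred in items:
            if known_note_ids is not None and note_id not in known_note_ids:
                raise ReferenceError_(f"prediction references unknown note_id {note_id!r}")
            obj = {
                "note_id": note_id,
                "label": pred.label.value,
                "status": pred.status.value,
                "start_char": pred.span.start_char if pred.span else None,
                "end_char": pred.span.end_char if pred.span else None,
                "start_score": pred.start_score,
                "end_score": pred.end_score,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_predictions(path: str | Path) -> list[tuple[str, AnchoredPrediction]]:
    """Read back predictions written by :func:`write_predictions`."""
    out: list[tuple[str, AnchoredPrediction]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                label = SectionLabel(obj["label"])
                status = PredictionStatus(obj["status"])
                span = None
                if obj.get("start_char") is not None:
                    span = SectionSpan(label, obj["start_char"], obj["end_char"])
                pred = AnchoredPrediction(
                    label=label,
                    status=status,
                    span=span,
                    start_score=obj.get("start_score"),
                    end_score=obj.get("end_score"),
                )
            except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
                raise ParseError(f"malformed prediction at line {lineno}: {exc}") from exc
            out.append((obj["note_id"], pred))
    return out
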