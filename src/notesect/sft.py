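"""Supervised fine-tuning dataset preparation.

Annotated corpora become prompt/completion pairs: the prompt renders the
unified sectioning instruction over the note, and the completion names,
per label, the first five and last five words of the gold span (or an
absent marker).  The completion mirrors the backend output JSON so a model
trained on it natively emits the structure the anchorer consumes, and
every emitted target is verified at build time to re-anchor to its gold
span with score 1.0.

Training itself is out of scope; :class:`SFTConfig` records the
rank-stabilized LoRA hyperparameters so an external trainer reproduces
the reference setup (rank 16, alpha 16, 5 epochs, batch size 2, learning
rate 2e-4).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .anchoring import MatchPolicy, extract_span
from .backends import PromptSpec, build_prompt
from .models import (
    AnnotatedNote,
    NotesectError,
    PredictionStatus,
    SectionLabel,
    slice_section,
)


@dataclass(frozen=True)
class SFTExample:
    prompt: str
    completion: dict
    note_id: str
    patient_id: str


@dataclass(frozen=True)
class SFTConfig:
    lora_rank: int = 16
    lora_alpha: int = 16
    epochs: int = 5
    batch_size: int = 2
    learning_rate: float = 2e-4
    method_tag: str = "rsLoRA"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "SFTConfig":
        return cls(**json.loads(payload))


def build_sft_dataset(
    corpus: Sequence[AnnotatedNote],
    spec: PromptSpec = PromptSpec(),
    policy: MatchPolicy = MatchPolicy(),
) -> list[SFTExample]:
    """One training example per note, with build-time re-anchoring checks.

    A gold span whose boundary words fail to re-anchor exactly (score 1.0
    and the recovered span equal to gold) indicates a corrupt annotation
    and raises an integrity error naming the note.
    """
    examples: list[SFTExample] = []
    failures: list[str] = []
    for ann in corpus:
        sections: dict[str, dict | None] = {}
        for label in SectionLabel:
            gold = ann.spans.get(label)
            if gold is None:
                sections[label.value] = None
                continue
            words = slice_section(ann.note, gold).split()
            first = " ".join(words[:5])
            last = " ".join(words[-5:])
            pred = extract_span(ann.note, label, first, last, policy)
            if (
                pred.status is not PredictionStatus.MATCHED
                or pred.span != gold
                or pred.start_score != 1.0
                or pred.end_score != 1.0
            ):
                failures.append(f"{ann.note.note_id}/{label.value}")
                continue
            sections[label.value] = {"first": first, "last": last}
        prompt = build_prompt(spec, ann.note, list(SectionLabel))
        examples.append(
            SFTExample(
                prompt=prompt,
                completion={"sections": sections},
                note_id=ann.note.note_id,
                patient_id=ann.note.patient_id,
            )
        )
    if failures:
        raise NotesectError(
            "gold spans failed to re-anchor exactly: " + ", ".join(failures)
        )
    return examples


def patient_disjoint_split(
    corpus: Sequence[AnnotatedNote], test_fraction: float, seed: int
) -> tuple[list[AnnotatedNote], list[AnnotatedNote]]:
    """Split a corpus at patient granularity; train/test share no patient."""
    if not (0.0 < test_fraction < 1.0):
        raise NotesectError("test_fraction must lie strictly between 0 and 1")
    patients = sorted({ann.note.patient_id for ann in corpus})
    if len(patients) < 2:
        raise NotesectError("cannot split a corpus with fewer than 2 patients")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    n_test = min(len(patients) - 1, max(1, round(test_fraction * len(patients))))
    test_patients = set(order[:n_test])
    train = [ann for ann in corpus if ann.note.patient_id not in test_patients]
    test = [ann for ann in corpus if ann.note.patient_id in test_patients]
    return train, test


def write_sft_jsonl(examples: Sequence[SFTExample], path: str | Path) -> None:
    """Serialize examples to chat-style JSONL, byte-deterministically."""
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            obj = {
                "prompt": ex.prompt,
                "completion": ex.completion,
                "note_id": ex.note_id,
                "patient_id": ex.patient_id,
            }
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def read_sft_jsonl(path: str | Path) -> list[SFTExample]:
    out: list[SFTExample] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                SFTExample(
                    prompt=obj["prompt"],
                    completion=obj["completion"],
                    note_id=obj["note_id"],
                    patient_id=obj["patient_id"],
                )
            )
    return out
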