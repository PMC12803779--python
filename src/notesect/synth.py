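"""Deterministic generator of semi-structured oncology-style progress notes.

Real progress-note corpora in this domain are protected health information,
so every downstream stage is exercised on synthetic notes with gold spans
recorded at assembly time.  Defaults mirror the reference corpus statistics:
86.6% of notes carry a recent-clinical-history section, 87.2% an
assessment-and-plan section, and note length averages 1814 whitespace
tokens.  Token counts are drawn from a log-normal (note lengths are
right-skewed; only the mean and its confidence interval are known, not the
distribution).  All filler text is fabricated clinical-sounding vocabulary,
never real patient data.

Section headers are drawn from weighted variant pools ("HPI:", "Interval
History:", "Assessment and Plan:", ...) and are INCLUDED in the gold span:
annotated sections are anchored at the section opening, and one consistent
convention keeps the overlap metrics interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import (
    AnnotatedNote,
    ClinicalNote,
    Group,
    NotesectError,
    ProviderType,
    SectionLabel,
    SectionSpan,
)

DEFAULT_RCH_HEADERS: dict[str, float] = {
    "HPI:": 3.0,
    "History of Present Illness:": 3.0,
    "Interval History:": 2.0,
    "Recent History:": 1.0,
    "Hx of Present Illness:": 1.0,
}

DEFAULT_AP_HEADERS: dict[str, float] = {
    "A/P:": 2.0,
    "Assessment and Plan:": 3.0,
    "Assessment & Plan:": 2.0,
    "Impression and Plan:": 2.0,
    "A&P:": 1.0,
}

# Fabricated clinical-sounding filler vocabulary; disjoint pools keep
# accidental 5-gram collisions between blocks vanishingly unlikely.
_NARRATIVE = (
    "patient reports denies endorses ongoing intermittent mild moderate severe "
    "fatigue nausea vomiting anorexia dyspnea cough pain numbness tingling "
    "headache dizziness fevers chills sweats weight appetite stable improved "
    "worsened since last visit cycle infusion tolerated without significant "
    "complications symptoms managed supportive care oral intake adequate "
    "bowel habits unchanged sleep quality fair energy levels diminished "
    "ambulating independently performance status preserved reviewed today"
).split()

_EXAM = (
    "vitals afebrile normotensive pulse regular lungs clear auscultation "
    "bilaterally abdomen soft nontender nondistended extremities warm "
    "edema absent neuro grossly intact alert oriented mucosa moist skin "
    "unremarkable lymph nodes palpable cardiac rhythm murmurs rubs gallops "
    "respiratory effort comfortable oxygen saturation room air"
).split()

_PLAN = (
    "continue current regimen monitor counts repeat imaging scheduled labs "
    "weekly follow consider dose reduction toxicity supportive antiemetics "
    "prescribed hydration encouraged return clinic weeks restaging scans "
    "discussed goals therapy risks benefits documented consent pending "
    "referral palliative nutrition consult ordered surveillance maintained"
).split()

_ADMIN = (
    "seen evaluated clinic today accompanied chart reviewed medications "
    "reconciled allergies confirmed history obtained records requested "
    "prior outside documentation scanned insurance authorization pending "
    "electronically signed attending addendum dictated transcribed"
).split()


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_notes: int = 100
    p_rch: float = 0.866
    p_ap: float = 0.872
    mean_tokens: float = 1814.0
    sigma_log: float = 0.45
    max_tokens: int = 6000  # practical note-length cap; keeps prompts inside an 8192-token window
    header_variant_weights: dict[SectionLabel, dict[str, float]] = field(
        default_factory=lambda: {
            SectionLabel.RCH: dict(DEFAULT_RCH_HEADERS),
            SectionLabel.AP: dict(DEFAULT_AP_HEADERS),
        }
    )
    noise_level: float = 0.2

    def __post_init__(self) -> None:
        if self.n_notes <= 0:
            raise NotesectError("n_notes must be positive")
        for name, p in (("p_rch", self.p_rch), ("p_ap", self.p_ap)):
            if not (0.0 <= p <= 1.0):
                raise NotesectError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.noise_level <= 1.0):
            raise NotesectError("noise_level must lie in [0, 1]")
        if self.mean_tokens <= 0:
            raise NotesectError("mean_tokens must be positive")
        for label, weights in self.header_variant_weights.items():
            if not weights or any(w < 0 for w in weights.values()) or not any(weights.values()):
                raise NotesectError(f"header weights for {label.value} must be non-negative, not all zero")


def _sentences(rng: np.random.Generator, vocab: list[str], n_words: int) -> str:
    """Build ~n_words of filler text as newline-separated sentence lines."""
    if n_words <= 0:
        n_words = 1
    words = rng.choice(vocab, size=n_words)
    lines: list[str] = []
    i = 0
    while i < n_words:
        ln = int(rng.integers(6, 14))
        chunk = words[i : i + ln]
        lines.append(" ".join(chunk).capitalize() + ".")
        i += ln
    return "\n".join(lines)


def _closing_sentence(rng: np.random.Generator, label: SectionLabel) -> str:
    """Dated closing line, as clinicians write; the embedded date and count
    also make each section's final 5-gram effectively unique in the note."""
    m, d, y = int(rng.integers(1, 13)), int(rng.integers(1, 29)), int(rng.integers(2018, 2026))
    k = int(rng.integers(1, 40))
    if label is SectionLabel.RCH:
        return f"Symptoms last reviewed at visit {k} on {m:02d}/{d:02d}/{y}."
    return f"Return to clinic on {m:02d}/{d:02d}/{y} to begin cycle {k}."


def _pick_header(rng: np.random.Generator, weights: dict[str, float], noise: float) -> str:
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    header = str(rng.choice(names, p=w / w.sum()))
    if noise > 0 and rng.random() < noise:
        style = rng.integers(0, 3)
        if style == 0:
            header = header.upper()
        elif style == 1 and header.endswith(":"):
            header = header[:-1]
        else:
            header = header.lower()
    return header


def _one_note(rng: np.random.Generator, cfg: GeneratorConfig, note_id: str, patient_id: str) -> AnnotatedNote:
    mu = math.log(cfg.mean_tokens) - cfg.sigma_log**2 / 2
    total = min(cfg.max_tokens, max(40, int(rng.lognormal(mu, cfg.sigma_log))))

    has_rch = rng.random() < cfg.p_rch
    has_ap = rng.random() < cfg.p_ap

    # crude token budget per block
    n_admin = max(5, int(total * 0.08))
    n_sig = max(3, int(total * 0.04))
    n_exam = max(8, int(total * 0.22))
    remaining = max(10, total - n_admin - n_sig - n_exam)
    n_rch = int(remaining * 0.45) if has_rch else 0
    n_ap = remaining - n_rch if has_ap else 0
    if not has_rch and not has_ap:
        n_exam += remaining

    parts: list[str] = []
    spans: dict[SectionLabel, SectionSpan] = {}
    cursor = 0

    def append(block: str) -> None:
        nonlocal cursor
        parts.append(block)
        cursor += len(block)

    append(_sentences(rng, _ADMIN, n_admin) + "\n\n")
    exam_header = "Physical Exam:\n"
    sig_header = "Signature:\n"
    if has_rch:
        header = _pick_header(rng, cfg.header_variant_weights[SectionLabel.RCH], cfg.noise_level)
        body = _sentences(rng, _NARRATIVE, max(6, n_rch))
        block = header + "\n" + body + "\n" + _closing_sentence(rng, SectionLabel.RCH)
        spans[SectionLabel.RCH] = SectionSpan(SectionLabel.RCH, cursor, cursor + len(block))
        append(block + "\n\n")
    append(exam_header + _sentences(rng, _EXAM, n_exam) + "\n\n")
    if has_ap:
        header = _pick_header(rng, cfg.header_variant_weights[SectionLabel.AP], cfg.noise_level)
        body = _sentences(rng, _PLAN, max(6, n_ap))
        block = header + "\n" + body + "\n" + _closing_sentence(rng, SectionLabel.AP)
        spans[SectionLabel.AP] = SectionSpan(SectionLabel.AP, cursor, cursor + len(block))
        append(block + "\n\n")
    append(sig_header + _sentences(rng, _ADMIN, n_sig))

    provider = ProviderType(
        str(rng.choice(
            ["physician", "nurse_practitioner", "physician_assistant"],
            p=[0.617, 0.297, 0.086],
        ))
    )
    group = Group(str(rng.choice(["breast", "gi", "neuro"], p=[0.425, 0.405, 0.17])))
    note = ClinicalNote(
        note_id=note_id,
        patient_id=patient_id,
        text="".join(parts),
        provider_type=provider,
        group=group,
    )
    return AnnotatedNote(note=note, spans=spans, annotator_id="synthetic")


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedNote]:
    """Generate a corpus of annotated notes; identical config → identical corpus.

    Notes are assigned to patients at roughly the reference corpus ratio of
    ~2.6 notes per patient.
    """
    rng = np.random.default_rng(config.seed)
    n_patients = max(1, round(config.n_notes / 2.65))
    patient_of_note = rng.integers(0, n_patients, size=config.n_notes)
    corpus = [
        _one_note(rng, config, f"note{i:05d}", f"pt{patient_of_note[i]:05d}")
        for i in range(config.n_notes)
    ]
    return corpus


def corpus_summary(corpus: list[AnnotatedNote]) -> dict:
    """Descriptive statistics of a corpus: counts, provider mix, token length
    with a normal-approximation 95% CI, and per-label section presence rates."""
    if not corpus:
        raise NotesectError("empty corpus")
    n = len(corpus)
    tokens = np.array([len(ann.note.text.split()) for ann in corpus], dtype=float)
    mean = float(tokens.mean())
    sem = float(tokens.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    providers: dict[str, float] = {p.value: 0.0 for p in ProviderType}
    for ann in corpus:
        providers[ann.note.provider_type.value] += 1
    providers = {k: v / n for k, v in providers.items()}
    return {
        "n_notes": n,
        "n_unique_patients": len({ann.note.patient_id for ann in corpus}),
        "provider_mix": providers,
        "mean_tokens": mean,
        "tokens_ci95": (mean - 1.96 * sem, mean + 1.96 * sem),
        "presence": {
            label.value: sum(label in ann.spans for ann in corpus) / n for label in SectionLabel
        },
    }
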