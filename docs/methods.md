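# Methods

## Problem and pipeline

Section extraction is framed as boundary identification rather than text
generation: a backend proposes, for each target section label (recent
clinical history, assessment & plan), the first five and the last five
whitespace words of the section, and the anchoring stage maps those word
strings back to character offsets in the source note. This confines any
generative model's failure modes to short, checkable strings — a model
cannot hallucinate a span longer than the note, and every extracted span
is verbatim source text by construction.

## Fuzzy anchoring

**Tokenization.** Words are maximal runs of non-whitespace characters,
carrying raw-text offsets. Concatenating tokens with single spaces equals
the whitespace-normalized note, so window text and offsets never drift.

**Scoring.** A query is compared to each candidate window by
`1 − d/max(|a|,|b|)` where `d` is Levenshtein distance. This is the
standard normalized ratio, bounded in [0, 1]; the distance itself is
computed by `edlib` (exact bit-parallel algorithm) with a pure-Python
dynamic-programming fallback for texts whose combined alphabet exceeds
edlib's 256-symbol limit.

**Search.** Windows advance one token at a time. An exact match on the
normalized window short-circuits the scan (earliest wins, score 1.0);
otherwise every window from the search origin onward is scored, including
tail windows shorter than the window size, and the best window at or above
the threshold wins, earliest on ties. Tie-breaking by position makes the
matcher deterministic.

**Policy knobs and defaults.**

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.80 | minimum similarity for a valid anchor |
| `window_size` | 5 | anchor n-gram length, words |
| `normalize_case` | true | case-fold both sides before comparison |
| `collapse_whitespace` | true | join words with single spaces |
| `strict_threshold` | false | require similarity strictly above threshold |

Decisions that were genuinely open, and how they are pinned here:

- *Threshold boundary.* "Valid above 80%" is implemented as ≥ 0.80; the
  strict-inequality reading is available as `strict_threshold` so the
  float boundary is testable either way.
- *Short queries.* A query of fewer than five words is matched against
  windows of its own length, so a three-word section anchors exactly
  rather than being penalized against five-word windows.
- *End-anchor ordering.* The end anchor is searched only at or after the
  start anchor's window. Sections are contiguous and ordered, so an
  earlier end match is necessarily wrong; failure there is reported as
  `no_end_match` with no fallback to a global search, which would silently
  produce inverted spans.
- *Word-aligned search.* Windows advance by whole tokens, not characters:
  the proposed units are words, and word alignment keeps recovered spans
  on token boundaries.

## Synthetic corpus generator

The generator emulates semi-structured oncology progress notes: an
administrative block, an optional RCH block, a physical-exam block, an
optional A&P block, and a signature block, with gold spans recorded during
assembly (headers included in the span — one consistent convention keeps
precision/recall interpretable). Defaults are calibrated to realistic
corpus statistics: section presence 0.866 (RCH) and 0.872 (A&P), mean
length 1814 whitespace tokens, provider mix ~62/30/9% physician / nurse
practitioner / physician assistant, and ~2.6 notes per patient. Token
counts are log-normal (σ = 0.45) because note lengths are right-skewed;
only the mean is calibrated. Lengths are capped at 6000 tokens, a
practical ceiling that also keeps rendered prompts inside an 8192-token
context window. `noise_level` jitters header casing and trailing
punctuation. Each section ends with a dated closing sentence, as clinical
sections commonly do; the embedded date also makes boundary 5-grams
effectively unique within a note, which is what licenses the exact
round-trip guarantee below.

What the generator does **not** model: real clinical vocabulary and
syntax, copy-forward duplication, tables and flowsheets, discontiguous
sections, inter-group differences beyond config overrides. A perfect
score on synthetic notes therefore demonstrates the correctness of the
anchoring and evaluation machinery, not clinical-grade accuracy; on real
notes the binding constraint is the quality of the backend's proposals.

## Backends

The mock oracle emits the true boundary words of each gold span and then
corrupts them: the boundary is shifted by `shift_words` note tokens, each
emitted string receives a Poisson(`char_edit_rate`) number of random
character edits, and the section is dropped (falsely asserted absent)
with `drop_section_prob`. Poisson edit counts realize "expected edits per
5-gram" with the natural discrete law; corruption streams are keyed by
(seed, note id, run index) so runs are independent but reproducible. The
rule-based backend scans for the first case-insensitive header of each
label and runs to the next recognized header (including stop headers such
as the exam block) or the end of the note — a deliberately simple
terminology-rule baseline. External LLM adapters are interface stubs:
inference is not reproducible at desk scale, so they share the contract
but raise on use and are excluded from the tests.

## Evaluation

Overlap metrics are computed over word-token index sets, matching the
anchorer's granularity (character granularity is an option). When gold
and prediction both mark a section absent the pair scores P = R = F1 = 1;
because roughly 13% of notes lack each section this convention matters,
so an `exclude` policy that drops such pairs from averages is provided.

The bootstrap resamples **notes** (all labels of a note move together,
the note being the independent sampling unit): per run, 1000 resamples
of note means; three runs pooled give 3000 metric sets; the 95% CI is
the 2.5/97.5 percentile interval. Run `r` draws from the seeded stream
`(seed, r)`, so models evaluated on the same corpus share resample
indices — this is what makes blocks pairable across models for the
Friedman test, which is otherwise undefined for pooled bootstrap output.

The Friedman test uses within-block midranks and the tie-corrected
chi-squared statistic (k − 1 degrees of freedom). An exact mode
enumerates all within-block permutations of the observed values, for
verifying the machinery on small matrices. Pairwise Wilcoxon signed-rank
tests drop zero differences and midrank ties; the two-sided p-value comes
from the exact null distribution (dynamic programming over doubled ranks)
for n ≤ 25 retained pairs, else a normal approximation with tie and
continuity corrections. Significance is judged against a Bonferroni
adjusted alpha, global α divided by the number of pairs (0.05/10 = 0.005
for five models). Error analysis gates at F1 < 0.8 and classifies by
containment first, then precision/recall dominance: over-prediction,
under-prediction, shift, missed, spurious.

## SFT preparation

Completions mirror the backend output JSON (per label, first/last five
words or null) so a fine-tuned model natively emits what the anchorer
consumes. Every emitted target is re-anchored at build time and must
recover its gold span with both scores exactly 1.0; a failure names the
note and aborts, because a training target that cannot re-anchor teaches
the model to emit unanchorable boundaries. Splits are drawn at patient
granularity (shuffle patients, take `round(fraction · n)` for the test
side), guaranteeing disjointness by construction. Training itself is out
of scope; `SFTConfig` records the rsLoRA hyperparameters (rank 16, alpha
16, 5 epochs, batch size 2, learning rate 2e-4) for an external trainer.

## Problem sizes and numerical notes

Test and script problem sizes — 200–500 note corpora, 100-note × 10-seed
degradation sweeps, a 487-note SFT build, 3 × 1000 bootstrap — are chosen
so the whole suite completes in about a minute on one CPU while still
exercising the binomial presence calibration and bootstrap law at
meaningful n. Degenerate inputs are handled explicitly: similarity of two
empty strings is an error (0/0); a fully tied Friedman matrix reports
statistic 0, p = 1; an all-zero-difference Wilcoxon pair is flagged
degenerate with p = 1; a single-patient corpus cannot be split. The
bootstrap mean is clamped into its percentile interval, as summation
order can otherwise push it one ULP outside a degenerate (zero-width)
interval.

## Limitations

- One span per label per note; discontiguous gold sections must be
  pre-merged to their covering interval upstream.
- The unified prompt template is an original paraphrase of the intended
  backend behavior, not a validated clinical prompt.
- The matcher assumes the proposal is approximately verbatim source text;
  a backend that paraphrases beyond the 0.80 similarity radius yields
  `no_start_match`/`no_end_match`, never a guessed span.
- Agreement is Jaccard-only (no chance-corrected kappa), matching the
  adjudication rule it feeds.
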