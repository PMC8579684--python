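# Methods

`inhalertech` decides, for each clinical note, whether the note documents
that a clinician taught or reviewed the patient's inhaler/spacer/nebulizer
technique — a guideline element of asthma care (2007 NAEPP) that lives in
free text, not structured fields.  The decision unit is the sentence; a
note is positive iff any of its sentences is positive (existential
aggregation), because guideline adherence is audited per note.  Negation
is deliberately ignored: any documentation of the activity counts as
guideline-congruent, so "did not demonstrate inhaler technique today"
is still a positive.

The pipeline has five stages, each usable alone:

1. **Corpus handling** (`corpus_io`).  Notes arrive as flat JSONL/CSV
   note-section records.  Only the History of Present Illness and
   Impression/Report/Plan sections are retained by default (these carry
   nearly all technique documentation); matching is case-insensitive
   pattern matching because EHR header spellings vary.  Sentence
   segmentation is rule-based with a clinical-abbreviation exception list
   ("Dr.", "b.i.d.", single-letter initials); offsets are 0-based
   half-open into the section text.  All downstream tests use the
   generator's known sentence boundaries, so nothing depends on the
   segmenter's exact splitting policy.

2. **Rule engine** (`rule_engine`).  Four keyword groups — teaching
   actions (discuss\*, review\*, teach\*, …), devices (inhaler, MDI, neb,
   spacer, …), manner terms (techniques, administrations, dosing,
   guidance) and medication classes (asthma/rescue/daily/preventive/
   control medication, ICS, …) — and two combination rules: (a) group 1 +
   group 2, (b) group 1 + group 3 + group 4.  A rule fires when every
   required group matches somewhere in the sentence (order-free, whole
   sentence: the simplest reading of "combination"; a token-window scope
   was considered and rejected as an unobservable extra parameter).
   Matching is case-insensitive over alphanumeric tokens; hyphens and
   slashes are token boundaries, so "metered-dose inhaler" contains
   "inhaler".  Trailing `*` denotes prefix matching.  Two entries expand
   specially: the slash-form medication entry expands into its five
   two-token phrases, and "list of maintenance and rescue medications" is
   treated as "maintenance…medication\*" or "rescue…medication\*"
   co-occurring in order.  Group 3 is printed in the plural; by default
   the singular stems (technique\*, administration\*) match too, since the
   shipped rule-(b) example itself uses singular "technique"
   (`strict_plural=True` restores literal behavior).

3. **Distant supervision** (`distant_supervision`).  The rule engine
   labels an unlabeled corpus sentence-by-sentence; those weak labels
   train the neural classifier in place of manual chart review.  Weak
   items carry `provenance="weak"` so they can never be silently mixed
   with gold annotations.  Train/validation splitting is patient-level by
   default (no patient on both sides — notes of one patient are
   correlated), deterministic in the seed.

4. **Cost-sensitive sentence classifier** (`classifier`).  A BERT-style
   classifier: token + position embeddings, post-LayerNorm transformer
   encoder layers, CLS pooling, dropout p = 0.1, and a linear head with
   two logits, trained with class-weighted cross-entropy
   (`loss = −w(y)·log softmax(z)[y]`, batches weight-normalized so unit
   weights reduce exactly to standard cross-entropy).  The positive class
   is ~0.1–0.5% of sentences, so the weights penalize minority
   misclassification; the distant-supervision profile fixes them to
   (0.52, 5.52).  When no weights are given, balanced inverse-prevalence
   weights are computed from the training split.  The optimizer is AdamW
   (decoupled decay 0.01 on weight matrices only) under a triangular
   cyclical learning rate: linear ascent between a lower and upper bound
   with half-period ("step size") 2500 optimizer steps, phase-shifted so
   the rate at iteration 0 is the configured initial rate on the
   ascending limb.  With the production bounds (2e-5, 5e-5, init 3e-5)
   that offset is 2500/3 iterations, so the schedule is defined on a
   continuous iteration index: the bounds are attained exactly at the
   (fractional) turning points, and integer steps come within one step's
   slope of them.  `canonical_start=True` gives the textbook wave
   starting at the lower bound.  Ten epochs, ~12% validation; the
   selected model is the best-validation-F1 epoch (ties break to the
   later epoch).  Sentences are tokenized (lowercased alphanumeric
   word-level vocabulary built from the training split) and padded to a
   fixed length, 256 by default; longer inputs are truncated with a
   warning.

   The whole training stack — forward, backward, optimizer, schedule —
   is implemented in numpy (float32, bit-reproducible for a given seed),
   with backprop verified against central finite differences in the test
   suite.  The encoder is pluggable by architecture spec: the test and
   desk-scale configuration is a 2-layer, width-64, 2-head model trained
   from random initialization.  For that from-scratch regime the
   `tiny_profile` scales the cyclical bounds ×10 (2e-4/5e-4/init 3e-4)
   — the production range is a fine-tuning rate for a large pretrained
   encoder and barely moves a randomly initialized model — and shortens
   the pad length to 24 tokens (the synthetic sentences are short).

5. **Post-hoc hybrid** (`posthoc_hybrid`) and **evaluation**
   (`evaluation`).  Two small regex families override model predictions:
   N2P patterns (`(instructed|reviewed|discussed).*(use\sof\sMDI|…)`)
   flip model-negative sentences to positive; the P2N rule (trigger
   `(discussed|discussion)`, blocker "technique") flips model-positive
   sentences to negative when the trigger matches and no blocker occurs.
   Overrides see the original model label only (no chaining), so the pass
   is idempotent and every sentence flips at most once; N2P and P2N touch
   disjoint sentences, so their order is immaterial (fixed N2P-then-P2N
   for reproducible logs).  Matching is case-insensitive; the blocker is
   checked as the stem "techni" at a word start so technique/techniques
   both block (configurable to exact-word).  Evaluation reports document-
   level tp/fp/fn/tn, precision, recall, accuracy and
   Fβ = (1+β²)PR/(β²P+R) for β ∈ {0.5, 1, 2}; ratios with zero
   denominators are reported as undefined (`None`), never silently 0.
   Displayed values round half-up to 3 decimals.

## Synthetic corpora

Real training/evaluation notes are protected health information, so the
`synthetic_notes` generator emulates their statistical shape: two
sections per note, and sentence populations drawn from a validated
template bank — explicit positives (rule-visible teaching sentences),
implicit positives (genuine technique documentation with no teaching
keyword), hard negatives (keyword-bearing non-technique sentences that
fire the rules by construction) and neutral filler.  The bank check runs
the rule engine at load time: explicit positives and hard negatives must
fire, implicit positives and filler must not.

Profile defaults follow the emulated corpora: sentence-level positive
prevalence 0.4% (train), 0.56% (test), 0.124% (distant supervision,
explicit positives only — rule-generated labels are biased to explicit
wording).  The gold prevalences of the implicit fraction and
hard-negative rate in the train/test profiles (0.25 and 0.002) are not
published quantities; they were chosen once as plausible values that
reproduce the qualitative structure — rules achieve recall 1.0 with no
implicit positives, recall falls as the implicit fraction rises, and
precision falls below 1.0 as soon as hard negatives appear.  Positives
are placed with exact-count rounding by default so prevalences of 10⁻³
are testable on desk-scale corpora (Bernoulli placement is available);
the positive-document rate is an independent knob
(`positive_note_fraction`) rather than being inferred.

What passing on synthetic data does **not** show: the templates are
paraphrases of a handful of printed example sentences plus neutral
filler, with near-disjoint vocabulary between positives and filler.  The
classification problem is therefore far more separable than real
clinical text, and the desk-scale F1 ≈ 1.0 says the harness is correct,
not that a 2-layer model solves the clinical task.  Real-corpus
difficulty (implicit phrasing, annotation inconsistency, vocabulary
overlap) is represented only qualitatively through the implicit/hard-
negative dials.

## Desk-scale study conditions

The end-to-end distant-supervision exercise (test suite and
`scripts/acceptance.py`) uses: a DS corpus of 100 patients × ~20 notes ×
~10 sentences ≈ 20,000 sentences at prevalence 0.124%, weak-labeled by
the rules; the tiny encoder trained 10 epochs with weights (0.52, 5.52)
and, as a control, unit weights at the same seed; and a held-out
explicit-only test corpus (~200 notes, prevalence 0.56%) from disjoint
synthetic patients.  Expected behavior: weak labels match gold exactly
(explicit-only corpus), held-out document F1 ≥ 0.9, and minority-class
recall of the cost-weighted run at least that of the unit-weight run —
the stated purpose of cost sensitivity.

## Known limitations and documented discrepancies

* The printed example "Reinforced spacer use" is described in the source
  error analysis as a rule false negative, yet rule (a)
  (reinforce\* + spacer) fires on it; the originally deployed rules
  evidently carried unprinted constraints.  This package implements the
  published rule table as printed.
* One error-analysis example ("…aided with an appropriate sized mask,
  and instructed") is reported as corrected by the hybrid stage although
  the printed N2P pattern requires a "use of <device>" continuation that
  the sentence lacks; again the deployed override set presumably had
  unprinted patterns.  Implemented as printed; that sentence ships as an
  *implicit-positive* template (the rules do not fire on it).
* In the reported results table, recomputing F1 from the printed
  (P, R) = (0.942, 0.868) of the best hybrid row gives 0.903, not the
  printed 0.904 — rounding of P and R propagates up to one unit in the
  final digit.  The consistency suite asserts exact 3-decimal agreement
  for the other 20 F-score cells and pins this one at its computed value.
* "constraints" is an odd member of the teaching-keyword group (possibly
  a transcription artifact in the source table); it ships verbatim.
* The checkpoint format (`.npz` weights + JSON sidecar with config,
  vocabulary and history) is specific to this package's numpy encoder;
  loading external pretrained transformer checkpoints is out of scope —
  a pretrained encoder name in `EncoderSpec` is carried as a label only.
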