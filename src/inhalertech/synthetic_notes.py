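"""Synthetic clinical-note corpora with controlled label structure.

The real study corpora are protected health information, so every stage
of the pipeline is exercised on generated notes that copy their
*statistical* shape: two retained sections per note (History of Present
Illness; Impression/Report/Plan), a sentence-level positive prevalence of
roughly 0.4% (train), 0.56% (test) or 0.124% (distant-supervision
corpus), and three sentence populations besides neutral filler:

* **explicit positives** — teaching/review sentences the keyword rules
  catch ("Discussed correct inhaler technique.");
* **implicit positives** — genuine technique documentation with no
  teaching keyword ("Mom voices no concerns about his technique in using
  the inhaler."), invisible to rules by construction;
* **hard negatives** — keyword-bearing sentences that are *not* technique
  teaching ("Discussed 3rd neb treatment here versus one upon home."),
  rule false positives by construction.

Positives are placed with exact-count rounding by default so the tiny
prevalences are testable at desk scale; a Bernoulli mode is available.
Generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import ClinicalNote, Label, LabeledSentence, Provenance, Sentence
from .rule_engine import DEFAULT_RULES, KeywordLexicon, default_lexicon, evaluate_rules

SECTION_HPI = "History of Present Illness"
SECTION_IRP = "Impression/Report/Plan"

KIND_EXPLICIT = "explicit_positive"
KIND_IMPLICIT = "implicit_positive"
KIND_HARD_NEGATIVE = "hard_negative"
KIND_FILLER = "filler"


@dataclass
class SyntheticCorpusConfig:
    """Shape and label structure of a generated corpus.

    ``positive_sentence_rate`` profiles follow the emulated corpora:
    train 0.004, test 0.0056, distant supervision 0.00124.
    ``implicit_positive_fraction`` is the share of positives that rules
    cannot see; ``hard_negative_rate`` the share of all sentences that are
    keyword-bearing negatives.  ``positive_note_fraction``, when set,
    confines positive sentences to that fraction of notes (the
    document-level positive rate is otherwise an emergent quantity).
    """

    n_patients: int = 50
    notes_per_patient: tuple[int, int] = (1, 3)
    sentences_per_note: tuple[int, int] = (6, 12)
    positive_sentence_rate: float = 0.004
    implicit_positive_fraction: float = 0.0
    hard_negative_rate: float = 0.0
    positive_note_fraction: float | None = None
    exact_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.positive_sentence_rate,
            self.implicit_positive_fraction,
            self.hard_negative_rate,
        ):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")

    @classmethod
    def train_profile(cls, **overrides) -> "SyntheticCorpusConfig":
        """Manually-reviewed training corpus: 0.4% positive sentences."""
        overrides.setdefault("positive_sentence_rate", 0.004)
        overrides.setdefault("implicit_positive_fraction", 0.25)
        overrides.setdefault("hard_negative_rate", 0.002)
        return cls(**overrides)

    @classmethod
    def test_profile(cls, **overrides) -> "SyntheticCorpusConfig":
        """Held-out test corpus: 0.56% positive sentences."""
        overrides.setdefault("positive_sentence_rate", 0.0056)
        overrides.setdefault("implicit_positive_fraction", 0.25)
        overrides.setdefault("hard_negative_rate", 0.002)
        return cls(**overrides)

    @classmethod
    def distant_supervision_profile(cls, **overrides) -> "SyntheticCorpusConfig":
        """Large weakly-labeled corpus: 0.124% positives, explicit only
        (rule-generated labels are biased toward explicit wording)."""
        overrides.setdefault("positive_sentence_rate", 0.00124)
        overrides.setdefault("implicit_positive_fraction", 0.0)
        overrides.setdefault("hard_negative_rate", 0.0)
        return cls(**overrides)


@dataclass
class TemplateBank:
    """Sentence templates with their gold labels, plus slot fillers.

    ``validate`` enforces the construction invariants with the rule
    engine: explicit positives and hard negatives fire the rules, implicit
    positives and filler do not.
    """

    explicit_positive: list[str]
    implicit_positive: list[str]
    hard_negative: list[str]
    filler: list[str]
    slot_fillers: dict[str, list[str]] = field(default_factory=dict)

    def instantiate(self, template: str, rng: np.random.Generator) -> str:
        out = template
        for slot, values in self.slot_fillers.items():
            while "{" + slot + "}" in out:
                out = out.replace(
                    "{" + slot + "}", values[int(rng.integers(len(values)))], 1
                )
        return out

    def all_instances(self, templates: Sequence[str]) -> list[str]:
        """Every template with every slot filled by its first value
        (sufficient for rule-behavior validation: slot fillers carry no
        lexicon keywords)."""
        out = []
        for t in templates:
            for slot, values in self.slot_fillers.items():
                t = t.replace("{" + slot + "}", values[0])
            out.append(t)
        return out

    def validate(self, lexicon: KeywordLexicon | None = None) -> None:
        lexicon = lexicon or default_lexicon()
        for t in self.all_instances(self.explicit_positive):
            if not evaluate_rules(t, lexicon, DEFAULT_RULES).matched:
                raise ValueError(f"explicit positive template does not fire rules: {t!r}")
        for t in self.all_instances(self.hard_negative):
            if not evaluate_rules(t, lexicon, DEFAULT_RULES).matched:
                raise ValueError(f"hard negative template does not fire rules: {t!r}")
        for t in self.all_instances(self.implicit_positive):
            if evaluate_rules(t, lexicon, DEFAULT_RULES).matched:
                raise ValueError(f"implicit positive template fires rules: {t!r}")
        for t in self.all_instances(self.filler):
            if evaluate_rules(t, lexicon, DEFAULT_RULES).matched:
                raise ValueError(f"filler template fires rules: {t!r}")


def default_bank() -> TemplateBank:
    bank = TemplateBank(
        explicit_positive=[
            "Discussed correct inhaler technique.",
            "Reviewed inhaler use with {name} today.",
            "{name} received asthma education and instruction in appropriate metered-dose inhaler technique.",
            "Demonstrated proper spacer technique for {name}.",
            "Checked MDI technique and reinforced each step.",
            "We taught daily medication technique at today's visit.",
            "Explained how to use the nebulizer with a mask.",
            "Reviewed dosing guidance for his asthma medication.",
            "Educated {name} on proper use of the optichamber.",
            "Observed {name} demonstrate inhaler technique in clinic.",
        ],
        implicit_positive=[
            "Mom voices no concerns about his technique in using the inhaler.",
            "{name} is comfortable with her spacer technique.",
            "Our nurse went in before me and watched his technique and compliance.",
            "I did some training today regarding the use of {med} with a spacer.",
            "{name} was aided with an appropriate sized mask, and instructed.",
        ],
        hard_negative=[
            "Discussed 3rd neb treatment here versus one upon home.",
            "We reviewed her medications and discussed labeling the {med} with a green sticker for a daily inhaler.",
            "Reviewed refill history for the inhaler at the front desk.",
            "Discussed insurance coverage for the nebulizer machine.",
        ],
        filler=[
            "{name} is doing well overall.",
            "Follow up in {months} months.",
            "Lungs clear to auscultation bilaterally.",
            "No fever or night cough reported.",
            "{med} refilled at the current dose.",
            "Symptoms have improved since the last visit.",
            "Mother reports good adherence at home.",
            "Continue the current treatment plan.",
            "Weight and height are tracking appropriately.",
            "No emergency department visits since the last appointment.",
            "Triggers include pollen and cold air.",
            "Sleep is undisturbed most nights.",
            "Peak flow readings are stable.",
            "Immunizations are up to date.",
            "School attendance has been regular.",
        ],
        slot_fillers={
            "name": ["Alex", "Jordan", "Sam", "Riley", "Casey", "Morgan"],
            "med": ["Flovent", "Pulmicort", "Albuterol", "Singulair"],
            "months": ["2", "3", "6"],
        },
    )
    bank.validate()
    return bank


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its gold labels and sentence kinds."""

    notes: list[ClinicalNote]
    gold_sentences: list[LabeledSentence]
    gold_documents: dict[str, Label]
    kinds: dict[tuple[str, int], str]
    config: SyntheticCorpusConfig


def _count(rate: float, n: int, exact: bool, rng: np.random.Generator) -> int:
    return round(rate * n) if exact else int(rng.binomial(n, rate))


def generate_corpus(
    config: SyntheticCorpusConfig, bank: TemplateBank | None = None
) -> SyntheticCorpus:
    """Generate notes, gold sentence labels and gold document labels.

    Positive and hard-negative sentences are placed uniformly at random
    over all sentence slots with exact-count rounding (default).  Each
    note's sentences are split between the two target sections.  Document
    gold is the OR of sentence gold.  Byte-identical output for a given
    seed.
    """
    bank = bank or default_bank()
    rng = np.random.default_rng(config.seed)

    # lay out slots: (patient, note, n_sentences)
    layout: list[tuple[str, str, int]] = []
    for pi in range(config.n_patients):
        patient_id = f"p{pi:04d}"
        lo, hi = config.notes_per_patient
        for ni in range(int(rng.integers(lo, hi + 1))):
            slo, shi = config.sentences_per_note
            layout.append(
                (patient_id, f"{patient_id}-n{ni:02d}", int(rng.integers(slo, shi + 1)))
            )
    total = sum(n for _, _, n in layout)
    n_pos = _count(config.positive_sentence_rate, total, config.exact_counts, rng)
    n_implicit = round(config.implicit_positive_fraction * n_pos)
    n_explicit = n_pos - n_implicit
    n_hard = _count(config.hard_negative_rate, total, config.exact_counts, rng)
    if n_pos + n_hard > total:
        raise ValueError(
            f"infeasible config: {n_pos} positives + {n_hard} hard negatives "
            f"exceed {total} sentence slots"
        )

    # global slot ids -> kinds
    if config.positive_note_fraction is not None:
        n_notes = len(layout)
        n_pos_notes = max(1, round(config.positive_note_fraction * n_notes)) if n_pos else 0
        chosen = set(rng.choice(n_notes, size=n_pos_notes, replace=False).tolist())
        eligible = []
        offset = 0
        for i, (_, _, n) in enumerate(layout):
            if i in chosen:
                eligible.extend(range(offset, offset + n))
            offset += n
        if n_pos > len(eligible):
            raise ValueError(
                "infeasible config: positive_note_fraction leaves too few slots"
            )
        pos_slots = rng.choice(len(eligible), size=n_pos, replace=False)
        pos_ids = {int(eligible[i]) for i in pos_slots}
    else:
        pos_ids = set(rng.choice(total, size=n_pos, replace=False).tolist()) if n_pos else set()
    pos_list = sorted(pos_ids)
    rng.shuffle(pos_list)
    explicit_ids = set(pos_list[:n_explicit])
    remaining = np.array(sorted(set(range(total)) - pos_ids), dtype=int)
    hard_ids = (
        set(rng.choice(remaining, size=n_hard, replace=False).tolist())
        if n_hard
        else set()
    )

    notes: list[ClinicalNote] = []
    gold_sentences: list[LabeledSentence] = []
    gold_documents: dict[str, Label] = {}
    kinds: dict[tuple[str, int], str] = {}
    slot = 0
    for patient_id, note_id, n_sent in layout:
        texts: list[str] = []
        sent_meta: list[tuple[str, Label]] = []
        for _ in range(n_sent):
            if slot in pos_ids:
                kind = KIND_EXPLICIT if slot in explicit_ids else KIND_IMPLICIT
                pool = (
                    bank.explicit_positive
                    if kind == KIND_EXPLICIT
                    else bank.implicit_positive
                )
                label = Label.PRESENT
            elif slot in hard_ids:
                kind, pool, label = KIND_HARD_NEGATIVE, bank.hard_negative, Label.ABSENT
            else:
                kind, pool, label = KIND_FILLER, bank.filler, Label.ABSENT
            template = pool[int(rng.integers(len(pool)))]
            texts.append(bank.instantiate(template, rng))
            sent_meta.append((kind, label))
            slot += 1

        n_hpi = (n_sent + 1) // 2
        sections = []
        idx = 0
        for section_name, chunk in (
            (SECTION_HPI, texts[:n_hpi]),
            (SECTION_IRP, texts[n_hpi:]),
        ):
            if not chunk and n_sent:
                sections.append((section_name, ""))
                continue
            section_text = " ".join(chunk)
            offset = 0
            for t in chunk:
                a = section_text.index(t, offset)
                b = a + len(t)
                offset = b
                kind, label = sent_meta[idx]
                sent = Sentence(
                    note_id=note_id,
                    section_name=section_name,
                    sentence_index=idx,
                    text=t,
                    char_span=(a, b),
                    patient_id=patient_id,
                )
                gold_sentences.append(
                    LabeledSentence.from_sentence(sent, label, Provenance.GOLD)
                )
                kinds[(note_id, idx)] = kind
                idx += 1
            sections.append((section_name, section_text))
        notes.append(ClinicalNote(note_id, patient_id, sections))
        gold_documents[note_id] = (
            Label.PRESENT
            if any(lbl is Label.PRESENT for _, lbl in sent_meta)
            else Label.ABSENT
        )
    return SyntheticCorpus(notes, gold_sentences, gold_documents, kinds, config)


def corpus_report(corpus: SyntheticCorpus) -> dict:
    """Counts and prevalences, consistent with the gold labels by direct
    counting."""
    n_sent = len(corpus.gold_sentences)
    n_present = sum(
        1 for s in corpus.gold_sentences if s.label is Label.PRESENT
    )
    kind_counts: dict[str, int] = {}
    for k in corpus.kinds.values():
        kind_counts[k] = kind_counts.get(k, 0) + 1
    return {
        "n_patients": len({n.patient_id for n in corpus.notes}),
        "n_notes": len(corpus.notes),
        "n_sentences": n_sent,
        "n_present_sentences": n_present,
        "sentence_prevalence": (n_present / n_sent) if n_sent else float("nan"),
        "n_present_documents": sum(
            1 for v in corpus.gold_documents.values() if v is Label.PRESENT
        ),
        "kind_counts": kind_counts,
    }
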