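"""Weak labeling (distant supervision) of unlabeled note corpora.

Rules stand in for manual chart review: every sentence of a
section-filtered, segmented corpus receives the rule engine's decision as
a weak label.  Weak labels carry ``provenance = weak`` so they can never
be silently mixed with gold annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import (
    ClinicalNote,
    Label,
    LabeledSentence,
    Provenance,
    corpus_sentences,
)
from .rule_engine import (
    DEFAULT_RULES,
    CombinationRule,
    KeywordLexicon,
    evaluate_rules,
)


@dataclass
class WeakDataset:
    """Rule-labeled sentences plus bookkeeping.

    ``prevalence`` is the fraction of present labels; NaN for an empty
    dataset (never silently zero).
    """

    items: list[LabeledSentence]
    source_corpus_id: str = ""

    @property
    def prevalence(self) -> float:
        if not self.items:
            return math.nan
        n_pos = sum(1 for s in self.items if s.label is Label.PRESENT)
        return n_pos / len(self.items)


def weak_label(
    corpus: Sequence[ClinicalNote],
    lexicon: KeywordLexicon,
    rules: Sequence[CombinationRule] = DEFAULT_RULES,
    source_corpus_id: str = "",
) -> WeakDataset:
    """Label every sentence of the corpus with the rule engine's decision."""
    items: list[LabeledSentence] = []
    for sent in corpus_sentences(corpus):
        decision = evaluate_rules(sent.text, lexicon, rules)
        items.append(
            LabeledSentence.from_sentence(
                sent,
                Label.PRESENT if decision.matched else Label.ABSENT,
                Provenance.WEAK,
            )
        )
    return WeakDataset(items, source_corpus_id)


def stratify_split(
    items: Sequence[LabeledSentence],
    validation_fraction: float,
    unit: str = "patient",
    seed: int = 0,
) -> tuple[list[LabeledSentence], list[LabeledSentence]]:
    """Deterministic train/validation split.

    With ``unit="patient"`` no patient appears on both sides (prevents
    leakage across notes of the same patient); ``unit="sentence"`` splits
    the sentence list directly.  The number of validation patients (or
    sentences) is ``round(fraction * n)``, at least 1.
    """
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if unit == "patient":
        patients = sorted({s.patient_id for s in items})
        if len(patients) < 2:
            raise ValueError("patient-level split needs at least 2 patients")
        order = rng.permutation(len(patients))
        n_val = max(1, round(validation_fraction * len(patients)))
        val_patients = {patients[i] for i in order[:n_val]}
        train = [s for s in items if s.patient_id not in val_patients]
        val = [s for s in items if s.patient_id in val_patients]
    elif unit == "sentence":
        order = rng.permutation(len(items))
        n_val = max(1, round(validation_fraction * len(items)))
        val_idx = set(order[:n_val].tolist())
        train = [s for i, s in enumerate(items) if i not in val_idx]
        val = [s for i, s in enumerate(items) if i in val_idx]
    else:
        raise ValueError(f"unknown split unit {unit!r}")
    return train, val
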