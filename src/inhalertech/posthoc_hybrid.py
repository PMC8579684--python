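"""Post-hoc rule correction of model predictions (the hybrid model).

A sentence classifier sometimes fails on trivially easy sentences through
over- or under-fitting; a small set of regex overrides fixes those.  N2P
(negative-to-positive) patterns are applied to model-absent sentences and
flip them to present on a match; P2N (positive-to-negative) rules are
applied to model-present sentences and flip them to absent when a trigger
matches and a blocking term is not indicated.  Overrides see the ORIGINAL
model label only — a flipped label is never re-examined — so the pass is
idempotent and every sentence flips at most once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .corpus_io import Label, LabeledSentence, Provenance

logger = logging.getLogger(__name__)

_DEFAULT_RULESET_PATH = Path(__file__).parent / "data" / "posthoc_rules.yaml"


@dataclass(frozen=True)
class P2NRule:
    """Trigger regex plus a blocking term.

    The blocker is checked as the stem at a word start ("techni" covers
    technique/techniques); ``exact_word`` restores whole-word matching.
    """

    trigger: str
    blocker: str
    exact_word: bool = False

    def blocked(self, text: str) -> bool:
        if self.exact_word:
            pat = r"\b" + re.escape(self.blocker) + r"\b"
        else:
            stem = self.blocker[: len("techni")] if self.blocker.lower().startswith(
                "techni"
            ) else self.blocker
            pat = r"\b" + re.escape(stem)
        return re.search(pat, text, re.IGNORECASE) is not None


@dataclass
class PostHocRuleSet:
    """N2P patterns and P2N (trigger, blocker) rules."""

    n2p_patterns: list[str]
    p2n_rules: list[P2NRule]
    _n2p_compiled: list[re.Pattern] = field(init=False, repr=False)
    _p2n_compiled: list[re.Pattern] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        try:
            self._n2p_compiled = [
                re.compile(p, re.IGNORECASE) for p in self.n2p_patterns
            ]
            self._p2n_compiled = [
                re.compile(r.trigger, re.IGNORECASE) for r in self.p2n_rules
            ]
        except re.error as e:
            raise ValueError(f"malformed post-hoc pattern: {e}") from e

    def serialize(self) -> dict:
        """Round-trip dict holding the pattern strings verbatim."""
        return {
            "n2p": list(self.n2p_patterns),
            "p2n": [
                {"trigger": r.trigger, "blocker": r.blocker} for r in self.p2n_rules
            ],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.serialize(), fh, default_flow_style=False)


def load_ruleset(path: str | Path | None = None) -> PostHocRuleSet:
    """Load a ruleset from YAML; default is the shipped override set."""
    path = Path(path) if path is not None else _DEFAULT_RULESET_PATH
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return PostHocRuleSet(
        n2p_patterns=list(cfg.get("n2p", [])),
        p2n_rules=[
            P2NRule(trigger=r["trigger"], blocker=r["blocker"])
            for r in cfg.get("p2n", [])
        ],
    )


def default_ruleset() -> PostHocRuleSet:
    return load_ruleset()


def apply_n2p(
    sentence_text: str, model_label: Label, ruleset: PostHocRuleSet
) -> Label:
    """Flip absent → present when an N2P pattern matches; else unchanged."""
    if model_label is Label.ABSENT and any(
        p.search(sentence_text) for p in ruleset._n2p_compiled
    ):
        return Label.PRESENT
    return model_label


def apply_p2n(
    sentence_text: str, model_label: Label, ruleset: PostHocRuleSet
) -> Label:
    """Flip present → absent when a trigger matches and no blocker occurs."""
    if model_label is Label.PRESENT:
        for pat, rule in zip(ruleset._p2n_compiled, ruleset.p2n_rules):
            if pat.search(sentence_text) and not rule.blocked(sentence_text):
                return Label.ABSENT
    return model_label


def hybridize(
    predictions: Sequence[LabeledSentence],
    ruleset: PostHocRuleSet | None = None,
) -> list[LabeledSentence]:
    """Apply N2P then P2N to model predictions, one pass, no chaining.

    N2P acts on model-absent items and P2N on model-present items, both
    against the original model label, so the two rule families touch
    disjoint sentences.  Every flip is logged with the firing direction.
    """
    ruleset = ruleset if ruleset is not None else default_ruleset()
    bad = [s for s in predictions if s.provenance is not Provenance.MODEL]
    if bad:
        raise ValueError(
            f"hybridize expects model predictions; got provenance "
            f"{sorted({s.provenance.value for s in bad})}"
        )
    out: list[LabeledSentence] = []
    for s in predictions:
        label = apply_n2p(s.text, s.label, ruleset)
        label = apply_p2n(s.text, s.label, ruleset) if label is s.label else label
        if label is not s.label:
            logger.info(
                "post-hoc flip %s->%s on note %s: %r",
                s.label.value, label.value, s.note_id, s.text,
            )
        out.append(LabeledSentence.from_sentence(s, label, Provenance.HYBRID))
    return out
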