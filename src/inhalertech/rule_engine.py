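"""Keyword-combination rules for inhaler-technique sentences.

The lexicon has four keyword groups — (1) teaching/review actions,
(2) delivery devices, (3) manner terms, (4) asthma medication classes —
and two combination rules: rule ``a`` fires when a sentence contains a
group-1 and a group-2 keyword, rule ``b`` when it contains keywords from
groups 1, 3 and 4.  Co-occurrence is within one sentence, any order, any
distance.

Matching semantics
------------------
Sentences are tokenized into alphanumeric runs (hyphens and slashes are
boundaries, so "metered-dose inhaler" contains the token "inhaler");
matching is case-insensitive.  A trailing asterisk denotes prefix
matching ("discuss*" matches "Discussed").  Multi-word keywords match as
contiguous token sequences.  Two lexicon entries expand specially:

* "asthma/rescue/daily/preventive/control medication" expands to the five
  two-token phrases {asthma, rescue, daily, preventive, control} +
  "medication";
* "list of maintenance and rescue medications" matches when
  "maintenance" … "medication*" or "rescue" … "medication*" co-occur in
  order within the sentence (gapped phrase).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .corpus_io import Label, Sentence

_DEFAULT_LEXICON_PATH = Path(__file__).parent / "data" / "lexicon.yaml"

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric tokens; hyphens/slashes are boundaries."""
    return [m.group().lower() for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# keyword matchers


@dataclass(frozen=True)
class _Part:
    """One word of a keyword: exact token or prefix stem."""

    stem: str
    prefix: bool

    def matches(self, token: str) -> bool:
        return token.startswith(self.stem) if self.prefix else token == self.stem


def _parse_word(word: str) -> _Part:
    word = word.lower()
    if word.endswith("*"):
        return _Part(word[:-1], True)
    return _Part(word, False)


@dataclass(frozen=True)
class KeywordMatcher:
    """A compiled lexicon entry.

    ``parts`` must match contiguously unless ``gapped``, in which case
    they must appear in order anywhere in the sentence.
    """

    surface: str
    parts: tuple[_Part, ...]
    gapped: bool = False

    def find(self, tokens: Sequence[str]) -> str | None:
        """Return the matched token span as a string, or None."""
        n, k = len(tokens), len(self.parts)
        if k == 0 or n < k:
            return None
        if not self.gapped:
            for i in range(n - k + 1):
                if all(p.matches(tokens[i + j]) for j, p in enumerate(self.parts)):
                    return " ".join(tokens[i : i + k])
            return None
        hit: list[str] = []
        j = 0
        for tok in tokens:
            if j < k and self.parts[j].matches(tok):
                hit.append(tok)
                j += 1
        return " ".join(hit) if j == k else None


_SLASH_PHRASE = re.compile(r"^(\S+(?:/\S+)+)\s+(.+)$")


def expand_entry(entry: str) -> list[KeywordMatcher]:
    """Compile one lexicon entry into its matcher alternatives."""
    entry = entry.strip()
    if entry.lower() == "list of maintenance and rescue medications":
        return [
            KeywordMatcher(entry, (_parse_word(w), _parse_word("medication*")), gapped=True)
            for w in ("maintenance", "rescue")
        ]
    m = _SLASH_PHRASE.match(entry)
    if m:
        heads, tail = m.group(1).split("/"), m.group(2)
        tail_parts = tuple(_parse_word(w) for w in tail.split())
        return [
            KeywordMatcher(f"{h} {tail}", (_parse_word(h),) + tail_parts)
            for h in heads
        ]
    return [KeywordMatcher(entry, tuple(_parse_word(w) for w in entry.split()))]


# Group-3 entries are printed in the plural; by default the singular stem
# is matched too (the shipped rule-b example itself uses singular
# "technique").  ``strict_plural`` restores the literal behavior.
_GROUP3_SOFTEN = {"techniques": "technique*", "administrations": "administration*"}


@dataclass
class KeywordLexicon:
    """The four keyword groups, compiled for matching."""

    groups: dict[int, list[str]]
    strict_plural: bool = False
    _matchers: dict[int, list[KeywordMatcher]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.groups or any(not v for v in self.groups.values()):
            raise ValueError("every keyword group must be non-empty")
        self._matchers = {}
        for gid, entries in self.groups.items():
            compiled: list[KeywordMatcher] = []
            for entry in entries:
                e = entry
                if gid == 3 and not self.strict_plural:
                    e = _GROUP3_SOFTEN.get(entry.lower(), entry)
                compiled.extend(expand_entry(e))
            self._matchers[int(gid)] = compiled

    def matchers(self, group_id: int) -> list[KeywordMatcher]:
        return self._matchers[group_id]

    def group_ids(self) -> list[int]:
        return sorted(self._matchers)


@dataclass(frozen=True)
class CombinationRule:
    """A rule fires when every required group matches in the sentence."""

    rule_id: str
    required_groups: frozenset[int]

    def __post_init__(self) -> None:
        if not self.required_groups <= {1, 2, 3, 4}:
            raise ValueError("required_groups must be a subset of {1,2,3,4}")


DEFAULT_RULES = (
    CombinationRule("a", frozenset({1, 2})),
    CombinationRule("b", frozenset({1, 3, 4})),
)


@dataclass
class RuleDecision:
    """Outcome of the rule engine on one sentence."""

    matched: bool
    fired_rules: list[str]
    matched_keywords: dict[int, list[str]]


def load_lexicon(path: str | Path | None = None, strict_plural: bool = False):
    """Load lexicon + rules from YAML; default is the shipped config."""
    path = Path(path) if path is not None else _DEFAULT_LEXICON_PATH
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    groups = {int(k): list(v) for k, v in cfg["groups"].items()}
    rules = [
        CombinationRule(str(rid), frozenset(int(g) for g in req))
        for rid, req in cfg["rules"].items()
    ]
    return KeywordLexicon(groups, strict_plural=strict_plural), rules


def default_lexicon(strict_plural: bool = False) -> KeywordLexicon:
    return load_lexicon(strict_plural=strict_plural)[0]


def keyword_in_sentence(keyword: str, sentence_text: str) -> bool:
    """True iff the lexicon entry occurs in the sentence.

    Case-insensitive, word-boundary-respecting; asterisk entries match any
    continuation of the stem within a word.
    """
    tokens = tokenize(sentence_text)
    return any(m.find(tokens) is not None for m in expand_entry(keyword))


def evaluate_rules(
    sentence_text: str,
    lexicon: KeywordLexicon,
    rules: Sequence[CombinationRule] = DEFAULT_RULES,
) -> RuleDecision:
    """Apply every combination rule to one sentence.

    A rule fires iff each of its required groups has at least one keyword
    match anywhere in the sentence (order-free co-occurrence).
    """
    tokens = tokenize(sentence_text)
    matched_keywords: dict[int, list[str]] = {}
    for gid in lexicon.group_ids():
        hits = [s for m in lexicon.matchers(gid) if (s := m.find(tokens)) is not None]
        if hits:
            matched_keywords[gid] = hits
    fired = [
        r.rule_id
        for r in rules
        if all(g in matched_keywords for g in r.required_groups)
    ]
    return RuleDecision(bool(fired), fired, matched_keywords)


def rule_label_document(
    sentences: Sequence[Sentence],
    lexicon: KeywordLexicon,
    rules: Sequence[CombinationRule] = DEFAULT_RULES,
) -> tuple[Label, list[RuleDecision]]:
    """Document-level rule decision: present iff any sentence matches."""
    note_ids = {s.note_id for s in sentences}
    if len(note_ids) > 1:
        raise ValueError(f"sentences span multiple notes: {sorted(note_ids)}")
    decisions = [evaluate_rules(s.text, lexicon, rules) for s in sentences]
    label = Label.PRESENT if any(d.matched for d in decisions) else Label.ABSENT
    return label, decisions
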