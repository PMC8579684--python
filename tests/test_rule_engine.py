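"""Keyword-combination rule engine, checked against an independent oracle.

The oracle re-implements the matching semantics with different mechanics:
regular expressions applied to the raw lowercased sentence (the engine
matches over a token list), enumerating every (keyword, position) pair.
"""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhalertech import (
    Label,
    Sentence,
    default_lexicon,
    evaluate_rules,
    keyword_in_sentence,
    rule_label_document,
)
from inhalertech.rule_engine import DEFAULT_RULES, CombinationRule, KeywordLexicon
from inhalertech.synthetic_notes import SyntheticCorpusConfig, generate_corpus

# ---------------------------------------------------------------------------
# brute-force oracle

_B = r"(?<![a-z0-9])"  # left word boundary over alphanumeric tokens
_E = r"(?![a-z0-9])"


def _word_pat(word: str) -> str:
    if word.endswith("*"):
        return _B + re.escape(word[:-1].lower()) + r"[a-z0-9]*"
    return _B + re.escape(word.lower()) + _E


def _entry_patterns(entry: str) -> list[str]:
    e = entry.lower()
    if e == "list of maintenance and rescue medications":
        return [
            _word_pat(w) + r".*" + _word_pat("medication*")
            for w in ("maintenance", "rescue")
        ]
    first, _, rest = e.partition(" ")
    if "/" in first and rest:
        tail = r"[^a-z0-9]+".join(_word_pat(w) for w in rest.split())
        return [_word_pat(h) + r"[^a-z0-9]+" + tail for h in first.split("/")]
    return [r"[^a-z0-9]+".join(_word_pat(w) for w in e.split())]


_G3_SOFTEN = {"techniques": "technique*", "administrations": "administration*"}


def oracle_matches(sentence: str, lexicon: KeywordLexicon) -> dict[int, bool]:
    text = sentence.lower()
    out = {}
    for gid, entries in lexicon.groups.items():
        pats = []
        for entry in entries:
            if gid == 3 and not lexicon.strict_plural:
                entry = _G3_SOFTEN.get(entry.lower(), entry)
            pats.extend(_entry_patterns(entry))
        out[gid] = any(re.search(p, text) for p in pats)
    return out


def oracle_decision(sentence: str, lexicon: KeywordLexicon, rules) -> bool:
    groups = oracle_matches(sentence, lexicon)
    return any(all(groups[g] for g in r.required_groups) for r in rules)


# ---------------------------------------------------------------------------
# keyword matching


class TestKeywordInSentence:
    @pytest.mark.parametrize(
        "keyword,sentence,expected",
        [
            ("discuss*", "Discussed correct inhaler technique", True),
            ("taught", "The patient was taut", False),
            ("how to use", "showed her how to use the spacer", True),
            ("inhaler", "appropriate metered-dose inhaler technique", True),
            ("neb", "Discussed 3rd neb treatment here", True),
            ("neb", "a nebulous complaint", False),  # exact entry, boundary
            ("asthma/rescue/daily/preventive/control medication",
             "teach daily medication technique", True),
            ("asthma/rescue/daily/preventive/control medication",
             "daily peak flow readings", False),
            ("list of maintenance and rescue medications",
             "reviewed the list of maintenance and rescue medications", True),
            ("list of maintenance and rescue medications",
             "maintenance visit scheduled", False),
            ("ICS", "started on an ics today", True),
        ],
    )
    def test_examples(self, keyword, sentence, expected):
        assert keyword_in_sentence(keyword, sentence) is expected


# ---------------------------------------------------------------------------
# rule evaluation


class TestEvaluateRules:
    @pytest.mark.parametrize(
        "sentence,fired",
        [
            ("Discussed correct inhaler technique", ["a"]),
            ("A patient received asthma education and instruction in "
             "appropriate metered-dose inhaler technique", ["a"]),
            ("We reviewed her medications and discussed labeling the Flovent "
             "with a green sticker for a daily inhaler", ["a"]),
            ("teach daily medication technique", ["b"]),
            ("", []),
            ("Patient doing well today", []),
        ],
    )
    def test_examples(self, lexicon, sentence, fired):
        decision = evaluate_rules(sentence, lexicon)
        assert decision.fired_rules == fired
        assert decision.matched is bool(fired)

    def test_matched_keywords_are_present_in_sentence(self, lexicon):
        d = evaluate_rules("Reviewed inhaler use with mom", lexicon)
        assert d.matched
        for hits in d.matched_keywords.values():
            for h in hits:
                for w in h.split():
                    assert w in "reviewed inhaler use with mom"

    def test_strict_plural_restores_literal_group3(self):
        lex = default_lexicon(strict_plural=True)
        # rule-b example uses singular "technique": literal mode misses it
        assert not evaluate_rules("teach daily medication technique", lex).matched
        assert evaluate_rules("teach daily medication techniques", lex).matched

    def test_case_invariance(self, lexicon, bank):
        for t in bank.all_instances(bank.explicit_positive + bank.filler):
            a = evaluate_rules(t, lexicon)
            b = evaluate_rules(t.upper(), lexicon)
            assert a.matched == b.matched and a.fired_rules == b.fired_rules

    def test_monotonicity_adding_keywords_never_unmatches(self, lexicon, bank):
        bigger = KeywordLexicon(
            {g: kws + ["zz_unmatched*", "extra keyword"]
             for g, kws in lexicon.groups.items()}
        )
        for t in bank.all_instances(bank.explicit_positive + bank.hard_negative):
            assert evaluate_rules(t, bigger).matched


_WORDS = [
    "discussed", "reviewed", "taught", "checked", "inhaler", "spacer", "neb",
    "technique", "techniques", "dosing", "guidance", "daily", "medication",
    "asthma", "patient", "mom", "well", "follow", "up", "visit", "ics",
    "metered-dose", "how", "to", "use", "the", "and", "instruction",
]


class TestOracleEquivalence:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(_WORDS), min_size=0, max_size=12))
    def test_random_word_salads(self, words):
        lexicon = default_lexicon()
        sentence = " ".join(words)
        got = evaluate_rules(sentence, lexicon).matched
        assert got == oracle_decision(sentence, lexicon, DEFAULT_RULES)

    def test_generated_corpus_sentence_by_sentence(self, lexicon):
        corpus = generate_corpus(SyntheticCorpusConfig(
            n_patients=10, notes_per_patient=(2, 3), sentences_per_note=(5, 8),
            positive_sentence_rate=0.2, implicit_positive_fraction=0.3,
            hard_negative_rate=0.1, seed=11,
        ))
        for s in corpus.gold_sentences:
            got = evaluate_rules(s.text, lexicon).matched
            assert got == oracle_decision(s.text, lexicon, DEFAULT_RULES), s.text


# ---------------------------------------------------------------------------
# document-level aggregation


class TestRuleLabelDocument:
    def _sent(self, i, text, note="n1"):
        return Sentence(note, "HPI", i, text, (0, len(text)), "p1")

    def test_existential_aggregation(self, lexicon):
        sents = [self._sent(i, "Patient doing well") for i in range(99)]
        sents.append(self._sent(99, "Discussed correct inhaler technique"))
        label, decisions = rule_label_document(sents, lexicon)
        assert label is Label.PRESENT
        assert sum(d.matched for d in decisions) == 1

    def test_empty_is_absent(self, lexicon):
        label, decisions = rule_label_document([], lexicon)
        assert label is Label.ABSENT and decisions == []

    def test_mixed_note_ids_rejected(self, lexicon):
        sents = [self._sent(0, "a", "n1"), self._sent(1, "b", "n2")]
        with pytest.raises(ValueError, match="multiple notes"):
            rule_label_document(sents, lexicon)

    def test_document_labels_equal_or_of_oracle(self, lexicon):
        corpus = generate_corpus(SyntheticCorpusConfig(
            n_patients=8, notes_per_patient=(1, 2), sentences_per_note=(4, 7),
            positive_sentence_rate=0.15, hard_negative_rate=0.1, seed=3,
        ))
        by_note = {}
        for s in corpus.gold_sentences:
            by_note.setdefault(s.note_id, []).append(s)
        for note_id, sents in by_note.items():
            label, _ = rule_label_document(sents, lexicon)
            want = any(
                oracle_decision(s.text, lexicon, DEFAULT_RULES) for s in sents
            )
            assert (label is Label.PRESENT) == want


class TestCombinationRule:
    def test_groups_must_be_known(self):
        with pytest.raises(ValueError):
            CombinationRule("c", frozenset({1, 5}))

    def test_shipped_default_is_rules_a_and_b(self, rules):
        assert {r.rule_id: r.required_groups for r in rules} == {
            "a": frozenset({1, 2}),
            "b": frozenset({1, 3, 4}),
        }
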