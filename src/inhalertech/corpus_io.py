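"""Reading, writing and segmenting clinical-note corpora.

A corpus is a flat file of note-section records (JSONL or CSV, one record
per section) grouped into :class:`ClinicalNote` objects.  Only two note
sections typically carry inhaler-technique documentation — History of
Present Illness and Impression/Report/Plan — so :func:`filter_sections`
defaults to keeping those.  Sentence segmentation is rule-based with a
clinical-abbreviation exception list; all offsets are 0-based, half-open
into the section text.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = ("note_id", "patient_id", "section", "text")

#: Default section-name patterns: History of Present Illness and
#: Impression/Report/Plan (header spellings vary across EHRs, so matching
#: is case-insensitive substring/regex).
DEFAULT_SECTION_PATTERNS = (
    "history of present illness",
    "hpi",
    "impression",
    "report",
    "plan",
)


class Label(str, Enum):
    """Binary sentence/document label for the inhaler-technique concept."""

    PRESENT = "present"
    ABSENT = "absent"


class Provenance(str, Enum):
    """Where a label came from, so pipeline stages stay auditable."""

    GOLD = "gold"
    WEAK = "weak"
    MODEL = "model"
    HYBRID = "hybrid"


@dataclass
class ClinicalNote:
    """One clinical note: ids plus an ordered list of (section, text)."""

    note_id: str
    patient_id: str
    sections: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.note_id:
            raise ValueError("note_id must be non-empty")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass
class Sentence:
    """A single sentence: the classification unit.

    ``char_span`` is a 0-based half-open offset pair into the *section*
    text; ``sentence_index`` counts sentences within the note (across
    sections, in order).
    """

    note_id: str
    section_name: str
    sentence_index: int
    text: str
    char_span: tuple[int, int]
    patient_id: str = ""


@dataclass
class LabeledSentence(Sentence):
    """A sentence with a binary label and its provenance."""

    label: Label = Label.ABSENT
    provenance: Provenance = Provenance.GOLD

    @classmethod
    def from_sentence(
        cls, sent: Sentence, label: Label, provenance: Provenance
    ) -> "LabeledSentence":
        return cls(
            note_id=sent.note_id,
            section_name=sent.section_name,
            sentence_index=sent.sentence_index,
            text=sent.text,
            char_span=sent.char_span,
            patient_id=sent.patient_id,
            label=Label(label),
            provenance=Provenance(provenance),
        )


class CorpusFormatError(ValueError):
    """A corpus file violates the record contract."""


def _records_to_notes(records: Iterable[dict], source: str) -> list[ClinicalNote]:
    notes: dict[str, ClinicalNote] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, rec in enumerate(records, start=1):
        for f in REQUIRED_FIELDS:
            if f not in rec or rec[f] is None:
                raise CorpusFormatError(
                    f"{source}: record {lineno} missing required field {f!r}"
                )
        note_id = str(rec["note_id"])
        patient_id = str(rec["patient_id"])
        section = str(rec["section"])
        text = str(rec["text"])
        key = (note_id, section)
        if key in seen:
            raise CorpusFormatError(
                f"{source}: record {lineno} duplicates (note_id, section) {key!r}"
            )
        seen.add(key)
        if note_id in notes:
            note = notes[note_id]
            if note.patient_id != patient_id:
                raise CorpusFormatError(
                    f"{source}: record {lineno}: note {note_id!r} carries "
                    f"conflicting patient ids {note.patient_id!r} vs {patient_id!r}"
                )
            note.sections.append((section, text))
        else:
            notes[note_id] = ClinicalNote(note_id, patient_id, [(section, text)])
    return list(notes.values())


def read_corpus(path: str | Path, format: str | None = None) -> list[ClinicalNote]:
    """Read a note corpus from JSONL or CSV.

    Each record carries ``note_id``, ``patient_id``, ``section``, ``text``.
    Records sharing a note_id are grouped into one :class:`ClinicalNote`
    with sections in file order.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            records = [json.loads(line) for line in fh if line.strip()]
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            records = list(csv.DictReader(fh))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    return _records_to_notes(records, str(path))


def write_corpus(
    corpus: Sequence[ClinicalNote], path: str | Path, format: str | None = None
) -> None:
    """Write a corpus as one record per note-section (JSONL or CSV), UTF-8."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    rows = [
        {"note_id": n.note_id, "patient_id": n.patient_id, "section": s, "text": t}
        for n in corpus
        for s, t in n.sections
    ]
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(REQUIRED_FIELDS))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


def filter_sections(
    note: ClinicalNote,
    keep: Sequence[str] = DEFAULT_SECTION_PATTERNS,
) -> ClinicalNote:
    """Keep only sections whose name matches any pattern (case-insensitive).

    Patterns are regexes searched within the section name, so plain
    substrings work as-is.  A note with zero matching sections is returned
    with an empty section list and logged.
    """
    if not keep:
        raise ValueError("keep patterns must be non-empty")
    compiled = [re.compile(p, re.IGNORECASE) for p in keep]
    kept = [
        (name, text)
        for name, text in note.sections
        if any(c.search(name) for c in compiled)
    ]
    if note.sections and not kept:
        logger.warning("note %s: no sections matched %r", note.note_id, list(keep))
    return replace(note, sections=kept)


# Abbreviations after which a period does not end a sentence.  Stored
# lowercase without the trailing period.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "st", "jr", "sr", "vs", "etc", "approx",
    "e.g", "i.e", "b.i.d", "t.i.d", "q.i.d", "q.d", "p.r.n", "p.o",
    "mg", "ml", "tab", "resp", "appt",
}

_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)")


def _segment_text(text: str) -> list[tuple[int, int]]:
    """Return half-open spans of sentences within ``text``."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        # look back at the token preceding the terminator
        prev = text[start : m.start()].rstrip()
        last_tok = prev.split()[-1].lower() if prev.split() else ""
        last_tok = last_tok.lstrip("(\"'")
        if m.group().startswith(".") and last_tok in _ABBREVIATIONS:
            continue
        # single-letter initials ("J. Smith")
        if m.group() == "." and len(last_tok) == 1 and last_tok.isalpha():
            continue
        spans.append((start, end))
        start = end
    if text[start:].strip():
        spans.append((start, len(text)))
    # trim whitespace off each span
    trimmed = []
    for a, b in spans:
        seg = text[a:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        a2, b2 = a + lead, b - trail
        if a2 < b2:
            trimmed.append((a2, b2))
    return trimmed


def segment_sentences(note: ClinicalNote) -> list[Sentence]:
    """Deterministically segment every retained section into sentences.

    Sentences carry no leading/trailing whitespace and their char spans
    index into the section text they came from.
    """
    out: list[Sentence] = []
    idx = 0
    for section_name, text in note.sections:
        for a, b in _segment_text(text):
            out.append(
                Sentence(
                    note_id=note.note_id,
                    section_name=section_name,
                    sentence_index=idx,
                    text=text[a:b],
                    char_span=(a, b),
                    patient_id=note.patient_id,
                )
            )
            idx += 1
    return out


def corpus_sentences(
    corpus: Sequence[ClinicalNote],
    keep: Sequence[str] | None = DEFAULT_SECTION_PATTERNS,
) -> list[Sentence]:
    """Section-filter and segment a whole corpus."""
    out: list[Sentence] = []
    for note in corpus:
        filtered = filter_sections(note, keep) if keep is not None else note
        out.extend(segment_sentences(filtered))
    return out


def write_sentences(items: Sequence[LabeledSentence], path: str | Path) -> None:
    """Serialize labeled sentences to JSONL."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in items:
            fh.write(
                json.dumps(
                    {
                        "note_id": s.note_id,
                        "patient_id": s.patient_id,
                        "section": s.section_name,
                        "sentence_index": s.sentence_index,
                        "text": s.text,
                        "label": s.label.value,
                        "provenance": s.provenance.value,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_sentences(path: str | Path) -> list[LabeledSentence]:
    """Read labeled sentences from the JSONL dialect of :func:`write_sentences`."""
    out: list[LabeledSentence] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                LabeledSentence(
                    note_id=rec["note_id"],
                    patient_id=rec.get("patient_id", ""),
                    section_name=rec.get("section", ""),
                    sentence_index=int(rec["sentence_index"]),
                    text=rec["text"],
                    char_span=(0, len(rec["text"])),
                    label=Label(rec["label"]),
                    provenance=Provenance(rec["provenance"]),
                )
            )
    return out
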