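"""Consultation-text preparation: synonym normalization, tokenization, corpus building.

The raw material is free-text consultation notes (EMR diagnosis
descriptions). Before any vectorization they are normalized with a
synonym dictionary (variant disease names -> canonical terms), split
into tokens with a pluggable tokenizer that keeps multi-word domain
terms whole, and filtered against a stop-word list; bare numbers and
punctuation-only tokens are dropped.
"""

from __future__ import annotations

import csv
import datetime
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence


class EmptyCorpusError(ValueError):
    """Raised when no valid consultation record survives filtering."""


@dataclass(frozen=True)
class ConsultationRecord:
    """One consultation event linking a patient's EMR text to a specialist."""

    patient_id: str
    specialist_id: str
    department: str
    date: datetime.date
    text: str

    @classmethod
    def from_strings(cls, patient_id: str, specialist_id: str, department: str,
                     date: str, text: str) -> "ConsultationRecord":
        return cls(patient_id, specialist_id, department,
                   datetime.date.fromisoformat(date.strip()), text)

    @property
    def is_valid(self) -> bool:
        return bool(self.patient_id) and bool(self.specialist_id) and bool(self.text.strip())


@dataclass
class Dictionaries:
    """Stop-word list, synonym map (variant -> canonical) and user term list.

    The synonym map must be acyclic after one application: a canonical
    term may not itself appear as a variant.
    """

    stopwords: set[str] = field(default_factory=set)
    synonyms: dict[str, str] = field(default_factory=dict)
    user_terms: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for entry in self.stopwords | self.user_terms:
            if not entry:
                raise ValueError("empty dictionary entry")
        for variant, canon in self.synonyms.items():
            if not variant or not canon:
                raise ValueError("empty synonym entry")
            if canon in self.synonyms:
                raise ValueError(
                    f"synonym map not acyclic: canonical term {canon!r} is itself a variant")

    @classmethod
    def from_paths(cls, stopwords=None, synonyms=None, user_terms=None) -> "Dictionaries":
        d = cls()
        if stopwords:
            with open(stopwords, encoding="utf-8") as fh:
                d.stopwords = {line.strip() for line in fh if line.strip()}
        if synonyms:
            with open(synonyms, encoding="utf-8") as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line.strip():
                        continue
                    variant, _, canon = line.partition("\t")
                    d.synonyms[variant.strip()] = canon.strip()
        if user_terms:
            with open(user_terms, encoding="utf-8") as fh:
                d.user_terms = {line.strip() for line in fh if line.strip()}
        d.validate()
        return d


@dataclass
class Corpus:
    """Tokenized documents plus per-document consultation metadata."""

    documents: list[tuple[str, list[str]]]
    doc_meta: dict[str, tuple[str, str, datetime.date]]
    vocabulary: list[str]

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [doc_id for doc_id, _ in self.documents]

    def tokens_of(self, doc_id: str) -> list[str]:
        for did, toks in self.documents:
            if did == doc_id:
                return toks
        raise KeyError(doc_id)


def normalize_text(raw: str, synonyms: dict[str, str]) -> str:
    """Replace variant terms with their canonical form, longest match first.

    A single left-to-right pass over word boundaries; because canonical
    terms are never variants themselves, the operation is idempotent.
    """
    if not raw or not synonyms:
        return raw
    pattern = "|".join(
        re.escape(v) for v in sorted(synonyms, key=len, reverse=True))
    rx = re.compile(r"(?<!\w)(?:%s)(?!\w)" % pattern)
    return rx.sub(lambda m: synonyms[m.group(0)], raw)


def _has_letter(token: str) -> bool:
    return any(ch.isalpha() for ch in token)


_EDGE_PUNCT = re.compile(r"^\W+|\W+$", re.UNICODE)


def tokenize(text: str, dicts: Dictionaries,
             tokenizer: Callable[[str], list[str]] | None = None) -> list[str]:
    """Split text into filtered tokens.

    Multi-word user terms are recognized greedily (longest match first)
    and kept as single tokens. Other tokens are stripped of edge
    punctuation; stop words and tokens without any alphabetic character
    (bare numbers, symbols) are removed. A custom ``tokenizer`` may
    replace the whitespace pre-split (e.g. a Chinese segmenter).
    """
    if not text:
        return []
    raw = tokenizer(text) if tokenizer is not None else text.split()
    max_len = max((t.count(" ") + 1 for t in dicts.user_terms), default=1)
    out: list[str] = []
    i = 0
    while i < len(raw):
        matched = False
        for length in range(min(max_len, len(raw) - i), 0, -1):
            phrase = " ".join(raw[i:i + length])
            if phrase in dicts.user_terms:
                out.append(phrase)
                i += length
                matched = True
                break
        if matched:
            continue
        tok = _EDGE_PUNCT.sub("", raw[i])
        i += 1
        if tok and tok not in dicts.stopwords and _has_letter(tok):
            out.append(tok)
    return out


def build_corpus(records: Sequence[ConsultationRecord], dicts: Dictionaries,
                 tokenizer: Callable[[str], list[str]] | None = None) -> Corpus:
    """Build a de-duplicated, normalized, tokenized corpus.

    A duplicate is a record equal in all five fields (two patients may
    legitimately share a diagnosis sentence). Records that are invalid,
    or whose text tokenizes to nothing, are dropped; if nothing
    survives an :class:`EmptyCorpusError` is raised.
    """
    dicts.validate()
    seen: set[ConsultationRecord] = set()
    documents: list[tuple[str, list[str]]] = []
    doc_meta: dict[str, tuple[str, str, datetime.date]] = {}
    vocab: dict[str, None] = {}
    idx = 0
    for rec in records:
        if not rec.is_valid or rec in seen:
            continue
        seen.add(rec)
        tokens = tokenize(normalize_text(rec.text, dicts.synonyms), dicts, tokenizer)
        if not tokens:
            continue
        doc_id = f"d{idx:05d}"
        idx += 1
        documents.append((doc_id, tokens))
        doc_meta[doc_id] = (rec.patient_id, rec.specialist_id, rec.date)
        for t in tokens:
            vocab.setdefault(t)
    if not documents:
        raise EmptyCorpusError("no valid consultation records after filtering")
    return Corpus(documents, doc_meta, list(vocab))


def read_consultations_csv(path) -> list[ConsultationRecord]:
    """Read records from a UTF-8 CSV with the documented header."""
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        expected = ["patient_id", "specialist_id", "department", "date", "text"]
        if reader.fieldnames != expected:
            raise ValueError(f"unexpected consultation header {reader.fieldnames!r}, "
                             f"want {expected!r}")
        for row in reader:
            records.append(ConsultationRecord.from_strings(
                row["patient_id"], row["specialist_id"], row["department"],
                row["date"], row["text"]))
    return records


def write_consultations_csv(records: Iterable[ConsultationRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "specialist_id", "department", "date", "text"])
        for r in records:
            writer.writerow([r.patient_id, r.specialist_id, r.department,
                             r.date.isoformat(), r.text])
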