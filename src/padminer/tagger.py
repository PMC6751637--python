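"""Sentence segmentation, dictionary tagging and the disease-abbreviation filter.

The tagger annotates pathogen and disease class mentions in text with the
two refined dictionaries.  Matching is word-boundary aligned (a boundary is
a transition between alphanumeric and non-alphanumeric, so "rat" never
matches inside "strategy"), case-insensitive except for short all-caps
abbreviation forms, and overlapping candidates within one category resolve
to the longest match with ties broken leftmost.

Disease-name abbreviations are notoriously ambiguous ("ALS" is both
amyotrophic lateral sclerosis and advanced life support), so a rule-based
filter inspects each document: abbreviations and their long forms are
detected from parenthetical patterns by Schwartz–Hearst-style letter
alignment, and a disease mention whose surface is an abbreviation is kept
only if a known long form of its disease class occurs elsewhere in the
document, or a detected expansion contains a disease-indicating keyword
("disease", "syndrome", ...).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from .lexicon import TermDictionary, normalize_term

__all__ = [
    "Document",
    "Sentence",
    "Mention",
    "TaggedSentence",
    "AbbreviationMap",
    "split_sentences",
    "tag_sentence",
    "detect_abbreviations",
    "filter_disease_abbreviations",
    "tag_document",
    "tag_corpus",
    "read_corpus",
    "write_tagged_jsonl",
    "read_tagged_jsonl",
    "DEFAULT_SPLIT_EXCEPTIONS",
    "DEFAULT_DISEASE_KEYWORDS",
]


@dataclass(frozen=True)
class Document:
    """One corpus record (stands for one article)."""

    doc_id: str
    text: str


@dataclass(frozen=True)
class Sentence:
    doc_id: str
    index: int  # 0-based ordinal within the document
    text: str
    char_offset: int  # start offset in the document


@dataclass(frozen=True)
class Mention:
    """A dictionary hit inside a sentence.

    ``span`` is a 0-based half-open character interval within the sentence;
    ``class_ids`` carries every class the matched form can denote.
    """

    class_ids: frozenset[str]
    category: str
    span: tuple[int, int]
    surface: str


@dataclass
class TaggedSentence:
    sentence: Sentence
    mentions: list[Mention] = field(default_factory=list)


@dataclass
class AbbreviationMap:
    """Short form -> set of detected long forms, per document."""

    pairs: dict[str, set[str]] = field(default_factory=dict)

    def add(self, short: str, long: str) -> None:
        self.pairs.setdefault(short, set()).add(long)

    def long_forms(self, short: str) -> set[str]:
        return set(self.pairs.get(short, ()))


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

# tokens after which a period never ends a sentence
DEFAULT_SPLIT_EXCEPTIONS = frozenset(
    {
        "al", "approx", "ca", "cf", "dr", "e.g", "et", "etc", "fig", "figs",
        "i.e", "inc", "jr", "mr", "mrs", "ms", "no", "prof", "resp", "sp",
        "spp", "st", "subsp", "var", "vs",
    }
)

_BOUNDARY_RE = re.compile(r"[.!?]+")
_WORD_BEFORE_RE = re.compile(r"(\S+)$")


def _is_abbreviation_token(token: str, exceptions: frozenset[str]) -> bool:
    token = token.lstrip("([\"'")
    return token.lower().rstrip(".") in exceptions or token.lower() in exceptions


def split_sentences(
    doc: Document, exceptions: frozenset[str] = DEFAULT_SPLIT_EXCEPTIONS
) -> list[Sentence]:
    """Rule-based sentence splitter with an abbreviation exception list.

    A run of ``.!?`` ends a sentence when it is followed by whitespace and
    an upper-case letter, digit or opening quote, unless the preceding
    token is a known abbreviation.  Offsets index into the document text;
    no non-whitespace character is lost.
    """
    text = doc.text
    boundaries: list[int] = []
    for match in _BOUNDARY_RE.finditer(text):
        end = match.end()
        rest = text[end:]
        if rest.strip() == "":
            continue  # trailing punctuation; final flush handles it
        stripped = rest.lstrip()
        if not rest[0].isspace():
            continue
        if not (stripped[0].isupper() or stripped[0].isdigit() or stripped[0] in "\"'("):
            continue
        before = _WORD_BEFORE_RE.search(text[: match.start()])
        if (
            "." in match.group()
            and before
            and _is_abbreviation_token(before.group(1), exceptions)
        ):
            continue
        boundaries.append(end)

    sentences: list[Sentence] = []
    start = 0
    for end in boundaries + [len(text)]:
        chunk = text[start:end]
        stripped = chunk.strip()
        if stripped:
            offset = start + chunk.index(stripped[0])
            sentences.append(
                Sentence(
                    doc_id=doc.doc_id,
                    index=len(sentences),
                    text=text[offset : offset + len(stripped)],
                    char_offset=offset,
                )
            )
        start = end
    return sentences


# ---------------------------------------------------------------------------
# dictionary tagging
# ---------------------------------------------------------------------------


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


def _boundary_ok(text: str, start: int, end: int) -> bool:
    if start > 0 and _is_word_char(text[start - 1]):
        return False
    if end < len(text) and _is_word_char(text[end]):
        return False
    return True


def _candidate_matches(
    text: str, dictionary: TermDictionary
) -> list[tuple[int, int, str]]:
    """All word-boundary-aligned occurrences of dictionary forms.

    Returns (start, end, normalized_form) triples, possibly overlapping.
    Multi-space gaps in text match the single-space normalized forms.
    """
    lower = text.lower()
    out: list[tuple[int, int, str]] = []
    for form in dictionary.entries:
        case_sensitive = form in dictionary.case_sensitive_forms
        haystack = text if case_sensitive else lower
        needle = form if case_sensitive else form.lower()
        if " " in needle:
            pattern = re.compile(re.escape(needle).replace("\\ ", r"\s+"))
            for match in pattern.finditer(haystack):
                if _boundary_ok(text, match.start(), match.end()):
                    out.append((match.start(), match.end(), form))
        else:
            pos = haystack.find(needle)
            while pos != -1:
                end = pos + len(needle)
                if _boundary_ok(text, pos, end):
                    out.append((pos, end, form))
                pos = haystack.find(needle, pos + 1)
    return out


def _resolve_overlaps(
    candidates: list[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    """Longest match wins; ties to the leftmost; survivors never overlap."""
    chosen: list[tuple[int, int, str]] = []
    for start, end, form in sorted(candidates, key=lambda c: (c[0] - c[1], c[0], c[2])):
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, form))
    return sorted(chosen)


def tag_sentence(sentence: Sentence, dictionary: TermDictionary) -> list[Mention]:
    """Tag every maximal dictionary match in one sentence.

    Each surviving match yields one :class:`Mention` carrying all class ids
    the matched form maps to.
    """
    if not dictionary.entries:
        raise ValueError("empty dictionary")
    mentions = []
    for start, end, form in _resolve_overlaps(
        _candidate_matches(sentence.text, dictionary)
    ):
        mentions.append(
            Mention(
                class_ids=frozenset(dictionary.entries[form]),
                category=dictionary.category,
                span=(start, end),
                surface=sentence.text[start:end],
            )
        )
    return mentions


# ---------------------------------------------------------------------------
# abbreviation detection (Schwartz–Hearst-style parenthetical alignment)
# ---------------------------------------------------------------------------

_PAREN_RE = re.compile(r"\(([^()]{1,60})\)")
SHORT_FORM_MIN_LEN = 2
SHORT_FORM_MAX_LEN = 10


def _valid_short_form(short: str) -> bool:
    if not SHORT_FORM_MIN_LEN <= len(short) <= SHORT_FORM_MAX_LEN:
        return False
    if not any(ch.isalpha() for ch in short):
        return False
    strong = sum(1 for ch in short if ch.isupper() or ch.isdigit())
    return strong * 2 >= len(short)


def _align_long_form(short: str, window: str) -> str | None:
    """Right-to-left alignment of the short form inside the candidate window.

    Every alphanumeric character of the short form must appear, in order,
    in the window; the first character must start a word.  Returns the
    aligned long form (a suffix of the window) or None.
    """
    chars = [ch.lower() for ch in short if ch.isalnum()]
    if not chars:
        return None
    w = window.lower()
    li = len(w) - 1
    si = len(chars) - 1
    while si >= 0:
        while li >= 0 and w[li] != chars[si]:
            li -= 1
        if li < 0:
            return None
        if si == 0:
            # first character must begin a word
            if li > 0 and w[li - 1].isalnum():
                li -= 1
                continue
            break
        li -= 1
        si -= 1
    return window[li:].strip() or None


def detect_abbreviations(doc: Document) -> AbbreviationMap:
    """Find "LONG FORM (SF)" patterns and record SF -> long form.

    A short-form candidate is 2–10 characters, contains a letter, and at
    least half of its characters are uppercase or digits.  The long-form
    window is the up-to-min(|SF|+5, 2|SF|) words before the parenthesis;
    the alignment requires every alphanumeric short-form character in
    order, scanning right to left.
    """
    abbrevs = AbbreviationMap()
    text = doc.text
    for match in _PAREN_RE.finditer(text):
        short = match.group(1).strip()
        if not _valid_short_form(short):
            continue
        before = text[: match.start()].rstrip()
        # window ends at the current sentence-ish boundary to avoid
        # swallowing unrelated text
        words = re.split(r"\s+", before)
        max_words = min(len(short) + 5, 2 * len(short))
        window = " ".join(words[-max_words:]) if words else ""
        window = window.strip()
        if not window:
            continue
        long_form = _align_long_form(short, window)
        if long_form and long_form.lower() != short.lower():
            abbrevs.add(short, long_form)
    return abbrevs


# ---------------------------------------------------------------------------
# disease abbreviation filter
# ---------------------------------------------------------------------------

DEFAULT_DISEASE_KEYWORDS = frozenset(
    {"disease", "disorder", "syndrome", "defect", "infection", "fever"}
)


def _looks_like_abbreviation(surface: str) -> bool:
    if not SHORT_FORM_MIN_LEN <= len(surface) <= SHORT_FORM_MAX_LEN:
        return False
    letters = [ch for ch in surface if ch.isalpha()]
    return bool(letters) and all(ch.isupper() for ch in letters)


def _contains_word(haystack: str, needle: str) -> bool:
    """Case-insensitive word-boundary substring test."""
    pattern = re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(needle.lower()).replace("\\ ", r"\s+")
        + r"(?![A-Za-z0-9])"
    )
    return bool(pattern.search(haystack.lower()))


def filter_disease_abbreviations(
    mentions: Sequence[Mention],
    abbrevs: AbbreviationMap,
    disease_dict: TermDictionary,
    doc: Document,
    keywords: Iterable[str] = DEFAULT_DISEASE_KEYWORDS,
) -> list[Mention]:
    """Drop disease mentions whose abbreviation surface lacks disease evidence.

    A disease mention with an abbreviation-shaped surface (all-caps letters,
    2–10 chars) is kept iff

    a. another dictionary surface form of one of its classes — a long form —
       occurs elsewhere in the document, or
    b. a detected parenthetical expansion of the abbreviation contains a
       disease-indicating keyword.

    Pathogen mentions and non-abbreviation disease mentions pass through
    unchanged.
    """
    keywords = {k.lower() for k in keywords}
    kept: list[Mention] = []
    for mention in mentions:
        if mention.category != "disease" or not _looks_like_abbreviation(
            mention.surface
        ):
            kept.append(mention)
            continue
        surface_key = normalize_term(mention.surface)
        keep = False
        # rule (a): a long form from the disease dictionary occurs in the doc
        for cid in mention.class_ids:
            for form in disease_dict.forms_for(cid):
                if form == surface_key:
                    continue
                if _contains_word(doc.text, form):
                    keep = True
                    break
            if keep:
                break
        # rule (b): a detected expansion names a disease-like concept
        if not keep:
            for long_form in abbrevs.long_forms(mention.surface):
                if any(_contains_word(long_form, kw) for kw in keywords):
                    keep = True
                    break
        if keep:
            kept.append(mention)
    return kept


# ---------------------------------------------------------------------------
# corpus-level drivers and JSONL round-trip
# ---------------------------------------------------------------------------


def tag_document(
    doc: Document,
    pathogen_dict: TermDictionary,
    disease_dict: TermDictionary,
    apply_abbrev_filter: bool = True,
    keywords: Iterable[str] = DEFAULT_DISEASE_KEYWORDS,
) -> list[TaggedSentence]:
    """Split, tag with both dictionaries, and (optionally) filter disease
    abbreviations using document-level context."""
    abbrevs = detect_abbreviations(doc) if apply_abbrev_filter else AbbreviationMap()
    tagged: list[TaggedSentence] = []
    for sentence in split_sentences(doc):
        mentions = tag_sentence(sentence, pathogen_dict) + tag_sentence(
            sentence, disease_dict
        )
        if apply_abbrev_filter:
            mentions = filter_disease_abbreviations(
                mentions, abbrevs, disease_dict, doc, keywords
            )
        tagged.append(TaggedSentence(sentence=sentence, mentions=sorted(
            mentions, key=lambda m: (m.span, m.category)
        )))
    return tagged


def tag_corpus(
    docs: Iterable[Document],
    pathogen_dict: TermDictionary,
    disease_dict: TermDictionary,
    apply_abbrev_filter: bool = True,
) -> Iterator[TaggedSentence]:
    for doc in docs:
        yield from tag_document(
            doc, pathogen_dict, disease_dict, apply_abbrev_filter
        )


def read_corpus(path: Union[str, Path]) -> list[Document]:
    """Load a corpus: a JSONL file (fields: id, text) or a directory of
    ``.txt`` files whose filenames are document ids."""
    path = Path(path)
    docs: list[Document] = []
    if path.is_dir():
        for txt in sorted(path.glob("*.txt")):
            docs.append(Document(doc_id=txt.stem, text=txt.read_text()))
    else:
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line:
                    continue
                record = json.loads(line)
                docs.append(Document(doc_id=str(record["id"]), text=record["text"]))
    seen: set[str] = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id: {doc.doc_id}")
        seen.add(doc.doc_id)
    return docs


def write_tagged_jsonl(
    tagged: Iterable[TaggedSentence], path: Union[str, Path]
) -> None:
    with open(path, "w") as handle:
        for ts in tagged:
            record = {
                "doc_id": ts.sentence.doc_id,
                "sent_index": ts.sentence.index,
                "text": ts.sentence.text,
                "char_offset": ts.sentence.char_offset,
                "mentions": [
                    {
                        "class_ids": sorted(m.class_ids),
                        "category": m.category,
                        "start": m.span[0],
                        "end": m.span[1],
                        "surface": m.surface,
                    }
                    for m in ts.mentions
                ],
            }
            handle.write(json.dumps(record, sort_keys=True) + "\n")


def read_tagged_jsonl(path: Union[str, Path]) -> list[TaggedSentence]:
    tagged: list[TaggedSentence] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            record = json.loads(line)
            sentence = Sentence(
                doc_id=record["doc_id"],
                index=record["sent_index"],
                text=record["text"],
                char_offset=record["char_offset"],
            )
            mentions = [
                Mention(
                    class_ids=frozenset(m["class_ids"]),
                    category=m["category"],
                    span=(m["start"], m["end"]),
                    surface=m["surface"],
                )
                for m in record["mentions"]
            ]
            tagged.append(TaggedSentence(sentence=sentence, mentions=mentions))
    return tagged
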