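"""Dictionary construction: refined surface-form -> class-id indexes.

A :class:`TermDictionary` maps every usable label or synonym from an
ontology branch to the set of classes it can denote.  Refinement removes
terms shorter than a minimum length (3 characters by default) and terms
that collide with common English words or geographic names (the stoplist).

Normalization policy: surface forms are whitespace-trimmed, internal runs
of whitespace are collapsed, and the form is lowercased — EXCEPT all-
uppercase forms of at most 5 characters ("ALS", "SARS"), which are stored
and matched case-sensitively so that short abbreviations do not swallow
ordinary words.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Union

from .ontology import Ontology

__all__ = [
    "TermDictionary",
    "RefinementConfig",
    "refine_terms",
    "build_dictionary",
    "normalize_term",
    "is_case_sensitive_form",
    "load_stoplist",
    "default_stoplist",
    "DictionaryError",
]

CATEGORIES = ("pathogen", "disease")

# all-caps forms up to this length keep their case (abbreviation guard)
CASE_SENSITIVE_MAX_LEN = 5

_WS_RE = re.compile(r"\s+")


class DictionaryError(ValueError):
    """Raised for misconfigured dictionary builds (empty branch / result)."""


def _collapse(term: str) -> str:
    return _WS_RE.sub(" ", term.strip())


def is_case_sensitive_form(term: str) -> bool:
    """All-uppercase forms of <= 5 characters are matched with exact case."""
    collapsed = _collapse(term)
    return (
        0 < len(collapsed) <= CASE_SENSITIVE_MAX_LEN
        and collapsed.isupper()
    )


def normalize_term(term: str) -> str:
    """Dictionary-key normalization: trim, collapse whitespace, lowercase
    (case preserved for short all-uppercase abbreviations)."""
    collapsed = _collapse(term)
    if is_case_sensitive_form(collapsed):
        return collapsed
    return collapsed.lower()


def load_stoplist(source: Union[str, Path, IO[str]]) -> set[str]:
    """Read a stoplist file: one term per line, ``#`` comments allowed."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    stop: set[str] = set()
    for line in lines:
        entry = line.split("#", 1)[0].strip()
        if entry:
            stop.add(_collapse(entry).lower())
    return stop


@lru_cache(maxsize=1)
def _packaged_stoplist() -> frozenset[str]:
    ref = resources.files("padminer.data").joinpath("stoplist.txt")
    with ref.open("r") as handle:
        return frozenset(load_stoplist(handle))


def default_stoplist() -> set[str]:
    """The packaged common-English + geographic stoplist."""
    return set(_packaged_stoplist())


def refine_terms(
    terms: Iterable[str], min_length: int = 3, stoplist: Iterable[str] | None = None
) -> set[str]:
    """Filter a term set: drop terms shorter than ``min_length`` characters
    (after trimming) and terms whose normalized lowercase form is in the
    stoplist.  Returns a subset of the input, unchanged strings."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    stop = {_collapse(s).lower() for s in (stoplist or ())}
    kept: set[str] = set()
    for term in terms:
        collapsed = _collapse(term)
        if len(collapsed) < min_length:
            continue
        if collapsed.lower() in stop:
            continue
        kept.add(term)
    return kept


@dataclass
class RefinementConfig:
    """Settings applied when building a dictionary from an ontology branch."""

    min_length: int = 3
    stoplist: set[str] = field(default_factory=default_stoplist)


@dataclass
class TermDictionary:
    """Refined surface-form -> class-id index for one entity category.

    ``entries`` is keyed by normalized form; a form shared by several
    classes maps to all of them (ambiguity is preserved and resolved
    downstream by per-class counting).  ``case_sensitive_forms`` lists the
    keys that must be matched with exact case.
    """

    category: str
    entries: dict[str, set[str]] = field(default_factory=dict)
    case_sensitive_forms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, surface: str, class_id: str) -> None:
        key = normalize_term(surface)
        if not key:
            return
        self.entries.setdefault(key, set()).add(class_id)
        if is_case_sensitive_form(key):
            self.case_sensitive_forms.add(key)

    def lookup(self, surface: str) -> set[str]:
        """Class ids for a surface form under the matching case policy."""
        collapsed = _collapse(surface)
        if collapsed in self.case_sensitive_forms:
            return set(self.entries[collapsed])
        return set(self.entries.get(collapsed.lower(), ()))

    def class_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.entries.values():
            out |= ids
        return out

    def forms_for(self, class_id: str) -> set[str]:
        """All normalized surface forms mapped to ``class_id``."""
        return {form for form, ids in self.entries.items() if class_id in ids}

    # ---- TSV round-trip -------------------------------------------------

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write one (surface_form, class_id) row per pair."""
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            for form in sorted(self.entries):
                for cid in sorted(self.entries[form]):
                    writer.writerow([form, cid])

    @classmethod
    def from_tsv(cls, path: Union[str, Path], category: str) -> "TermDictionary":
        dictionary = cls(category=category)
        with open(path, newline="") as handle:
            for row in csv.reader(handle, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                dictionary.add(row[0], row[1])
        return dictionary


def build_dictionary(
    ontology: Ontology,
    branch: Iterable[str],
    category: str,
    config: RefinementConfig | None = None,
) -> TermDictionary:
    """Build a refined dictionary from the classes in ``branch``.

    Every label and synonym of every non-obsolete class in the branch that
    survives :func:`refine_terms` is indexed under its normalized form.
    """
    config = config or RefinementConfig()
    branch = set(branch)
    if not branch:
        raise DictionaryError("empty branch: no classes to index")
    unknown = branch - set(ontology.classes)
    if unknown:
        raise DictionaryError(f"branch ids not in ontology: {sorted(unknown)[:5]}")

    dictionary = TermDictionary(category=category)
    for cid in sorted(branch):
        cls = ontology.classes[cid]
        if cls.obsolete:
            continue
        for term in refine_terms(cls.labels(), config.min_length, config.stoplist):
            dictionary.add(term, cid)
    if not dictionary.entries:
        raise DictionaryError(
            "refinement removed every term; check branch roots and stoplist"
        )
    return dictionary
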