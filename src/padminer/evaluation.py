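"""Evaluation of extracted associations against reference pair lists.

Supports per-resource recall (how many curated pairs the miner recovers),
Venn-style overlap partitions between several pair sets, and standard
precision/recall/F1 over a manually labeled sample.  Matching is at the
exact-class level: an extracted subclass association earns no credit for a
reference pair stated at the superclass.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "ReferenceSet",
    "EvaluationResult",
    "read_reference_tsv",
    "recall_against",
    "overlap_partition",
    "score_labeled_sample",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class ReferenceSet:
    """A named, manually curated set of (pathogen id, disease id) pairs."""

    name: str
    pairs: frozenset[Pair]


def read_reference_tsv(path: Union[str, Path], name: str | None = None) -> ReferenceSet:
    """Read a reference list: two tab-separated CURIEs per line, ``#``
    comments allowed."""
    path = Path(path)
    pairs: set[Pair] = set()
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            pairs.add((row[0].strip(), row[1].strip()))
    return ReferenceSet(name=name or path.stem, pairs=frozenset(pairs))


def recall_against(
    extracted: Iterable[Pair], reference: ReferenceSet
) -> tuple[float, set[Pair], set[Pair]]:
    """Recall of the extraction against one reference resource.

    Returns ``(recall, found, missed)`` where found/missed partition the
    reference pairs.
    """
    if not reference.pairs:
        raise ValueError(f"reference set {reference.name!r} is empty")
    extracted = set(extracted)
    found = set(reference.pairs) & extracted
    missed = set(reference.pairs) - extracted
    return len(found) / len(reference.pairs), found, missed


def overlap_partition(
    sets: Mapping[str, Iterable[Pair]]
) -> dict[frozenset[str], int]:
    """Exact-membership partition of several named pair sets.

    Maps each non-empty membership signature (the set of names a pair
    belongs to) to the number of pairs with exactly that signature; counts
    sum to the size of the union.
    """
    if len(sets) < 2:
        raise ValueError("overlap_partition needs at least two sets")
    materialized = {name: set(pairs) for name, pairs in sets.items()}
    union: set[Pair] = set().union(*materialized.values())
    partition: dict[frozenset[str], int] = {}
    for pair in union:
        signature = frozenset(
            name for name, pairs in materialized.items() if pair in pairs
        )
        partition[signature] = partition.get(signature, 0) + 1
    return partition


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts and derived metrics for a labeled sample."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_score: float


def _safe_ratio(num: int, den: int, metric: str) -> float:
    if den == 0:
        warnings.warn(f"{metric} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def score_labeled_sample(
    predictions: Iterable[tuple[Pair, bool]],
    labels: Iterable[tuple[Pair, bool]],
) -> EvaluationResult:
    """Precision/recall/F1 from system accept/reject decisions and manual
    true-association labels; every prediction must be labeled."""
    label_map = dict(labels)
    tp = fp = fn = tn = 0
    for pair, accepted in predictions:
        if pair not in label_map:
            raise ValueError(f"prediction {pair} has no label")
        truth = label_map[pair]
        if accepted and truth:
            tp += 1
        elif accepted and not truth:
            fp += 1
        elif not accepted and truth:
            fn += 1
        else:
            tn += 1
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f_score = math.nan
        if not (math.isnan(precision) or math.isnan(recall)):
            warnings.warn("F-score undefined (precision + recall = 0); reporting NaN")
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return EvaluationResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f_score=f_score,
    )
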