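"""Ontology-propagated co-occurrence counting and class-level NPMI scoring.

A sentence enters the counting space when it mentions at least one pathogen
and at least one disease class; ``n_tot`` is the size of that space.  Every
mentioned class contributes, once per sentence, to its own count and to the
count of every ancestor (subsumption propagation — counting a mention of a
subclass toward all superclasses is equivalent to matching the expanded
term set Terms(C) directly, because Terms(C) is the union of labels over
the subclass closure).  The association strength of a (pathogen C,
disease D) pair is the normalized pointwise mutual information

    npmi(C, D) = log( n_CD * n_tot / (n_C * n_D) ) / ( -log( n_CD / n_tot ) )

which lies in [-1, 1]: 1 for perfect collocation, 0 for independence, -1
for never co-occurring.  Accepted associations must exceed an NPMI
threshold (default 0.2, strict) and reach a minimum co-occurrence count
(default 10, inclusive).  An association is *direct* when at least one
evidence sentence mentions both classes by their own labels; otherwise it
is inferred through the ontology (*indirect*).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .ontology import Ontology, UnknownClassError
from .tagger import TaggedSentence

__all__ = [
    "CooccurrenceCounts",
    "Association",
    "count_cooccurrences",
    "npmi",
    "npmi_from_counts",
    "extract_associations",
    "passes_thresholds",
    "classify_direct",
    "write_associations_tsv",
    "read_associations_tsv",
    "write_associations_ntriples",
    "DEFAULT_NPMI_THRESHOLD",
    "DEFAULT_COUNT_THRESHOLD",
]

DEFAULT_NPMI_THRESHOLD = 0.2
DEFAULT_COUNT_THRESHOLD = 10

Pair = tuple[str, str]


@dataclass
class CooccurrenceCounts:
    """Sentence-level counts over the co-occurrence space.

    ``n_tot`` counts sentences with >= 1 pathogen and >= 1 disease mention.
    ``n_c``/``n_d``/``n_cd`` are ancestor-propagated per-class and per-pair
    sentence counts; ``evidence`` maps a pair to its contributing
    (doc_id, sent_index) locations; ``direct_pairs`` holds the pairs with at
    least one sentence mentioning both classes by their own labels.
    """

    n_tot: int = 0
    n_c: dict[str, int] = field(default_factory=dict)
    n_d: dict[str, int] = field(default_factory=dict)
    n_cd: dict[Pair, int] = field(default_factory=dict)
    evidence: dict[Pair, list[tuple[str, int]]] = field(default_factory=dict)
    direct_pairs: set[Pair] = field(default_factory=set)


def _propagated(
    class_ids: Iterable[str], ontology: Ontology, roots: set[str] | None
) -> set[str]:
    """Ancestor-or-self closure of the mentioned classes.

    When ``roots`` is given, propagation is capped at the branch roots:
    only ancestors inside the branch (descendants of some root) are kept,
    so counts never aggregate up to vacuous top-level classes.
    """
    out: set[str] = set()
    for cid in class_ids:
        out |= ontology.ancestors(cid)
    if roots is not None:
        in_branch: set[str] = set()
        for rid in roots:
            in_branch |= ontology.descendants(rid)
        out &= in_branch
    return out


def count_cooccurrences(
    tagged: Iterable[TaggedSentence],
    pathogen_ontology: Ontology,
    disease_ontology: Ontology,
    pathogen_roots: set[str] | None = None,
    disease_roots: set[str] | None = None,
    whole_corpus_marginals: bool = False,
) -> CooccurrenceCounts:
    """Accumulate n_tot, n_C, n_D and n_CD from a tagged sentence stream.

    Counting uses set semantics: a class mentioned several times in one
    sentence counts once, and each pair collects each sentence once.  By
    default the marginals n_C and n_D are counted within the same
    co-occurrence space as n_tot, which keeps every ratio in the NPMI
    formula a probability; ``whole_corpus_marginals=True`` instead counts
    them over every sentence with a mention of that category.
    """
    shared = pathogen_ontology.curie_prefixes() & disease_ontology.curie_prefixes()
    if shared:
        raise ValueError(
            f"pathogen and disease ontologies share CURIE prefixes: {sorted(shared)}"
        )

    counts = CooccurrenceCounts()
    for ts in tagged:
        patho_direct: set[str] = set()
        dis_direct: set[str] = set()
        for mention in ts.mentions:
            if mention.category == "pathogen":
                for cid in mention.class_ids:
                    if cid not in pathogen_ontology:
                        raise UnknownClassError(cid)
                patho_direct |= mention.class_ids
            else:
                for cid in mention.class_ids:
                    if cid not in disease_ontology:
                        raise UnknownClassError(cid)
                dis_direct |= mention.class_ids

        patho_up = _propagated(patho_direct, pathogen_ontology, pathogen_roots)
        dis_up = _propagated(dis_direct, disease_ontology, disease_roots)
        in_space = bool(patho_up) and bool(dis_up)

        if whole_corpus_marginals:
            for c in patho_up:
                counts.n_c[c] = counts.n_c.get(c, 0) + 1
            for d in dis_up:
                counts.n_d[d] = counts.n_d.get(d, 0) + 1
        elif in_space:
            for c in patho_up:
                counts.n_c[c] = counts.n_c.get(c, 0) + 1
            for d in dis_up:
                counts.n_d[d] = counts.n_d.get(d, 0) + 1

        if not in_space:
            continue
        counts.n_tot += 1
        where = (ts.sentence.doc_id, ts.sentence.index)
        for c in patho_up:
            for d in dis_up:
                pair = (c, d)
                counts.n_cd[pair] = counts.n_cd.get(pair, 0) + 1
                counts.evidence.setdefault(pair, []).append(where)
                if c in patho_direct and d in dis_direct:
                    counts.direct_pairs.add(pair)
    return counts


def npmi_from_counts(n_tot: int, n_c: int, n_d: int, n_cd: int) -> float:
    """Normalized pointwise mutual information from raw sentence counts.

    The continuous limits are honoured: ``n_cd == 0`` gives -1 and
    ``n_cd == n_tot`` gives +1.  The logarithm base cancels.
    """
    if n_tot <= 0:
        raise ValueError("empty counting space (n_tot = 0)")
    if n_c < 1 or n_d < 1:
        raise ValueError("npmi requires n_C >= 1 and n_D >= 1")
    if n_cd < 0 or n_cd > n_tot:
        raise ValueError("n_CD must lie in [0, n_tot]")
    if n_cd == 0:
        return -1.0
    if n_cd == n_tot:
        return 1.0
    pmi = math.log(n_cd * n_tot / (n_c * n_d))
    return pmi / (-math.log(n_cd / n_tot))


def npmi(counts: CooccurrenceCounts, pathogen_id: str, disease_id: str) -> float:
    """NPMI of one (pathogen class, disease class) pair from accumulated counts."""
    return npmi_from_counts(
        counts.n_tot,
        counts.n_c.get(pathogen_id, 0),
        counts.n_d.get(disease_id, 0),
        counts.n_cd.get((pathogen_id, disease_id), 0),
    )


@dataclass(frozen=True)
class Association:
    """A scored, accepted pathogen–disease pair."""

    pathogen_id: str
    disease_id: str
    npmi: float
    count: int
    direct: bool
    evidence: tuple[tuple[str, int], ...]


def classify_direct(
    pair: Pair,
    counts: CooccurrenceCounts,
    pathogen_ontology: Ontology | None = None,
    disease_ontology: Ontology | None = None,
) -> bool:
    """True iff some evidence sentence mentions both classes by their own
    labels (before ancestor propagation); False when the pair is reached
    only through proper subclasses."""
    if pair not in counts.evidence:
        raise ValueError(f"pair {pair} has no evidence")
    return pair in counts.direct_pairs


def passes_thresholds(
    score: float,
    count: int,
    npmi_threshold: float = DEFAULT_NPMI_THRESHOLD,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
) -> bool:
    """Acceptance predicate: NPMI strictly above the threshold ("above 0.2"
    is read strictly) and count at least the minimum ("at least 10 times"
    is inclusive)."""
    return count >= count_threshold and score > npmi_threshold


def extract_associations(
    counts: CooccurrenceCounts,
    npmi_threshold: float = DEFAULT_NPMI_THRESHOLD,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
) -> list[Association]:
    """Apply the acceptance thresholds to every counted pair.

    A pair is accepted iff its co-occurrence count is at least
    ``count_threshold`` (inclusive) and its NPMI is strictly greater than
    ``npmi_threshold``.  Output is sorted by NPMI descending, then by
    pathogen and disease id, for deterministic downstream artifacts.
    """
    if not (math.isfinite(npmi_threshold) and count_threshold >= 1):
        raise ValueError("thresholds must be finite and count_threshold >= 1")
    accepted: list[Association] = []
    for pair, n_cd in counts.n_cd.items():
        if n_cd < count_threshold:
            continue
        score = npmi(counts, *pair)
        if passes_thresholds(score, n_cd, npmi_threshold, count_threshold):
            accepted.append(
                Association(
                    pathogen_id=pair[0],
                    disease_id=pair[1],
                    npmi=score,
                    count=n_cd,
                    direct=classify_direct(pair, counts),
                    evidence=tuple(counts.evidence[pair]),
                )
            )
    accepted.sort(key=lambda a: (-a.npmi, a.pathogen_id, a.disease_id))
    return accepted


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_TSV_HEADER = [
    "pathogen_id",
    "pathogen_label",
    "disease_id",
    "disease_label",
    "npmi",
    "n_CD",
    "n_C",
    "n_D",
    "direct",
    "evidence",
]


def write_associations_tsv(
    associations: Iterable[Association],
    counts: CooccurrenceCounts,
    pathogen_ontology: Ontology,
    disease_ontology: Ontology,
    path: Union[str, Path],
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for a in associations:
            writer.writerow(
                [
                    a.pathogen_id,
                    pathogen_ontology[a.pathogen_id].label,
                    a.disease_id,
                    disease_ontology[a.disease_id].label,
                    f"{a.npmi:.6f}",
                    a.count,
                    counts.n_c.get(a.pathogen_id, 0),
                    counts.n_d.get(a.disease_id, 0),
                    "true" if a.direct else "false",
                    ";".join(f"{doc}:{sent}" for doc, sent in a.evidence),
                ]
            )


def read_associations_tsv(path: Union[str, Path]) -> list[dict]:
    with open(path, newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


def write_associations_ntriples(
    associations: Iterable[Association], path: Union[str, Path]
) -> None:
    """Export associations as RDF N-Triples (one node per association with
    pathogen/disease references and score/count literals)."""
    from rdflib import BNode, Graph, Literal, Namespace, RDF, URIRef
    from rdflib.namespace import XSD

    PDM = Namespace("https://padminer.example.org/vocab#")
    OBO = Namespace("http://purl.obolibrary.org/obo/")
    graph = Graph()
    for a in associations:
        node = BNode()
        graph.add((node, RDF.type, PDM.PathogenDiseaseAssociation))
        graph.add((node, PDM.pathogen, URIRef(OBO + a.pathogen_id.replace(":", "_"))))
        graph.add((node, PDM.disease, URIRef(OBO + a.disease_id.replace(":", "_"))))
        graph.add((node, PDM.npmi, Literal(round(a.npmi, 6), datatype=XSD.double)))
        graph.add((node, PDM.cooccurrenceCount, Literal(a.count, datatype=XSD.integer)))
        graph.add((node, PDM.direct, Literal(a.direct, datatype=XSD.boolean)))
    graph.serialize(destination=str(path), format="nt", encoding="utf-8")
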