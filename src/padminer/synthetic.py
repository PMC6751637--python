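"""Seeded synthetic ontologies and corpora with planted associations.

The generator emulates the statistical structure the mining pipeline is
built to detect: a corpus in which a few pathogen–disease pairs co-occur
far more often than independence predicts, against a background of
independent decoy co-occurrences and single-category sentences.  Every
artifact is deterministic under its seed, so fixtures never need to be
shipped or downloaded.

Semantics of the planted probabilities: each generated sentence is a
*co-occurrence carrier* with probability ``cooccurrence_rate``.  Given a
carrier, planted pair *i* is realised with probability
``joint_probability_i`` (so joint probabilities are conditional on the
co-occurrence sentence space and must sum to at most 1); the remaining
carrier mass emits a decoy — an independently, uniformly sampled
(pathogen, disease) pair that was never planted.  Consequently the
empirical ``n_CD / n_tot`` of a planted pair is a consistent estimator of
its configured joint probability.  Non-carrier sentences mention at most
one category (at ``background_rate`` per category) or are plain filler, so
the co-occurrence space is exactly the carrier set.

Pairs planted with ``via_subclasses_only`` are realised exclusively through
labels of proper subclasses, producing associations that are recoverable at
the planted class only through ontology propagation (direct = False).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

from .lexicon import default_stoplist
from .ontology import Ontology, parse_obo

__all__ = [
    "PlantedPair",
    "SyntheticSpec",
    "GroundTruth",
    "generate_ontologies",
    "generate_corpus",
    "write_fixture",
]

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"

_CARRIER_FRAMES = (
    "{P} was isolated from patients with {D}.",
    "Infection with {P} frequently causes {D}.",
    "{D} in the cohort was attributed to {P}.",
    "Cases of {D} were linked to {P} exposure.",
)
_PATHOGEN_FRAMES = (
    "Samples of {P} were cultured from the isolates.",
    "The assay detected {P} in three specimens.",
)
_DISEASE_FRAMES = (
    "Several participants presented with {D}.",
    "Clinical records documented {D} in the ward.",
)
_FILLER_FRAMES = (
    "The cohort completed the follow-up without further findings.",
    "Laboratory workflows were standardized across sites.",
    "Ethical approval was obtained before enrollment.",
    "Statistical analyses were performed on the pooled records.",
)

_AMBIGUOUS_SYNONYMS = ("arabia", "congo", "major", "cold")


@dataclass(frozen=True)
class PlantedPair:
    """One planted association and its conditional joint probability."""

    pathogen_id: str
    disease_id: str
    joint_probability: float
    via_subclasses_only: bool = False


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe a small but non-trivial corpus: two 12-class
    ontologies of depth <= 3, 2000 sentences of which ~30% are
    pathogen+disease carriers, four planted pairs (one reachable only via
    subclasses), and independent decoys filling the remaining carrier mass.
    """

    n_pathogen_classes: int = 12
    n_disease_classes: int = 12
    max_depth: int = 3
    n_sentences: int = 2000
    planted_pairs: list[PlantedPair] | None = None  # None -> default layout
    cooccurrence_rate: float = 0.3
    background_rate: float = 0.15
    abbreviation_rate: float = 0.3
    ambiguity_rate: float = 0.0
    synonym_use_rate: float = 0.3
    subclass_use_rate: float = 0.25
    sentences_per_doc: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathogen_classes < 2 or self.n_disease_classes < 2:
            raise ValueError("need at least 2 classes per ontology")
        for rate in (
            self.cooccurrence_rate,
            self.background_rate,
            self.abbreviation_rate,
            self.ambiguity_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted where: pair-level and sentence-level annotations."""

    planted: list[dict] = field(default_factory=list)
    sentences: list[dict] = field(default_factory=list)

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(p["pathogen_id"], p["disease_id"]) for p in self.planted}

    def to_json(self) -> str:
        return json.dumps(
            {"planted": self.planted, "sentences": self.sentences}, indent=1
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls(planted=data["planted"], sentences=data["sentences"])


# ---------------------------------------------------------------------------
# ontology generation
# ---------------------------------------------------------------------------


def _word(rng: random.Random, n_syllables: int, taken: set[str]) -> str:
    stop = default_stoplist()
    while True:
        word = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
            for _ in range(n_syllables)
        )
        if word not in taken and word not in stop:
            taken.add(word)
            return word


def _label(rng: random.Random, taken: set[str]) -> str:
    return f"{_word(rng, 3, taken)} {_word(rng, rng.randint(2, 3), taken)}"


def _acronym(label: str, taken: set[str]) -> str | None:
    words = label.split()
    base = (words[0][0] + words[1][0] + words[1][1]).upper()
    for extra in ("", words[0][1].upper(), words[1][2].upper()):
        candidate = base + extra
        if candidate not in taken and len(candidate) <= 5:
            taken.add(candidate)
            return candidate
    return None


def _generate_tree(
    rng: random.Random,
    prefix: str,
    n_classes: int,
    max_depth: int,
    with_acronyms: bool,
    abbreviation_rate: float,
    ambiguity_rate: float,
    taken_words: set[str],
    taken_acronyms: set[str],
    ontology_name: str,
    seed: int,
) -> str:
    ids = [f"{prefix}:{i:07d}" for i in range(1, n_classes + 1)]
    depth = {ids[0]: 0}
    parent: dict[str, str] = {}
    for cid in ids[1:]:
        eligible = [i for i in depth if depth[i] < max_depth]
        chosen = rng.choice(sorted(eligible))
        parent[cid] = chosen
        depth[cid] = depth[chosen] + 1

    lines = [
        "format-version: 1.2",
        f"ontology: synthetic-{ontology_name}",
        f"remark: synthetic {ontology_name} ontology (seed={seed})",
        "",
    ]
    for cid in ids:
        label = _label(rng, taken_words)
        synonyms = []
        for _ in range(rng.randint(0, 2)):
            if rng.random() < ambiguity_rate:
                synonyms.append(rng.choice(_AMBIGUOUS_SYNONYMS))
            else:
                synonyms.append(_word(rng, rng.randint(3, 4), taken_words))
        if with_acronyms and rng.random() < abbreviation_rate:
            acro = _acronym(label, taken_acronyms)
            if acro:
                synonyms.append(acro)
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        lines.append(f"name: {label}")
        for syn in synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        if cid in parent:
            lines.append(f"is_a: {parent[cid]}")
        lines.append("")
    return "\n".join(lines)


def generate_ontologies(spec: SyntheticSpec) -> tuple[str, str]:
    """Emit (pathogen OBO text, disease OBO text); byte-stable under seed."""
    rng = random.Random(f"{spec.seed}:ontologies")
    taken_words: set[str] = set()
    taken_acronyms: set[str] = set()
    pathogen = _generate_tree(
        rng, "PATH", spec.n_pathogen_classes, spec.max_depth,
        with_acronyms=False, abbreviation_rate=0.0,
        ambiguity_rate=spec.ambiguity_rate,
        taken_words=taken_words, taken_acronyms=taken_acronyms,
        ontology_name="pathogen", seed=spec.seed,
    )
    disease = _generate_tree(
        rng, "DIS", spec.n_disease_classes, spec.max_depth,
        with_acronyms=True, abbreviation_rate=spec.abbreviation_rate,
        ambiguity_rate=spec.ambiguity_rate,
        taken_words=taken_words, taken_acronyms=taken_acronyms,
        ontology_name="disease", seed=spec.seed,
    )
    return pathogen, disease


# ---------------------------------------------------------------------------
# planted-pair defaults
# ---------------------------------------------------------------------------


def default_planted_pairs(
    pathogen_ontology: Ontology, disease_ontology: Ontology
) -> list[PlantedPair]:
    """Deterministic default layout: three leaf pairs of decreasing joint
    probability plus one internal pair planted only via subclasses.

    The internal pair is chosen first and the direct-pair leaves are taken
    from outside its subtrees where possible, so the indirect signal is not
    diluted by the marginal counts of the other planted pairs.
    """

    def leaves(onto: Ontology) -> list[str]:
        having_children = {p for c in onto.classes.values() for p in c.parents}
        return sorted(i for i in onto.classes if i not in having_children)

    def internal(onto: Ontology) -> list[str]:
        having_children = {p for c in onto.classes.values() for p in c.parents}
        return sorted(having_children - onto.roots)

    p_internal, d_internal = internal(pathogen_ontology), internal(disease_ontology)
    pairs: list[PlantedPair] = []
    p_excluded: set[str] = set()
    d_excluded: set[str] = set()
    if p_internal and d_internal:
        # smallest subtree keeps the internal pair's marginals tight so the
        # propagated signal is not diluted by its own branch
        p_int = min(p_internal, key=lambda i: (len(pathogen_ontology.descendants(i)), i))
        d_int = min(d_internal, key=lambda i: (len(disease_ontology.descendants(i)), i))
        pairs.append(PlantedPair(p_int, d_int, 0.07, True))
        p_excluded = pathogen_ontology.descendants(p_int)
        d_excluded = disease_ontology.descendants(d_int)

    def pick(pool: list[str], excluded: set[str], k: int) -> list[str]:
        free = [x for x in pool if x not in excluded]
        chosen = free[:k]
        used = set(chosen)
        for x in pool:  # fall back to excluded leaves on tiny ontologies
            if len(chosen) == k:
                break
            if x not in used:
                chosen.append(x)
                used.add(x)
        while len(chosen) < k:  # degenerate: reuse leaves
            chosen.append(pool[len(chosen) % len(pool)])
        return chosen

    p_pick = pick(leaves(pathogen_ontology), p_excluded, 3)
    d_pick = pick(leaves(disease_ontology), d_excluded, 3)
    for (p, d), prob in zip(zip(p_pick, d_pick), (0.08, 0.06, 0.05)):
        pairs.append(PlantedPair(p, d, prob))
    return pairs


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def _surface_forms(onto: Ontology, cid: str) -> list[str]:
    """Label plus non-acronym synonyms, deterministic order."""
    cls = onto.classes[cid]
    forms = [cls.label] + sorted(s for s in cls.synonyms if not s.isupper())
    return [f for f in forms if f]


def _acronym_of(onto: Ontology, cid: str) -> str | None:
    for syn in sorted(onto.classes[cid].synonyms):
        if syn.isupper():
            return syn
    return None


def _pick_surface(
    rng: random.Random,
    onto: Ontology,
    cid: str,
    via_subclasses_only: bool,
    subclass_use_rate: float,
    synonym_use_rate: float,
) -> tuple[str, str]:
    """Choose (realised class id, surface string) for a planted class."""
    proper = sorted(onto.descendants(cid) - {cid})
    if via_subclasses_only:
        if not proper:
            raise ValueError(f"{cid} has no proper subclasses to plant through")
        realised = rng.choice(proper)
    elif proper and rng.random() < subclass_use_rate:
        realised = rng.choice(proper)
    else:
        realised = cid
    forms = _surface_forms(onto, realised)
    if len(forms) > 1 and rng.random() < synonym_use_rate:
        return realised, rng.choice(forms[1:])
    return realised, forms[0]


def generate_corpus(
    spec: SyntheticSpec, ontologies: tuple[str, str]
) -> tuple[str, GroundTruth]:
    """Emit the corpus as JSONL text plus its ground truth.

    Sentences are drawn independently per the module-level semantics and
    grouped into documents of ``sentences_per_doc``.
    """
    pathogen_onto = parse_obo(ontologies[0])
    disease_onto = parse_obo(ontologies[1])
    planted = spec.planted_pairs
    if planted is None:
        planted = default_planted_pairs(pathogen_onto, disease_onto)
    total_joint = sum(p.joint_probability for p in planted)
    if total_joint > 1.0 + 1e-9:
        raise ValueError("planted joint probabilities sum to more than 1")
    for pair in planted:
        if pair.pathogen_id not in pathogen_onto:
            raise ValueError(f"planted pair references unknown {pair.pathogen_id}")
        if pair.disease_id not in disease_onto:
            raise ValueError(f"planted pair references unknown {pair.disease_id}")
    planted_keys = {(p.pathogen_id, p.disease_id) for p in planted}

    rng = random.Random(f"{spec.seed}:corpus")
    all_pathogens = sorted(pathogen_onto.classes)
    all_diseases = sorted(disease_onto.classes)

    truth = GroundTruth(
        planted=[
            {
                "pathogen_id": p.pathogen_id,
                "disease_id": p.disease_id,
                "joint_probability": p.joint_probability,
                "expected_direct": not p.via_subclasses_only,
            }
            for p in planted
        ]
    )

    sentence_texts: list[str] = []
    annotations: list[dict] = []
    for _ in range(spec.n_sentences):
        u = rng.random()
        if u < spec.cooccurrence_rate:
            v = rng.random()
            kind = "decoy"
            chosen: PlantedPair | None = None
            cum = 0.0
            for pair in planted:
                cum += pair.joint_probability
                if v < cum:
                    chosen = pair
                    kind = "planted"
                    break
            if chosen is not None:
                p_real, p_surface = _pick_surface(
                    rng, pathogen_onto, chosen.pathogen_id,
                    chosen.via_subclasses_only,
                    spec.subclass_use_rate, spec.synonym_use_rate,
                )
                d_real, d_surface = _pick_surface(
                    rng, disease_onto, chosen.disease_id,
                    chosen.via_subclasses_only,
                    spec.subclass_use_rate, spec.synonym_use_rate,
                )
            else:
                while True:
                    p_real = rng.choice(all_pathogens)
                    d_real = rng.choice(all_diseases)
                    if (p_real, d_real) not in planted_keys:
                        break
                p_surface = _surface_forms(pathogen_onto, p_real)[0]
                d_surface = _surface_forms(disease_onto, d_real)[0]
            acro = _acronym_of(disease_onto, d_real)
            if acro and rng.random() < 0.5:
                d_surface = f"{disease_onto.classes[d_real].label} ({acro})"
            frame = rng.choice(_CARRIER_FRAMES)
            text = frame.format(P=p_surface, D=d_surface)
            # sentences must start uppercase or the splitter merges them
            text = text[0].upper() + text[1:]
            annotations.append(
                {"kind": kind, "pathogen_ids": [p_real], "disease_ids": [d_real]}
            )
        elif u < spec.cooccurrence_rate + spec.background_rate:
            p_real = rng.choice(all_pathogens)
            text = rng.choice(_PATHOGEN_FRAMES).format(
                P=_surface_forms(pathogen_onto, p_real)[0]
            )
            annotations.append(
                {"kind": "background", "pathogen_ids": [p_real], "disease_ids": []}
            )
        elif u < spec.cooccurrence_rate + 2 * spec.background_rate:
            d_real = rng.choice(all_diseases)
            text = rng.choice(_DISEASE_FRAMES).format(
                D=_surface_forms(disease_onto, d_real)[0]
            )
            annotations.append(
                {"kind": "background", "pathogen_ids": [], "disease_ids": [d_real]}
            )
        else:
            text = rng.choice(_FILLER_FRAMES)
            annotations.append(
                {"kind": "filler", "pathogen_ids": [], "disease_ids": []}
            )
        sentence_texts.append(text)

    lines: list[str] = []
    for start in range(0, len(sentence_texts), spec.sentences_per_doc):
        chunk = sentence_texts[start : start + spec.sentences_per_doc]
        doc_index = start // spec.sentences_per_doc
        doc_id = f"doc-{doc_index:04d}"
        for offset, annotation in enumerate(annotations[start : start + len(chunk)]):
            annotation["doc_id"] = doc_id
            annotation["sent_index"] = offset
        lines.append(
            json.dumps({"id": doc_id, "text": " ".join(chunk)}, sort_keys=True)
        )
    truth.sentences = annotations
    return "\n".join(lines) + "\n", truth


def write_fixture(spec: SyntheticSpec, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Materialize pathogen.obo, disease.obo, corpus.jsonl and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pathogen, disease = generate_ontologies(spec)
    corpus, truth = generate_corpus(spec, (pathogen, disease))
    paths = {
        "pathogen_obo": out / "pathogen.obo",
        "disease_obo": out / "disease.obo",
        "corpus": out / "corpus.jsonl",
        "truth": out / "truth.json",
        "spec": out / "spec.json",
    }
    paths["pathogen_obo"].write_text(pathogen)
    paths["disease_obo"].write_text(disease)
    paths["corpus"].write_text(corpus)
    paths["truth"].write_text(truth.to_json())
    spec_dict = asdict(spec)
    if spec.planted_pairs is not None:
        spec_dict["planted_pairs"] = [asdict(p) for p in spec.planted_pairs]
    paths["spec"].write_text(json.dumps(spec_dict, indent=1))
    return paths
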