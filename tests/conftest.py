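"""Shared fixtures: miniature ontologies, dictionaries and documents."""

from __future__ import annotations

import pytest

from padminer import (
    Document,
    TermDictionary,
    parse_obo,
)

DIAMOND_OBO = """\
format-version: 1.2
ontology: test-diamond

[Term]
id: X:1
name: top

[Term]
id: X:2
name: left
is_a: X:1

[Term]
id: X:3
name: right
is_a: X:1

[Term]
id: X:4
name: bottom
is_a: X:2
is_a: X:3
"""

DISEASE_OBO = """\
format-version: 1.2
ontology: test-disease

[Term]
id: DOID:1
name: disease

[Term]
id: DOID:2
name: infectious disease
is_a: DOID:1

[Term]
id: DOID:3
name: dengue disease
synonym: "breakbone fever" EXACT []
is_a: DOID:2

[Term]
id: DOID:4
name: dengue hemorrhagic fever
is_a: DOID:3

[Term]
id: DOID:5
name: dengue shock syndrome
is_a: DOID:3

[Term]
id: DOID:6
name: amyotrophic lateral sclerosis
synonym: "ALS" EXACT []
is_a: DOID:1

[Term]
id: DOID:7
name: severe acute respiratory syndrome
synonym: "SARS" EXACT []
is_a: DOID:2

[Term]
id: DOID:8
name: necrotizing ulcerative gingivitis
is_a: DOID:1

[Term]
id: DOID:9
name: old plague name
is_obsolete: true
is_a: DOID:2
"""

PATHOGEN_OBO = """\
format-version: 1.2
ontology: test-pathogen

[Term]
id: TAXON:1
name: pathogen root

[Term]
id: TAXON:2
name: Flavivirus
is_a: TAXON:1

[Term]
id: TAXON:3
name: Dengue virus
synonym: "DENV" EXACT []
is_a: TAXON:2

[Term]
id: TAXON:4
name: Yersinia pestis
synonym: "plague bacterium" RELATED []
is_a: TAXON:1

[Term]
id: TAXON:5
name: Katanga
is_a: TAXON:1
"""


@pytest.fixture(scope="session")
def diamond_ontology():
    return parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def disease_ontology():
    return parse_obo(DISEASE_OBO)


@pytest.fixture(scope="session")
def pathogen_ontology():
    return parse_obo(PATHOGEN_OBO)


@pytest.fixture()
def disease_dict(disease_ontology):
    d = TermDictionary(category="disease")
    for cid in disease_ontology.extract_branch(disease_ontology.roots):
        for term in disease_ontology.classes[cid].labels():
            d.add(term, cid)
    return d


@pytest.fixture()
def pathogen_dict(pathogen_ontology):
    d = TermDictionary(category="pathogen")
    for cid in pathogen_ontology.extract_branch(pathogen_ontology.roots):
        for term in pathogen_ontology.classes[cid].labels():
            d.add(term, cid)
    return d


@pytest.fixture()
def dengue_doc():
    return Document(
        doc_id="doc-1",
        text=(
            "Dengue virus was isolated from patients with dengue hemorrhagic "
            "fever. Infection by Yersinia pestis is rare here. Severe acute "
            "respiratory syndrome (SARS) spread quickly."
        ),
    )
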