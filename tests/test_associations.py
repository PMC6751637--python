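"""Co-occurrence counting, NPMI scoring and threshold semantics."""

from __future__ import annotations

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from padminer import (
    CooccurrenceCounts,
    Mention,
    Sentence,
    TaggedSentence,
    classify_direct,
    count_cooccurrences,
    extract_associations,
    npmi,
    npmi_from_counts,
    parse_obo,
    passes_thresholds,
    read_associations_tsv,
    write_associations_tsv,
)
from padminer.associations import write_associations_ntriples
from padminer.ontology import UnknownClassError

PATHO_OBO = """\
[Term]
id: P:1
name: proot

[Term]
id: P:2
name: pmid
is_a: P:1

[Term]
id: P:3
name: pleaf
is_a: P:2

[Term]
id: P:4
name: pother
is_a: P:1
"""

DIS_OBO = """\
[Term]
id: D:1
name: droot

[Term]
id: D:2
name: dmid
is_a: D:1

[Term]
id: D:3
name: dleaf
is_a: D:2

[Term]
id: D:4
name: dother
is_a: D:1
"""


@pytest.fixture(scope="module")
def ontologies():
    return parse_obo(PATHO_OBO), parse_obo(DIS_OBO)


def ts(doc_id, index, pathogens=(), diseases=()):
    """Build a TaggedSentence with one mention per listed class id."""
    mentions = []
    pos = 0
    for cid in pathogens:
        mentions.append(
            Mention(frozenset({cid}), "pathogen", (pos, pos + 1), "x")
        )
        pos += 2
    for cid in diseases:
        mentions.append(Mention(frozenset({cid}), "disease", (pos, pos + 1), "y"))
        pos += 2
    return TaggedSentence(
        sentence=Sentence(doc_id=doc_id, index=index, text="t" * 40, char_offset=0),
        mentions=mentions,
    )


def brute_force_counts(sentences, patho_onto, dis_onto):
    """Triple-enumeration oracle: for every sentence and every class pair,
    test membership of the mentioned classes in the descendant sets."""
    space = []
    for s in sentences:
        p = {c for m in s.mentions if m.category == "pathogen" for c in m.class_ids}
        d = {c for m in s.mentions if m.category == "disease" for c in m.class_ids}
        if p and d:
            space.append((s, p, d))
    n_tot = len(space)
    n_c, n_d, n_cd = {}, {}, {}
    for C in patho_onto.classes:
        desc = patho_onto.descendants(C)
        for s, p, d in space:
            if p & desc:
                n_c[C] = n_c.get(C, 0) + 1
    for D in dis_onto.classes:
        desc = dis_onto.descendants(D)
        for s, p, d in space:
            if d & desc:
                n_d[D] = n_d.get(D, 0) + 1
    for C in patho_onto.classes:
        cdesc = patho_onto.descendants(C)
        for D in dis_onto.classes:
            ddesc = dis_onto.descendants(D)
            for s, p, d in space:
                if (p & cdesc) and (d & ddesc):
                    n_cd[(C, D)] = n_cd.get((C, D), 0) + 1
    return n_tot, n_c, n_d, n_cd


class TestNpmi:
    def test_perfect_collocation(self):
        assert npmi_from_counts(100, 5, 5, 5) == pytest.approx(1.0)

    def test_exact_independence(self):
        assert npmi_from_counts(100, 10, 10, 1) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value(self):
        expected = math.log(10) / math.log(50)
        assert npmi_from_counts(1000, 50, 40, 20) == pytest.approx(
            expected, abs=1e-9
        )

    def test_limits(self):
        assert npmi_from_counts(100, 10, 10, 0) == -1.0
        assert npmi_from_counts(100, 100, 100, 100) == 1.0

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            npmi_from_counts(0, 1, 1, 0)

    @given(st.data())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_bounds_over_valid_counts(self, data):
        n_tot = data.draw(st.integers(1, 10_000))
        n_c = data.draw(st.integers(1, n_tot))
        n_d = data.draw(st.integers(1, n_tot))
        n_cd = data.draw(st.integers(0, min(n_c, n_d)))
        value = npmi_from_counts(n_tot, n_c, n_d, n_cd)
        assert -1.0 <= value <= 1.0 + 1e-12

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_joint_count(self, data):
        n_tot = data.draw(st.integers(2, 1000))
        n_c = data.draw(st.integers(2, n_tot))
        n_d = data.draw(st.integers(2, n_tot))
        hi = min(n_c, n_d)
        k = data.draw(st.integers(1, hi - 1))
        lo, up = npmi_from_counts(n_tot, n_c, n_d, k), npmi_from_counts(
            n_tot, n_c, n_d, k + 1
        )
        assert up >= lo
        if n_c * n_d < n_tot * n_tot:  # otherwise the score is pinned at -1
            assert up > lo


class TestCounting:
    def test_single_sentence_propagation(self, ontologies):
        patho, dis = ontologies
        counts = count_cooccurrences([ts("d", 0, ["P:3"], ["D:3"])], patho, dis)
        assert counts.n_tot == 1
        assert counts.n_c == {"P:3": 1, "P:2": 1, "P:1": 1}
        assert counts.n_d == {"D:3": 1, "D:2": 1, "D:1": 1}
        assert counts.n_cd[("P:3", "D:3")] == 1
        assert counts.n_cd[("P:3", "D:2")] == 1
        assert counts.n_cd[("P:1", "D:1")] == 1
        assert counts.evidence[("P:3", "D:2")] == [("d", 0)]

    def test_single_category_sentence_contributes_nothing(self, ontologies):
        patho, dis = ontologies
        counts = count_cooccurrences([ts("d", 0, ["P:3"], [])], patho, dis)
        assert counts.n_tot == 0
        assert counts.n_c == {} and counts.n_cd == {}

    def test_repeated_mention_counts_once(self, ontologies):
        patho, dis = ontologies
        once = count_cooccurrences([ts("d", 0, ["P:3"], ["D:3"])], patho, dis)
        twice = count_cooccurrences(
            [ts("d", 0, ["P:3", "P:3"], ["D:3"])], patho, dis
        )
        assert once.n_c == twice.n_c and once.n_cd == twice.n_cd

    def test_unknown_class_id_rejected(self, ontologies):
        patho, dis = ontologies
        with pytest.raises(UnknownClassError, match="P:99"):
            count_cooccurrences([ts("d", 0, ["P:99"], ["D:3"])], patho, dis)

    def test_colliding_curie_prefixes_rejected(self, ontologies):
        patho, _ = ontologies
        with pytest.raises(ValueError, match="prefix"):
            count_cooccurrences([], patho, patho)

    def test_propagation_cap_at_branch_roots(self, ontologies):
        patho, dis = ontologies
        counts = count_cooccurrences(
            [ts("d", 0, ["P:3"], ["D:3"])], patho, dis,
            pathogen_roots={"P:2"}, disease_roots={"D:2"},
        )
        assert "P:1" not in counts.n_c and "D:1" not in counts.n_d
        assert ("P:1", "D:1") not in counts.n_cd

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, ontologies, seed):
        patho, dis = ontologies
        rng = random.Random(seed)
        sentences = []
        p_ids = list(patho.classes)
        d_ids = list(dis.classes)
        for i in range(120):
            p = [rng.choice(p_ids) for _ in range(rng.randint(0, 2))]
            d = [rng.choice(d_ids) for _ in range(rng.randint(0, 2))]
            sentences.append(ts(f"doc-{i // 10}", i % 10, p, d))
        counts = count_cooccurrences(sentences, patho, dis)
        n_tot, n_c, n_d, n_cd = brute_force_counts(sentences, patho, dis)
        assert counts.n_tot == n_tot
        assert counts.n_c == n_c
        assert counts.n_d == n_d
        assert counts.n_cd == n_cd
        for pair, n in counts.n_cd.items():
            assert len(counts.evidence[pair]) == n

    def test_monotone_under_ancestor_replacement(self, ontologies):
        patho, dis = ontologies
        rng = random.Random(7)
        sentences = [
            ts(
                "d", i,
                [rng.choice(list(patho.classes))],
                [rng.choice(list(dis.classes))],
            )
            for i in range(60)
        ]
        counts = count_cooccurrences(sentences, patho, dis)
        for cls in patho.classes.values():
            for parent in cls.parents:
                assert counts.n_c.get(parent, 0) >= counts.n_c.get(cls.id, 0)
        for cls in dis.classes.values():
            for parent in cls.parents:
                assert counts.n_d.get(parent, 0) >= counts.n_d.get(cls.id, 0)
        for (c, d), n in counts.n_cd.items():
            for cp in patho.classes[c].parents:
                assert counts.n_cd.get((cp, d), 0) >= n
            for dp in dis.classes[d].parents:
                assert counts.n_cd.get((c, dp), 0) >= n


class TestThresholds:
    def test_acceptance_predicate_boundaries(self):
        assert passes_thresholds(0.25, 12)
        assert not passes_thresholds(0.20, 12)  # strictly above 0.2
        assert not passes_thresholds(0.25, 9)  # at least 10 times
        assert not passes_thresholds(0.9, 2)  # the two-co-occurrence rejection

    def test_low_count_pair_rejected_despite_high_npmi(self, ontologies):
        patho, dis = ontologies
        sentences = [ts("d", i, ["P:4"], ["D:4"]) for i in range(2)]
        sentences += [
            ts("d", 10 + i, ["P:3"], ["D:3"]) for i in range(20)
        ]
        counts = count_cooccurrences(sentences, patho, dis)
        accepted = {(a.pathogen_id, a.disease_id) for a in extract_associations(counts)}
        assert ("P:4", "D:4") not in accepted  # co-occurred only twice
        assert ("P:3", "D:3") in accepted

    def test_matches_brute_force_filter(self, ontologies):
        patho, dis = ontologies
        rng = random.Random(3)
        sentences = [
            ts(
                "d", i,
                [rng.choice(list(patho.classes))],
                [rng.choice(list(dis.classes))],
            )
            for i in range(200)
        ]
        counts = count_cooccurrences(sentences, patho, dis)
        got = {(a.pathogen_id, a.disease_id) for a in extract_associations(counts, 0.05, 5)}
        expected = {
            pair
            for pair, n in counts.n_cd.items()
            if n >= 5 and npmi(counts, *pair) > 0.05
        }
        assert got == expected

    def test_output_sorted_deterministically(self, ontologies):
        patho, dis = ontologies
        sentences = [ts("d", i, ["P:3"], ["D:3"]) for i in range(15)]
        sentences += [ts("d", 100 + i, ["P:4"], ["D:4"]) for i in range(12)]
        counts = count_cooccurrences(sentences, patho, dis)
        accepted = extract_associations(counts, -1.0, 1)
        scores = [a.npmi for a in accepted]
        assert scores == sorted(scores, reverse=True)

    def test_vacuous_thresholds_return_all_pairs(self, ontologies):
        patho, dis = ontologies
        sentences = [ts("d", i, ["P:3"], ["D:4"]) for i in range(3)]
        counts = count_cooccurrences(sentences, patho, dis)
        accepted = extract_associations(counts, npmi_threshold=-1.0 - 1e-9,
                                        count_threshold=1)
        assert {(a.pathogen_id, a.disease_id) for a in accepted} == set(
            counts.n_cd
        )


class TestDirectness:
    def test_direct_when_own_labels_cooccur(self, ontologies):
        patho, dis = ontologies
        counts = count_cooccurrences([ts("d", 0, ["P:2"], ["D:2"])], patho, dis)
        assert classify_direct(("P:2", "D:2"), counts)

    def test_indirect_when_only_subclass_labels(self, ontologies):
        patho, dis = ontologies
        counts = count_cooccurrences([ts("d", 0, ["P:3"], ["D:3"])], patho, dis)
        assert not classify_direct(("P:2", "D:2"), counts)
        assert not classify_direct(("P:2", "D:3"), counts)
        assert classify_direct(("P:3", "D:3"), counts)

    def test_mixed_evidence_is_direct(self, ontologies):
        patho, dis = ontologies
        counts = count_cooccurrences(
            [ts("d", 0, ["P:3"], ["D:3"]), ts("d", 1, ["P:2"], ["D:2"])],
            patho, dis,
        )
        assert classify_direct(("P:2", "D:2"), counts)

    def test_pair_without_evidence_rejected(self, ontologies):
        patho, dis = ontologies
        counts = count_cooccurrences([ts("d", 0, ["P:3"], ["D:3"])], patho, dis)
        with pytest.raises(ValueError):
            classify_direct(("P:4", "D:4"), counts)


class TestExport:
    def test_tsv_round_trip_fields(self, ontologies, tmp_path):
        patho, dis = ontologies
        sentences = [ts("doc", i, ["P:3"], ["D:3"]) for i in range(12)]
        counts = count_cooccurrences(sentences, patho, dis)
        accepted = extract_associations(counts, 0.1, 10)
        out = tmp_path / "assoc.tsv"
        write_associations_tsv(accepted, counts, patho, dis, out)
        rows = read_associations_tsv(out)
        assert rows
        first = rows[0]
        assert first["pathogen_label"] and first["disease_label"]
        assert first["direct"] in {"true", "false"}
        assert len(first["npmi"].split(".")[1]) == 6
        assert first["evidence"].count(":") == int(first["n_CD"])

    def test_ntriples_export(self, ontologies, tmp_path):
        patho, dis = ontologies
        sentences = [ts("doc", i, ["P:3"], ["D:3"]) for i in range(12)]
        counts = count_cooccurrences(sentences, patho, dis)
        accepted = extract_associations(counts, 0.1, 10)
        out = tmp_path / "assoc.nt"
        write_associations_ntriples(accepted, out)
        content = out.read_text()
        assert "P_3" in content and "cooccurrenceCount" in content
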