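# padminer

Ontology-based mining of pathogen–disease associations from literature.

Infectious-disease research needs structured knowledge of which pathogens
cause which diseases, but most of that knowledge sits in free text.
`padminer` implements a literature-mining pipeline for extracting such
associations: it builds refined term dictionaries from two OBO ontologies
(a pathogen taxonomy and a disease ontology), tags pathogen and disease
class mentions in sentences, filters ambiguous disease abbreviations, and
scores class pairs by how much more often they co-occur in sentences than
independence predicts. It is aimed at biomedical text-mining practitioners
and at anyone who needs a reproducible, offline-testable implementation of
class-level co-occurrence statistics over ontologies.

## The statistic

Let `Labels(C)` be the label and synonyms of an ontology class `C`, and

```
Terms(C) := { x | x ∈ Labels(S), S ⊑ C }
```

the set of all strings that can refer to `C` or any of its subclasses
(`⊑` is the `is_a` subsumption relation). Over the set of sentences that
mention at least one pathogen and one disease, define

- `n_tot` — the number of such co-occurrence sentences,
- `n_C`, `n_D` — sentences containing a term from `Terms(C)` / `Terms(D)`,
- `n_C,D` — sentences containing both.

The association strength of a (pathogen `C`, disease `D`) pair is the
class-level normalized pointwise mutual information

```
npmi(C, D) = log( n_C,D · n_tot / (n_C · n_D) ) / ( −log( n_C,D / n_tot ) )
```

which lies in [−1, 1] (1 = perfect collocation, 0 = independence,
−1 = never co-occur). A pair is accepted when `npmi > 0.2` (strict) and
`n_C,D ≥ 10` (inclusive). In practice the subsumption propagation is
implemented by counting each mentioned class toward all of its ancestors,
which is equivalent to matching the expanded `Terms(C)` sets directly. An
accepted association is *direct* if both classes' own labels co-occur in at
least one evidence sentence, and *ontology-inferred* (indirect) when it is
supported only through subclass labels.

## Worked example

The package ships a seeded generator that emits miniature ontologies and a
corpus with planted associations, so the whole pipeline runs without any
downloads:

```sh
padminer simulate --seed 1 --out-dir demo
padminer ontology stats demo/pathogen.obo
#  classes:  12
#  is_a edges: 11
#  roots:    1
#  obsolete: 0

cat > demo/config.json <<'EOF'
{
 "pathogen_obo": "demo/pathogen.obo",
 "disease_obo": "demo/disease.obo",
 "corpus": "demo/corpus.jsonl",
 "out_dir": "demo/run"
}
EOF
padminer run --config demo/config.json
# {"out_dir": "demo/run", "associations": 10}
```

The accepted associations land in `demo/run/associations.tsv`:

```
pathogen_id   pathogen_label  disease_id   disease_label  npmi      n_CD  n_C  n_D  direct
PATH:0000001  tagiti sinifu   DIS:0000001  gigulu miba    1.000000  604   604  604  true
PATH:0000007  fizeru gagu     DIS:0000011  zutafa nitase  0.562142  37    75   62   true
PATH:0000004  vanelu tasade   DIS:0000005  binumi pabupo  0.548014  38    71   71   true
PATH:0000006  bivaso fene     DIS:0000007  zilamo pine    0.472877  49    96   94   true
PATH:0000003  pipiva rabomu   DIS:0000011  zutafa nitase  0.428270  37    109  62   false
...
```

Reading the rows: the two root classes co-occur in every co-occurrence
sentence (`npmi = 1`), a vacuous top-of-hierarchy association that ancestor
propagation always produces. The next rows are the planted pairs: e.g.
`fizeru gagu` and `zutafa nitase` co-occur in 37 of 604 co-occurrence
sentences against 75 × 62 marginals, giving `npmi ≈ 0.56`. The last row
shown is an ontology-inferred association (`direct = false`): the pair was
planted only through subclass labels, and its own labels never co-occur —
the association is recovered purely through `is_a` propagation, with the
evidence column (not shown) pointing at the contributing sentences.

Per-stage subcommands (`build-dict`, `tag`, `extract`, `evaluate`) expose
the same pipeline piecewise; `padminer tag` writes mention-level JSONL and
`padminer extract` accepts it back, so stages can be re-run independently.

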