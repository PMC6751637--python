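# Methods

## Pipeline

`padminer` extracts (pathogen class, disease class) associations from text
in four stages.

1. **Dictionary construction.** Each ontology is parsed from OBO flat-file
   text; only `is_a` edges define subsumption, all synonym scopes
   (EXACT/RELATED/NARROW/BROAD) are ingested, and obsolete classes are kept
   in the container but excluded from closures and dictionaries. A branch
   (one or more root classes, e.g. the infectious-disease branch of a
   disease ontology, or the pathogenic groups of a taxonomy) is expanded to
   its subclass closure and every label/synonym surviving refinement is
   indexed. Refinement drops terms shorter than `min_length` characters
   (default 3) and terms on a stoplist of common-English and geographic
   words; the packaged default stoplist is a config file and can be
   replaced. Surface forms are whitespace-normalized and lowercased, except
   all-uppercase forms of ≤ 5 characters, which are stored and matched
   case-sensitively so short abbreviations ("ALS") do not match ordinary
   text ("als…").

2. **Tagging.** Documents are split into sentences by a rule-based splitter
   (punctuation followed by whitespace and an upper-case/digit opener, with
   an abbreviation exception list; a period followed by a lower-case word,
   as in "E. coli", never splits). Dictionary matching is word-boundary
   aligned on both edges — a boundary is an alphanumeric/non-alphanumeric
   transition, so "rat" never matches inside "strategy" — and overlapping
   candidates within a category resolve to the longest match, ties going to
   the leftmost. A form shared by k classes yields one mention carrying all
   k class ids; disambiguation happens statistically downstream, per class.

3. **Abbreviation filtering.** Disease-name abbreviations are ambiguous, so
   a document-level rule filter inspects every disease mention whose
   surface looks like an abbreviation (2–10 characters, letters all
   uppercase). Abbreviation/long-form pairs are first detected from
   parenthetical patterns by right-to-left letter alignment (the classic
   Schwartz–Hearst procedure): a short-form candidate must be 2–10
   characters, contain a letter — a condition added so pure-number
   parentheticals like "(12)" are never candidates — and be at least half
   uppercase/digits; its characters must appear in order in a window of at
   most min(|SF|+5, 2·|SF|) words before the parenthesis, with the first
   character starting a word. A disease abbreviation mention is kept iff
   (a) another dictionary surface form of one of its classes (a long form)
   occurs elsewhere in the document, or (b) a detected expansion contains a
   disease-indicating keyword (default: disease, disorder, syndrome,
   defect, infection, fever; configurable). Pathogen mentions are never
   filtered.

4. **Counting and scoring.** A sentence enters the co-occurrence space iff
   it has at least one pathogen and one disease mention; `n_tot` is the
   size of that space. Counting uses set semantics (a class mentioned twice
   in a sentence counts once) and ancestor propagation: each mentioned
   class counts toward itself and every ancestor, capped at the configured
   branch roots. Propagation by count aggregation is equivalent to matching
   the expanded `Terms(C)` string sets, but costs O(mentions × depth)
   instead of O(|Terms|). Pairs are scored with class-level NPMI and
   accepted when `npmi > npmi_threshold` (default 0.2, strict) and
   `n_CD ≥ count_threshold` (default 10, inclusive). An association is
   flagged direct iff some evidence sentence mentions both classes by their
   own labels before propagation.

## Numerical and edge-case choices

- `n_CD = 0` maps to NPMI −1 and `n_CD = n_tot` to +1, the continuous
  limits of the formula, rather than raising; `n_tot = 0` is an error.
  The logarithm base cancels and is irrelevant.
- By default the marginals `n_C`, `n_D` are counted inside the same
  restricted space as `n_tot`, which keeps every ratio in the formula a
  probability and the score inside [−1, 1]. Counting marginals over the
  whole corpus instead is available as `whole_corpus_marginals`; with it
  the score may leave [−1, 1] when a marginal exceeds `n_tot`, so it is
  off by default.
- Output ordering is NPMI descending with (pathogen id, disease id) as tie
  break, so runs are byte-reproducible.
- Ancestor propagation up to the branch roots inclusively also produces
  top-of-hierarchy pairs (e.g. root × root scores +1 whenever both roots
  subsume every mention). These are vacuous but harmless; capping at the
  branch roots prevents anything above the configured branches from
  appearing.
- Dangling `is_a` targets in an OBO file are dropped with a warning (they
  are common in real exports); cyclic `is_a` graphs and id-less `[Term]`
  stanzas are rejected with errors naming a cycle / the offending line.
- Evaluation against reference pair lists is at the exact-class level; a
  subclass-level extraction earns no credit for a superclass reference
  pair. This is the stricter of the plausible conventions and is applied
  uniformly.

## The synthetic-data generator

The generator emulates the statistical structure the method detects — a few
genuinely collocated class pairs over a noisy background — with known
ground truth, so every stage is testable offline.

Each sentence is drawn independently. With probability `cooccurrence_rate`
(default 0.3) it is a *carrier*: given that, planted pair *i* is realised
with probability `joint_probability_i` (defaults 0.08, 0.06, 0.05 for three
leaf pairs and 0.07 for one internal pair realised only through proper
subclasses), and with the remaining probability a *decoy* pair is sampled
uniformly and independently over all classes. Non-carrier sentences mention
a single random pathogen or disease (at `background_rate` each, default
0.15) or are plain filler. Surfaces are drawn from labels and synonyms;
disease classes carry an all-caps acronym synonym with probability
`abbreviation_rate`, introduced in text as "label (ACRONYM)" so the
abbreviation detector and filter are exercised; `ambiguity_rate` plants
stoplist words as synonyms to exercise refinement. Carrier sentences use
fixed English frames ("X was isolated from patients with Y.") so the
splitter and boundary rules see realistic text.

Joint probabilities are defined **conditional on the co-occurrence space**:
because non-carrier sentences never co-occur, `n_CD / n_tot` for a planted
leaf pair is a consistent estimator of its configured probability (the
calibration test checks agreement within three standard errors at 2000
sentences). Two structural consequences are worth knowing. First, sentences
realised at subclasses of a planted internal pair make the subclass-level
pairs genuinely associated too, so "decoy" accounting in the tests treats
the ancestor closure of the *realised* planted mentions as planted signal.
Second, because planted mass occupies part of the space, pure-decoy cells
carry a small positive PMI of log(1/decoy-mass) — an unavoidable artifact
of conditioning — which is why total planted mass is kept near 0.25: decoy
aggregates then stay well below the 0.2 acceptance threshold while planted
pairs score 0.3–0.7.

Randomness comes from Python's Mersenne Twister seeded with strings derived
from the integer seed ("`{seed}:ontologies`", "`{seed}:corpus`"), which is
byte-stable across platforms; identical specs produce byte-identical OBO,
JSONL and ground-truth files. Default sizes — two 12-class ontologies of
depth ≤ 3, 2000 sentences in 200 documents — are small enough for the full
multi-seed study to run in seconds while leaving the smallest planted pair
(0.05) an expected 30 co-occurrences, comfortably above the count
threshold. The indirect pair's expected NPMI sits near 0.3; a strict 0.2
threshold therefore leaves it a few-percent per-seed chance of a near-miss,
which the multi-seed recovery rate reports honestly when it occurs.

What passing on synthetic corpora does **not** show: the generator has no
negation or speculation, no coordination or anaphora, no nested or
sentence-spanning entity structure, uniform decoy marginals instead of the
heavy-tailed frequencies of real literature, and clean dictionaries without
the massive cross-domain ambiguity of a real taxonomy. Results on these
fixtures validate the machinery (parsing, matching, propagation, scoring,
thresholds, determinism), not corpus-scale extraction quality.

## Known limitations

- Dictionary matching is exact (after case/whitespace normalization); no
  stemming, spelling variation, or morphological expansion.
- The abbreviation filter considers disease mentions only; pathogen-name
  abbreviations pass through unfiltered.
- Sentence splitting is rule-based; unusual punctuation can over- or
  under-split, though offsets always remain consistent.
- Reference evaluation requires pre-mapped CURIE pairs; mapping external
  resource identifiers onto the ontologies is out of scope.
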