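# Methods

## Co-occurrence model

The unit of evidence is the abstract: a miRNA and a disease (or lipid
phenotype identifier) mentioned in the same abstract are taken to be
associated, and the strength of the association is judged against the
null hypothesis that the two entities are mentioned independently. For a
pair observed over *n* abstracts the counts are laid out as a 2×2 table —
*a* abstracts mentioning both, *b* only the miRNA, *c* only the disease,
*d* neither. Conditioning on the margins, *a* follows the hypergeometric
law

    P(a) = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! n!),

and the reported p-value is the one-sided (enrichment/right) tail
P(X ≥ a): this is the direction of interest, since the question is
whether co-mention is *more* frequent than independence predicts. A pair
is called significant at raw p ≤ 0.05 (α configurable). No
multiple-testing correction is applied at this screening stage by
default — the false-discovery control belongs to the downstream
enrichment stage — but `score_all_pairs(bh=True)` switches significance
calls to Benjamini–Hochberg adjusted p-values. Pairs with *a* = 0 are not
scored: zero co-occurrence carries no association evidence under this
model.

Ranking ties (frequent, because many pairs share a disease margin and a
co-occurrence count) are broken by descending supporting-paper count,
then lexicographic miRNA name, then group name. This deterministic order
reproduces published association tables in which blocks of pairs share
one p-value.

### Numerics

Two arithmetic paths back the same API:

- **n ≤ 500** (any corpus this package is meant for): point
  probabilities are exact binomial-coefficient ratios
  C(a+b, a)·C(c+d, c)/C(n, a+c) formed over Python integers and rounded
  once to float; the tail is the rounded sum of exact terms. With
  `exact=True` the untruncated `fractions.Fraction` is returned, which is
  what the monotonicity and normalization tests assert on (float
  rounding can collapse adjacent tails whose difference is below one ulp).
- **n > 500**: log-gamma arithmetic with a log-sum-exp tail, accurate to
  roughly 1e-12 relative at n ~ 1e4 and usable to n ~ 1e5.

The tail is summed over the admissible range
max(0, r+c−n) ≤ a′ ≤ min(r, c) of the fixed margins; degenerate margins
that admit a single table give p = 1 exactly.

## Mention recognition

Recognition is deterministic dictionary + pattern matching (replacing
manual extraction with a reproducible procedure). One case-insensitive,
word-boundary-anchored pattern covers the nomenclature families —
optional species (``hsa-``) and precursor (``pre-``) prefixes, the core
keywords ``microRNA``/``miRNA``/``miR``/``let``/``lin``, a numeric core
with optional family letter and locus suffix (``199a-1``), and compound
continuations (``/222``, ``/b``, ``& -16``). En and em dashes are mapped
to ASCII hyphens before matching (the literature itself prints
``miR-15 & –16`` with an en-dash). Matches are normalized back to
canonical ids: prefixes stripped (the precursor flag is kept on the
span), capitalization canonicalized to ``miR-``/``let-``/``lin-``, and
compounds expanded to their member ids. If the compound form itself is a
lexicon entry (e.g. ``miR-33a/b``, published as its own association row),
the compound id is reported *in addition to* the expansion, so downstream
counting can treat it as its own pair key. Tokens that fail to resolve
are flagged on the span, never dropped.

Disease/identifier groups match against explicit synonym sets with
longest-match-wins (an abstract containing only "HDL-Cholesterol" counts
toward that group, not also "HDL"; "low HDL-C" outranks "HDL-C"), and a
group is counted at most once per abstract. Offsets are 0-based,
half-open, into ``title + "\n" + body``.

The packaged default lexicon reconstructs a human miRNA roster of 167
names (the four diseases and seven identifier groups are packaged with
common British/American spelling synonyms). Its miRBase accession column
holds synthetic placeholders, flagged in the file header: real accessions
must be supplied to bridge to real target databases.

## Networks

The association network is strictly bipartite: miRNA and disease nodes,
one edge per scored pair carrying the p-value, the supporting paper
count, and −log10 p (a numeric stand-in for "edge thickness" styling).
GraphML and XGMML exports round-trip losslessly; SIF and edge TSV carry
topology plus weight.

RegIN extension adds, for each seed miRNA accession, every target gene
listed in any loaded source database (direction configurable to
regulators or both). Each edge's support set records which sources
contain it; the overlap threshold keeps edges with ≥ k supporting
sources ("or more" semantics, so with exactly three sources k = 3 is the
per-seed intersection of the source target sets). Hide/show masks
sources non-destructively — support sets are recomputed against the
visible sources and unhiding restores the original network exactly. The
filter obeys threshold(k₂)∘threshold(k₁) = threshold(max(k₁,k₂)) and is
monotone non-increasing in k. Accounting tables report per-set node/edge
and per-source edge counts and defined-target counts, with a grand total
that is the plain sum over seed sets (sets sharing a target count it
repeatedly, matching per-set bookkeeping). Gene identifiers are treated
as opaque symbols; no cross-database id harmonization is attempted.

## GO enrichment

Annotations are closed under the true-path rule (every gene annotated to
a term is annotated to its is_a ancestors) before counting; a
`propagate_annotations=False` flag preserves raw direct counts. For a
term annotating K of the N background genes, a query of n genes with k
annotated scores P(X ≥ k) under Hypergeometric(N, K, n) — computed via
the same exact Fisher tail machinery (the GO table (k, n−k, K−k,
N−K−n+k) has the query size and the annotation count as its margins).
The background universe defaults to all genes in the annotation table;
pass the RegIN target union to restrict it. Only terms with k ≥ 1 are
tested, and exactly that family defines m for the Benjamini–Hochberg
step-up adjustment (documented because it changes m relative to testing
every ontology term). Significance applies α = 0.05 to adjusted
p-values; a raw-p mode is available.

## Synthetic data: what it emulates, and what it does not

The corpus generator emulates a retrieval set in which some
(miRNA, disease) pairs are genuinely associated. Each abstract is
dedicated round-robin to one planted pair and co-mentions it with
probability `p_comention` (default 0.6; otherwise one of the two
entities appears alone); every other miRNA and disease is mentioned
independently at background rates (default 0.05 each). Defaults are 300
abstracts, twelve miRNAs spanning every nomenclature family, four
disease groups, and two planted pairs. With probability `p_compound`
(0.2) an intended miRNA pulls in its sibling rendered as a compound
abbreviation, which also induces realistic miRNA–miRNA co-mention
correlation. Surface forms are sampled over all template families;
filler vocabulary is checked against both lexicons at generation time,
so recognition on synthetic text is exact by construction — the NER
round-trip test therefore validates the recognizer's handling of the
surface families, not its robustness to noisy prose. Real abstracts
add negation, hedging, species ambiguity, and out-of-lexicon synonyms;
passing tests here do not certify recall on such text.

A generated corpus whose planted pair is never realized (tiny n or small
`p_comention`) raises a generation error rather than silently producing
an unlearnable fixture. All generators are bit-reproducible under their
seed (`random.Random`, whose algorithm is stable across platforms).

RegINs are generated from an explicit overlap specification (target →
supporting source subset), making threshold/intersection behaviour
checkable against ground truth. The GO fixture grows a single-rooted DAG
(each term's parent drawn among earlier terms, hence acyclic) and plants
one enriched term annotating exactly a chosen gene block; remaining
genes get one or two uniformly random annotations.

### Calibration note

Fisher's exact test is conservative on discrete tables: the probability
of p ≤ α under the null is at most α and typically below it. The null
calibration check accordingly asserts that the fraction of significant
pairs (over all candidate pairs, scored or not) does not exceed the
binomial upper confidence bound at α = 0.05; on the default null
conditions the observed fraction is ≈ 0.02–0.03. A two-sided containment
around α would fail for *any* valid exact-test implementation.

## Pipeline determinism and sizes

All randomness flows from one top-level seed, split into fixed per-stage
substreams (corpus, RegIN spec, GO fixture). Numbers in TSVs use fixed
formats (p-values as two-decimal scientific notation, e.g. ``3.40E-05``),
JSON is key-sorted, and all text artifacts use ``\n`` line endings, so
reruns are byte-identical and the manifest records a SHA-256 per
artifact. The test suite and the acceptance script use corpus-scale
problem sizes — 300-abstract corpora, 20 recovery and 50–200 calibration
replicates, exhaustive table sweeps to n = 25 — chosen so the full
validation completes in well under a minute of statistics while still
exercising every code path, including the large-n log-space branch.

## Known limitations

- NER is dictionary/pattern-based; it does not attempt statistical NER,
  species disambiguation beyond prefix stripping, or full-text mining.
- The co-occurrence assumption counts presence, not stance: a negated
  mention counts as evidence.
- Identical significance blocks in ranked output are ordered by the
  documented tie-break, which is a convention, not evidence.
- The packaged lexicon's accession column is placeholder-only; Table-5
  style bridging to real databases requires real accessions.
- GO "total genes" counts are propagated per-term background counts over
  the supplied annotation table; they are not comparable to counts
  reported against other backgrounds or ontology releases.
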