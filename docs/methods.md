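# Methods

## Scope and model

`dsim` treats disease–disease similarity as a two-layer problem: a
*score* layer (five measures over the Disease Ontology and its
annotation channels) and a *significance* layer (an empirical null built
from the all-pairs score distribution). A third component transfers
curated therapeutic chemicals (TCs) across significantly similar
diseases.

The ontology substrate is the DO `is_a` DAG. Ancestor sets are
self-inclusive throughout (a term is its own ancestor), which is the
convention under which every measure's self-similarity reduces cleanly:
`lin(t,t) = wang(t,t) = 1`, `resnik(t,t) = IC(t)`. Only `is_a` edges are
used; `part_of` and xref lines in the OBO are ignored, since DO's
hierarchy is `is_a`. Multi-rooted input is closed under a synthesized
virtual root whose IC is pinned to 0, keeping common ancestors total.
Alternate ids are mapped to canonical terms and prefixes upper-cased.

## Information content

IC is computed over the **disease** unit: `p(t)` is the fraction of
annotated diseases (DO terms with at least one directly associated gene)
found at or below `t`, and `IC(t) = −ln p(t)`. The alternative —
counting disease–gene annotation events rather than diseases — is
defensible; the disease unit was chosen because the objects being
compared are disease terms, and the choice is recorded in run metadata
(`ic_corpus_unit`) so result sets are comparable. Natural log is used:
Lin is base-invariant and Resnik only rescales; the base is likewise in
the metadata. Terms subsuming no annotated disease have undefined IC and
are excluded from MICA candidacy; MICA ties on IC are broken toward the
lexicographically smallest term id when the ancestor itself is reported
(the IC value is tie-independent).

Disease→gene associations are propagated up the DAG under the true-path
rule before any use. The functional measures (PSB, SemFunSim) consume
these **propagated** sets: semantic inheritance of associations is what
couples the gene channel to the ontology. Rows naming unknown DOIDs are
skipped and counted by default; `--strict` promotes them to errors.

## The five measures

**Resnik** and **Lin** are as standard (see README). Resnik is reported
raw; `--normalize` divides by the corpus maximum IC for cross-method
display only, since the measures natively live on heterogeneous scales.

**Wang** uses a single `is_a` decay factor `w_isa`, default 0.8 — the
canonical value for this family of measures — exposed as `--wang-w`.
S-values are computed by the dynamic-programming recurrence
(leaves-first over the ancestor subgraph); the test suite verifies the
recurrence against naive max-over-paths enumeration, which is the
defining formulation.

**PSB** is realized as a weighted Jaccard over disease biological-process
profiles: the profile of a disease is the union of GO-BP terms annotated
to its (propagated) genes. Default weights are 1 per term; `--psb-weight
idf` weighs each term by `−ln` of its document frequency across disease
profiles, damping ubiquitous processes. This is a declared
reimplementation choice: it captures process-overlap between the
diseases' gene complements with the simplest defensible statistic, and
both weight modes are exposed so the choice is inspectable.

**SemFunSim** is a best-match average over propagated gene sets with a
pairwise gene similarity of 1 for identical genes, 0 for pairs absent
from the gene network, and the min–max-normalized network score
otherwise. Normalization bounds are the observed corpus extremes,
recorded in run metadata; a degenerate network (all scores equal) maps
every stored edge to 1 with a warning. The original measure learned
weights across several association channels; here the weighted network
file is the single functional channel.

A disease lacking the inputs a method needs (no genes, no BP-annotated
genes) receives a **null** score for that method — an empty result cell,
never a zero. Zero means "compared and found dissimilar"; null means
"not comparable".

## Significance

For each method the background is the set of all non-null pair scores in
the current run — the honest equivalent of "all pairs of diseases",
which for any given corpus is run-relative. Scores are z-scored with the
population SD (at all-pairs scale the sample/population distinction is
negligible; the choice is recorded), converted to one-sided upper-tail
P-values under a standard-normal reference, and BH-adjusted with the
family = all scored pairs of the method in the run. The normality of the
reference is an approximation — real score backgrounds are skewed — so
the P-values are calibrated screening statistics rather than exact tail
probabilities; the test suite verifies exact calibration when the
background is truly normal, and verifies the BH step against an
independent reference implementation. Background mean/SD/family size are
emitted in run metadata.

Thresholds follow the conventional `α ∈ {0.05, 0.10}` (other values are
accepted with a warning). Pair filtering is union-style: retained when
at least `--min-methods` methods are individually significant. A
single-pair report (`simpd`) for identical terms falls outside the
unordered-pairs BH family; it reports score, z and P, leaving the
adjusted P blank.

## Therapeutic-chemical transfer

Only rows whose evidence field marks a *therapeutic* relationship enter
the TC store; marker/mechanism rows are aetiology, not treatment.
Diseases with no retained row are absent keys — absence from the store
is semantically distinct from an empty set and propagates to empty
shared-TC results. Candidates for a query are the union of neighbours'
TCs minus the query's own (they are not "potential" if already curated;
`--include-known` overrides). The ranking key is a design choice, since
"sorted" does not determine one: default `score-sum` (sum over
supporting diseases of their best significant similarity score across
methods, which mixes scales when raw Resnik is selected — by design, the
best *available* evidence wins), alternative `support-count`; ties break
on the other statistic, then ascending chemical id, giving a
deterministic total order. Neither key is canonical and both are
labelled as interpretations.

## Synthetic data generator

The generator plants known structure behind the real file formats (OBO,
TSV, GAF 2.1, CTD-style chemicals table) so every reader and measure is
exercised end-to-end:

- a complete `branching`-ary tree of `depth` levels (defaults 3/3: 40
  terms, 27 leaf diseases);
- per top-level branch, disjoint blocks of genes (180-gene pool), GO-BP
  terms (60 per branch) and network edges — cross-branch pairs therefore
  share nothing and are the planted *dissimilar* pairs (exactly 0 under
  Resnik, Lin, PSB, SemFunSim);
- one sibling leaf pair per branch planted *similar*, sharing
  `overlap_fraction` (default 0.8) of genes, hence of BP profiles, and
  of chemicals (8 genes and 5 chemicals per disease);
- each disease's genes form a sparse ring module in the network rather
  than a clique, keeping chance best-match similarity between different
  diseases' gene sets low so that planted gene sharing, not block-level
  edge density, drives SemFunSim;
- for each planted similar pair, one chemical of the donor is withheld
  from the query — the built-in repositioning ground truth — and one
  leaf outside all planted pairs is omitted from the chemicals file,
  emulating a disease absent from the chemical database.

Outputs are byte-identical per seed. The generator emulates structure,
not scale: it does not reproduce DO's size, HumanNet's degree
distribution, annotation noise, or incomplete/biased curation. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of planted signal, not performance on real corpora.

## Numerical and degenerate-input choices

- Backgrounds require ≥ 2 scores and nonzero variance; constant
  backgrounds are a hard "degenerate background" error.
- `lin` is defined as 0 when both terms sit at the root (zero IC sum).
- Weighted-Jaccard with an all-zero-weight union (possible under IDF
  when every shared term is ubiquitous) returns 1 for identical profiles
  and 0 otherwise.
- Duplicate/reversed network rows keep the maximal score; self-edges are
  dropped.
- All result orderings (tables, candidate lists) are total and
  deterministic under permuted input.

## Problem sizes

Default verification runs use the default generator bundle (27 diseases,
351 pairs, five methods) plus a 10,000-draw Monte-Carlo calibration of
the significance layer and 1,000 random vectors for the BH cross-check;
the complete suite runs in a few seconds on one CPU.

## Known limitations

- The normal-reference one-sided P is an approximation on skewed real
  backgrounds (see above).
- PSB and SemFunSim are reimplementations from their defining ideas, not
  ports of the original parameterizations; constants (IDF weights,
  normalization bounds) are declared choices surfaced as options.
- Gene identifiers must already share one namespace across the three
  annotation channels; no id conversion is attempted.
- The BH family is global per method per run; per-query families would
  give different adjusted P-values.
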