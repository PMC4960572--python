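# dsim — disease similarity with empirical significance and drug repositioning

`dsim` computes similarity between human disease terms of the Disease
Ontology (DO), attaches an empirical significance level to every score,
and uses significantly similar diseases to propose candidate therapeutic
chemicals (TCs) — the working hypothesis being that similar diseases can
be treated by common chemicals, so a disease with no curated treatment
can borrow the TCs of its significant neighbours.

It is aimed at researchers in disease genomics and computational drug
repositioning who have (or can map their data to) DOID-keyed inputs.

## Methods

Five term-similarity measures over the DO `is_a` DAG:

- **Resnik** — `sim(t1, t2) = max_{a ∈ CA(t1,t2)} IC(a)`, the information
  content of the most informative common ancestor (MICA), with
  `IC(t) = −ln p(t)` and `p(t)` the fraction of annotated diseases at or
  below `t`;
- **Lin** — `2·IC(MICA) / (IC(t1) + IC(t2))` ∈ [0, 1];
- **Wang** — purely structural: each ancestor `a` of `t` carries an
  S-value `S_t(a)` (1 at `t`, decaying by a factor `w = 0.8` per `is_a`
  hop, max over paths), and
  `sim(t1, t2) = Σ_{a ∈ A1∩A2} (S_{t1}(a) + S_{t2}(a)) / (SV(t1) + SV(t2))`;
- **PSB** — weighted Jaccard of the GO biological-process profiles
  induced by the two diseases' gene sets;
- **SemFunSim** — best-match average (BMA) of the two diseases'
  propagated gene sets under a pairwise gene functional similarity
  derived from a weighted gene network (min–max-normalized
  log-likelihood scores; identical genes score 1, unconnected pairs 0).

Significance is empirical, per method: scores of **all** disease pairs
form the background; each score is z-scored against that background's
mean and population SD, converted to a one-sided upper-tail P-value
`1 − Φ(z)`, and Benjamini–Hochberg adjusted across all scored pairs.
A pair is significant at `α ∈ {0.05, 0.10}` when its adjusted P is below
`α`; a result table keeps a pair when at least `--min-methods` methods
agree ("1 or more" = union), and renders failing method cells as null.

Candidate TCs for a query disease are the curated TCs of its significant
neighbours (minus its own), ranked by the sum of supporting similarity
scores (see `docs/methods.md` for details and caveats).

## Worked example

Generate a synthetic input bundle (40-term ontology, 27 diseases with
planted similar/dissimilar pairs) and query one of the planted diseases:

```
$ dsim fixtures --out demo --seed 0
wrote bundle with 40 terms and 27 diseases to demo

$ dsim simdis --disease DOID:0000014 --obo demo/ontology.obo \
    --disease-genes demo/disease_genes.tsv --gene-net demo/gene_network.tsv \
    --gaf demo/gene_bp.gaf --chemicals demo/chemicals.tsv --alpha 0.05
index  query         similar       ...  psb (score (p))                            semfunsim (score (p))
1      DOID:0000014  DOID:0000015  ...  0.6666666666666666 (0.0014061213074519395)  0.9212927995971802 (0.0009645072432915998)
2      DOID:0000014  DOID:0000016  ...
```

Row 1 is the planted similar partner: its PSB score is 0.667 with
adjusted P ≈ 1.4e-3 and its SemFunSim score 0.921 with adjusted
P ≈ 9.6e-4 — significant at 0.05 under three of five methods (the empty
cells are methods whose adjusted P exceeded the threshold, not zero
scores). Row 2 is a sibling disease significant under Wang only.

Candidate chemicals transferred from significant neighbours:

```
$ dsim tc --disease DOID:0000014 --obo demo/ontology.obo ... --chemicals demo/chemicals.tsv
rank  chemical_id  chemical_name  rank_score          n_support  support
1     MESH:C00100  chem-001-00    0.9212927995971802  1          DOID:0000015|semfunsim|0.92...|0.00096...
```

The top candidate is exactly the chemical the generator withheld from
DOID:0000014 and planted on its similar neighbour — the repositioning
ground truth recovered at rank 1.

Other subcommands: `terms` (valid DOIDs), `simpd` (one pair: all scores,
z, P, adjusted P, shared TCs), `precompute` (all-pairs score/background
cache), `fixtures`. All flags can come from a `--config key=value` file;
explicit flags win. Exit codes: 0 success, 2 input error, 3 data
integrity error.

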