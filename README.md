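# provean

Alignment-based prediction of the functional effect of protein sequence
variants: single and multiple amino acid substitutions, in-frame insertions,
deletions, and replacements.

A variant's effect is measured as the change in semi-global (free end-gap)
alignment score between the query and each member of a *supporting sequence
set* of homologs, caused by applying the variant to the query.  The
supporting set is built by E-value filtering, redundancy removal via greedy
80%-identity clustering, ranking clusters by similarity to the query, and
capping at 45 clusters (the query itself always participates, so scoring
works even with zero homologs).  Per-sequence deltas are averaged within each
cluster and then across clusters with equal weight, so over-represented
subfamilies cannot bias the result.  A variant is called deleterious when
this final score is ≤ −2.282 (inclusive).

Defaults: BLOSUM62 (bundled, NCBI text format), gap open 10 / extend 1
(classic Gotoh convention: a length-L gap costs `open + (L−1)·extend`; the
`open + L·extend` convention is selectable).

## Library

```python
import provean as pv

query = pv.ProteinSequence("Q", "MKTGAELVRW...")
variant = pv.parse_variant("G4C", query)           # also F508del, K10_L12del,
                                                   # 10_11insGS, A5_G6delinsTR
sset = pv.build_supporting_set(query, homologs)    # homologs: list of sequences
result = pv.provean_score(query, variant, sset)
result.score, result.prediction                    # e.g. -7.5, DELETERIOUS
```

`ProveanScorer` caches the per-subject base alignments for batch scoring and
the saturation scan (every single substitution/deletion/insertion at every
position).

## CLI

One command, five subcommands:

```sh
provean score query.fasta --variants vars.tsv --homologs homs.fasta -o out.tsv
provean scan  query.fasta --homologs homs.fasta -o matrix.tsv
provean eval  labeled_scores.tsv -o report.json          # or --threshold -2.282
provean sweep query.fasta --variants vars.tsv --homologs homs.fasta \
              --gap-pairs 10:1,8:2 --identities 0.75,0.8 --cluster-counts 30,45 \
              -o sweep.tsv
provean simulate --length 100 --n-homologs 30 --seed 1 --out-prefix fam
```

Variant TSV: one variant string per line, optional second column
`deleterious|neutral`.  Homologs can also come from standard 12-column BLAST
tabular output (`--hits`) or CD-HIT `.clstr` files (library API).  A YAML
config (`--config`) can override matrix, gap penalties/convention, identity
threshold, cluster cap, decision threshold, and seed.

## Evaluation utilities

`provean.evalbench` provides confusion metrics (deleterious = positive
class), balanced accuracy `(sensitivity + specificity) / 2`, ROC/AUC with
lower-score-is-positive orientation, balanced-separation threshold selection
(maximize min(sensitivity, specificity)), and a parameter-grid sweep driver.
`provean.synthfam` generates synthetic homolog families with
conserved/free-position structure and labeled variant sets for download-free
end-to-end testing.

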