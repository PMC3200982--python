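# dishin

Semantic similarity between ontology concepts — and between the entities
(e.g. proteins) annotated with them — based on the information content the
concepts share in a DAG ontology such as the Gene Ontology.

Classical shared-information measures reduce the common ancestors of two
concepts to the single Most Informative Common Ancestor (MICA), which
silently treats the ontology as a tree. This package implements, alongside
MICA, two definitions that exploit multiple inheritance:

* **GraSM** — the mean IC over *disjunctive* common ancestors selected
  greedily: an ancestor joins the set only if one of the concepts reaches
  it by an upward path avoiding every ancestor already selected.
* **DiShIn** — the mean IC over one representative per *path-difference*
  class. With `Paths(c, a)` the number of distinct directed paths from `c`
  up to `a`, common ancestors are grouped by
  `PD(c1, c2, a) = |Paths(c1, a) − Paths(c2, a)|` and the most informative
  ancestor of each group is kept. Ancestors reached through the same
  imbalance of interpretations are redundant; parallel interpretations
  shared equally by both concepts (PD = 0) collapse onto the MICA instead
  of dragging the average down. Because the path counts are precomputed
  once per ontology release, a pairwise query is linear in the number of
  common ancestors — it is even expressible as a single SQL query over two
  tables, which `dishin.precompute_store` implements verbatim on SQLite.

Information content is corpus-based: `IC(c) = −log(freq(c)/maxFreq)`,
where `freq(c)` counts the distinct entities annotated to `c` or any of
its descendants. Any of the three shared-information backends can plug
into Resnik (`Sim = Share`), Lin (`Sim = 2·Share/(IC(c1)+IC(c2))`) or
Jiang-Conrath (`Dist = IC(c1)+IC(c2)−2·Share`), and entities are compared
by the symmetric best-match average of their annotation sets.

## Worked example

The package ships the canonical illustration fixtures. On the metals DAG
(*gold* and *silver* are both precious and coinage metals):

```python
>>> from dishin import *
>>> m = metals_fixture()
>>> paths = transitive_closure_paths(m.dag)
>>> paths.count("gold", "metal"), paths.count("platinum", "metal")
(2, 1)
>>> path_difference(paths, "platinum", "gold", "metal")
1
>>> ic = information_content(propagate_frequencies(m.dag, m.corpus))
>>> dca_dishin(ic, paths, "platinum", "gold")
('precious', 'metal')
>>> dca_dishin(ic, paths, "platinum", "palladium")
('precious',)
```

*gold*'s second route to *metal* (via *coinage*) is an interpretation
*platinum* lacks, so the pair is penalised by averaging in the less
informative *metal*; *silver*/*gold*, whose multiple inheritance is
parallel (all PD = 0), keep the full MICA information.

On the hydroxylase fixture — two 7-alpha-hydroxylase activities that are
each children of both *steroid hydroxylase* (IC 0.6671) and an
*oxidoreductase acting with oxygen* class (IC 0.3846):

```python
>>> h = hydroxylase_fixture()
>>> hp = transitive_closure_paths(h.dag)
>>> hic = h.ic_table()
>>> from dishin.fixtures import HYDROXYLASE_LEAF_1 as l1, HYDROXYLASE_LEAF_2 as l2
>>> share_grasm(hic, hp, h.dag, l1, l2).value
0.52585
>>> share_dishin(hic, hp, l1, l2).value
0.6671
```

GraSM averages the two disjunctive ancestors down to 0.52585 even though
both concepts share both interpretations equally; DiShIn sees equal path
counts everywhere (one group), keeps the MICA alone and reports 0.6671.

## Command line

```sh
dishin synth --n-concepts 200 --edge-density 1.9 --n-entities 50 --seed 7 \
       --out-obo go.obo --out-gaf go.gaf
dishin precompute --obo go.obo --gaf go.gaf --out go.db
dishin termsim --store go.db --pairs pairs.tsv --share dishin --measure resnik
dishin entsim  --store go.db --pairs protein_pairs.tsv --share dishin --measure lin
dishin stats   --scores scores.tsv --gold seqsim.tsv --baseline resnik=0.7397
```

`stats` reports the Pearson correlation with a gold standard plus Fisher
z-tests against named baseline coefficients and Fisher-transform
confidence intervals.

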