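# Methods

## Model

An ontology is a DAG of concepts with child→parent edges along the
hierarchical relations `is_a` and `part_of` (the relation set is
configurable; only `is_a` is used by default; cross-cutting relations such
as `regulates` are out of scope). All path language is upward:
`Paths(c, a)` is the number of distinct directed paths from `c` to an
ancestor `a`, computed by dynamic programming over a topological order —
a directly connected pair has one path per edge and otherwise
`Paths(c, a) = Σ_p Paths(p, a)` over the parents `p` of `c`, since every
upward path leaves `c` through exactly one parent. The closure is stored
with the counts (`PathTable`) and drives everything downstream.

**Reflexivity convention.** `Anc(c)` includes `c` and `Paths(c, c) = 1`
(the empty path). This is a convention, not a theorem: it makes
self-comparison well defined (`Share(c, c) = IC(c)`, Lin self-similarity
1, Jiang-Conrath self-distance 0) and makes the SQL predicate
`Paths(c1, a) > 0 AND Paths(c2, a) > 0` coincide exactly with the
common-ancestor set.

**Information content.** Given an annotation corpus,
`freq(c)` = number of *distinct* entities annotated to `c` or any
descendant (set semantics — an entity annotated to two descendants counts
once), `maxFreq = max_c freq(c)` (the root frequency when a root exists),
and `IC(c) = −log(freq(c)/maxFreq)`. Zero-frequency concepts get no IC
rather than a smoothed one: a *query* concept without IC is an error; a
common *ancestor* without IC is treated as outside the common-ancestor
set, with a logged warning. The log base defaults to `e` and is
configurable (`2`, `10`); Lin similarity is invariant to it, Resnik and
Jiang-Conrath scale by `1/ln(base)` — asserted by test.

## Shared information

* `Share_mica = max{IC(a) : a ∈ CA(c1, c2)}`.
* `Share_grasm` = mean IC over the greedily selected disjunctive common
  ancestors: visit CA in descending-IC order starting from the MICA; a
  candidate is added iff at least one of the two concepts has an upward
  path to it containing no already-selected ancestor. The starting concept
  counts as lying on its own paths, which is what makes self-comparison
  terminate at `{c}` and makes the selection collapse to the MICA on any
  tree. The membership test is reachability in the DAG with the selected
  nodes deleted — exponential path enumeration is never needed, but GraSM
  remains the brute-force comparator here and is not otherwise optimised.
* `Share_dishin` = mean IC over one representative per path-difference
  class: group CA by `PD(c1, c2, a) = |Paths(c1, a) − Paths(c2, a)|` and
  keep the maximal-IC member of each group.

The published definitions of both DCA sets contain formal slips (a strict
inequality quantified over the element itself, and an unsatisfiable path
condition); the formulations above are the readings that reproduce every
documented worked value, and we adopt them as this package's definitions.

All ties (equal IC within a PD group, equal IC at the MICA, ordering of a
DCA set) break deterministically: descending IC, then lexicographically
ascending concept id. Ties affect only which representative is reported,
never the shared-information value.

Disjoint roots (e.g. cross-namespace comparisons) give `Share = 0` with an
empty DCA set and a warning — never an exception — so entity-level
aggregation over mixed annotation sets degrades gracefully.

Invariants maintained by the test suite: `Share_dishin ≤ Share_mica` and
`Share_grasm ≤ Share_mica` with equality whenever the DCA set is a
singleton (the MICA always belongs to both sets); symmetry under swapping
the pair; on trees all three coincide; the DP-based DiShIn equals a
recomputation from exhaustively enumerated paths on random DAGs.

## Measures and entity similarity

Resnik (`Share`), Lin (`2·Share/(IC1+IC2)`, defined 0 when the denominator
is 0, i.e. a root compared with a root) and Jiang-Conrath
(`IC1 + IC2 − 2·Share`, kept as a distance, no similarity transform) each
accept any share backend. Entities are compared by the symmetric
best-match average: the mean over one annotation set of the best
counterpart in the other, averaged over both directions ("best" is the
minimum for the Jiang-Conrath distance). Since corpus-derived IC is
monotone along ancestry, `Share ≤ IC(MICA) ≤ min(IC1, IC2)` for every
backend and Lin stays in `[0, 1]`; with hand-assigned (non-corpus) IC
tables this can fail, so the bound is monitored in tests rather than
clamped in code.

## Precomputed store

Path counts and IC are computed once per ontology/corpus release and
persisted in SQLite: `IC(concept, value)` and
`Paths(concept, ancestor, value)` with a composite primary key and a
concept index. A pairwise DiShIn query is then a single SQL statement —
self-join of `Paths` on the ancestor, `GROUP BY` the absolute count
difference, `MAX(IC)` per group, `AVG` — whose inner join yields exactly
one row per common ancestor (asserted by row accounting, not wall-clock).
The store additionally carries `Concepts`, `Edges` and `Annotations`
tables plus metadata (input fingerprint, relation set, log base, build
time) so one file is self-contained for every CLI operation, and a rebuild
over a store made from different inputs is refused. SQL's grouped `MAX`
does not pin the representative row under IC ties; the DCA-reporting query
applies the same descending-IC/ascending-id sort as the in-memory engine,
keeping both routes bit-consistent (equivalence asserted to 1e-9 on every
fixture and on batches of random DAGs).

## Fixtures and synthetic data

The **metals** fixture is the eight-concept classification with
*silver*/*gold* doubly inherited (precious, coinage), *copper* under
coinage only. Its bundled corpus annotates one distinct entity directly to
each concept, so every concept has positive frequency and the IC ordering
needed by the worked examples (`IC(copper) > IC(coinage) > IC(metal)`)
falls out of the corpus rather than being assigned.

The **hydroxylase** fixture is a minimal five-node reconstruction of the
multiple-inheritance neighbourhood of *steroid 7-alpha-hydroxylase
activity* and *oxysterol 7-alpha-hydroxylase activity*: both leaves are
children of both *steroid hydroxylase* (SH) and an *oxidoreductase acting
with oxygen* class (OWO), SH is a child of OWO, OWO of the top
oxidoreductase — the smallest topology giving each leaf one path to SH
and two to the top. IC values 0.6671 (SH) and 0.3846 (OWO) are the
documented study values; the top's 0.1000 and the leaves' 1.0 are
arbitrary fixture constants on which no asserted output depends (GraSM's
average excludes the top; DiShIn selects SH alone). The fixture is a
reconstruction, not a snapshot of any GO release.

The **generator** emulates a rooted subontology plus corpus: nodes are
created in topological order, each non-root node draws one uniform parent
among earlier nodes (rooted and connected by construction), then uniform
extra (child, earlier-parent) edges are added up to
`round(density·(n−1))` — exactly a tree at density 1.0. Densities are
chosen per test in the range observed across the three GO subontologies
(1.16–1.95 edges per node); entities receive `1 + Poisson(2.7)`
uniformly-sampled concepts (mean 3.7, a typical per-protein
molecular-function annotation load). Everything derives from a single
integer seed; identical specs produce identical edge lists. What the
generator does *not* emulate: GO's depth/branching profile, the skewed
(non-uniform) annotation frequencies of real corpora, evidence-code
structure, and inter-namespace structure — so passing property tests
establish algorithmic correctness and the documented orderings, not
real-data correlation performance, which requires the external
protein-pair evaluation platform and the historical GO/UniProt releases.

## Evaluation statistics

Measures are conventionally benchmarked by Pearson correlation with
sequence similarity over a fixed protein-pair set. Two coefficients on the
same sample of size `n` are compared via Fisher's transformation:
`z = (atanh r − atanh ρ0)·√(n−3)` with a two-sided normal p-value
(two-sided because a near-zero observed difference must give p ≈ 1, as in
the published molecular-function comparison). Confidence intervals are
`tanh(atanh r ± z_level/√(n−3))`; `separation_confidence_level` returns
the largest level at which two intervals just separate,
`2Φ(|Δ atanh|·√(n−3)/2) − 1`, which is the quantity the published
confidence-level grid tabulates. With the printed (4-decimal) biological
process coefficients the DiShIn-vs-GraSM separation threshold computes to
97.7% — rounding to the tabulated 98%, at which exact level the two
intervals still marginally overlap; the test suite therefore asserts the
interval separation against the Resnik baseline (which holds at 98%) and
the rounded separation thresholds (20/99/98) for the whole column.

## Problem sizes

Worked-example checks run on the 5- and 8-node fixtures. Property and
equivalence batches use 100 seeded random DAGs of 6–12 concepts — small
enough for the exponential enumeration oracles to stay exact — and
generator calibration uses n = 200. The full-scale published evaluation
(13,430 protein pairs against an August-2008 ontology release) is out of
scope here; the dual-route equivalences and ordering properties are the
desk-scale substitute.

## Known limitations

Subsumption only: no `regulates`, no OWL semantics, no relatedness beyond
shared ancestry. GraSM is intentionally the unoptimised comparator. IC
variants (structural IC, simGIC-style graph overlap) are not provided.
Cyclic inputs are rejected, never repaired.
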