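"""Deterministic worked-example fixtures and a seeded random generator.

Two hand-built fixtures anchor the test surface:

* the **metals** DAG — a small classification of metals in which *gold* and
  *silver* are multiply inherited as both precious and coinage metals; the
  canonical illustration of why path differences detect non-parallel
  multiple inheritance.
* the **hydroxylase** DAG — a minimal reconstruction of the molecular
  function subgraph around *steroid 7-alpha-hydroxylase activity* and
  *oxysterol 7-alpha-hydroxylase activity*: both leaves hang under both
  *steroid hydroxylase* (IC 0.6671) and *oxidoreductase acting with
  oxygen* (IC 0.3846), which are themselves chained.  It is the minimal
  topology reproducing the documented path counts (one path from each leaf
  to steroid hydroxylase, two to the top oxidoreductase), not a snapshot of
  any real GO release.

The random generator emits rooted DAGs at a requested edge density plus an
annotation corpus; densities around 1.2–1.9 emulate the three GO
subontologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .annotation_ic import AnnotationCorpus, ICTable
from .dag_core import Concept, OntologyDAG
from .errors import ParameterError


@dataclass
class FixtureBundle:
    """A fixture DAG plus optional corpus, IC override and expected outputs.

    ``expected`` maps a descriptive key to ``{"value": ..., "note": ...}``
    where the note records where the expectation comes from.
    """

    dag: OntologyDAG
    corpus: AnnotationCorpus | None = None
    ic_override: dict[str, float] | None = None
    expected: Mapping[str, dict[str, Any]] = field(default_factory=dict)

    def ic_table(self, log_base: float = np.e) -> ICTable:
        """The override ICs as an :class:`ICTable` (fixture log units)."""
        if self.ic_override is None:
            raise ValueError("fixture carries no IC override")
        return ICTable(ic=dict(self.ic_override), log_base=log_base)


def metals_fixture() -> FixtureBundle:
    """The metals classification DAG with its documented expected values.

    Eight concepts; *silver* and *gold* are both precious and coinage,
    *copper* is coinage only, *platinum* and *palladium* precious only.
    The bundled corpus annotates one distinct entity directly to each
    concept, giving every concept a positive frequency.
    """
    names = [
        "metal", "precious", "coinage",
        "platinum", "palladium", "silver", "gold", "copper",
    ]
    edges = [
        ("precious", "metal", "is_a"),
        ("coinage", "metal", "is_a"),
        ("platinum", "precious", "is_a"),
        ("palladium", "precious", "is_a"),
        ("silver", "precious", "is_a"),
        ("silver", "coinage", "is_a"),
        ("gold", "precious", "is_a"),
        ("gold", "coinage", "is_a"),
        ("copper", "coinage", "is_a"),
    ]
    dag = OntologyDAG(
        (Concept(id=n, name=n, namespace="metals") for n in names), edges
    )
    corpus = AnnotationCorpus({f"entity-{n}": {n} for n in names})
    expected = {
        "pd(platinum,palladium,precious)": {"value": 0, "note": "worked example"},
        "pd(platinum,palladium,metal)": {"value": 0, "note": "worked example"},
        "pd(platinum,gold,precious)": {"value": 0, "note": "worked example"},
        "pd(platinum,gold,metal)": {"value": 1, "note": "worked example"},
        "pd(silver,gold,precious)": {"value": 0, "note": "worked example"},
        "pd(silver,gold,coinage)": {"value": 0, "note": "worked example"},
        "pd(silver,gold,metal)": {"value": 0, "note": "worked example"},
        "paths(gold,metal)": {"value": 2, "note": "implied by pd listing"},
        "paths(platinum,metal)": {"value": 1, "note": "implied by pd listing"},
        "dca_dishin(platinum,gold)": {
            "value": {"precious", "metal"}, "note": "worked example",
        },
        "dca_dishin(platinum,palladium)": {
            "value": {"precious"}, "note": "worked example",
        },
        "dca_grasm(silver,gold)": {
            "value": {"precious", "coinage"}, "note": "worked example",
        },
        "dca_grasm(platinum,palladium)": {
            "value": {"precious"}, "note": "worked example",
        },
    }
    return FixtureBundle(dag=dag, corpus=corpus, expected=expected)


#: Concept ids of the hydroxylase reconstruction.
HYDROXYLASE_LEAF_1 = "steroid-7-alpha-hydroxylase-activity"
HYDROXYLASE_LEAF_2 = "oxysterol-7-alpha-hydroxylase-activity"
STEROID_HYDROXYLASE = "steroid-hydroxylase-activity"
OXIDOREDUCTASE_O2 = "oxidoreductase-activity-on-paired-donors-with-o2"
OXIDOREDUCTASE = "oxidoreductase-activity"


def hydroxylase_fixture() -> FixtureBundle:
    """Minimal multiple-inheritance subgraph of two hydroxylase activities.

    The two leaves are each a direct child of both *steroid hydroxylase*
    (SH) and the *oxidoreductase acting with oxygen* class (OWO); SH is
    itself a child of OWO, which hangs under the top *oxidoreductase*.
    Hence each leaf has 1 path to SH and 2 paths to OWO and to the top.
    The IC override pins SH at 0.6671 and OWO at 0.3846 (the documented
    study values); the top's IC (0.1000) and the leaf ICs (1.0) are
    arbitrary fixture constants that no expected output depends on.
    """
    l1, l2 = HYDROXYLASE_LEAF_1, HYDROXYLASE_LEAF_2
    sh, owo, top = STEROID_HYDROXYLASE, OXIDOREDUCTASE_O2, OXIDOREDUCTASE
    edges = [
        (l1, sh, "is_a"),
        (l2, sh, "is_a"),
        (l1, owo, "is_a"),
        (l2, owo, "is_a"),
        (sh, owo, "is_a"),
        (owo, top, "is_a"),
    ]
    dag = OntologyDAG(
        (
            Concept(id=i, name=i.replace("-", " "), namespace="molecular_function")
            for i in (l1, l2, sh, owo, top)
        ),
        edges,
    )
    ic_override = {sh: 0.6671, owo: 0.3846, top: 0.1000, l1: 1.0, l2: 1.0}
    expected = {
        "paths(leaf,steroid-hydroxylase)": {"value": 1, "note": "stated path count"},
        "paths(leaf,top-oxidoreductase)": {"value": 2, "note": "stated path count"},
        "share_grasm(l1,l2)": {
            "value": (0.6671 + 0.3846) / 2, "note": "documented 0.5259"},
        "share_dishin(l1,l2)": {"value": 0.6671, "note": "documented 0.6671"},
        "dca_grasm(l1,l2)": {"value": {sh, owo}, "note": "two disjunctive ancestors"},
        "dca_dishin(l1,l2)": {"value": {sh}, "note": "singleton MICA"},
    }
    return FixtureBundle(dag=dag, ic_override=ic_override, expected=expected)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the random DAG + corpus generator.

    target_edge_density:
        edges per node; 1.0 yields a tree, GO-like values are 1.16
        (molecular function) to 1.95 (biological process).
    mean_annotations:
        average annotated concepts per entity; the default 3.7 mirrors a
        typical per-protein molecular-function annotation load.
    """

    n_concepts: int
    target_edge_density: float = 1.2
    n_entities: int = 20
    seed: int = 0
    mean_annotations: float = 3.7


def synth_ontology(spec: SynthSpec) -> tuple[OntologyDAG, AnnotationCorpus]:
    """Generate a rooted random DAG and an annotation corpus, reproducibly.

    Nodes are created in topological order; each non-root node first draws
    one parent among earlier nodes (guaranteeing a single-rooted, connected
    DAG), then extra (child, earlier-parent) edges are added uniformly
    until ``round(density · (n − 1))`` edges exist — a tree exactly at
    density 1.0, and within 10% of the target edges-per-node for any
    non-trivial size.  Entities are annotated to uniformly sampled
    concepts, at least one each.
    """
    n = spec.n_concepts
    if n < 1:
        raise ParameterError("n_concepts must be >= 1")
    if spec.n_entities < 1:
        raise ParameterError("n_entities must be >= 1")
    target_edges = round(spec.target_edge_density * (n - 1))
    max_edges = n * (n - 1) // 2
    if target_edges < n - 1:
        raise ParameterError(
            f"edge density {spec.target_edge_density} cannot keep a DAG on "
            f"{n} concepts rooted (needs >= 1.0)"
        )
    if target_edges > max_edges:
        raise ParameterError(
            f"edge density {spec.target_edge_density} asks for {target_edges} "
            f"edges but {n} concepts admit at most {max_edges}"
        )
    rng = np.random.default_rng(spec.seed)
    width = len(str(max(n - 1, 1)))
    ids = [f"syn:{i:0{width}d}" for i in range(n)]
    edge_set: set[tuple[int, int]] = set()
    for child in range(1, n):
        edge_set.add((child, int(rng.integers(0, child))))
    spare = [
        (child, parent)
        for child in range(2, n)
        for parent in range(child)
        if (child, parent) not in edge_set
    ]
    extra = target_edges - len(edge_set)
    if extra > 0:
        chosen = rng.choice(len(spare), size=extra, replace=False)
        edge_set.update(spare[i] for i in sorted(chosen))
    dag = OntologyDAG(
        (Concept(id=i, name=i, namespace="synthetic") for i in ids),
        ((ids[c], ids[p], "is_a") for c, p in sorted(edge_set)),
    )
    annotations: dict[str, set[str]] = {}
    for e in range(spec.n_entities):
        k = min(n, 1 + int(rng.poisson(max(spec.mean_annotations - 1.0, 0.0))))
        chosen = rng.choice(n, size=k, replace=False)
        annotations[f"ent:{e:04d}"] = {ids[i] for i in chosen}
    return dag, AnnotationCorpus(annotations)
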