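"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own dynamic programs:
path counts come from explicit path enumeration on a freshly built graph,
reachability from a hand-rolled breadth-first walk over the raw edge list.
"""

from __future__ import annotations

import networkx as nx
import pytest

from dishin import (
    AnnotationCorpus,
    OntologyDAG,
    SynthSpec,
    hydroxylase_fixture,
    information_content,
    metals_fixture,
    propagate_frequencies,
    synth_ontology,
    transitive_closure_paths,
)
from dishin.fixtures import (
    HYDROXYLASE_LEAF_1,
    HYDROXYLASE_LEAF_2,
)


@pytest.fixture(scope="session")
def metals():
    bundle = metals_fixture()
    paths = transitive_closure_paths(bundle.dag)
    ic = information_content(propagate_frequencies(bundle.dag, bundle.corpus))
    return bundle, paths, ic


@pytest.fixture(scope="session")
def hydroxylase():
    bundle = hydroxylase_fixture()
    paths = transitive_closure_paths(bundle.dag)
    return bundle, paths, bundle.ic_table()


@pytest.fixture(scope="session")
def hydroxylase_leaves():
    return HYDROXYLASE_LEAF_1, HYDROXYLASE_LEAF_2


def build_engine(dag: OntologyDAG, corpus: AnnotationCorpus, log_base: float = 2.718281828459045):
    paths = transitive_closure_paths(dag)
    ic = information_content(propagate_frequencies(dag, corpus), log_base)
    return ic, paths


def random_instance(seed: int, n: int = 10, density: float = 1.5, n_entities: int = 12):
    return synth_ontology(
        SynthSpec(
            n_concepts=n,
            target_edge_density=density,
            n_entities=n_entities,
            seed=seed,
        )
    )


# -- independent oracles ---------------------------------------------------


def oracle_path_count(dag: OntologyDAG, c: str, a: str) -> int:
    """Count upward paths by explicit enumeration (exponential, tiny n)."""
    if c == a:
        return 1
    g = nx.DiGraph()
    g.add_nodes_from(x.id for x in dag.concepts)
    g.add_edges_from((child, parent) for child, parent, _ in dag.edges)
    return sum(1 for _ in nx.all_simple_paths(g, c, a))


def oracle_reachable(dag: OntologyDAG, c: str) -> set[str]:
    """Upward reachability (reflexive) by a plain breadth-first edge walk."""
    up: dict[str, set[str]] = {}
    for child, parent, _ in dag.edges:
        up.setdefault(child, set()).add(parent)
    seen = {c}
    frontier = [c]
    while frontier:
        nxt = []
        for node in frontier:
            for parent in up.get(node, ()):
                if parent not in seen:
                    seen.add(parent)
                    nxt.append(parent)
        frontier = nxt
    return seen


def oracle_dishin(ic, dag: OntologyDAG, c1: str, c2: str) -> float:
    """Recompute DiShIn from enumerated paths: group by |Δpaths|, take the
    max-IC ancestor of each group, average."""
    ca = oracle_reachable(dag, c1) & oracle_reachable(dag, c2)
    ca = {a for a in ca if a in ic}
    groups: dict[int, list[str]] = {}
    for a in ca:
        pd = abs(oracle_path_count(dag, c1, a) - oracle_path_count(dag, c2, a))
        groups.setdefault(pd, []).append(a)
    if not groups:
        return 0.0
    picks = [max(members, key=lambda a: (ic[a], a)) for members in groups.values()]
    values = sorted(ic[a] for a in picks)
    return sum(values) / len(values)
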