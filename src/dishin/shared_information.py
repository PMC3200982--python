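"""Shared information content: MICA, GraSM, and DiShIn.

Three definitions of the information two concepts share in a DAG ontology:

* **MICA** — the classical definition: the IC of the single Most
  Informative Common Ancestor.
* **GraSM** — the mean IC over disjunctive common ancestors selected
  greedily: starting from the MICA, a further common ancestor joins the set
  only if at least one of the two concepts reaches it through an upward
  path avoiding every ancestor already selected (an independent
  interpretation).
* **DiShIn** — the mean IC over one representative per *path-difference*
  class: common ancestors are grouped by
  ``PD(c1, c2, a) = |Paths(c1, a) − Paths(c2, a)|`` and the most informative
  ancestor of each group is kept.  Ancestors reached through the same
  imbalance of interpretations are redundant; parallel interpretations
  shared equally by both concepts (PD = 0) collapse onto the MICA instead
  of dragging the average down.

All three return 0 with an empty ancestor set when the concepts live under
disjoint roots.  Deterministic tie-breaks: within equal IC, the
lexicographically smallest concept id is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import fmean

from .annotation_ic import ICTable
from .dag_core import OntologyDAG, PathTable
from .errors import NotAnAncestorError, ZeroFrequencyError

logger = logging.getLogger(__name__)

SHARE_METHODS = ("mica", "grasm", "dishin")


@dataclass(frozen=True)
class SharedInfoResult:
    """A shared-information value and the ancestor set that produced it.

    ``dca`` is ordered by descending IC (id-ascending among ties); it is
    empty exactly when ``value`` is 0 by the disjoint-roots convention.
    """

    value: float
    dca: tuple[str, ...]
    method: str


@dataclass(frozen=True)
class PDValue:
    """Path difference of one common ancestor for a fixed concept pair."""

    ancestor: str
    pd: int


def path_difference(paths: PathTable, c1: str, c2: str, a: str) -> int:
    """``PD(c1, c2, a) = |Paths(c1, a) − Paths(c2, a)|``.

    *a* must be a common ancestor of the pair (both counts positive).
    """
    k1, k2 = paths.count(c1, a), paths.count(c2, a)
    if k1 == 0 or k2 == 0:
        raise NotAnAncestorError(
            f"{a!r} is not a common ancestor of {c1!r} and {c2!r}"
        )
    return abs(k1 - k2)


def _informative(ic: ICTable, ca: set[str]) -> set[str]:
    """Drop common ancestors without IC (zero corpus frequency), with a log."""
    missing = {a for a in ca if a not in ic}
    if missing:
        logger.warning(
            "ignoring %d common ancestor(s) with undefined information "
            "content: %s",
            len(missing),
            ", ".join(sorted(missing)),
        )
    return ca - missing


def _by_ic(ic: ICTable, ancestors: set[str]) -> list[str]:
    """Descending IC, then ascending id — the package-wide deterministic order."""
    return sorted(ancestors, key=lambda a: (-ic[a], a))


def _require_ic(ic: ICTable, *concepts: str) -> None:
    for c in concepts:
        if c not in ic:
            raise ZeroFrequencyError(
                f"concept {c!r} has no information content (zero corpus "
                "frequency); similarity is undefined"
            )


def share_mica(ic: ICTable, ca: set[str]) -> SharedInfoResult:
    """Shared information as the IC of the most informative common ancestor."""
    usable = _informative(ic, set(ca))
    if not usable:
        return SharedInfoResult(0.0, (), "mica")
    mica = _by_ic(ic, usable)[0]
    return SharedInfoResult(ic[mica], (mica,), "mica")


def dca_dishin(ic: ICTable, paths: PathTable, c1: str, c2: str) -> tuple[str, ...]:
    """DiShIn disjunctive common ancestors of a pair.

    Partition the common ancestors by path difference and keep the most
    informative member of each class; returned in descending-IC order.
    """
    usable = _informative(ic, paths.common_ancestors(c1, c2))
    groups: dict[int, list[str]] = {}
    for a in usable:
        groups.setdefault(path_difference(paths, c1, c2, a), []).append(a)
    selected = {_by_ic(ic, set(members))[0] for members in groups.values()}
    return tuple(_by_ic(ic, selected))


def share_dishin(ic: ICTable, paths: PathTable, c1: str, c2: str) -> SharedInfoResult:
    """Mean IC over the DiShIn disjunctive common ancestors."""
    _require_ic(ic, c1, c2)
    dca = dca_dishin(ic, paths, c1, c2)
    if not dca:
        logger.warning("no common ancestors for (%r, %r); shared IC is 0", c1, c2)
        return SharedInfoResult(0.0, (), "dishin")
    return SharedInfoResult(fmean(ic[a] for a in dca), dca, "dishin")


def _reaches_avoiding(
    dag: OntologyDAG, concept: str, target: str, blocked: set[str]
) -> bool:
    """Is there an upward path concept→target visiting no blocked node?

    The starting concept itself counts as part of the path, the target does
    not (it is the candidate under test, never already selected).
    """
    if concept in blocked:
        return False
    if concept == target:
        return True
    stack = [concept]
    seen = {concept}
    while stack:
        node = stack.pop()
        for parent in dag.parents(node):
            if parent == target:
                return True
            if parent not in seen and parent not in blocked:
                seen.add(parent)
                stack.append(parent)
    return False


def grasm_dca(
    ic: ICTable, paths: PathTable, dag: OntologyDAG, c1: str, c2: str
) -> tuple[str, ...]:
    """GraSM disjunctive common ancestors of a pair (greedy selection).

    Visit common ancestors in descending-IC order starting from the MICA; a
    candidate joins the selection iff at least one of the two concepts has
    an upward path to it that avoids every already-selected ancestor, i.e.
    the candidate carries an interpretation not subsumed by the selection.
    On a tree every upward path from a concept passes through the MICA, so
    the result degenerates to the singleton MICA.
    """
    usable = _informative(ic, paths.common_ancestors(c1, c2))
    if not usable:
        return ()
    ordered = _by_ic(ic, usable)
    selected: list[str] = [ordered[0]]
    for candidate in ordered[1:]:
        blocked = set(selected)
        if _reaches_avoiding(dag, c1, candidate, blocked) or _reaches_avoiding(
            dag, c2, candidate, blocked
        ):
            selected.append(candidate)
    return tuple(selected)


def share_grasm(
    ic: ICTable, paths: PathTable, dag: OntologyDAG, c1: str, c2: str
) -> SharedInfoResult:
    """Mean IC over the GraSM disjunctive common ancestors."""
    _require_ic(ic, c1, c2)
    dca = grasm_dca(ic, paths, dag, c1, c2)
    if not dca:
        logger.warning("no common ancestors for (%r, %r); shared IC is 0", c1, c2)
        return SharedInfoResult(0.0, (), "grasm")
    return SharedInfoResult(fmean(ic[a] for a in dca), dca, "grasm")


def shared_information(
    method: str,
    ic: ICTable,
    paths: PathTable,
    dag: OntologyDAG,
    c1: str,
    c2: str,
) -> SharedInfoResult:
    """Dispatch on ``method`` in {mica, grasm, dishin}; uniform IC checks."""
    if method not in SHARE_METHODS:
        raise ValueError(f"unknown share method {method!r}; choose from {SHARE_METHODS}")
    if method == "mica":
        _require_ic(ic, c1, c2)
        return share_mica(ic, paths.common_ancestors(c1, c2))
    if method == "grasm":
        return share_grasm(ic, paths, dag, c1, c2)
    return share_dishin(ic, paths, c1, c2)
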