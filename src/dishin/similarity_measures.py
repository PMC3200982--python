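"""Concept-level measures (Resnik, Lin, Jiang-Conrath) and entity-level
best-match-average similarity.

Any of the three shared-information backends (mica, grasm, dishin) can be
plugged into any of the three classical measures:

* Resnik:  ``Sim = Share(c1, c2)``
* Lin:     ``Sim = 2·Share / (IC(c1) + IC(c2))``  (0 when the denominator is 0)
* Jiang-Conrath:  ``Dist = IC(c1) + IC(c2) − 2·Share``  — a *distance*,
  reported as such (small = similar).

Entities (e.g. proteins) annotated to several concepts are compared by the
symmetric best-match average: each annotation of one entity is paired with
its best-scoring counterpart in the other entity's annotation set, the two
directional averages are then averaged.  For Jiang-Conrath "best" means the
minimum and the aggregate remains a distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

from .annotation_ic import ICTable
from .dag_core import OntologyDAG, PathTable
from .errors import UndefinedSimilarityError
from .shared_information import SHARE_METHODS, shared_information

MEASURES = ("resnik", "lin", "jc")


@dataclass(frozen=True)
class MeasureSpec:
    """A concept measure paired with a shared-information backend."""

    measure: str = "resnik"
    share_method: str = "dishin"

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; choose from {MEASURES}")
        if self.share_method not in SHARE_METHODS:
            raise ValueError(
                f"unknown share method {self.share_method!r}; "
                f"choose from {SHARE_METHODS}"
            )

    @property
    def is_distance(self) -> bool:
        return self.measure == "jc"


def concept_similarity(
    spec: MeasureSpec,
    ic: ICTable,
    paths: PathTable,
    dag: OntologyDAG,
    c1: str,
    c2: str,
) -> float:
    """Similarity (or JC distance) between two concepts under *spec*."""
    share = shared_information(spec.share_method, ic, paths, dag, c1, c2).value
    if spec.measure == "resnik":
        return share
    ic_sum = ic[c1] + ic[c2]
    if spec.measure == "lin":
        return 2.0 * share / ic_sum if ic_sum > 0 else 0.0
    return ic_sum - 2.0 * share  # jc


def entity_similarity_bma(
    spec: MeasureSpec,
    ic: ICTable,
    paths: PathTable,
    dag: OntologyDAG,
    annots1: set[str],
    annots2: set[str],
) -> float:
    """Symmetric best-match average over two annotation sets.

    Annotations without defined IC are dropped first; if either side is
    left empty the comparison is undefined and raises.
    """
    a1 = sorted(c for c in annots1 if c in ic)
    a2 = sorted(c for c in annots2 if c in ic)
    if not a1 or not a2:
        raise UndefinedSimilarityError(
            "best-match average undefined: annotation set empty after "
            f"dropping concepts without IC (left={len(a1)}, right={len(a2)})"
        )
    best = max if not spec.is_distance else min
    matrix = {
        (x, y): concept_similarity(spec, ic, paths, dag, x, y)
        for x in a1
        for y in a2
    }
    forward = fmean(best(matrix[(x, y)] for y in a2) for x in a1)
    backward = fmean(best(matrix[(x, y)] for x in a1) for y in a2)
    return (forward + backward) / 2.0
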