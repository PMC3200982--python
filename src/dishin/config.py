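"""Global conventions bundled in one serialisable configuration object."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import IO

from .dag_core import DEFAULT_RELATIONS, HIERARCHICAL_RELATIONS
from .errors import ParameterError

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass(frozen=True)
class SimilarityConfig:
    """Conventions shared across the pipeline.

    relations:
        hierarchical relations used for ancestors; subset of
        ``{is_a, part_of}`` (default ``{is_a}``).
    log_base:
        base of the IC logarithm (default ``e``).  Lin similarity is
        invariant to it; Resnik and Jiang-Conrath scale by ``1/ln(base)``.
    namespace:
        optional restriction to one subontology.
    share_method / measure:
        defaults for similarity computations.
    seed:
        seed for synthetic-data generation, when applicable.
    """

    relations: frozenset[str] = DEFAULT_RELATIONS
    log_base: float = math.e
    namespace: str | None = None
    share_method: str = "dishin"
    measure: str = "resnik"
    seed: int | None = None

    def __post_init__(self) -> None:
        bad = set(self.relations) - HIERARCHICAL_RELATIONS
        if bad:
            raise ParameterError(f"unsupported relations {sorted(bad)}")
        if self.log_base <= 0 or self.log_base == 1:
            raise ParameterError("log base must be positive and != 1")

    # -- flat key=value (de)serialisation ----------------------------------

    def to_stream(self, stream: IO[str]) -> None:
        stream.write(f"relations={','.join(sorted(self.relations))}\n")
        base = {v: k for k, v in _LOG_BASES.items()}.get(self.log_base)
        stream.write(f"log_base={base or repr(self.log_base)}\n")
        stream.write(f"namespace={self.namespace or ''}\n")
        stream.write(f"share_method={self.share_method}\n")
        stream.write(f"measure={self.measure}\n")
        stream.write(f"seed={'' if self.seed is None else self.seed}\n")

    @classmethod
    def from_stream(cls, stream: IO[str]) -> "SimilarityConfig":
        values: dict[str, str] = {}
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParameterError(f"config line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        cfg = cls()
        if "relations" in values:
            cfg = replace(cfg, relations=frozenset(
                r for r in values["relations"].split(",") if r
            ))
        if values.get("log_base"):
            cfg = replace(cfg, log_base=parse_log_base(values["log_base"]))
        if values.get("namespace"):
            cfg = replace(cfg, namespace=values["namespace"])
        if values.get("share_method"):
            cfg = replace(cfg, share_method=values["share_method"])
        if values.get("measure"):
            cfg = replace(cfg, measure=values["measure"])
        if values.get("seed"):
            cfg = replace(cfg, seed=int(values["seed"]))
        return cfg


def parse_log_base(token: str) -> float:
    """Accept ``e``, ``2``, ``10`` or any float literal > 0, != 1."""
    if token in _LOG_BASES:
        return _LOG_BASES[token]
    try:
        value = float(token)
    except ValueError:
        raise ParameterError(f"unparseable log base {token!r}") from None
    if value <= 0 or value == 1:
        raise ParameterError("log base must be positive and != 1")
    return value
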