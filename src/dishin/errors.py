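"""Exception hierarchy.

Every error raised by this package derives from :class:`DishinError`; the
``exit_code`` attribute gives the process exit status used by the CLI so
that distinct failure modes are distinguishable in shell pipelines.
"""


class DishinError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class OboParseError(DishinError):
    """Malformed OBO input; the message names the offending line."""

    exit_code = 3


class GafParseError(DishinError):
    """Malformed GAF input; the message names the offending line."""

    exit_code = 3


class UnknownConceptError(DishinError, KeyError):
    """A concept id was not found in the ontology / table queried."""

    exit_code = 4

    def __str__(self) -> str:  # KeyError quotes its repr; keep a plain message
        return Exception.__str__(self)


class CycleError(DishinError):
    """The hierarchical relation graph is not acyclic."""

    exit_code = 5


class NotAnAncestorError(DishinError, ValueError):
    """A path-difference query named a concept that is not a common ancestor."""

    exit_code = 6


class EmptyCorpusError(DishinError):
    """No usable annotations: information content is undefined."""

    exit_code = 6


class ZeroFrequencyError(DishinError):
    """A queried concept has no corpus frequency, hence no information content."""

    exit_code = 6


class UndefinedSimilarityError(DishinError):
    """Entity comparison impossible (no annotated concepts with defined IC)."""

    exit_code = 6


class UndefinedCorrelationError(DishinError):
    """Correlation undefined (zero variance or too few points)."""

    exit_code = 6


class ParameterError(DishinError, ValueError):
    """Invalid or unsatisfiable parameter combination."""

    exit_code = 7


class StoreError(DishinError):
    """Precomputed-store failure (unwritable destination, metadata mismatch)."""

    exit_code = 8
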