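"""Exception hierarchy.

Every error raised by the package derives from :class:`TCMSpaceError`, so
callers can catch domain failures without catching programming errors.
"""


class TCMSpaceError(Exception):
    """Base class for all package errors."""


class EmptyInput(TCMSpaceError):
    """An input collection was empty where at least one record is required."""


class DuplicateRecord(TCMSpaceError):
    """A record identifier occurred more than once."""


class ValidationError(TCMSpaceError):
    """A domain object failed validation; the message lists offending records."""


class DegenerateGraph(TCMSpaceError):
    """A path-based statistic was requested on a graph with no reachable pairs."""


class InsufficientSupport(TCMSpaceError):
    """Too few distinct positive degrees to fit a power law."""


class UnknownHerb(TCMSpaceError):
    """A pair-set member is absent from the network or embedding."""


class EmptyGroup(TCMSpaceError):
    """A herb declared in the vocabulary has no compounds."""


class InvalidMass(TCMSpaceError):
    """A compound mass was zero, negative, or non-finite."""


class InsufficientData(TCMSpaceError):
    """Fewer herbs than requested principal components."""


class SpaceMismatch(TCMSpaceError):
    """Distance requested between points of two different embeddings."""


class InvalidPairCount(TCMSpaceError):
    """Permutation pair-set size outside [1, number of available pairs]."""


class PairSetMismatch(TCMSpaceError):
    """The three per-space reports were not built from the same pair set."""


class GenerationFailure(TCMSpaceError):
    """Synthetic generation could not satisfy its constraints after bounded retries."""


class ParseError(TCMSpaceError):
    """A file did not parse under the declared dialect.

    Carries the path and (1-based) line number where parsing failed.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
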