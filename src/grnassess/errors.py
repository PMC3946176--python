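"""Exception hierarchy.

All package-specific failures derive from :class:`GrnAssessError`, so callers
(and the command-line wrapper) can distinguish bad input from genuine bugs.
"""


class GrnAssessError(Exception):
    """Base class for all errors raised by grnassess."""


class SelfLoopError(GrnAssessError):
    """A self-regulatory edge (u, u) was supplied where the edge universe
    excludes auto-regulation."""


class CyclicGraphError(GrnAssessError):
    """An operation defined only for acyclic digraphs received a digraph
    containing a directed cycle."""


class TooLargeError(GrnAssessError):
    """Exhaustive ensemble enumeration was requested on a node set larger
    than the configured cap."""


class MissingBoundsError(GrnAssessError):
    """Inferability-aware scoring was requested without ensemble bounds."""


class UniverseMismatchError(GrnAssessError):
    """A predicted edge refers to a gene outside the gold-standard universe,
    or is a self-loop."""


class DegenerateGoldError(GrnAssessError):
    """The positive (P') or negative (N') class is empty, so ROC/PR curves
    are undefined."""


class ShortRankingError(GrnAssessError):
    """A ranked edge list is shorter than the analysis requires."""


class MismatchedTeamsError(GrnAssessError):
    """Two team rankings do not contain the same set of teams."""


class ZeroNullError(GrnAssessError):
    """A null-distribution percentile AUC is zero, so ratio scores are
    undefined."""


class ParseError(GrnAssessError):
    """A gold-standard or prediction file could not be parsed.

    Carries the 1-based line number when the failure is localised.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateEdgeError(GrnAssessError):
    """The same edge occurs more than once in a ranked prediction."""


class InfeasibleSpecError(GrnAssessError):
    """A synthetic-network motif specification does not fit in the requested
    number of nodes."""
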