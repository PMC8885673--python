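"""Exception hierarchy.

Every analysis-facing failure raises a subclass of :class:`CoinflamError`,
so callers (and the CLI) can distinguish bad scientific input from bugs.
"""


class CoinflamError(ValueError):
    """Base class for all package-specific errors."""


class InvalidDesignError(CoinflamError):
    """A simulation design or effect model violates its invariants."""


class MissingProbeError(CoinflamError):
    """Gene-set probes absent from the expression matrix."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            f"{len(self.missing)} partition probe(s) missing from matrix: "
            f"{', '.join(map(str, self.missing[:10]))}"
            + ("..." if len(self.missing) > 10 else "")
        )


class MissingSampleError(CoinflamError):
    """A referenced sample id is not a column of the expression matrix."""


class UndefinedRatioError(CoinflamError):
    """Denominator of the composite index is zero."""


class DegenerateTestError(CoinflamError):
    """A paired test has no usable differences (all zero)."""


class EmptySampleError(CoinflamError):
    """A community sample has zero total counts."""


class InvalidDistanceError(CoinflamError):
    """Distance matrix is not symmetric / hollow."""


class NoEvidenceError(CoinflamError):
    """Signed regulator network shares no targets with the observations."""


class DegenerateClassError(CoinflamError):
    """A class has too few samples for a between-class contrast."""


class EmptyInputError(CoinflamError):
    """An operation received an empty collection where data is required."""
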