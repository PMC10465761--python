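"""Named error conditions raised across the pipeline.

Each validation failure has its own class so callers (and the CLI) can
report which contract was violated rather than a generic parse error.
"""


class SigreverseError(Exception):
    """Base class for all pipeline errors."""


class UnknownSampleError(SigreverseError):
    """Sample ids in the group table and expression matrix disagree."""


class DuplicateGeneError(SigreverseError):
    """A gene identifier occurs more than once in a matrix."""


class NonNumericValueError(SigreverseError):
    """An expression or statistic cell could not be parsed as a number."""


class GroupSizeError(SigreverseError):
    """A case or control group has fewer than two samples."""


class EmptyMatrixError(SigreverseError):
    """An expression matrix with no genes or no samples."""


class EmptySignatureError(SigreverseError):
    """The differential screen retained no up or no down genes."""


class DisjointSignatureError(SigreverseError):
    """No disease-signature gene overlaps a drug's perturbation profile."""


class MissingStandardError(SigreverseError):
    """A receptor in the docking table has no standard-drug reference."""


class FunnelOrderError(SigreverseError):
    """A funnel stage is not a subset of its predecessor."""


class InvalidConfigError(SigreverseError):
    """A simulation or pipeline configuration violates its invariants."""
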