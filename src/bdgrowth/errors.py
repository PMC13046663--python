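"""Exception hierarchy.

Degenerate inputs (all coalescence times equal, zero internal branch length)
raise explicit errors rather than returning infinities, so that tabulated
study output can distinguish estimator failure from an estimate.
"""


class BDGrowthError(Exception):
    """Base class for all package errors."""


class DegenerateSampleError(BDGrowthError):
    """The estimator's denominator vanishes (e.g. all coalescence times equal)."""


class ConvergenceError(BDGrowthError):
    """An iterative fit (the logistic MLE) failed to converge."""


class TreeError(BDGrowthError):
    """A genealogy violates the structural requirements (binary, ultrametric,
    branch lengths present)."""
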