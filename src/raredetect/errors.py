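"""Exception hierarchy for raredetect."""


class RaredetectError(Exception):
    """Base class for all raredetect errors."""


class ImpossibleConstraintError(RaredetectError):
    """A truncation interval carries zero probability mass.

    Callers computing a rectangular multinomial probability map this to
    probability 0 (the event cannot occur).
    """


class EdgeworthDivergenceError(RaredetectError):
    """The Edgeworth series failed to converge (terms growing in magnitude)."""


class TargetUnreachableError(RaredetectError):
    """No sample size up to ``max_n`` reaches the target probability."""


class NonMonotoneInversionError(RaredetectError):
    """Sample-size inversion requested for an event that is not monotone in n.

    Finite upper bounds make the event probability non-monotone in the number
    of draws, so the minimal-n definition is ill-posed for bisection.
    """


class FrequencyBudgetError(RaredetectError):
    """Requested subpopulation frequencies sum to more than 1."""


class CountsTableError(RaredetectError):
    """An observed-counts table is malformed (zero counts, duplicates, ...)."""
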