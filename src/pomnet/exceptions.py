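"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`PomnetError`
(itself a ``ValueError``) so callers can catch one type at the CLI boundary.
"""


class PomnetError(ValueError):
    """Base class for all domain errors raised by pomnet."""


class TableFormatError(PomnetError):
    """An OTU table file violates the expected tab-delimited format."""


class InvalidConfigError(PomnetError):
    """A configuration object fails its invariants."""


class InfeasibleDepthError(PomnetError):
    """Requested rarefaction depth exceeds a sample's total count."""


class DegenerateSampleError(PomnetError):
    """A sample contains no reads where at least one is required."""


class NoHeavyFractionError(PomnetError):
    """A density window selects no gradient fraction."""


class ScaleError(PomnetError):
    """Input expected on the relative-abundance scale is not normalized."""


class AbsentOtuError(PomnetError):
    """Both fractions report zero abundance for an OTU."""


class PairingError(PomnetError):
    """PA/FL samples are not paired at some pressure level."""


class InsufficientSamplesError(PomnetError):
    """Too few samples to estimate pairwise correlations."""


class NoTransitionError(PomnetError):
    """No threshold on the scan grid satisfies the Poisson criterion."""
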