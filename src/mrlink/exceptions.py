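"""Exception hierarchy for the MR pipeline.

Every recoverable per-pair failure (empty instrument set, too few SNPs for a
method, degenerate weights) raises a subclass of :class:`MrLinkError` so the
bi-directional driver can record the pair as not-estimable and continue.
"""


class MrLinkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrLinkError):
    """Invalid user configuration (bad threshold, missing column, bad path)."""


class EmptyInputError(MrLinkError):
    """An input table contained zero valid rows."""


class EmptyInstrumentsError(MrLinkError):
    """Instrument selection left no SNPs; the exposure is not analysable."""


class EmptyHarmonizationError(MrLinkError):
    """No instrument survived harmonization against the outcome."""


class InsufficientInstrumentsError(MrLinkError):
    """Fewer SNPs than the estimator's minimum (e.g. MR-Egger needs >= 3)."""


class DegenerateWeightsError(MrLinkError):
    """All penalized weights collapsed to zero; no estimate is defined."""


class EstimationError(MrLinkError):
    """Numerical optimisation failed to converge inside its bracket."""


class GenerationError(MrLinkError):
    """The simulator could not satisfy its constraints within bounded retries."""
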