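"""Exception types raised across the package."""


class ClonoprevError(Exception):
    """Base class for all package-specific errors."""


class SaturationError(ClonoprevError, ValueError):
    """All droplets positive: the Poisson concentration estimate diverges."""


class UndefinedVAFError(ClonoprevError, ValueError):
    """Variant and wild-type concentrations are both zero."""


class EmptyPosteriorError(ClonoprevError, RuntimeError):
    """Rejection ABC accepted no draws; increase tolerance or n_sims."""


class UnattributableMutationError(ClonoprevError, ValueError):
    """No active signature can emit the mutation's trinucleotide channel."""


class MissingYearError(ClonoprevError, KeyError):
    """An exposure-window year is absent from the PM2.5 series."""
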