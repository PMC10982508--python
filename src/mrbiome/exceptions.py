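"""Exception hierarchy shared across the package."""


class MRBiomeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRBiomeError):
    """A configuration value or column mapping is unusable."""


class ValidationError(MRBiomeError):
    """Input data violates a structural invariant."""


class InsufficientInstrumentsError(MRBiomeError):
    """An estimator was called with fewer SNPs than it requires."""


class UndefinedRatioError(MRBiomeError):
    """Wald ratio requested for a SNP with zero exposure effect."""
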