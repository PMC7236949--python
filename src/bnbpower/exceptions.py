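"""Exception hierarchy shared across the package."""


class BnbPowerError(Exception):
    """Base class for all package-specific errors."""


class NonIdentifiableError(BnbPowerError, ValueError):
    """The data carry no information about the parameters (e.g. all counts zero)."""


class FitError(BnbPowerError, RuntimeError):
    """A maximum-likelihood fit failed or produced an inconsistent result."""


class WaldUnavailableError(FitError):
    """The Wald statistic cannot be formed (singular or indefinite information)."""
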