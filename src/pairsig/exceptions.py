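"""Exception types raised across the package."""


class PairSigError(Exception):
    """Base class for all pairsig errors."""


class ConfigurationError(PairSigError, ValueError):
    """Invalid simulation or selection configuration."""


class FormatError(PairSigError, ValueError):
    """A file or table violates its column/value contract."""


class FitError(PairSigError, RuntimeError):
    """A model fit failed or is degenerate."""
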