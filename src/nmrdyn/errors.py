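"""Exception hierarchy for nmrdyn."""


class NmrdynError(Exception):
    """Base class for all nmrdyn errors."""


class FormatError(NmrdynError):
    """Malformed input table (missing columns, non-numeric fields, ...)."""


class ValidationError(NmrdynError):
    """Data violates a contract (duplicates, non-physical values, ...)."""


class FitError(NmrdynError):
    """A fit could not be performed (too few points, ill-conditioned, ...)."""
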