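"""Exception hierarchy for grsvol."""


class GrsvolError(Exception):
    """Base class for all grsvol errors."""


class FormatError(GrsvolError):
    """A file could not be parsed in the declared format."""


class ValidationError(GrsvolError):
    """Parsed data violates a domain invariant."""


class HarmonizeError(GrsvolError):
    """Training and target data share no usable variants."""


class UndefinedLDError(GrsvolError):
    """Pairwise LD is undefined (zero variance or no overlap)."""


class FitError(GrsvolError):
    """A regression fit could not be carried out."""
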