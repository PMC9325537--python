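"""Exception hierarchy shared across the package."""


class GnormsError(Exception):
    """Base class for all errors raised by gnorms."""


class ValidationError(GnormsError):
    """Malformed input data: bad counts, identifiers, proportions, config."""


class DesignError(GnormsError):
    """Experimental design cannot support the requested model."""
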