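"""Exception hierarchy for udilab."""


class UdilabError(Exception):
    """Base class for all udilab errors."""


class ConfigurationError(UdilabError):
    """Invalid or inconsistent user-supplied parameters."""


class FormatError(UdilabError):
    """A file does not conform to the expected delimited-text layout."""


class DegenerateInputError(UdilabError):
    """Input is structurally valid but too short/empty for the operation."""


class ValidationError(UdilabError):
    """A value violates a documented domain constraint."""


class ConvergenceError(UdilabError):
    """Iterative decomposition failed; message names the stopping criterion."""
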