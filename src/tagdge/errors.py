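"""Exception hierarchy.

All user-facing failures derive from :class:`TagDGEError` so callers (and the
CLI) can distinguish bad input from genuine bugs.
"""


class TagDGEError(Exception):
    """Base class for all package errors."""


class InputError(TagDGEError):
    """Invalid data passed to an operation (bad sequence alphabet, empty
    catalog, mismatched gene universes, ...)."""


class ConfigError(TagDGEError):
    """Invalid configuration (fractions out of range, bad length bounds, ...)."""


class ParseError(TagDGEError):
    """Malformed input file; carries enough context to locate the record."""


class SimulationError(TagDGEError):
    """Simulation preconditions violated (e.g. an expressed gene with no
    extractable tag)."""
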