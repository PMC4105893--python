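"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (input errors -> 2, configuration
errors -> 3); library users catch them like any ValueError.
"""


class MicrocalcError(Exception):
    """Base class for all package-specific errors."""


class InputError(MicrocalcError):
    """A file or in-memory input is missing, unreadable or malformed."""


class ConfigError(MicrocalcError):
    """A configuration object violates its invariants."""


class PlacementError(MicrocalcError):
    """The injection simulator could not place a cluster inside the mask."""
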