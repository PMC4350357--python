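"""Exception hierarchy.

Every validation failure raises a subclass of :class:`AccsigError` so the CLI can
catch one type, print a one-line reason and exit nonzero.
"""


class AccsigError(Exception):
    """Base class for all package errors."""


class FormatError(AccsigError):
    """Malformed input file: duplicate identifiers, non-numeric cells, bad vocabulary."""


class PairingError(AccsigError):
    """Tumor/normal pairing cannot be resolved (orphan patients, no pairs)."""


class ConfigError(AccsigError):
    """Invalid configuration or parameter value."""


class DesignError(AccsigError):
    """Study design too small for the requested statistic (e.g. <2 pairs)."""


class StateError(AccsigError):
    """Operation applied to an object in the wrong state (e.g. log2 of a log2 matrix)."""


class InputError(AccsigError):
    """Semantically invalid input to an analysis operation."""
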