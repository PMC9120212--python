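"""Typed exceptions shared across the package."""


class BarcodelimError(Exception):
    """Base class for all package errors."""


class InputError(BarcodelimError):
    """Malformed or inconsistent on-disk input."""


class AlignmentError(InputError):
    """Alignment-level invariant violated (ragged lengths, bad characters)."""


class DomainMismatchError(BarcodelimError):
    """Two objects do not share the same specimen-id domain."""

    def __init__(self, message, only_a=(), only_b=()):
        super().__init__(message)
        self.only_a = frozenset(only_a)
        self.only_b = frozenset(only_b)


class UndefinedDistanceError(BarcodelimError):
    """A pairwise distance could not be computed (no comparable sites)."""


class SaturationError(BarcodelimError):
    """Observed divergence outside the model's invertible range (JC69: p >= 0.75)."""


class ConfigError(BarcodelimError):
    """Invalid parameter combination."""


class OrdinationError(BarcodelimError):
    """PCoA cannot be performed on the given input."""
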