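"""Exception hierarchy shared across modules."""


class BeadphosError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BeadphosError):
    """Invalid configuration: missing residue sets, empty code tables, etc."""


class DuplicateSequenceError(BeadphosError):
    """Library expansion produced duplicate sequences."""

    def __init__(self, collisions):
        self.collisions = list(collisions)
        super().__init__(f"duplicate expanded sequences: {self.collisions}")


class SchemaError(BeadphosError):
    """A delimited table did not match its declared schema."""


class InputError(BeadphosError):
    """Malformed numeric input (non-finite intensities, bad positions...)."""


class UndefinedScoreError(BeadphosError):
    """Dephosphorylation score undefined (e.g. zero starting intensity)."""


class FitError(BeadphosError):
    """A curve fit could not be computed at all (distinct from fit_ok=False)."""


class AmbiguityError(BeadphosError):
    """Operation required a unique choice that the input does not determine."""


class ConflictError(BeadphosError):
    """Two records claim the same output cell."""
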