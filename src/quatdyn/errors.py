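"""Package exception hierarchy."""


class QuatdynError(Exception):
    """Base class for all quatdyn errors."""


class FormatError(QuatdynError, ValueError):
    """A structure or trajectory file could not be parsed."""


class UnknownElementError(FormatError):
    """An atom's element symbol could not be resolved to a mass."""


class AtomCountMismatchError(QuatdynError, ValueError):
    """A trajectory frame does not match the model's atom count."""


class SelectionError(QuatdynError, ValueError):
    """A selection expression failed to parse or referenced unknown fields."""


class PartitionError(QuatdynError, ValueError):
    """An invalid trimer partition was requested."""


class DegenerateGeometryError(QuatdynError, ValueError):
    """A superposition problem is rank-deficient (collinear or too few points)."""
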