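"""Exception hierarchy for dockjury."""


class DockjuryError(Exception):
    """Base class for all dockjury errors."""


class PDBParseError(DockjuryError):
    """A PDB-format record could not be parsed."""


class EmptyStructureError(DockjuryError):
    """Input contained no usable ATOM records."""


class FormatError(DockjuryError):
    """A CASP QA exchange file violates the expected format."""


class RangeError(DockjuryError):
    """A value lies outside its documented range."""


class StoichiometryError(DockjuryError):
    """A stoichiometry string could not be parsed or is invalid."""


class MappingError(DockjuryError):
    """Model and reference share no sequence-compatible chain group."""


class DegenerateInputError(DockjuryError):
    """Too few or collinear points for a rigid superposition."""


class ConfigError(DockjuryError):
    """A jury configuration is incomplete or inconsistent."""


class GenerationError(DockjuryError):
    """Synthetic complex generation produced an interface-free geometry."""
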