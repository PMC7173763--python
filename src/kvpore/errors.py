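"""Exception hierarchy shared across the package."""


class KvporeError(Exception):
    """Base class for all kvpore errors."""


class PDBFormatError(KvporeError):
    """A PDB file violates the fixed-column dialect this package reads."""


class EmptyInputError(KvporeError):
    """An input contained no usable records (e.g. a PDB with zero models)."""


class EnergyTableError(KvporeError):
    """An energy table is malformed, incomplete or contains duplicates."""


class ConfigError(KvporeError):
    """A configuration file contains unknown keys or invalid values."""


class ResidueResolutionError(KvporeError):
    """A residue selection resolved to no atoms in a frame."""


class GeometryError(KvporeError):
    """Degenerate geometry (e.g. collinear points in a torsion)."""


class CapabilityError(KvporeError):
    """A request exceeds what exact enumeration supports."""
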