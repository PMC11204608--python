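"""Exception hierarchy shared across the pipeline."""


class FootprintMorphError(Exception):
    """Base class for all package errors."""


class ParameterError(FootprintMorphError, ValueError):
    """A caller-supplied parameter is out of its admissible range."""


class DegenerateGeometryError(FootprintMorphError, ValueError):
    """Input geometry does not determine the requested quantity
    (collinear landmarks, coplanar sphere points, zero-width patches...)."""


class EmptyInputError(FootprintMorphError, ValueError):
    """An operation received an empty mask, mesh or value list."""


class EmptyFootprintError(FootprintMorphError, ValueError):
    """No bone face lies within tracing range of the paint surface."""


class OpenMeshError(FootprintMorphError, ValueError):
    """A closed (watertight) mesh is required for volume integrals."""


class FormatError(FootprintMorphError, ValueError):
    """A file could not be parsed in its declared format."""


class SubdivisionError(FootprintMorphError, ValueError):
    """A subdivision rule produced an empty child footprint."""
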