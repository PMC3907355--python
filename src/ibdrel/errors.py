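"""Exception hierarchy for ibdrel."""


class IbdrelError(Exception):
    """Base class for all ibdrel errors."""


class ParseError(IbdrelError):
    """A segment, map, or manifest file could not be parsed."""


class CoordinateError(IbdrelError):
    """A position or chromosome is inconsistent with the genetic map."""


class ParameterError(IbdrelError):
    """A model or masking parameter is outside its valid range."""


class EstimationError(IbdrelError):
    """A model could not be estimated from the supplied data."""


class PedigreeError(IbdrelError):
    """A pedigree structure is malformed (cycles, missing parents)."""


class InputError(IbdrelError):
    """Segment data violate a model contract (e.g. IBD2 outside IBD1)."""
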