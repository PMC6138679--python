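"""Exception hierarchy shared across the pipeline stages."""


class CollagenGpoError(Exception):
    """Base class for all package errors."""


class InputError(CollagenGpoError):
    """An input file is missing, empty or unparsable."""


class AlignmentShapeError(InputError):
    """Aligned records do not share a common column count."""


class NoRegisterError(CollagenGpoError):
    """No reading frame places glycine at a majority of triplet-1 positions."""


class ParameterError(CollagenGpoError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class RangeError(CollagenGpoError, IndexError):
    """A coordinate falls outside the span of the object it indexes."""


class StructureError(CollagenGpoError):
    """An atomic model violates a structural requirement (missing atoms,
    wrong chain count, broken covalent geometry)."""


class ConfigError(CollagenGpoError, ValueError):
    """A synthetic-data generator configuration is internally inconsistent."""
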