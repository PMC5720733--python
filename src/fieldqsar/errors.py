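"""Exception hierarchy for the fieldqsar pipeline.

Every stage raises a subclass of :class:`FieldQSARError` so callers can
distinguish pipeline failures from programming errors.
"""


class FieldQSARError(Exception):
    """Base class for all fieldqsar errors."""


class FormatError(FieldQSARError):
    """An input file could not be parsed."""


class MissingActivityError(FieldQSARError):
    """A structure record has no matching activity row."""


class DuplicateIdError(FieldQSARError):
    """Two records share the same compound id."""


class DomainError(FieldQSARError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ParameterError(FieldQSARError, ValueError):
    """An option or parameter value is invalid."""


class NoTemplateMatchError(FieldQSARError):
    """A ligand does not contain the alignment template."""

    def __init__(self, ligand_id: str, pattern: str):
        self.ligand_id = ligand_id
        self.pattern = pattern
        super().__init__(
            f"ligand {ligand_id!r} does not match template {pattern!r}"
        )


class MissingPoseError(FieldQSARError):
    """No docked pose was supplied for a ligand in docking alignment."""


class DegenerateGeometryError(FieldQSARError):
    """Coordinates are collinear or otherwise under-determined."""


class InfeasibleSpecError(FieldQSARError):
    """A synthetic complex specification contradicts itself."""
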