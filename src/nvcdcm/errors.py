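"""Exception types shared across the pipeline.

Validation problems (bad shapes, inconsistent options) raise subclasses of
:class:`ValidationError`; numerical failures during integration or inversion
raise subclasses of :class:`NumericalError`.  The CLI maps these onto distinct
exit codes (2 and 3 respectively).
"""


class ValidationError(ValueError):
    """Inconsistent user input: shapes, option strings, schedules."""


class ParameterError(ValidationError):
    """A parameter value violates its domain (e.g. non-positive rate)."""


class ShapeError(ValidationError):
    """Array dimensions do not match the declared architecture."""


class NumericalError(RuntimeError):
    """A computation produced non-finite or otherwise unusable numbers."""


class IntegrationError(NumericalError):
    """ODE integration blew up; carries the offending parameter block."""

    def __init__(self, message: str, block: str | None = None):
        super().__init__(message)
        self.block = block
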