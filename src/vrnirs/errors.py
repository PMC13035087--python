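"""Exception hierarchy for the pipeline."""


class VrnirsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VrnirsError, ValueError):
    """An analysis or simulation parameter is out of its valid range."""


class InvalidInputError(VrnirsError, ValueError):
    """Input data violate a structural precondition (shape, sign, schema)."""


class ConfigurationError(VrnirsError, ValueError):
    """A configuration asset (extinction table, DPF coefficients) is unusable."""
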