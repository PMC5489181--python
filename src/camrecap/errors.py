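"""Exception types shared across the package."""


class CamrecapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CamrecapError):
    """An input table is missing required columns or is otherwise malformed."""


class EmptyInputError(CamrecapError):
    """An input source contained no usable records."""


class DesignError(CamrecapError):
    """A survey design is internally inconsistent (overlaps, bad ordering...)."""


class FitError(CamrecapError):
    """Maximum-likelihood optimisation failed for every starting point."""
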