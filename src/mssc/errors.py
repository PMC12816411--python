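"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (usage=1, data=2, I/O=3); library users
catch :class:`MsscError` for anything raised deliberately by this package.
"""


class MsscError(Exception):
    """Base class for all errors raised by mssc."""


class ConfigurationError(MsscError):
    """A parameter value violates a documented precondition."""


class FormatError(MsscError):
    """An input file has an unsupported layout (e.g. CMYK)."""


class DimensionError(MsscError):
    """Two operands have incompatible shapes."""


class DataError(MsscError):
    """Tabular input violates its schema or carries no usable rows."""


class SymmetryError(MsscError):
    """A spectrum lost conjugate symmetry: the inverse transform of a
    real image's filtered spectrum produced a non-negligible imaginary part."""
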