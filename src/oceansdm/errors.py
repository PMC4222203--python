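"""Exception hierarchy shared across the package."""


class OceanSDMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OceanSDMError, ValueError):
    """Invalid generator or run-configuration parameters."""


class InputError(OceanSDMError, ValueError):
    """Invalid data passed to an operation."""


class FormatError(OceanSDMError, ValueError):
    """A file does not conform to the expected on-disk format."""


class UnitError(OceanSDMError, ValueError):
    """Unknown or unconvertible measurement units."""


class AlignmentError(OceanSDMError, ValueError):
    """Grids or stacks do not share the same geometry/mask."""


class StateError(OceanSDMError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. unfitted model)."""
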