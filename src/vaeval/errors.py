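"""Exception hierarchy.

All package-specific failures derive from :class:`VaevalError` so callers can
catch pipeline errors without swallowing programming errors.
"""


class VaevalError(Exception):
    """Base class for all vaeval errors."""


class ValidationError(VaevalError):
    """Input data failed validation."""


class InvalidCodeError(ValidationError):
    """A cause-of-death code does not parse as a valid code."""


class ConfigurationError(VaevalError):
    """A table, policy, or run configuration is internally inconsistent."""


class ContractError(VaevalError):
    """A caller violated an interface contract (e.g. mismatched record ids)."""


class AgeOutOfRangeError(VaevalError):
    """Age at death falls outside the strata covered by the study design."""


class UndefinedStratumError(VaevalError):
    """A metric was requested on an empty stratum restriction."""
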