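"""Exception and warning types used across the package."""


class CtPhantomError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CtPhantomError, ValueError):
    """An argument is non-finite, out of its physical domain, or malformed."""


class ConfigurationError(CtPhantomError, ValueError):
    """Mutually inconsistent objects, e.g. mismatched reference tube potentials."""


class InvalidModelError(CtPhantomError, ValueError):
    """A model cannot be used for the requested operation (e.g. k <= 0 at a rebase point)."""


class UnderdeterminedFitError(CtPhantomError, ValueError):
    """Too few distinct tube potentials to determine the model coefficients."""


class InfeasibleTargetError(CtPhantomError, ValueError):
    """The target attenuation cannot be reached with a filling ratio in (0, 1]."""


class InsufficientMaterialDataError(CtPhantomError, ValueError):
    """A material lacks the per-kV attenuation data required for the operation."""


class AlignmentError(CtPhantomError, ValueError):
    """Volumes or label maps do not share shape/spacing."""


class MissingGridPointError(CtPhantomError, KeyError):
    """A requested tube potential is absent from a plan's kV grid."""


class EnergyRangeWarning(UserWarning):
    """A tube potential lies outside the model's validated 70-140 kV range."""
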