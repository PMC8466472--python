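"""Exception types raised across the plant model."""


class MrnaPlantError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MrnaPlantError, ValueError):
    """An argument violates a documented precondition."""


class NonConvergenceError(MrnaPlantError, RuntimeError):
    """A balance or fit has no admissible solution."""


class StepSizeError(MrnaPlantError, RuntimeError):
    """Integration step too large: a conservation audit failed."""


class BracketingError(MrnaPlantError, RuntimeError):
    """A root-finder bracket does not enclose a sign change."""


class ScenarioValidationError(MrnaPlantError, ValueError):
    """A scenario file or object violates the schema."""


class SingularFitError(MrnaPlantError, RuntimeError):
    """A least-squares problem is rank deficient."""


class LookupError_(MrnaPlantError, KeyError):
    """A required key (e.g. a cost-index year) is absent."""
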