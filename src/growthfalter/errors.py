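"""Exception hierarchy for the growthfalter package."""


class GrowthFalterError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GrowthFalterError):
    """An invalid configuration value; the message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ReferenceRangeError(GrowthFalterError):
    """Requested age lies outside the growth-reference grid."""


class DomainError(GrowthFalterError):
    """A measurement value outside its physical domain (e.g. length <= 0)."""


class PanelDataError(GrowthFalterError):
    """Inconsistent panel data; the message identifies the child-visit."""


class CurveFitError(GrowthFalterError):
    """A per-child growth-curve fit failed; the message names the child."""

    def __init__(self, child_id, message: str):
        self.child_id = child_id
        super().__init__(f"curve fit failed for child {child_id!r}: {message}")


class SingularModelError(GrowthFalterError):
    """A second-stage design matrix is rank deficient; names the model."""


class ThresholdSelectionError(GrowthFalterError):
    """No candidate centile reaches the required cohort coverage."""

    def __init__(self, max_coverage: float, message: str = ""):
        self.max_coverage = max_coverage
        super().__init__(
            message
            or f"no candidate centile reaches required coverage; "
            f"maximum coverage attained = {max_coverage:.4f}"
        )
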