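"""Exception hierarchy.

Validation problems (bad input data, bad configuration) and estimation
problems (model failures) are kept distinct so the CLI can map them to
different exit codes.
"""


class EpiaccelError(Exception):
    """Base class for all package errors."""


class ValidationError(EpiaccelError):
    """Input data or configuration violates a contract."""


class MissingSiteError(ValidationError):
    """A methylation profile lacks a CpG site required by the clock."""

    def __init__(self, site_key: str, context: str = ""):
        self.site_key = site_key
        msg = f"methylation profile is missing clock site {site_key!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class MethylationRangeError(ValidationError):
    """A methylation value lies outside the [0, 100] percent scale."""

    def __init__(self, site_key: str, value: float, context: str = ""):
        self.site_key = site_key
        self.value = value
        msg = (
            f"methylation at {site_key!r} is {value!r}; values must be "
            f"percentage points in [0, 100]"
        )
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class DegenerateTestError(EpiaccelError):
    """A statistical test is undefined on the given data (e.g. zero variance)."""


class SingularFitError(EpiaccelError):
    """A regression design is singular (constant predictor, collinearity)."""


class EstimationError(EpiaccelError):
    """A model failed to converge or produced an unusable fit."""


class InfeasibleTargetError(EpiaccelError):
    """Clock inversion cannot reach the target age within [0, 100] bounds."""

    def __init__(self, site_key: str, value: float, target: float):
        self.site_key = site_key
        self.value = value
        self.target = target
        super().__init__(
            f"cannot invert clock to DNAm age {target:g}: site {site_key!r} "
            f"would need methylation {value:g}, outside [0, 100]"
        )
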