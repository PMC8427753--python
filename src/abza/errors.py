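"""Exception and warning hierarchy for the abza package."""


class AbzaError(Exception):
    """Base class for all abza errors."""


class InvalidLandmarksError(AbzaError):
    """A landmark set violates its structural invariants (degenerate midline,
    missing terminal candidates outside the zero-angle case, ...)."""


class UndefinedAngleError(AbzaError):
    """The terminal point coincides with the vertex; the angle is undefined."""


class AngleOutOfRangeError(AbzaError):
    """The measured angle exceeds 90 degrees beyond the clamp tolerance.

    Under the definition the terminal point C lies anterior to the vertex O,
    so an angle materially above 90 degrees usually means the midline base
    and apex points were supplied in the wrong order.
    """


class ProtocolViolationError(AbzaError):
    """A measurement-protocol rule was broken, e.g. a patient with a
    hypoplastic/absent A1 but patent AcoA was not measured from the
    contralateral carotid injection."""


class ParseError(AbzaError):
    """An input file does not match the documented schema."""


class SeparationError(AbzaError):
    """Logistic fit failed: complete/quasi-separation, a single-class
    outcome, or non-convergence."""


class DegenerateTestError(AbzaError):
    """A statistical test cannot be computed (constant variable, empty
    margin, zero variance in both raters, ...)."""


class UnreachablePrevalenceError(AbzaError):
    """Intercept calibration cannot reach the requested outcome prevalence
    with the given coefficients."""


class AngleClampWarning(UserWarning):
    """An angle slightly above 90 degrees was clamped to 90 (marker jitter)."""


class BoundaryGradeWarning(UserWarning):
    """ABZA_trans fell exactly on the contested unit boundary; the configured
    precedence rule was applied."""


class ConstantScoreWarning(UserWarning):
    """All ROC scores are identical; AUC reported as 0.5."""
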