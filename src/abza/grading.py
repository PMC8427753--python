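"""ABZA normalization and the 0–4 collateral grade.

The measured angle is divided by the upper limit of the 95% normal
reference range (23.0°) to give the dimensionless ``ABZA_trans``; rounding
ABZA_trans to the nearest integer yields the 0–4 collateral grade.  The
operative piecewise bins (in trans units) are::

    grade 0 : trans <= 1.0
    grade 1 : 1.0 <  trans < 1.5
    grade 2 : 1.5 <= trans < 2.5
    grade 3 : 2.5 <= trans < 3.5
    grade 4 : 3.5 <= trans <= 90/23

so the solid degree-space edges sit at 23.0°/46.0°/69.0° and the dashed
(rounding) edges at 34.5°/57.5°/80.5°.  A grade above 2 — i.e. an angle of
at least 57.5° — defines good collateral circulation.

The source bins overlap at trans = 1.0 exactly (stated both as grade 0 and
as the start of grade 1); this package gives precedence to the grade-0
clause, emits a :class:`~abza.errors.BoundaryGradeWarning`, and lets
``GradingScheme.grade_at_unit_boundary`` override the choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

from .errors import BoundaryGradeWarning

GOOD = "good"
POOR = "poor"

_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class GradingScheme:
    """Parameters of the grade mapping.

    ``norm_upper_deg`` is the normalization constant (default 23.0°, the
    upper limit of the 95% normal reference range of ABZA).
    ``dichotomy_threshold_grade`` sets the good/poor split (good ⇔ grade >
    threshold).  ``grade_at_unit_boundary`` resolves the contested bin
    boundary at trans exactly 1.0 (0 by default).
    """

    norm_upper_deg: float = 23.0
    dichotomy_threshold_grade: int = 2
    grade_at_unit_boundary: int = 0

    def __post_init__(self) -> None:
        if self.norm_upper_deg <= 0:
            raise ValueError("norm_upper_deg must be positive")
        if self.grade_at_unit_boundary not in (0, 1):
            raise ValueError("grade_at_unit_boundary must be 0 or 1")

    @property
    def max_trans(self) -> float:
        """Largest attainable trans value (angle of 90°)."""
        return 90.0 / self.norm_upper_deg

    @property
    def solid_edges_deg(self) -> Tuple[float, float, float]:
        """Integer-multiple degree edges (23.0, 46.0, 69.0 by default)."""
        k = self.norm_upper_deg
        return (k, 2 * k, 3 * k)

    @property
    def dashed_edges_deg(self) -> Tuple[float, float, float]:
        """Half-integer rounding edges (34.5, 57.5, 80.5 by default)."""
        k = self.norm_upper_deg
        return (1.5 * k, 2.5 * k, 3.5 * k)

    @property
    def good_threshold_deg(self) -> float:
        """Degree-space boundary of the good-collateral class (57.5°)."""
        return (self.dichotomy_threshold_grade + 0.5) * self.norm_upper_deg

    def degree_interval(self, grade: int) -> Tuple[float, float]:
        """Half-open degree interval [lo, hi) covered by ``grade`` (the
        grade-4 interval is closed at 90°)."""
        k = self.norm_upper_deg
        edges = [0.0, k, 1.5 * k, 2.5 * k, 3.5 * k, 90.0]
        if grade not in range(5):
            raise ValueError(f"grade {grade} outside 0..4")
        return (edges[grade], edges[grade + 1])


@dataclass(frozen=True)
class ABZAGrade:
    """A graded measurement: trans ratio, integer grade, good/poor class."""

    abza_trans: float
    grade: int
    collateral_class: str

    def __post_init__(self) -> None:
        if self.grade not in range(5):
            raise ValueError(f"grade {self.grade} outside 0..4")
        if self.collateral_class not in (GOOD, POOR):
            raise ValueError(f"bad collateral_class {self.collateral_class!r}")


def abza_trans(abza_deg: float, scheme: GradingScheme = GradingScheme()) -> float:
    """Normalize an angle to trans units (angle / norm_upper_deg)."""
    if not 0.0 <= abza_deg <= 90.0 + _EDGE_TOL:
        raise ValueError(f"abza_deg {abza_deg} outside [0, 90]")
    return min(abza_deg, 90.0) / scheme.norm_upper_deg


def grade(trans: float, scheme: GradingScheme = GradingScheme()) -> int:
    """Map a trans ratio to the integer 0–4 collateral grade."""
    if trans < -_EDGE_TOL or trans > scheme.max_trans + _EDGE_TOL:
        raise ValueError(
            f"abza_trans {trans} outside [0, {scheme.max_trans:.4f}] — "
            "implies an impossible angle"
        )
    trans = min(max(trans, 0.0), scheme.max_trans)
    if math.isclose(trans, 1.0, rel_tol=0.0, abs_tol=_EDGE_TOL):
        warnings.warn(
            "ABZA_trans is exactly 1.0, the contested bin boundary; "
            f"assigning grade {scheme.grade_at_unit_boundary}",
            BoundaryGradeWarning,
            stacklevel=2,
        )
        return scheme.grade_at_unit_boundary
    if trans < 1.0:
        return 0
    if trans < 1.5:
        return 1
    if trans < 2.5:
        return 2
    if trans < 3.5:
        return 3
    return 4


def dichotomize(g: int, scheme: GradingScheme = GradingScheme()) -> str:
    """Good/poor collateral class: good ⇔ grade > threshold (default 2)."""
    if g not in range(5):
        raise ValueError(f"grade {g} outside 0..4")
    return GOOD if g > scheme.dichotomy_threshold_grade else POOR


def grade_angle(abza_deg: float, scheme: GradingScheme = GradingScheme()) -> ABZAGrade:
    """Convenience pipeline: degrees → trans → grade → class."""
    t = abza_trans(abza_deg, scheme)
    g = grade(t, scheme)
    return ABZAGrade(abza_trans=t, grade=g, collateral_class=dichotomize(g, scheme))
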