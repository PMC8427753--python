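"""Measurement of the anterior borderzone angle (ABZA) from 2D landmarks.

ABZA quantifies leptomeningeal collateral recruitment on an anteroposterior
DSA projection.  Three landmarks define it:

* ``T`` — the intracranial bifurcation of the internal carotid artery;
* the sagittal-sinus midline, supplied as an ordered (base, apex) point
  pair, with *apex* pointing toward the sinus apex;
* ``C`` — the center of the ACA–MCA pial borderzone (for a complete MCA
  occlusion, the center of the farthest points reached by retrograde
  cortical flow).

The vertex ``O`` is the orthogonal projection of ``T`` onto the midline,
and ABZA is the unsigned angle at ``O`` between the midline apex direction
and the ray ``O → C``.  Angles live in [0°, 90°]: 0° means no anterior
collateral filling at all, values near 90° mean retrograde filling all the
way back to the MCA bifurcation.

Coordinates are continuous 2D points in any consistent unit; orientation is
carried entirely by the ordered midline pair, so the measurement is
invariant to rotation, translation, uniform scaling and mirror reflection
of the image.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import (
    AngleClampWarning,
    AngleOutOfRangeError,
    InvalidLandmarksError,
    ProtocolViolationError,
    UndefinedAngleError,
)

Point = Tuple[float, float]

SIDES = ("left", "right")
OCCLUSION_STATES = ("mcao_complete", "stenosis_patent")
A1_STATES = ("normal", "hypoplastic_or_absent")

#: measurement provenance rules
RULE_STANDARD = "standard"
RULE_MCAO_RETROGRADE = "mcao_retrograde"
RULE_CONTRALATERAL = "contralateral"
RULE_ZERO = "zero_no_a1_no_acoa"

#: angles in (90, 90 + CLAMP_TOL_DEG] are clamped to 90 with a warning
CLAMP_TOL_DEG = 0.5

_DEGENERATE_REL_TOL = 1e-12


@dataclass(frozen=True)
class AngioLandmarks:
    """One patient's angiographic landmark set plus anatomical flags.

    Parameters
    ----------
    patient_id
        Free-text identifier.
    side
        Symptomatic side, ``"left"`` or ``"right"``.
    t
        Intracranial ICA bifurcation point T.
    midline
        Ordered (base, apex) pair defining the sagittal-sinus projection
        line; apex points toward the sinus apex.
    terminal_candidates
        Candidate ACA–MCA borderzone center points.  For a complete MCAO
        these are the several farthest points of retrograde pial flow;
        they may be empty only in the zero-angle case.
    occlusion
        ``"mcao_complete"`` (retrograde-flow rule) or ``"stenosis_patent"``.
    a1_status
        ``"normal"`` or ``"hypoplastic_or_absent"`` (A1 diameter < 0.5 mm
        or missing).
    acoa_patent
        Whether the anterior communicating artery is patent.
    measured_from_contralateral
        True when the landmarks come from the contralateral carotid
        injection (required when A1 is hypoplastic/absent but AcoA is
        patent).  No mirroring is applied internally.
    rater
        Optional rater identifier, used for inter-rater reliability input.
    """

    patient_id: str
    side: str
    t: Point
    midline: Tuple[Point, Point]
    terminal_candidates: Tuple[Point, ...] = ()
    occlusion: str = "mcao_complete"
    a1_status: str = "normal"
    acoa_patent: bool = True
    measured_from_contralateral: bool = False
    rater: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", (float(self.t[0]), float(self.t[1])))
        object.__setattr__(
            self,
            "midline",
            (
                (float(self.midline[0][0]), float(self.midline[0][1])),
                (float(self.midline[1][0]), float(self.midline[1][1])),
            ),
        )
        object.__setattr__(
            self,
            "terminal_candidates",
            tuple((float(x), float(y)) for x, y in self.terminal_candidates),
        )

    def validate(self) -> None:
        """Raise :class:`InvalidLandmarksError` on any invariant violation."""
        if self.side not in SIDES:
            raise InvalidLandmarksError(
                f"{self.patient_id}: unknown side {self.side!r}"
            )
        if self.occlusion not in OCCLUSION_STATES:
            raise InvalidLandmarksError(
                f"{self.patient_id}: unknown occlusion state {self.occlusion!r}"
            )
        if self.a1_status not in A1_STATES:
            raise InvalidLandmarksError(
                f"{self.patient_id}: unknown a1_status {self.a1_status!r}"
            )
        base, apex = self.midline
        if _is_degenerate(base, apex):
            raise InvalidLandmarksError(
                f"{self.patient_id}: midline base and apex coincide"
            )
        if self.a1_status == "normal" and self.measured_from_contralateral:
            raise InvalidLandmarksError(
                f"{self.patient_id}: contralateral measurement flagged but "
                "ipsilateral A1 is normal"
            )
        zero_case = self.a1_status == "hypoplastic_or_absent" and not self.acoa_patent
        if not self.terminal_candidates and not zero_case:
            raise InvalidLandmarksError(
                f"{self.patient_id}: terminal candidates may be empty only "
                "when A1 is hypoplastic/absent and AcoA is closed"
            )


@dataclass(frozen=True)
class ABZAMeasurement:
    """The measured angle plus its derivation.

    ``abza_deg`` is the angle α in degrees, in [0, 90].  ``vertex_O`` is the
    projection of T on the midline; ``terminal_C`` is the resolved terminal
    point (absent only in the zero-angle case).  ``rule_applied`` records
    which measurement rule produced the value.
    """

    abza_deg: float
    vertex_O: Point
    terminal_C: Optional[Point]
    rule_applied: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.abza_deg <= 90.0:
            raise ValueError(f"abza_deg {self.abza_deg} outside [0, 90]")
        if (self.rule_applied == RULE_ZERO) != (self.terminal_C is None):
            raise ValueError(
                "terminal_C must be absent exactly in the zero-angle case"
            )


def _is_degenerate(base: Point, apex: Point) -> bool:
    d = math.hypot(apex[0] - base[0], apex[1] - base[1])
    scale = max(1.0, abs(base[0]), abs(base[1]), abs(apex[0]), abs(apex[1]))
    return d <= _DEGENERATE_REL_TOL * scale


def project_vertex(t: Point, midline: Tuple[Point, Point]) -> Point:
    """Orthogonally project T onto the infinite midline, giving the vertex O.

    Raises :class:`InvalidLandmarksError` if the midline pair is degenerate.
    """
    base, apex = midline
    if _is_degenerate(base, apex):
        raise InvalidLandmarksError("degenerate midline: base and apex coincide")
    b = np.asarray(base, dtype=float)
    d = np.asarray(apex, dtype=float) - b
    w = np.asarray(t, dtype=float) - b
    o = b + (float(w @ d) / float(d @ d)) * d
    return (float(o[0]), float(o[1]))


def resolve_terminal_point(candidates: Sequence[Point]) -> Point:
    """Reduce the terminal candidates to the single terminal point C.

    A single candidate is returned as-is; several candidates — the farthest
    retrograde-flow points of an MCAO study — reduce to their centroid, the
    symmetric convention when the protocol does not pick one.
    """
    if len(candidates) == 0:
        raise InvalidLandmarksError(
            "no terminal candidates: route to the zero-angle rule instead"
        )
    arr = np.asarray(candidates, dtype=float)
    c = arr.mean(axis=0)
    return (float(c[0]), float(c[1]))


def angle_from_midline(
    o: Point,
    c: Point,
    midline: Tuple[Point, Point],
    clamp_tol_deg: float = CLAMP_TOL_DEG,
) -> float:
    """Unsigned angle in degrees between the midline apex direction and O→C.

    The angle is laterality-agnostic: reflecting C across the midline gives
    the same value.  Results in (90, 90 + ``clamp_tol_deg``] are clamped to
    90 with an :class:`AngleClampWarning` (marker jitter); beyond that an
    :class:`AngleOutOfRangeError` is raised, since C anatomically lies
    anterior to O — a larger value usually means the midline base and apex
    were swapped.
    """
    base, apex = midline
    if _is_degenerate(base, apex):
        raise InvalidLandmarksError("degenerate midline: base and apex coincide")
    u = np.asarray(apex, dtype=float) - np.asarray(base, dtype=float)
    v = np.asarray(c, dtype=float) - np.asarray(o, dtype=float)
    nv = float(np.hypot(v[0], v[1]))
    scale = max(1.0, float(np.max(np.abs(np.asarray(o)))), float(np.max(np.abs(np.asarray(c)))))
    if nv <= _DEGENERATE_REL_TOL * scale:
        raise UndefinedAngleError("terminal point coincides with the vertex")
    cosang = float(u @ v) / (float(np.hypot(u[0], u[1])) * nv)
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    if ang > 90.0 + clamp_tol_deg:
        raise AngleOutOfRangeError(
            f"angle {ang:.3f} deg exceeds 90: the terminal point lies below "
            "the vertex (midline base/apex likely swapped)"
        )
    if ang > 90.0:
        warnings.warn(
            f"angle {ang:.3f} deg clamped to 90 (within jitter tolerance)",
            AngleClampWarning,
            stacklevel=2,
        )
        ang = 90.0
    return ang


def measure_abza(
    landmarks: AngioLandmarks, clamp_tol_deg: float = CLAMP_TOL_DEG
) -> ABZAMeasurement:
    """Apply the full measurement protocol to one landmark set.

    Rules, in order:

    1. A1 hypoplastic/absent and AcoA closed — no anterior inflow path at
       all: ABZA is 0° by definition, no terminal point.
    2. A1 hypoplastic/absent but AcoA patent — the measurement must come
       from the contralateral carotid injection; otherwise a
       :class:`ProtocolViolationError` is raised.
    3. Otherwise, compose vertex projection, terminal-point resolution and
       the angle computation; the provenance rule is ``mcao_retrograde``
       for a complete occlusion (C from retrograde-flow points) and
       ``standard`` for a patent/stenosed MCA.
    """
    landmarks.validate()
    o = project_vertex(landmarks.t, landmarks.midline)

    if landmarks.a1_status == "hypoplastic_or_absent":
        if not landmarks.acoa_patent:
            return ABZAMeasurement(
                abza_deg=0.0,
                vertex_O=o,
                terminal_C=None,
                rule_applied=RULE_ZERO,
                patient_id=landmarks.patient_id,
            )
        if not landmarks.measured_from_contralateral:
            raise ProtocolViolationError(
                f"{landmarks.patient_id}: A1 hypoplastic/absent with patent "
                "AcoA — ABZA must be measured from contralateral carotid "
                "angiography images"
            )

    if landmarks.measured_from_contralateral:
        rule = RULE_CONTRALATERAL
    elif landmarks.occlusion == "mcao_complete":
        rule = RULE_MCAO_RETROGRADE
    else:
        rule = RULE_STANDARD

    c = resolve_terminal_point(landmarks.terminal_candidates)
    ang = angle_from_midline(o, c, landmarks.midline, clamp_tol_deg=clamp_tol_deg)
    return ABZAMeasurement(
        abza_deg=ang,
        vertex_O=o,
        terminal_C=c,
        rule_applied=rule,
        patient_id=landmarks.patient_id,
    )
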