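"""Deliverable machine-state sequences (VMAT plans).

A :class:`VmatPlan` is the shared container for both treatment-planning
output and plans reconstructed from delivery logs ("RT log file plans"):
an ordered list of arc beams, each a sequence of control points with
gantry/collimator angles, MLC leaf positions, jaw positions and a
cumulative meterset.

Conventions
-----------
* Patient coordinate system, millimetres; the stored isocenter is the
  machine rotation centre.
* Leaf and jaw positions are projected to the isocenter plane, in mm.
  Bank A holds the lower (more negative x) aperture edges, bank B the
  upper edges; the pair gap is ``b - a``.
* Gantry angles use the IEC 61217 scale folded into [-180, +180] deg.
* Meterset is stored as absolute cumulative MU per beam; the normalized
  cumulative meterset weight of a control point is ``cumulative_mu /
  beam.meterset_mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError

N_LEAF_PAIRS = 80
LEAF_WIDTH_MM = 5.0

#: y-edges of the 80 leaf rows at the isocenter plane (81 values, mm).
DEFAULT_LEAF_BOUNDARIES = np.linspace(
    -N_LEAF_PAIRS * LEAF_WIDTH_MM / 2.0, N_LEAF_PAIRS * LEAF_WIDTH_MM / 2.0,
    N_LEAF_PAIRS + 1,
)


@dataclass
class ControlPoint:
    """One sampled machine state within an arc beam."""

    gantry_deg: float
    collimator_deg: float
    leaves_a_mm: np.ndarray  # (80,) lower bank aperture edges
    leaves_b_mm: np.ndarray  # (80,) upper bank aperture edges
    jaws_mm: np.ndarray      # (4,) x1, x2, y1, y2
    cumulative_mu: float

    def __post_init__(self) -> None:
        self.leaves_a_mm = np.asarray(self.leaves_a_mm, dtype=float)
        self.leaves_b_mm = np.asarray(self.leaves_b_mm, dtype=float)
        self.jaws_mm = np.asarray(self.jaws_mm, dtype=float)
        if self.leaves_a_mm.shape != (N_LEAF_PAIRS,):
            raise ValidationError("bank A must hold 80 leaf positions")
        if self.leaves_b_mm.shape != (N_LEAF_PAIRS,):
            raise ValidationError("bank B must hold 80 leaf positions")
        if self.jaws_mm.shape != (4,):
            raise ValidationError("jaws must be (x1, x2, y1, y2)")

    @property
    def gaps_mm(self) -> np.ndarray:
        return self.leaves_b_mm - self.leaves_a_mm

    def copy(self) -> "ControlPoint":
        return ControlPoint(
            gantry_deg=self.gantry_deg,
            collimator_deg=self.collimator_deg,
            leaves_a_mm=self.leaves_a_mm.copy(),
            leaves_b_mm=self.leaves_b_mm.copy(),
            jaws_mm=self.jaws_mm.copy(),
            cumulative_mu=self.cumulative_mu,
        )


@dataclass
class ArcBeam:
    """One arc: an ordered control-point sequence plus its total meterset."""

    control_points: list[ControlPoint]
    meterset_mu: float
    name: str = "arc"

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    @property
    def cumulative_mu(self) -> np.ndarray:
        return np.array([cp.cumulative_mu for cp in self.control_points])

    @property
    def weights(self) -> np.ndarray:
        """Normalized cumulative meterset weights, 0 -> 1."""
        return self.cumulative_mu / self.meterset_mu

    @property
    def gantry_deg(self) -> np.ndarray:
        return np.array([cp.gantry_deg for cp in self.control_points])

    @property
    def collimator_deg(self) -> np.ndarray:
        return np.array([cp.collimator_deg for cp in self.control_points])

    @property
    def leaves_a_mm(self) -> np.ndarray:
        return np.stack([cp.leaves_a_mm for cp in self.control_points])

    @property
    def leaves_b_mm(self) -> np.ndarray:
        return np.stack([cp.leaves_b_mm for cp in self.control_points])

    @property
    def jaws_mm(self) -> np.ndarray:
        return np.stack([cp.jaws_mm for cp in self.control_points])

    def validate(self) -> None:
        if not self.control_points:
            raise ValidationError("beam has no control points")
        if not self.meterset_mu > 0:
            raise ValidationError("beam meterset must be positive")
        mu = self.cumulative_mu
        if np.any(np.diff(mu) < 0):
            raise ValidationError("cumulative meterset must be non-decreasing")
        if abs(mu[0]) > 1e-9:
            raise ValidationError("first control point must be at meterset 0")
        if abs(mu[-1] - self.meterset_mu) > 1e-6 * max(1.0, self.meterset_mu):
            raise ValidationError("last control point must close the meterset")

    def copy(self) -> "ArcBeam":
        return ArcBeam(
            control_points=[cp.copy() for cp in self.control_points],
            meterset_mu=self.meterset_mu,
            name=self.name,
        )


@dataclass
class VmatPlan:
    """A deliverable VMAT plan (or an RT log file plan)."""

    beams: list[ArcBeam]
    isocenter_mm: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    sad_mm: float = 1000.0
    leaf_boundaries_mm: np.ndarray = field(
        default_factory=lambda: DEFAULT_LEAF_BOUNDARIES.copy())
    energy: str = "6 MV"
    dose_reporting: str = "dose_to_medium"  # metadata label only
    name: str = "plan"

    def __post_init__(self) -> None:
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=float)
        self.leaf_boundaries_mm = np.asarray(self.leaf_boundaries_mm, dtype=float)

    @property
    def total_mu(self) -> float:
        return float(sum(b.meterset_mu for b in self.beams))

    @property
    def n_control_points(self) -> int:
        return sum(b.n_control_points for b in self.beams)

    def validate(self) -> None:
        if not self.beams:
            raise ValidationError("plan has no beams")
        if self.leaf_boundaries_mm.shape != (N_LEAF_PAIRS + 1,):
            raise ValidationError("leaf boundaries must have 81 edges")
        if np.any(np.diff(self.leaf_boundaries_mm) <= 0):
            raise ValidationError("leaf boundaries must increase")
        for beam in self.beams:
            beam.validate()

    def copy(self) -> "VmatPlan":
        return replace(
            self,
            beams=[b.copy() for b in self.beams],
            isocenter_mm=self.isocenter_mm.copy(),
            leaf_boundaries_mm=self.leaf_boundaries_mm.copy(),
        )


def _interp_knots(w: np.ndarray, wk: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of ``values`` (knots, ...) at ``w``.

    Duplicate knot abscissae are allowed (zero-meterset control points);
    queries at or beyond a duplicate resolve to the last of the duplicates.
    """
    w = np.asarray(w, dtype=float)
    j = np.searchsorted(wk, w, side="right")
    j = np.clip(j, 1, len(wk) - 1)
    w0, w1 = wk[j - 1], wk[j]
    denom = np.where(w1 > w0, w1 - w0, 1.0)
    f = np.clip((w - w0) / denom, 0.0, 1.0)
    v0, v1 = values[j - 1], values[j]
    return v0 + (v1 - v0) * f.reshape(f.shape + (1,) * (values.ndim - 1))


def sample_beam_state(beam: ArcBeam, w) -> dict[str, np.ndarray]:
    """Machine state of a beam at cumulative meterset weight(s) ``w``.

    The machine state is interpolated against cumulative meterset (dose
    rate is the leading parameter for this delivery model), linearly
    between control points.
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    wk = beam.weights
    return {
        "gantry_deg": _interp_knots(w, wk, beam.gantry_deg),
        "collimator_deg": _interp_knots(w, wk, beam.collimator_deg),
        "leaves_a_mm": _interp_knots(w, wk, beam.leaves_a_mm),
        "leaves_b_mm": _interp_knots(w, wk, beam.leaves_b_mm),
        "jaws_mm": _interp_knots(w, wk, beam.jaws_mm),
    }


def plans_equal(a: VmatPlan, b: VmatPlan, atol: float = 0.0) -> bool:
    """Field-wise equality of two plans (``atol=0`` means bit-exact)."""
    if len(a.beams) != len(b.beams):
        return False
    if not np.allclose(a.isocenter_mm, b.isocenter_mm, atol=atol, rtol=0):
        return False
    if a.sad_mm != b.sad_mm or a.energy != b.energy:
        return False
    if not np.allclose(a.leaf_boundaries_mm, b.leaf_boundaries_mm,
                       atol=atol, rtol=0):
        return False
    for ba, bb in zip(a.beams, b.beams):
        if ba.n_control_points != bb.n_control_points:
            return False
        if abs(ba.meterset_mu - bb.meterset_mu) > atol:
            return False
        for field_a, field_b in (
            (ba.gantry_deg, bb.gantry_deg),
            (ba.collimator_deg, bb.collimator_deg),
            (ba.cumulative_mu, bb.cumulative_mu),
            (ba.leaves_a_mm, bb.leaves_a_mm),
            (ba.leaves_b_mm, bb.leaves_b_mm),
            (ba.jaws_mm, bb.jaws_mm),
        ):
            if not np.allclose(field_a, field_b, atol=atol, rtol=0):
                return False
    return True
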