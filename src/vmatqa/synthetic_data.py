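"""Synthetic phantoms, structure sets and dual-arc prostate VMAT plans.

The generator emulates the study conditions the QA pipeline is meant for:
dual-arc 6 MV prostate plans at 2 Gy/fraction on an 80-pair MLC with 5 mm
leaves, gantry spanning -180..+180 deg, fixed per-arc collimator in
[0, 45] deg, minimum leaf gap 0.5-1.0 cm and PTV volumes of 61-630 ccm,
delivered to a water-density pelvis stand-in with rectum, bladder and
femoral-head organs at risk.

Apertures are built per control point from the beam's-eye-view projection
of the PTV (plus a margin), one interval per 5 mm leaf row; modulation is
a sweeping window narrower than the conformal interval whose centre
oscillates sinusoidally across it, which ties voxel dose to the leaf gap
and so produces the steep, gantry-dependent gradients and sub-millimetre
MLC-shift sensitivity of real modulated VMAT.  Total MU is normalized so
the engine's own
calculation of PTV Dmean equals the prescription, the desk-scale analogue
of clinical plan normalization.  All outputs are deterministic functions
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dose_engine import EngineConfig, compute_dose
from .exceptions import ValidationError
from .geometry import project_to_iso_plane
from .grids import PhantomVolume, StructureSet
from .plan import (DEFAULT_LEAF_BOUNDARIES, ArcBeam, ControlPoint, VmatPlan)

__all__ = ["PlanSpec", "make_phantom", "make_structures", "make_vmat_plan",
           "CohortCase", "generate_cohort"]

AIR_DENSITY = 0.0012  # g/cm^3, below the 0.1 g/cm^3 external threshold
WATER_DENSITY = 1.0


@dataclass(frozen=True)
class PlanSpec:
    """Knobs of the plan generator; defaults match the study conditions."""

    prescription_gy: float = 2.0
    n_arcs: int = 2
    control_points_per_arc: int = 61
    collimator_deg: tuple[float, ...] = (10.0, 35.0)
    gantry_span_deg: tuple[float, float] = (-180.0, 180.0)
    min_leaf_gap_cm: float = 0.6
    ptv_volume_ccm: float = 160.0
    modulation: float = 0.3      # 0 = conformal arc, 1 = strongest
    margin_mm: float = 7.0       # aperture margin around the PTV projection
    mu_per_arc: float = 300.0    # before normalization
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.prescription_gy > 0:
            raise ValidationError("prescription must be positive")
        if not 0.5 <= self.min_leaf_gap_cm <= 1.0:
            raise ValidationError("minimum leaf gap must lie in [0.5, 1.0] cm")
        if not 61.0 <= self.ptv_volume_ccm <= 630.0:
            raise ValidationError("PTV volume must lie in [61, 630] ccm")
        if not 0.0 <= self.modulation <= 1.0:
            raise ValidationError("modulation must lie in [0, 1]")
        if self.n_arcs < 1 or self.control_points_per_arc < 2:
            raise ValidationError("need >= 1 arc and >= 2 control points")
        if len(self.collimator_deg) < self.n_arcs:
            raise ValidationError("one collimator angle per arc required")
        for c in self.collimator_deg:
            if not 0.0 <= c <= 45.0:
                raise ValidationError("collimator angle must lie in [0, 45]")


def make_phantom(radius_mm: float = 125.0, length_mm: float = 180.0,
                 spacing_mm: float = 3.0, *,
                 anteroposterior_ratio: float = 1.0,
                 air_margin_mm: float = 9.0) -> PhantomVolume:
    """Water-density elliptical cylinder in air, centred on the isocenter.

    The cylinder axis runs along z (patient longitudinal); the transverse
    semi-axes are ``radius_mm`` (lateral) and ``radius_mm *
    anteroposterior_ratio``.  Deterministic.
    """
    if radius_mm <= 0 or length_mm <= 0 or spacing_mm <= 0:
        raise ValidationError("radius, length and spacing must be positive")
    if spacing_mm > min(radius_mm, length_mm):
        raise ValidationError("voxel spacing larger than the body")
    rx = radius_mm
    ry = radius_mm * anteroposterior_ratio

    def axis(half_extent):
        n = 2 * int(np.floor(half_extent / spacing_mm)) + 1
        return -spacing_mm * (n // 2), n

    (x0, nx), (y0, ny), (z0, nz) = (axis(rx + air_margin_mm),
                                    axis(ry + air_margin_mm),
                                    axis(length_mm / 2.0))
    x = x0 + spacing_mm * np.arange(nx)
    y = y0 + spacing_mm * np.arange(ny)
    inside = ((x[:, None] / rx) ** 2 + (y[None, :] / ry) ** 2) <= 1.0
    density = np.where(inside, WATER_DENSITY, AIR_DENSITY)
    density = np.repeat(density[:, :, None], nz, axis=2)
    return PhantomVolume(density=density, spacing_mm=spacing_mm,
                         origin_mm=np.array([x0, y0, z0]))


def make_structures(phantom: PhantomVolume, ptv_volume_ccm: float,
                    seed: int = 0) -> StructureSet:
    """PTV and organ-at-risk masks on the phantom grid.

    Ellipsoidal PTV centred on the isocenter; rectum posterior (+y) and
    bladder anterior-superior, each abutting the PTV; femoral heads
    lateral.  All masks are clipped to the external (body) contour.  The
    realized PTV volume tracks the request to within voxelization error.
    """
    if not 61.0 <= ptv_volume_ccm <= 630.0:
        raise ValidationError("PTV volume must lie in [61, 630] ccm")
    rng = np.random.default_rng(seed)
    fy = rng.uniform(0.85, 1.05)
    fz = rng.uniform(0.80, 1.00)
    a = (3.0 * ptv_volume_ccm * 1000.0 / (4.0 * np.pi * fy * fz)) ** (1.0 / 3.0)
    ax, ay, az = a, a * fy, a * fz

    geom = phantom.geometry
    gx, gy, gz = geom.axes(phantom.density.shape)
    X = gx[:, None, None]
    Y = gy[None, :, None]
    Z = gz[None, None, :]
    sp = float(np.max(phantom.spacing_mm))
    body = phantom.density >= 0.1

    ptv = (X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2 <= 1.0

    r_rect = 13.0
    y_rect = ay + r_rect + 0.5 * sp
    rectum = ((X ** 2 + (Y - y_rect) ** 2 <= r_rect ** 2)
              & (np.abs(Z) <= 45.0))

    r_bl = 18.0
    y_bl = -(ay + r_bl + 0.5 * sp)
    z_bl = 0.3 * az
    bladder = (X ** 2 + (Y - y_bl) ** 2 + (Z - z_bl) ** 2) <= r_bl ** 2

    r_fem = 13.0
    x_fem = ax + r_fem + 1.5 * sp
    femur_l = (((X - x_fem) ** 2 + Y ** 2 <= r_fem ** 2)
               & (np.abs(Z) <= 40.0))
    femur_r = (((X + x_fem) ** 2 + Y ** 2 <= r_fem ** 2)
               & (np.abs(Z) <= 40.0))

    masks = {
        "PTV": ptv & body,
        "rectum": rectum & body & ~ptv,
        "bladder": bladder & body & ~ptv,
        "femur_left": femur_l & body,
        "femur_right": femur_r & body,
        "external": body,
    }
    return StructureSet(masks=masks, spacing_mm=phantom.spacing_mm,
                        origin_mm=phantom.origin_mm)


# ---------------------------------------------------------------------------
# plan generation


def _bev_apertures(ptv_points: np.ndarray, gantry_deg: np.ndarray,
                   collimator_deg: float, sad_mm: float,
                   boundaries: np.ndarray, margin_mm: float):
    """Per-control-point leaf intervals fitting the PTV projection."""
    n_rows = boundaries.size - 1
    ncp = gantry_deg.size
    lo = np.full((ncp, n_rows), np.nan)
    hi = np.full((ncp, n_rows), np.nan)
    for i, g in enumerate(gantry_deg):
        x, y, _ = project_to_iso_plane(ptv_points, g, collimator_deg, sad_mm)
        rows = np.searchsorted(boundaries, y, side="right") - 1
        ok = (rows >= 0) & (rows < n_rows)
        r, xv = rows[ok], x[ok]
        mn = np.full(n_rows, np.inf)
        mx = np.full(n_rows, -np.inf)
        np.minimum.at(mn, r, xv)
        np.maximum.at(mx, r, xv)
        open_rows = np.isfinite(mn)
        lo[i, open_rows] = mn[open_rows] - margin_mm
        hi[i, open_rows] = mx[open_rows] + margin_mm
    return lo, hi


def make_vmat_plan(phantom: PhantomVolume, structures: StructureSet,
                   spec: PlanSpec, engine_cfg: EngineConfig | None = None,
                   normalize: bool = True) -> VmatPlan:
    """Deliverable dual-arc VMAT plan conforming to the PTV projection.

    With ``modulation=0`` every control point's aperture equals the PTV
    beam's-eye-view projection plus the margin (a conformal arc).  Leaf
    gaps never fall below the spec's minimum gap; cumulative meterset is
    strictly increasing 0 -> 1 per arc.  With ``normalize=True`` total MU
    is scaled so the engine's own noise-free PTV Dmean equals the
    prescription.
    """
    rng = np.random.default_rng(spec.seed)
    boundaries = DEFAULT_LEAF_BOUNDARIES
    n_rows = boundaries.size - 1
    iso = np.zeros(3)
    sad = 1000.0
    ptv_mask = structures.masks["PTV"]
    if not ptv_mask.any():
        raise ValidationError("PTV mask is empty")
    ptv_points = structures.geometry.voxel_centers(ptv_mask.shape)[
        ptv_mask.ravel()] - iso

    min_gap_mm = spec.min_leaf_gap_cm * 10.0
    ncp = spec.control_points_per_arc
    g_lo, g_hi = spec.gantry_span_deg
    beams = []
    for arc in range(spec.n_arcs):
        coll = float(spec.collimator_deg[arc])
        if arc % 2 == 0:
            gantry = np.linspace(g_lo, g_hi, ncp)
        else:
            gantry = np.linspace(g_hi, g_lo, ncp)
        lo, hi = _bev_apertures(ptv_points, gantry, coll, sad, boundaries,
                                spec.margin_mm)
        open_rows = np.any(np.isfinite(lo), axis=0)

        # Sweeping-window modulation: for modulation > 0 each open row's
        # aperture is a window narrower than the conformal interval whose
        # centre oscillates sinusoidally across it (seeded frequency/phase
        # per row).  Voxel dose then scales with the leaf gap, which is
        # what makes real modulated VMAT sensitive to sub-mm MLC shifts.
        # modulation = 0 reproduces the conformal interval exactly.
        s = np.linspace(0.0, 1.0, ncp)[:, None]
        freq = rng.integers(1, 4, size=n_rows).astype(float)
        phase = rng.uniform(0.0, 1.0, size=n_rows)
        width_frac = float(np.clip(1.0 - 1.8 * spec.modulation, 0.15, 1.0))
        full = np.where(np.isfinite(lo), hi - lo, min_gap_mm)
        width = np.maximum(width_frac * full, min_gap_mm)
        travel = np.maximum(full - width, 0.0)
        sweep = 0.5 + 0.5 * np.sin(2 * np.pi * (freq[None, :] * s + phase[None, :]))
        win_lo = np.where(np.isfinite(lo), lo, 0.0) + travel * sweep
        win_hi = win_lo + width

        # fill closed rows with a parked pair behind the x jaws
        row_lo = np.where(np.isfinite(lo), lo, 0.0)
        row_hi = np.where(np.isfinite(hi), hi, 0.0)
        jx1 = row_lo[:, open_rows].min() - 2.0 if open_rows.any() else -10.0
        jx2 = row_hi[:, open_rows].max() + 2.0 if open_rows.any() else 10.0
        ridx = np.nonzero(open_rows)[0]
        jy1 = boundaries[ridx.min()] - 2.0 if ridx.size else -10.0
        jy2 = boundaries[ridx.max() + 1] + 2.0 if ridx.size else 10.0
        park = jx2 + 30.0

        la = np.where(np.isfinite(lo), win_lo, park - min_gap_mm / 2.0)
        lb = np.where(np.isfinite(hi), win_hi, park + min_gap_mm / 2.0)
        deficit = np.maximum(min_gap_mm - (lb - la), 0.0)
        la -= deficit / 2.0
        lb += deficit / 2.0

        la, lb = np.round(la, 6), np.round(lb, 6)
        jaws = np.round(np.array([jx1, jx2, jy1, jy2]), 6)
        cps = [
            ControlPoint(
                gantry_deg=float(np.round(gantry[i], 6)),
                collimator_deg=coll,
                leaves_a_mm=la[i], leaves_b_mm=lb[i],
                jaws_mm=jaws.copy(),
                cumulative_mu=float(np.round(
                    spec.mu_per_arc * i / (ncp - 1), 6)),
            )
            for i in range(ncp)
        ]
        beams.append(ArcBeam(control_points=cps, meterset_mu=spec.mu_per_arc,
                             name=f"arc_{arc + 1}"))

    plan = VmatPlan(beams=beams, isocenter_mm=iso, sad_mm=sad,
                    leaf_boundaries_mm=boundaries.copy(),
                    name=f"synthetic_{spec.seed}")
    plan.validate()

    if normalize:
        cfg = engine_cfg if engine_cfg is not None else EngineConfig()
        dose = compute_dose(plan, phantom, replace(cfg, uncertainty="none"))
        mask = structures.mask_on(dose.geometry, dose.dose.shape)["PTV"]
        dmean = float(dose.dose[mask].mean())
        if dmean <= 0:
            raise ValidationError("PTV receives no dose; cannot normalize")
        scale = spec.prescription_gy / dmean
        for beam in plan.beams:
            for cp in beam.control_points:
                cp.cumulative_mu = float(np.round(cp.cumulative_mu * scale, 6))
            beam.meterset_mu = beam.control_points[-1].cumulative_mu
        plan.validate()
    return plan


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortCase:
    """One virtual patient: phantom, structures, plan and its spec."""

    case_id: int
    phantom: PhantomVolume
    structures: StructureSet
    plan: VmatPlan
    spec: PlanSpec


def generate_cohort(n: int = 30, seed: int = 7, *,
                    phantom: PhantomVolume | None = None,
                    engine_cfg: EngineConfig | None = None,
                    ptv_range_ccm: tuple[float, float] = (61.0, 630.0),
                    control_points_per_arc: int = 61,
                    normalize: bool = True) -> list[CohortCase]:
    """Randomized virtual-patient cohort emulating the study population.

    PTV volumes are drawn log-uniformly over ``ptv_range_ccm``, modulation
    over [0.15, 0.45], minimum leaf gap over [0.5, 1.0] cm and per-arc
    collimator angles over [0, 45] deg.  One shared phantom geometry is
    used unless an explicit phantom is given.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    ph = phantom if phantom is not None else make_phantom()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        vol = float(np.exp(rng.uniform(np.log(ptv_range_ccm[0]),
                                       np.log(ptv_range_ccm[1]))))
        spec = PlanSpec(
            ptv_volume_ccm=vol,
            modulation=float(rng.uniform(0.15, 0.45)),
            min_leaf_gap_cm=float(rng.uniform(0.5, 1.0)),
            collimator_deg=(float(rng.uniform(0, 45)),
                            float(rng.uniform(0, 45))),
            control_points_per_arc=control_points_per_arc,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        structures = make_structures(ph, vol, seed=spec.seed)
        plan = make_vmat_plan(ph, structures, spec, engine_cfg=engine_cfg,
                              normalize=normalize)
        cases.append(CohortCase(case_id=i, phantom=ph, structures=structures,
                                plan=plan, spec=spec))
    return cases
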