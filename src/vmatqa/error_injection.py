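"""MLC shift-error injection and the on-treatment sensitivity study.

A shift of +delta opens every leaf pair symmetrically (bank A moves down,
bank B up; each pair gap grows by 2*delta); a negative delta closes the
aperture the same way.  Pairs that would cross are clamped to zero gap
and counted.  Shifts are applied to the *plan* before delivery simulation
so the log faithfully records the erroneous positions, mirroring a plan
manipulated upstream of the machine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import GammaCriteria, gamma_index, metric_difference, passing_rate
from .delivery_log import JitterSpec, log_to_plan, simulate_delivery
from .dose_engine import EngineConfig, compute_dose
from .exceptions import ValidationError
from .grids import DoseGrid, PhantomVolume, StructureSet
from .plan import VmatPlan

__all__ = ["MlcErrorSpec", "MlcShiftResult", "SensitivityRow",
           "shift_mlc", "sensitivity_sweep", "detection_threshold"]

MAX_SHIFT_MM = 10.0  # machine-representable misalignment range


@dataclass(frozen=True)
class MlcErrorSpec:
    """A signed MLC shift: positive opens the aperture, negative closes it."""

    shift_mm: float
    mode: str = "symmetric_banks"  # both banks displaced by |shift| each

    def __post_init__(self) -> None:
        if abs(self.shift_mm) > MAX_SHIFT_MM:
            raise ValidationError(
                f"|shift| must be <= {MAX_SHIFT_MM} mm")
        if self.mode != "symmetric_banks":
            raise ValidationError("only symmetric_banks mode is defined")


@dataclass
class MlcShiftResult:
    """Shifted plan plus the number of leaf pairs clamped to zero gap."""

    plan: VmatPlan
    n_clamped_pairs: int


def shift_mlc(plan: VmatPlan, spec: MlcErrorSpec) -> MlcShiftResult:
    """Displace every leaf of each bank outward (+) or inward (-) by |shift|.

    Each pair gap changes by ``2 * shift_mm``; pairs that would cross are
    clamped to zero gap at their midpoint and counted.  All other plan
    fields are unchanged; ``shift_mm=0`` returns an identical copy.
    """
    out = plan.copy()
    d = spec.shift_mm
    n_clamped = 0
    for beam in out.beams:
        for cp in beam.control_points:
            a = cp.leaves_a_mm - d
            b = cp.leaves_b_mm + d
            crossed = a > b
            n_clamped += int(crossed.sum())
            mid = 0.5 * (a + b)
            cp.leaves_a_mm = np.where(crossed, mid, a)
            cp.leaves_b_mm = np.where(crossed, mid, b)
    out.name = f"{plan.name}_shift{d:+g}mm"
    return MlcShiftResult(plan=out, n_clamped_pairs=n_clamped)


@dataclass
class SensitivityRow:
    """One line of the sensitivity table for a given shift magnitude."""

    delta_mm: float
    gpr_overall_pct: float
    gpr_ptv_pct: float
    ptv_dmean_diff_pct: float
    n_clamped_pairs: int = 0

    def __post_init__(self) -> None:
        for v in (self.gpr_overall_pct, self.gpr_ptv_pct):
            if not 0.0 <= v <= 100.0:
                raise ValidationError("GPR must lie in [0, 100]")


def sensitivity_sweep(
    plan: VmatPlan,
    phantom: PhantomVolume,
    structures: StructureSet,
    deltas_mm=(-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75),
    cfg: EngineConfig | None = None,
    jitter: JitterSpec | None = None,
    criteria: GammaCriteria | None = None,
    duration_per_arc_s: float = 90.0,
    reference_dose: DoseGrid | None = None,
) -> list[SensitivityRow]:
    """On-treatment QA of shift-error-injected deliveries of one plan.

    For each delta: inject the shift, simulate delivery, reconstruct the
    RT log file plan, recompute dose, and compare against the unshifted
    plan's reference dose (gamma overall / PTV and PTV Dmean difference).
    The noise-free engine and jitter-free delivery defaults make the sweep
    deterministic so the monotone dose response is not masked.
    """
    deltas = [float(d) for d in deltas_mm]
    if not any(d == 0.0 for d in deltas):
        raise ValidationError("the sweep must include the error-free row (0)")
    cfg = cfg if cfg is not None else EngineConfig()
    jitter = jitter if jitter is not None else JitterSpec.zero()
    criteria = criteria if criteria is not None else GammaCriteria()
    reference = (reference_dose if reference_dose is not None
                 else compute_dose(plan, phantom, cfg))
    ptv = structures.mask_on(reference.geometry, reference.dose.shape)["PTV"]
    ref_dmean = float(reference.dose[ptv].mean())

    rows = []
    for d in deltas:
        shifted = shift_mlc(plan, MlcErrorSpec(shift_mm=d))
        log = simulate_delivery(shifted.plan, jitter, duration_per_arc_s)
        reconstructed = log_to_plan(log, shifted.plan)
        dose = compute_dose(reconstructed, phantom, cfg)
        gmap = gamma_index(reference, dose, criteria)
        dmean = float(dose.dose[ptv].mean())
        rows.append(SensitivityRow(
            delta_mm=d,
            gpr_overall_pct=passing_rate(gmap),
            gpr_ptv_pct=passing_rate(gmap, ptv),
            ptv_dmean_diff_pct=metric_difference(ref_dmean, dmean, ref_dmean),
            n_clamped_pairs=shifted.n_clamped_pairs,
        ))
    return rows


def detection_threshold(rows: list[SensitivityRow], limits) -> dict:
    """Smallest flagged |delta| per error sign under the QA limits.

    ``limits`` provides ``gpr_pass_limit_pct`` and
    ``ptv_dmean_tolerance_pct`` (see :class:`vmatqa.qa_pipeline.QaLimits`).
    Returns ``{"opening": |delta| or None, "closing": |delta| or None}``;
    ``None`` means every row of that sign passes.
    """
    if not any(r.delta_mm == 0.0 for r in rows):
        raise ValidationError("rows must include the error-free (0) row")

    def fails(row: SensitivityRow) -> bool:
        return (row.gpr_overall_pct < limits.gpr_pass_limit_pct
                or abs(row.ptv_dmean_diff_pct) > limits.ptv_dmean_tolerance_pct)

    result = {}
    for sign, name in ((1.0, "opening"), (-1.0, "closing")):
        branch = sorted((r for r in rows if r.delta_mm * sign > 0),
                        key=lambda r: abs(r.delta_mm))
        flagged = next((abs(r.delta_mm) for r in branch if fails(r)), None)
        result[name] = flagged
    return result
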