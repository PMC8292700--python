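"""Dose-distribution comparison statistics: 3D gamma, DVH and Dx/Vx metrics.

The gamma index of a reference voxel at position r with dose D_ref is

    gamma(r) = min over r' of sqrt( |r - r'|^2 / DTA^2
                                    + (D_eval(r') - D_ref(r))^2 / dD^2 )

with dD the dose-difference criterion as an absolute dose (percentage of
the normalization dose) and DTA the distance-to-agreement criterion.  The
minimum is taken over a dense sub-voxel lattice (step ``step_factor x
DTA``) within a search ball of radius ``search_factor x DTA``, the
evaluated dose being trilinearly interpolated at each probe position in
its native geometry.  Reference voxels below the low-dose threshold are
excluded from the evaluated mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .exceptions import UndefinedResultError, ValidationError
from .grids import DoseGrid

__all__ = [
    "GammaCriteria", "GammaMap", "DvhCurve", "MetricSpec",
    "gamma_index", "passing_rate", "dvh", "dvh_metric", "metric_difference",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-analysis parameters; defaults are the clinical 2%/1mm/20%."""

    dose_pct: float = 2.0         # % of the normalization dose
    dta_mm: float = 1.0           # distance to agreement
    threshold_pct: float = 20.0   # low-dose cutoff, % of normalization dose
    normalization: str = "global_max_reference"  # or "prescription"
    norm_dose_gy: float | None = None  # required for "prescription"
    search_factor: float = 3.0    # search ball radius, units of DTA
    step_factor: float = 0.1      # sub-voxel probe step, units of DTA

    def __post_init__(self) -> None:
        if not (self.dose_pct > 0 and self.dta_mm > 0
                and self.threshold_pct > 0):
            raise ValidationError("gamma criteria must all be positive")
        if self.normalization not in ("global_max_reference", "prescription"):
            raise ValidationError("unknown normalization mode")
        if not (0 < self.step_factor <= 1 and self.search_factor >= 1):
            raise ValidationError("invalid search discretization")


@dataclass
class GammaMap:
    """Per-voxel gamma on the reference grid plus the evaluated-voxel mask."""

    gamma: np.ndarray          # NaN outside the mask
    mask: np.ndarray           # reference voxels above the low-dose threshold
    criteria: GammaCriteria
    norm_dose_gy: float
    search_radius_mm: float


def _search_offsets(criteria: GammaCriteria):
    """Probe offsets within the search ball, sorted by distance."""
    step = criteria.step_factor * criteria.dta_mm
    radius = criteria.search_factor * criteria.dta_mm
    n = int(np.floor(radius / step + 1e-9))
    ax = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    r2 = np.sum(offsets ** 2, axis=1)
    keep = r2 <= radius ** 2 + 1e-9
    offsets, r2 = offsets[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    offsets = np.ascontiguousarray(offsets[order])
    rterm2 = np.ascontiguousarray(r2[order] / criteria.dta_mm ** 2)
    return offsets, rterm2


@numba.njit(cache=False)
def _gamma_search(ref_vals, ref_pos, ev, ev_origin, ev_spacing,
                  offsets, rterm2, dd_abs, fail_value):
    n_ref = ref_vals.size
    nx, ny, nz = ev.shape
    out = np.empty(n_ref)
    for m in range(n_ref):
        best = 1e300
        rx, ry, rz = ref_pos[m, 0], ref_pos[m, 1], ref_pos[m, 2]
        rv = ref_vals[m]
        for k in range(offsets.shape[0]):
            rt = rterm2[k]
            if rt >= best:
                break  # offsets are distance-sorted: no better point left
            fx = (rx + offsets[k, 0] - ev_origin[0]) / ev_spacing[0]
            if fx < 0.0 or fx > nx - 1:
                continue
            fy = (ry + offsets[k, 1] - ev_origin[1]) / ev_spacing[1]
            if fy < 0.0 or fy > ny - 1:
                continue
            fz = (rz + offsets[k, 2] - ev_origin[2]) / ev_spacing[2]
            if fz < 0.0 or fz > nz - 1:
                continue
            i = min(int(fx), nx - 2) if nx > 1 else 0
            j = min(int(fy), ny - 2) if ny > 1 else 0
            l = min(int(fz), nz - 2) if nz > 1 else 0
            tx, ty, tz = fx - i, fy - j, fz - l
            i1 = min(i + 1, nx - 1)
            j1 = min(j + 1, ny - 1)
            l1 = min(l + 1, nz - 1)
            c00 = ev[i, j, l] * (1 - tx) + ev[i1, j, l] * tx
            c10 = ev[i, j1, l] * (1 - tx) + ev[i1, j1, l] * tx
            c01 = ev[i, j, l1] * (1 - tx) + ev[i1, j, l1] * tx
            c11 = ev[i, j1, l1] * (1 - tx) + ev[i1, j1, l1] * tx
            c0 = c00 * (1 - ty) + c10 * ty
            c1 = c01 * (1 - ty) + c11 * ty
            d = c0 * (1 - tz) + c1 * tz
            diff = (d - rv) / dd_abs
            g2 = rt + diff * diff
            if g2 < best:
                best = g2
        out[m] = np.sqrt(best) if best < 1e300 else fail_value
    return out


def _normalization_dose(reference: DoseGrid, criteria: GammaCriteria) -> float:
    if criteria.normalization == "prescription":
        if criteria.norm_dose_gy is None or criteria.norm_dose_gy <= 0:
            raise ValidationError(
                "prescription normalization needs a positive norm_dose_gy")
        return float(criteria.norm_dose_gy)
    return float(reference.dose.max())


def gamma_index(reference: DoseGrid, evaluated: DoseGrid,
                criteria: GammaCriteria | None = None) -> GammaMap:
    """3D gamma of an evaluated dose grid against a reference grid."""
    criteria = criteria if criteria is not None else GammaCriteria()
    ref_geom, ev_geom = reference.geometry, evaluated.geometry
    ref_lo = ref_geom.origin_mm
    ref_hi = ref_geom.origin_mm + (np.array(reference.dose.shape) - 1) * ref_geom.spacing_mm
    ev_lo = ev_geom.origin_mm
    ev_hi = ev_geom.origin_mm + (np.array(evaluated.dose.shape) - 1) * ev_geom.spacing_mm
    if np.any(ref_hi < ev_lo) or np.any(ev_hi < ref_lo):
        raise ValidationError("reference and evaluated grids do not overlap")

    norm = _normalization_dose(reference, criteria)
    if norm <= 0:
        raise ValidationError("normalization dose must be positive")
    mask = reference.dose >= criteria.threshold_pct / 100.0 * norm

    gamma = np.full(reference.dose.shape, np.nan)
    if mask.any():
        points = ref_geom.voxel_centers(reference.dose.shape).reshape(
            reference.dose.shape + (3,))
        offsets, rterm2 = _search_offsets(criteria)
        gamma[mask] = _gamma_search(
            np.ascontiguousarray(reference.dose[mask]),
            np.ascontiguousarray(points[mask]),
            np.ascontiguousarray(evaluated.dose),
            ev_geom.origin_mm, ev_geom.spacing_mm,
            offsets, rterm2,
            criteria.dose_pct / 100.0 * norm,
            2.0 * criteria.search_factor,
        )
    return GammaMap(gamma=gamma, mask=mask, criteria=criteria,
                    norm_dose_gy=norm,
                    search_radius_mm=criteria.search_factor * criteria.dta_mm)


def passing_rate(gamma_map: GammaMap, roi_mask: np.ndarray | None = None
                 ) -> float:
    """Gamma passing rate (%): fraction of evaluated voxels with gamma <= 1."""
    sel = gamma_map.mask
    if roi_mask is not None:
        if roi_mask.shape != sel.shape:
            raise ValidationError("ROI mask geometry does not match the map")
        sel = sel & roi_mask
    n = int(sel.sum())
    if n == 0:
        raise UndefinedResultError(
            "no evaluated voxels in the requested region")
    return 100.0 * float((gamma_map.gamma[sel] <= 1.0).sum()) / n


# ---------------------------------------------------------------------------
# DVH


@dataclass
class DvhCurve:
    """Cumulative DVH: percent of ROI volume receiving at least each dose."""

    roi_name: str
    dose_gy: np.ndarray       # bin edges, fixed width, starting at 0
    volume_pct: np.ndarray    # non-increasing, volume_pct[0] == 100

    @property
    def bin_width_gy(self) -> float:
        return float(self.dose_gy[1] - self.dose_gy[0])


def dvh(dose: DoseGrid, roi_mask: np.ndarray, bin_width_gy: float = 0.01,
        roi_name: str = "ROI") -> DvhCurve:
    """Cumulative DVH of a dose grid over an ROI mask."""
    if roi_mask.shape != dose.dose.shape:
        raise ValidationError("ROI mask does not match the dose grid")
    vals = np.sort(dose.dose[roi_mask])
    if vals.size == 0:
        raise ValidationError("ROI is empty")
    if bin_width_gy <= 0:
        raise ValidationError("bin width must be positive")
    n_bins = int(np.ceil(vals[-1] / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    at_least = vals.size - np.searchsorted(vals, edges, side="left")
    return DvhCurve(roi_name=roi_name, dose_gy=edges,
                    volume_pct=100.0 * at_least / vals.size)


@dataclass(frozen=True)
class MetricSpec:
    """A DVH metric: Dmean, Dmax, Dx (Gy to the hottest x%) or Vx (% of ROI
    receiving >= x% of prescription)."""

    kind: str
    x: float | None = None
    prescription_gy: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("Dmean", "Dmax", "Dx", "Vx"):
            raise ValidationError("metric kind must be Dmean/Dmax/Dx/Vx")
        if self.kind == "Dx" and not (self.x is not None and 0 < self.x <= 100):
            raise ValidationError("Dx needs 0 < x <= 100")
        if self.kind == "Vx" and not (self.x is not None and self.x > 0):
            raise ValidationError("Vx needs x > 0")

    @classmethod
    def parse(cls, text: str, prescription_gy: float | None = None
              ) -> "MetricSpec":
        """Parse clinical shorthand: "Dmean", "Dmax", "D15", "V95", ..."""
        if text in ("Dmean", "Dmax"):
            return cls(kind=text, prescription_gy=prescription_gy)
        kind = {"D": "Dx", "V": "Vx"}.get(text[0])
        if kind is None:
            raise ValidationError(f"cannot parse metric {text!r}")
        return cls(kind=kind, x=float(text[1:]),
                   prescription_gy=prescription_gy)

    @property
    def label(self) -> str:
        if self.kind in ("Dmean", "Dmax"):
            return self.kind
        return f"{self.kind[0]}{self.x:g}"


def _metric_from_voxels(vals: np.ndarray, spec: MetricSpec) -> float:
    if spec.kind == "Dmean":
        return float(vals.mean())
    if spec.kind == "Dmax":
        return float(vals.max())
    if spec.kind == "Dx":
        # smallest dose received by at least x% of the ROI (hottest x%)
        k = int(np.ceil(vals.size * spec.x / 100.0))
        return float(np.sort(vals)[::-1][k - 1])
    if spec.prescription_gy is None or spec.prescription_gy <= 0:
        raise ValidationError("Vx needs a positive prescription dose")
    level = spec.x / 100.0 * spec.prescription_gy
    return 100.0 * float((vals >= level).sum()) / vals.size


def _metric_from_curve(curve: DvhCurve, spec: MetricSpec) -> float:
    d, v = curve.dose_gy, curve.volume_pct
    if spec.kind == "Dmean":
        # area under the cumulative DVH equals the mean dose
        return float(np.trapezoid(v, d)) / 100.0
    if spec.kind == "Dmax":
        nz = np.nonzero(v > 0)[0]
        return float(d[nz[-1]]) if nz.size else 0.0
    if spec.kind == "Dx":
        # V is non-increasing; smallest d with V(d) >= x, linearly interpolated
        idx = np.nonzero(v >= spec.x)[0]
        if idx.size == 0:
            return 0.0
        i = idx[-1]
        if i + 1 >= d.size or v[i + 1] == v[i]:
            return float(d[i])
        f = (v[i] - spec.x) / (v[i] - v[i + 1])
        return float(d[i] + f * (d[i + 1] - d[i]))
    if spec.prescription_gy is None or spec.prescription_gy <= 0:
        raise ValidationError("Vx needs a positive prescription dose")
    level = spec.x / 100.0 * spec.prescription_gy
    return float(np.interp(level, d, v))


def dvh_metric(source, spec: MetricSpec) -> float:
    """Evaluate a DVH metric from a DvhCurve or a ``(dose, roi_mask)`` pair.

    The pair form computes directly from the voxel doses (``dose`` may be a
    DoseGrid or an array); the curve form interpolates on the histogram and
    agrees with the direct route to within one bin width.
    """
    if isinstance(source, DvhCurve):
        return _metric_from_curve(source, spec)
    dose, mask = source
    arr = dose.dose if isinstance(dose, DoseGrid) else np.asarray(dose)
    vals = arr[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValidationError("ROI is empty")
    return _metric_from_voxels(vals, spec)


def metric_difference(reference: float, evaluated: float,
                      normalization: float) -> float:
    """Signed percentage difference, ``100 * (ref - eval) / norm``.

    Positive means under-delivery relative to the reference (the closing-
    error direction); negative means over-delivery.
    """
    if normalization == 0:
        raise UndefinedResultError("zero normalization value")
    return 100.0 * (reference - evaluated) / normalization
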