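"""Independent brute-force gamma oracle for cross-checking the fast search.

Scans the full probe lattice (no distance sorting, no early exit) with a
straightforward triple loop per reference voxel.  Slow but transparent;
only usable on small grids.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=False)
def _brute_kernel(ref_vals, ref_pos, ev, origin, spacing, dta, dd_abs,
                  step, radius, fail_value):
    n_ref = ref_vals.size
    nx, ny, nz = ev.shape
    n = int(np.floor(radius / step + 1e-9))
    out = np.empty(n_ref)
    for m in range(n_ref):
        best = 1e300
        rx, ry, rz = ref_pos[m, 0], ref_pos[m, 1], ref_pos[m, 2]
        rv = ref_vals[m]
        for ix in range(-n, n + 1):
            dx = ix * step
            for iy in range(-n, n + 1):
                dy = iy * step
                for iz in range(-n, n + 1):
                    dz = iz * step
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 > radius * radius + 1e-9:
                        continue
                    fx = (rx + dx - origin[0]) / spacing[0]
                    fy = (ry + dy - origin[1]) / spacing[1]
                    fz = (rz + dz - origin[2]) / spacing[2]
                    if (fx < 0.0 or fx > nx - 1 or fy < 0.0 or fy > ny - 1
                            or fz < 0.0 or fz > nz - 1):
                        continue
                    i = min(int(fx), nx - 2) if nx > 1 else 0
                    j = min(int(fy), ny - 2) if ny > 1 else 0
                    k = min(int(fz), nz - 2) if nz > 1 else 0
                    tx, ty, tz = fx - i, fy - j, fz - k
                    i1 = min(i + 1, nx - 1)
                    j1 = min(j + 1, ny - 1)
                    k1 = min(k + 1, nz - 1)
                    c00 = ev[i, j, k] * (1 - tx) + ev[i1, j, k] * tx
                    c10 = ev[i, j1, k] * (1 - tx) + ev[i1, j1, k] * tx
                    c01 = ev[i, j, k1] * (1 - tx) + ev[i1, j, k1] * tx
                    c11 = ev[i, j1, k1] * (1 - tx) + ev[i1, j1, k1] * tx
                    c0 = c00 * (1 - ty) + c10 * ty
                    c1 = c01 * (1 - ty) + c11 * ty
                    d = c0 * (1 - tz) + c1 * tz
                    diff = (d - rv) / dd_abs
                    g2 = r2 / (dta * dta) + diff * diff
                    if g2 < best:
                        best = g2
        out[m] = np.sqrt(best) if best < 1e300 else fail_value
    return out


def gamma_brute_force(reference, evaluated, criteria):
    """Exhaustive dense-lattice gamma on the reference grid's masked voxels.

    Returns an array shaped like the reference dose with NaN outside the
    low-dose threshold mask, mirroring the fast path's output contract.
    """
    norm = (criteria.norm_dose_gy
            if criteria.normalization == "prescription"
            else float(reference.dose.max()))
    mask = reference.dose >= criteria.threshold_pct / 100.0 * norm
    out = np.full(reference.dose.shape, np.nan)
    if not mask.any():
        return out, mask
    points = reference.geometry.voxel_centers(reference.dose.shape).reshape(
        reference.dose.shape + (3,))
    out[mask] = _brute_kernel(
        np.ascontiguousarray(reference.dose[mask]),
        np.ascontiguousarray(points[mask]),
        np.ascontiguousarray(evaluated.dose),
        evaluated.geometry.origin_mm, evaluated.geometry.spacing_mm,
        criteria.dta_mm, criteria.dose_pct / 100.0 * norm,
        criteria.step_factor * criteria.dta_mm,
        criteria.search_factor * criteria.dta_mm,
        2.0 * criteria.search_factor,
    )
    return out, mask
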