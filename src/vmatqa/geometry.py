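"""Beam geometry: the mapping between patient space and the beam's-eye view.

The gantry rotates about the patient's longitudinal (z) axis.  At gantry
angle g the source sits at ``SAD * (sin g, cos g, 0)`` relative to the
isocenter; the central axis points back through the isocenter.  A point is
projected divergently onto the isocenter plane and the collimator angle
then rotates the in-plane coordinates.  Both the dose engine and the
aperture generator use this one projection so their conventions cannot
drift apart.
"""

from __future__ import annotations

import numpy as np


def source_position(gantry_deg: float, sad_mm: float) -> np.ndarray:
    g = np.deg2rad(gantry_deg)
    return sad_mm * np.array([np.sin(g), np.cos(g), 0.0])


def project_to_iso_plane(
    points_mm: np.ndarray,
    gantry_deg: float,
    collimator_deg: float,
    sad_mm: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project points (N, 3; relative to isocenter) into the beam's-eye view.

    Returns ``(x, y, d_axis)`` where ``x``/``y`` are collimator-frame
    coordinates at the isocenter plane (mm) and ``d_axis`` is the distance
    from the source along the central axis (mm).  Points upstream of the
    source (``d_axis <= 0``) are returned with ``d_axis`` clipped to a tiny
    positive value; callers treat them as out of field.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    g = np.deg2rad(gantry_deg)
    src = sad_mm * np.array([np.sin(g), np.cos(g), 0.0])
    axis = -src / sad_mm                      # unit vector source -> isocenter
    e1 = np.array([np.cos(g), -np.sin(g), 0.0])  # transverse, in-plane
    e2 = np.array([0.0, 0.0, 1.0])               # along patient axis
    rel = pts - src
    d_axis = rel @ axis
    d_axis = np.maximum(d_axis, 1e-6)
    scale = sad_mm / d_axis
    xb = (rel @ e1) * scale
    yb = (rel @ e2) * scale
    c = np.deg2rad(collimator_deg)
    x = np.cos(c) * xb + np.sin(c) * yb
    y = -np.sin(c) * xb + np.cos(c) * yb
    return x, y, d_axis
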