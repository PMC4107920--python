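"""Detector ↔ reciprocal-space mapping for still exposures.

Conventions, fixed project-wide and written into the geometry
descriptor of every frame container:

* pixel indices are 0-based; ``fast`` is the first image axis stride-1
  direction (numpy column), ``slow`` the row;
* detector positions in mm are measured from the beam center, fast → x,
  slow → y; the beam travels along +z and hits the panel at
  ``distance`` mm;
* the incident wavevector is s0 = ẑ/λ and scattering vectors are
  q = (ŝ1 − ŝ0)/λ with |q| = 2 sin θ / λ = 1/d (no small-angle
  approximation anywhere).
"""

from __future__ import annotations

import numpy as np

from .physics import BeamSpec, DetectorSpec

__all__ = [
    "pixel_to_q",
    "q_to_pixel",
    "pixel_resolution",
    "pixel_s",
]


def pixel_to_q(fast: np.ndarray, slow: np.ndarray, det: DetectorSpec,
               beam: BeamSpec) -> np.ndarray:
    """Map (possibly fractional) pixel coordinates to scattering vectors
    q (Å⁻¹), shape (..., 3).  Exact Ewald-sphere geometry."""
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    x = (fast - det.beam_center_fast) * det.pixel_size
    y = (slow - det.beam_center_slow) * det.pixel_size
    z = np.full_like(x, det.distance)
    norm = np.sqrt(x * x + y * y + z * z)
    lam = beam.wavelength
    q = np.stack([x / norm, y / norm, z / norm - 1.0], axis=-1) / lam
    return q


def q_to_pixel(q: np.ndarray, det: DetectorSpec, beam: BeamSpec):
    """Project scattering vectors onto the panel.

    The outgoing direction is taken along s0 + q (renormalized, so
    vectors slightly off the Ewald sphere project along the nearest
    physical exit ray).  Returns ``(fast, slow, on_panel)``; rays that
    cannot hit the panel (exit direction with z ≤ 0) give NaN positions
    and ``on_panel=False``.
    """
    q = np.asarray(q, dtype=float)
    lam = beam.wavelength
    u = q * lam + np.array([0.0, 0.0, 1.0])  # ŝ1 up to normalization
    norm = np.linalg.norm(u, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = u / norm[..., None]
        t = det.distance / u[..., 2]
        x = u[..., 0] * t
        y = u[..., 1] * t
    forward = u[..., 2] > 1e-9
    fast = np.where(forward, x / det.pixel_size + det.beam_center_fast, np.nan)
    slow = np.where(forward, y / det.pixel_size + det.beam_center_slow, np.nan)
    on_panel = forward & (fast >= 0) & (fast <= det.n_fast - 1) \
        & (slow >= 0) & (slow <= det.n_slow - 1)
    return fast, slow, on_panel


def pixel_s(fast: np.ndarray, slow: np.ndarray, det: DetectorSpec,
            beam: BeamSpec) -> np.ndarray:
    """|q| = 1/d (Å⁻¹) for pixel coordinates."""
    return np.linalg.norm(pixel_to_q(fast, slow, det, beam), axis=-1)


def pixel_resolution(fast: np.ndarray, slow: np.ndarray, det: DetectorSpec,
                     beam: BeamSpec) -> np.ndarray:
    """Resolution d (Å) for pixel coordinates (inf at the beam center)."""
    s = pixel_s(fast, slow, det, beam)
    with np.errstate(divide="ignore"):
        return np.where(s > 0, 1.0 / s, np.inf)
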