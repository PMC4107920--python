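"""Reflection prediction for still (zero-rotation) exposures.

A reflection on a still diffracts only if its reciprocal-lattice point
lies close enough to the Ewald sphere.  The excitation error is

    ε = |q + s0| − 1/λ,   s0 = ẑ/λ,

and the acceptance window combines the effective rocking width from
crystal mosaicity, beam divergence and bandwidth in quadrature:

    σ(q) = sqrt( (η·|q|)² + (δ·|q|)² + (Δλ/λ · |q|² λ / 2)² )

with η the mosaic spread and δ the divergence, both in radians.  The
partiality of an accepted reflection is modelled as a Gaussian rocking
profile, p = exp(−ε²/2σ²) — the standard stills approximation; the
Monte Carlo merge downstream never corrects for it, it averages it out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .crystal import SymmetryInfo, UnitCell, generate_hkl
from .geometry import q_to_pixel
from .physics import BeamSpec, DetectorSpec

__all__ = ["StillPrediction", "predict_still", "excitation_sigma"]


@lru_cache(maxsize=8)
def _hkl_table(cell_key: tuple, d_min: float) -> np.ndarray:
    cell = UnitCell(*cell_key)
    return generate_hkl(cell, d_min)


def reflection_table(cell: UnitCell, sym: SymmetryInfo, d_min: float) -> np.ndarray:
    """Full-sphere non-absent reflection list for the cell, cached."""
    hkl = _hkl_table((cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma), d_min)
    return hkl[~sym.is_absent(hkl)]


def excitation_sigma(qlen: np.ndarray, beam: BeamSpec, mosaicity_deg: float) -> np.ndarray:
    """Effective Gaussian rocking width in excitation-error units (Å⁻¹)."""
    eta = math.radians(mosaicity_deg)
    lam = beam.wavelength
    return np.sqrt(
        (eta * qlen) ** 2
        + (beam.divergence * qlen) ** 2
        + (beam.bandwidth * qlen ** 2 * lam / 2.0) ** 2
    )


@dataclass
class StillPrediction:
    """Reflections excited on one still, with detector projections."""

    hkl: np.ndarray          # (n, 3) int
    q: np.ndarray            # (n, 3) Å⁻¹, crystal-rotated
    excitation: np.ndarray   # (n,) Å⁻¹, signed
    sigma: np.ndarray        # (n,) Å⁻¹ effective rocking width
    partiality: np.ndarray   # (n,) in [0, 1]
    fast: np.ndarray         # (n,) fractional pixels (NaN if unprojectable)
    slow: np.ndarray
    on_panel: np.ndarray     # (n,) bool

    def __len__(self) -> int:
        return len(self.hkl)


def predict_still(orientation: np.ndarray, cell: UnitCell, sym: SymmetryInfo,
                  beam: BeamSpec, det: DetectorSpec, d_min: float,
                  mosaicity_deg: float = 0.05,
                  cut_sigma: float = 3.0) -> StillPrediction:
    """Predict every reflection within ``cut_sigma`` rocking widths of
    the Ewald sphere, out to ``d_min``, for a crystal with rotation
    matrix ``orientation``.  Systematic absences are excluded;
    reflections projecting off the panel are flagged, not dropped."""
    R = np.asarray(orientation, dtype=float)
    if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
        raise ValueError("orientation must be a proper rotation matrix")
    hkl = reflection_table(cell, sym, d_min)
    A = R @ cell.b_matrix()
    q = hkl @ A.T
    qlen = np.linalg.norm(q, axis=1)
    lam = beam.wavelength
    k = 1.0 / lam
    # |q + s0| − 1/λ without forming the full vector sum twice
    eps = np.sqrt(qlen ** 2 + 2.0 * q[:, 2] * k + k * k) - k
    sigma = excitation_sigma(qlen, beam, mosaicity_deg)
    sel = np.abs(eps) <= cut_sigma * sigma
    hkl, q, eps, sigma = hkl[sel], q[sel], eps[sel], sigma[sel]
    partiality = np.exp(-0.5 * (eps / sigma) ** 2)
    fast, slow, on_panel = q_to_pixel(q, det, beam)
    return StillPrediction(hkl=hkl, q=q, excitation=eps, sigma=sigma,
                           partiality=partiality, fast=fast, slow=slow,
                           on_panel=on_panel)
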