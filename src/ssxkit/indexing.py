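"""Known-cell orientation determination for still patterns.

Each hit's peak list is back-projected onto the Ewald sphere, giving
one scattering vector per peak.  Since the unit cell is known a priori,
indexing reduces to an orientation search: find the rotation R that
superimposes the reciprocal lattice on the observed vectors.

The search is pair-based.  The lowest-resolution peaks are matched to
candidate reciprocal-lattice nodes by |q| and mutual angle; every
consistent (peak pair → node pair) correspondence yields a trial
rotation (two-vector Kabsch), all trials are scored in one vectorized
pass by the number of peaks landing within tolerance of an integer
node, and the best trial is polished by iterating full Kabsch
refinement over its matched set.  The tetragonal 422 orientation
degeneracy is accepted: any symmetry-equivalent rotation is correct and
downstream ASU mapping makes results invariant.

Cell refinement alternates orientation (Kabsch) and closed-form
least-squares updates of the reciprocal axis lengths (tetragonal
constraint by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .config import IndexingParams
from .crystal import SymmetryInfo, UnitCell, generate_hkl
from .geometry import pixel_to_q
from .peakfind import DetectedPeak
from .physics import BeamSpec, DetectorSpec

__all__ = [
    "ScatteringVectorSet",
    "CrystalOrientation",
    "peaks_to_scattering_vectors",
    "index_known_cell",
    "refine_cell",
]


@dataclass
class ScatteringVectorSet:
    """Per-peak reciprocal-space vectors (Å⁻¹) on the Ewald sphere."""

    q: np.ndarray       # (n, 3)
    fast: np.ndarray    # (n,) originating pixel coordinates
    slow: np.ndarray

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class CrystalOrientation:
    """An indexing solution: rotation, refined cell, bookkeeping."""

    rotation: np.ndarray       # (3, 3), proper
    cell: UnitCell
    hkl: np.ndarray            # (n_indexed, 3) assigned indices
    matched: np.ndarray        # bool mask over the input peaks
    rms_residual: float        # Å⁻¹

    @property
    def n_indexed_peaks(self) -> int:
        return int(self.matched.sum())

    def a_matrix(self) -> np.ndarray:
        return self.rotation @ self.cell.b_matrix()


def peaks_to_scattering_vectors(peaks: list[DetectedPeak], det: DetectorSpec,
                                beam: BeamSpec) -> ScatteringVectorSet:
    """Exact Ewald-sphere back-projection of peak centroids."""
    if len(peaks) == 0:
        return ScatteringVectorSet(q=np.zeros((0, 3)), fast=np.zeros(0), slow=np.zeros(0))
    fast = np.array([p.fast for p in peaks])
    slow = np.array([p.slow for p in peaks])
    return ScatteringVectorSet(q=pixel_to_q(fast, slow, det, beam), fast=fast, slow=slow)


@lru_cache(maxsize=8)
def _node_table(cell_key: tuple, d_min: float) -> tuple[np.ndarray, np.ndarray]:
    cell = UnitCell(*cell_key)
    hkl = generate_hkl(cell, d_min)
    qn = hkl @ cell.b_matrix().T
    lengths = np.linalg.norm(qn, axis=1)
    order = np.argsort(lengths)
    return qn[order], lengths[order]


def _kabsch(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Proper rotation R minimizing ||R a − b|| (rows are vectors)."""
    w = np.ones(len(a)) if weights is None else weights
    H = (a * w[:, None]).T @ b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _triads(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal triads (columns) from vector pairs,
    batched over the first axis."""
    e1 = v1 / np.linalg.norm(v1, axis=1, keepdims=True)
    e3 = np.cross(v1, v2)
    e3 = e3 / np.linalg.norm(e3, axis=1, keepdims=True)
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=2)


def _pair_rotations(a1, a2, b1, b2) -> np.ndarray:
    """Batched rotations mapping direction pairs (a1, a2) → (b1, b2)
    (exact for geometrically consistent pairs)."""
    return _triads(b1, b2) @ _triads(a1, a2).transpose(0, 2, 1)


def _score_rotations(rots: np.ndarray, binv: np.ndarray, q: np.ndarray,
                     bmat: np.ndarray, tol: float):
    """Indexed-peak count and rms residual for a batch of rotations."""
    # fractional indices: h = B⁻¹ Rᵀ q
    frac = np.einsum("ij,ckj,nk->cni", binv, rots, q)
    hint = np.round(frac)
    resid = np.einsum("ckj,jm,cnm->cnk", rots, bmat, hint) - q[None, :, :]
    dist = np.linalg.norm(resid, axis=2)
    matched = dist < tol
    counts = matched.sum(axis=1)
    with np.errstate(invalid="ignore"):
        rms = np.sqrt(np.where(counts > 0,
                               (dist ** 2 * matched).sum(axis=1) / np.maximum(counts, 1),
                               np.inf))
    return counts, rms, matched, hint


def index_known_cell(qvecs: ScatteringVectorSet, cell: UnitCell,
                     sym: SymmetryInfo,
                     params: IndexingParams | None = None) -> CrystalOrientation | None:
    """Index a still pattern against a known (prior) cell.

    Returns ``None`` when no orientation indexes at least
    ``min_indexed_fraction`` of the peaks — the per-frame failure mode
    that keeps serial indexing rates well below 100%.
    """
    params = params or IndexingParams()
    q = qvecs.q
    n = len(q)
    if n < params.min_peaks:
        return None
    bmat = cell.b_matrix()
    binv = np.linalg.inv(bmat)
    qlen = np.linalg.norm(q, axis=1)
    tol = params.q_tolerance_factor * 0.5 * _min_node_spacing(cell)

    # seed peaks: the lowest-|q| ones have the sparsest candidate sets
    order = np.argsort(qlen)
    seeds = order[: min(params.n_seed_peaks, n)]
    nodes_q, nodes_len = _node_table(
        (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        params.d_min_candidates)

    cand: dict[int, np.ndarray] = {}
    for i in seeds:
        lo = np.searchsorted(nodes_len, qlen[i] - params.length_tolerance)
        hi = np.searchsorted(nodes_len, qlen[i] + params.length_tolerance)
        cand[i] = np.arange(lo, hi)

    rot_batches = []
    for ai in range(len(seeds)):
        for bi in range(ai + 1, len(seeds)):
            i, j = seeds[ai], seeds[bi]
            ci, cj = cand[i], cand[j]
            if len(ci) == 0 or len(cj) == 0:
                continue
            cos_obs = float(q[i] @ q[j] / (qlen[i] * qlen[j]))
            if abs(cos_obs) > 0.99:
                continue  # nearly collinear pair constrains nothing
            vi, vj = nodes_q[ci], nodes_q[cj]
            cosm = (vi @ vj.T) / np.outer(nodes_len[ci], nodes_len[cj])
            pairs = np.argwhere(np.abs(cosm - cos_obs) < params.cos_angle_tolerance)
            if len(pairs) == 0:
                continue
            pairs = pairs[:400]
            a1, a2 = vi[pairs[:, 0]], vj[pairs[:, 1]]
            b1 = np.broadcast_to(q[i], a1.shape)
            b2 = np.broadcast_to(q[j], a1.shape)
            rot_batches.append(_pair_rotations(a1, a2, b1, b2))
    if not rot_batches:
        return None
    rots = np.concatenate(rot_batches)
    counts, rms, matched, hint = _score_rotations(rots, binv, q, bmat, tol)
    # best by count, ties broken by lower rms
    best = np.lexsort((rms, -counts))[0]
    if counts[best] < max(params.min_indexed_fraction * n, 3):
        return None

    R = rots[best]
    sel = matched[best]
    hkl = hint[best].astype(int)
    # polish: full Kabsch on the matched set, re-match, repeat
    for _ in range(params.refine_iterations):
        R = _kabsch((hkl[sel] @ bmat.T), q[sel])
        counts1, rms1, matched1, hint1 = _score_rotations(
            R[None], binv, q, bmat, tol)
        sel = matched1[0]
        hkl = hint1[0].astype(int)
        if not sel.any():
            return None
    resid = (hkl[sel] @ (R @ bmat).T) - q[sel]
    rms_final = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    if sel.sum() < max(params.min_indexed_fraction * n, 3):
        return None
    return CrystalOrientation(rotation=R, cell=cell, hkl=hkl[sel].copy(),
                              matched=sel, rms_residual=rms_final)


def _min_node_spacing(cell: UnitCell) -> float:
    """Shortest reciprocal-basis vector length (Å⁻¹)."""
    return float(np.linalg.norm(cell.b_matrix(), axis=0).min())


def refine_cell(orientation: CrystalOrientation, qvecs: ScatteringVectorSet,
                constraint: str = "tetragonal") -> tuple[UnitCell, float]:
    """Least-squares cell update from the indexed peaks.

    ``tetragonal`` refines (a = b, c) with closed-form updates
    alternated with orientation Kabsch steps; ``triclinic`` fits the
    full 3×3 orientation+cell matrix A = Q Hᵀ (H Hᵀ)⁻¹ and extracts the
    cell from its metric.  Returns the refined cell and the rms
    q-residual (Å⁻¹).  Ill-conditioned systems keep the prior cell.
    """
    sel = orientation.matched
    hkl = orientation.hkl.astype(float)
    q = qvecs.q[sel]
    if len(hkl) < 6:
        return orientation.cell, math.inf
    if constraint == "triclinic":
        H = hkl.T  # (3, n)
        try:
            A = q.T @ H.T @ np.linalg.inv(H @ H.T)
        except np.linalg.LinAlgError:
            return orientation.cell, math.inf
        cell = UnitCell.from_b_matrix(A)
        resid = hkl @ A.T - q
        return cell, float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    if constraint != "tetragonal":
        raise ValueError("constraint must be 'tetragonal' or 'triclinic'")

    a, c = orientation.cell.a, orientation.cell.c
    R = orientation.rotation
    for _ in range(4):
        B = UnitCell.tetragonal(a, c).b_matrix()
        R = _kabsch(hkl @ B.T, q)
        qp = q @ R  # Rᵀ q, rows
        num_a = (hkl[:, 0] * qp[:, 0] + hkl[:, 1] * qp[:, 1]).sum()
        den_a = (hkl[:, 0] ** 2 + hkl[:, 1] ** 2).sum()
        num_c = (hkl[:, 2] * qp[:, 2]).sum()
        den_c = (hkl[:, 2] ** 2).sum()
        if den_a <= 0 or den_c <= 0 or num_a <= 0 or num_c <= 0:
            return orientation.cell, math.inf
        a = den_a / num_a
        c = den_c / num_c
    cell = UnitCell.tetragonal(float(a), float(c))
    resid = hkl @ (R @ cell.b_matrix()).T - q
    rms = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    orientation.rotation = R
    orientation.cell = cell
    return cell, rms
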