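"""Unit cells, tetragonal symmetry and reciprocal-space bookkeeping.

The toolkit targets serial crystallography of tetragonal lysozyme
(space group P4(3)2(1)2, Laue class 4/mmm), but the cell arithmetic is
written for a general triclinic cell so that user-supplied geometries
work too.  Symmetry support is deliberately narrow: the 4/mmm Laue
group is built by closure from its generators and the systematic
absences of the 4(3) screw axis and the 2(1) axes are hard-coded
reflection conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "UnitCell",
    "SymmetryInfo",
    "generate_hkl",
]


@dataclass(frozen=True)
class UnitCell:
    """Direct-space unit cell. Lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")

    @classmethod
    def tetragonal(cls, a: float, c: float) -> "UnitCell":
        return cls(a, a, c, 90.0, 90.0, 90.0)

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (general triclinic formula)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(arg, 0.0))

    def b_matrix(self) -> np.ndarray:
        """Reciprocal-basis matrix B (Å⁻¹): q = B @ (h,k,l) in Cartesian.

        Busing–Levy convention: a* along x, b* in the xy plane.
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume
        astar = self.b * self.c * math.sin(math.radians(self.alpha)) / v
        bstar = self.a * self.c * math.sin(math.radians(self.beta)) / v
        cstar = self.a * self.b * sg / v
        sa = math.sin(math.radians(self.alpha))
        sb = math.sin(math.radians(self.beta))
        cos_gs = (ca * cb - cg) / (sa * sb)
        cos_bs = (ca * cg - cb) / (sa * sg)
        sin_gs = math.sqrt(max(1.0 - cos_gs * cos_gs, 0.0))
        sin_bs = math.sqrt(max(1.0 - cos_bs * cos_bs, 0.0))
        # Busing & Levy B matrix: a* along x, b* in the xy plane.
        B = np.array(
            [
                [astar, bstar * cos_gs, cstar * cos_bs],
                [0.0, bstar * sin_gs, -cstar * sin_bs * ca],
                [0.0, 0.0, 1.0 / self.c],
            ]
        )
        return B

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of reflections ``hkl`` (shape (..., 3))."""
        hkl = np.asarray(hkl, dtype=float)
        q = hkl @ self.b_matrix().T
        qlen = np.linalg.norm(q, axis=-1)
        with np.errstate(divide="ignore"):
            return np.where(qlen > 0, 1.0 / qlen, np.inf)

    @classmethod
    def from_b_matrix(cls, B: np.ndarray) -> "UnitCell":
        """Recover cell parameters from a (possibly rotated) reciprocal basis."""
        gstar = B.T @ B
        g = np.linalg.inv(gstar)
        a, b, c = np.sqrt(np.diag(g))
        alpha = math.degrees(math.acos(np.clip(g[1, 2] / (b * c), -1, 1)))
        beta = math.degrees(math.acos(np.clip(g[0, 2] / (a * c), -1, 1)))
        gamma = math.degrees(math.acos(np.clip(g[0, 1] / (a * b), -1, 1)))
        return cls(float(a), float(b), float(c), alpha, beta, gamma)


def _closure(generators: list[np.ndarray]) -> list[np.ndarray]:
    """Group closure over integer 3×3 matrices."""
    seen = {}
    frontier = [np.eye(3, dtype=int)] + [g.astype(int) for g in generators]
    for m in frontier:
        seen[m.tobytes()] = m
    while frontier:
        nxt = []
        for m in frontier:
            for g in generators:
                p = m @ g
                key = p.tobytes()
                if key not in seen:
                    seen[key] = p
                    nxt.append(p)
        frontier = nxt
    return list(seen.values())


@lru_cache(maxsize=None)
def _laue_4mmm_ops() -> tuple[np.ndarray, ...]:
    r4z = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
    r2x = np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1]])
    inv = -np.eye(3, dtype=int)
    ops = _closure([r4z, r2x, inv])
    assert len(ops) == 16
    return tuple(ops)


@dataclass(frozen=True)
class SymmetryInfo:
    """Symmetry metadata for space group P4(3)2(1)2.

    Only the pieces needed for snapshot merging are carried: the Laue
    group (4/mmm, order 16, Friedel mates included) for asymmetric-unit
    mapping, and the screw-axis reflection conditions for systematic
    absences.
    """

    space_group: str = "P43212"
    point_group: str = "422"
    laue_group: str = "4/mmm"

    def laue_operations(self) -> np.ndarray:
        """All 16 integer matrices of 4/mmm acting on (h,k,l)."""
        return np.stack(_laue_4mmm_ops())

    def is_absent(self, hkl: np.ndarray) -> np.ndarray:
        """Systematic absences: 4(3) axis → (0,0,l) needs l ≡ 0 (mod 4);
        2(1) axes → (h,0,0) needs even h, (0,k,0) needs even k."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        h, k, l = hkl[..., 0], hkl[..., 1], hkl[..., 2]
        absent = np.zeros(h.shape, dtype=bool)
        absent |= (h == 0) & (k == 0) & (l % 4 != 0)
        absent |= (k == 0) & (l == 0) & (h % 2 != 0)
        absent |= (h == 0) & (l == 0) & (k % 2 != 0)
        return absent

    def map_to_asu(self, hkl: np.ndarray) -> np.ndarray:
        """Canonical asymmetric-unit representative under 4/mmm.

        The representative is the lexicographically largest (h,k,l)
        tuple among the 16 Laue mates; this choice is trivially
        idempotent and invariant under the group by construction.
        """
        hkl = np.asarray(hkl, dtype=int)
        single = hkl.ndim == 1
        hkl2 = np.atleast_2d(hkl)
        ops = self.laue_operations()  # (16, 3, 3)
        mates = np.einsum("oij,nj->noi", ops, hkl2)  # (n, 16, 3)
        # lexicographic max over mates via a scalar sort key
        m = int(np.abs(hkl2).max(initial=0)) + 1
        base = 2 * m + 1
        key = ((mates[..., 0] + m) * base + (mates[..., 1] + m)) * base + (mates[..., 2] + m)
        best = np.argmax(key, axis=1)
        out = mates[np.arange(len(hkl2)), best]
        return out[0] if single else out


def generate_hkl(cell: UnitCell, d_min: float, d_max: float = np.inf) -> np.ndarray:
    """All integer reflections (full sphere, excluding (0,0,0)) with
    d_min ≤ d ≤ d_max. Brute-force box enumeration."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    # conservative index bounds: |h| ≤ a/d_min etc. for any cell shape
    hmax = int(np.ceil(cell.a / d_min)) + 1
    kmax = int(np.ceil(cell.b / d_min)) + 1
    lmax = int(np.ceil(cell.c / d_min)) + 1
    h = np.arange(-hmax, hmax + 1)
    k = np.arange(-kmax, kmax + 1)
    l = np.arange(-lmax, lmax + 1)
    H, K, L = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    keep = (d >= d_min) & (d <= d_max)
    return hkl[keep]
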