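"""Synthetic still-diffraction frame generator with ground truth.

The simulator stands in for the beamline: it produces stacks of 2D
photon-count images that look statistically like snapshot diffraction
from microcrystals flowing through a capillary, together with a truth
sidecar recording every rendered spot.  Emulated features:

* crystal arrivals per frame ~ Poisson(µ) — blanks, singles, multiples;
* orientations uniform on SO(3) (quaternion sampling);
* true intensities Wilson-distributed (exponential, acentric model)
  with mean falloff exp(−B s²/2), B configurable;
* excitation-error partiality with a Gaussian rocking profile;
* exposure spread from the Poiseuille transit-time distribution across
  the focus, truncated to a configured range;
* flat + water-ring background, Poisson noise everywhere;
* occasional "rolling" crystals whose spots smear into constant-radius
  azimuthal arcs (~5°).

Not emulated (documented limitations): absorption, polarization,
detector point spread beyond the Gaussian PSF, pink-beam modes,
centric-reflection intensity statistics, inter-crystal shadowing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.special import erf

from .config import PipelineConfig, SimulationParams
from .crystal import SymmetryInfo, UnitCell
from .geometry import pixel_to_q
from .physics import BeamSpec, DetectorSpec
from .prediction import predict_still, reflection_table

__all__ = [
    "StructureFactorSet",
    "CrystalEvent",
    "FrameStack",
    "sample_structure_factors",
    "sample_crystal_events",
    "render_frame",
    "iter_simulated_frames",
    "simulate_dataset",
    "simulate_measurements",
    "background_lambda",
]

TRUTH_COLUMNS = ["frame", "event", "h", "k", "l", "fast", "slow",
                 "photons", "partiality"]


# ---------------------------------------------------------------------------
# structure factors

@dataclass
class StructureFactorSet:
    """True amplitudes |F| for the asymmetric unit, Wilson statistics.

    Intensities are sampled from the acentric Wilson distribution
    (exponential) with shell mean exp(−B s²/2); the overall scale is 1
    at s = 0, so downstream photon counts are set entirely by the
    simulator's ``spot_scale``.  Symmetry mates share one amplitude by
    construction (lookup maps through the ASU).
    """

    cell: UnitCell
    sym: SymmetryInfo
    d_min: float
    wilson_b: float
    hkl: np.ndarray            # (n, 3) ASU representatives
    amplitude: np.ndarray      # (n,)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {tuple(h): i for i, h in enumerate(map(tuple, self.hkl))}

    def intensity_lookup(self, hkl: np.ndarray) -> np.ndarray:
        """True intensities |F|² for arbitrary (possibly non-ASU) indices.
        Unknown reflections (beyond d_min or absent) get 0."""
        asu = self.sym.map_to_asu(np.atleast_2d(hkl))
        out = np.zeros(len(asu))
        for i, h in enumerate(map(tuple, asu)):
            j = self._index.get(h)
            if j is not None:
                out[i] = self.amplitude[j] ** 2
        return out


def sample_structure_factors(cell: UnitCell, sym: SymmetryInfo, d_min: float,
                             wilson_b: float, seed) -> StructureFactorSet:
    """Draw one consistent set of true amplitudes for all non-absent ASU
    reflections with d ≥ d_min."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    rng = np.random.default_rng(seed)
    full = reflection_table(cell, sym, d_min)
    asu = sym.map_to_asu(full)
    uniq = np.unique(asu, axis=0)
    s = 1.0 / cell.d_spacing(uniq)
    mean_i = np.exp(-wilson_b * s ** 2 / 2.0)
    intensity = rng.exponential(scale=mean_i)
    return StructureFactorSet(cell=cell, sym=sym, d_min=d_min, wilson_b=wilson_b,
                              hkl=uniq, amplitude=np.sqrt(intensity))


# ---------------------------------------------------------------------------
# crystal events

@dataclass(frozen=True)
class CrystalEvent:
    """One crystal transiting the beam during one frame."""

    orientation: np.ndarray   # (3, 3) rotation matrix
    transit_time_ms: float
    size_scale: float = 1.0
    arc_angle_deg: float = 0.0  # 0 = no rolling


def random_rotation(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    m = 1 if n is None else n
    quat = rng.normal(size=(m, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    w, x, y, z = quat.T
    R = np.empty((m, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R[0] if n is None else R


def _sample_transit_ms(rng: np.random.Generator, sim: SimulationParams,
                       n: int) -> np.ndarray:
    """Transit times from the flux-weighted Poiseuille profile.

    A crystal crosses the focus at v(r) = 2 v̄ (1 − (r/R)²); sampling r
    flux-weighted gives (r/R)² = 1 − sqrt(1−u).  Absolute velocities
    cancel: times are mapped onto the configured range, whose bounds
    already encode beam width and mean flow.
    """
    lo, hi = sim.transit_time_range_ms
    u = rng.uniform(size=n)
    vfrac = np.sqrt(1.0 - u)        # v(r) / v_centerline in (0, 1]
    t = 1.0 / np.clip(vfrac, 1e-6, None)  # in units of centerline transit
    return np.clip(t * lo, lo, hi)


def sample_crystal_events(config: PipelineConfig, n_frames: int, seed,
                          force_singles: bool = False) -> list[list[CrystalEvent]]:
    """Per-frame crystal events: Poisson(µ) arrivals (or exactly one per
    frame with ``force_singles``), i.i.d. uniform orientations."""
    sim = config.simulation
    if sim.mean_crystals_per_frame < 0:
        raise ValueError("mean crystals per frame must be non-negative")
    rng = np.random.default_rng(seed)
    if force_singles:
        counts = np.ones(n_frames, dtype=int)
    else:
        counts = rng.poisson(sim.mean_crystals_per_frame, size=n_frames)
    total = int(counts.sum())
    rots = random_rotation(rng, max(total, 1))
    transit = _sample_transit_ms(rng, sim, max(total, 1))
    size = rng.lognormal(mean=-sim.size_scale_sigma ** 2 / 2.0,
                         sigma=sim.size_scale_sigma, size=max(total, 1))
    rolling = rng.uniform(size=max(total, 1)) < sim.rolling_fraction
    events: list[list[CrystalEvent]] = []
    j = 0
    for c in counts:
        frame_events = []
        for _ in range(int(c)):
            frame_events.append(CrystalEvent(
                orientation=rots[j],
                transit_time_ms=float(transit[j]),
                size_scale=float(size[j]),
                arc_angle_deg=sim.arc_angle_deg if rolling[j] else 0.0,
            ))
            j += 1
        events.append(frame_events)
    return events


# ---------------------------------------------------------------------------
# rendering

@lru_cache(maxsize=4)
def _background_lambda_cached(det: DetectorSpec, beam: BeamSpec,
                              flat: float, amp: float, ring_d: float,
                              width: float) -> np.ndarray:
    slow, fast = np.mgrid[0:det.n_slow, 0:det.n_fast]
    s = np.linalg.norm(pixel_to_q(fast.astype(float), slow.astype(float), det, beam), axis=-1)
    lam = flat + amp * np.exp(-0.5 * ((s - 1.0 / ring_d) / width) ** 2)
    return lam.astype(np.float32)


def background_lambda(det: DetectorSpec, beam: BeamSpec,
                      sim: SimulationParams) -> np.ndarray:
    """Expected background photons per pixel: flat term plus a radially
    symmetric water ring (Gaussian in s = 1/d)."""
    return _background_lambda_cached(det, beam, sim.background_flat,
                                     sim.ring_amplitude, sim.ring_d,
                                     sim.ring_width_s)


def _gaussian_stamp(photons: float, fast: float, slow: float, sigma: float,
                    image: np.ndarray,
                    rng: np.random.Generator | None = None) -> float:
    """Add a pixel-integrated 2D Gaussian to ``image``.

    With ``rng`` the patch is Poisson-sampled per pixel (integer
    counts); without it the expected photons are added as floats.
    Returns the photons deposited (tails beyond the ±4σ stamp and the
    panel are lost; <0.1% for the default PSF)."""
    n_slow, n_fast = image.shape
    half = int(math.ceil(4 * sigma))
    f0, s0 = int(round(fast)), int(round(slow))
    flo, fhi = max(f0 - half, 0), min(f0 + half + 1, n_fast)
    slo, shi = max(s0 - half, 0), min(s0 + half + 1, n_slow)
    if flo >= fhi or slo >= shi:
        return 0.0
    fedges = np.arange(flo, fhi + 1) - 0.5
    sedges = np.arange(slo, shi + 1) - 0.5
    rt2s = math.sqrt(2.0) * sigma
    cf = 0.5 * np.diff(erf((fedges - fast) / rt2s))
    cs = 0.5 * np.diff(erf((sedges - slow) / rt2s))
    patch = photons * np.outer(cs, cf)
    if rng is not None:
        patch = rng.poisson(patch)
    image[slo:shi, flo:fhi] += patch
    return float(patch.sum())


def render_frame(events: list[CrystalEvent], sf: StructureFactorSet,
                 config: PipelineConfig, seed, frame_index: int = 0,
                 poisson: bool = True):
    """Render one frame: Poisson background plus Poisson-sampled spots.

    Spot photons = partiality × |F|² × spot_scale × (transit/reference)
    × size_scale, spread by a pixel-integrated Gaussian PSF or, for
    rolling crystals, smeared along a constant-radius arc.  Returns
    ``(image, truth)`` where truth is a DataFrame with one row per
    rendered spot (expected photons, pre-noise).  With ``poisson=False``
    the expected-value image is returned as floats — used to verify
    photon conservation exactly.
    """
    det, beam, sim = config.detector, config.beam, config.simulation
    rng = np.random.default_rng(seed)
    lam = background_lambda(det, beam, sim)
    if poisson:
        image = rng.poisson(lam).astype(np.float64)
        stamp_rng = rng
    else:
        image = lam.astype(np.float64)
        stamp_rng = None
    truth_rows: list[tuple] = []
    for ev_idx, ev in enumerate(events):
        pred = predict_still(ev.orientation, sf.cell, sf.sym, beam, det,
                             d_min=sim.d_min, mosaicity_deg=sim.mosaicity_deg,
                             cut_sigma=sim.partiality_cut_sigma)
        if len(pred) == 0:
            continue
        intensity = sf.intensity_lookup(pred.hkl)
        photons = (pred.partiality * intensity * sim.spot_scale
                   * (ev.transit_time_ms / sim.reference_transit_ms)
                   * ev.size_scale)
        for i in np.flatnonzero(pred.on_panel & (photons > 1e-3)):
            n_ph = float(photons[i])
            f, s = float(pred.fast[i]), float(pred.slow[i])
            if ev.arc_angle_deg > 0:
                _render_arc(image, n_ph, f, s, ev.arc_angle_deg, det,
                            sim.psf_sigma_px, stamp_rng)
            else:
                _gaussian_stamp(n_ph, f, s, sim.psf_sigma_px, image, stamp_rng)
            truth_rows.append((frame_index, ev_idx, *pred.hkl[i], f, s, n_ph,
                               float(pred.partiality[i])))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if poisson:
        np.clip(image, 0, sim.count_ceiling, out=image)
        return image.astype(np.uint32), truth
    return image, truth


def _render_arc(image: np.ndarray, photons: float, fast: float, slow: float,
                arc_deg: float, det: DetectorSpec, sigma: float,
                rng: np.random.Generator | None) -> None:
    """Smear a spot along a constant-radius arc about the beam center."""
    dx = (fast - det.beam_center_fast)
    dy = (slow - det.beam_center_slow)
    n_sub = max(3, int(round(arc_deg / 0.5)))
    for ang in np.linspace(-arc_deg / 2.0, arc_deg / 2.0, n_sub):
        a = math.radians(ang)
        ca, sa = math.cos(a), math.sin(a)
        f = det.beam_center_fast + ca * dx - sa * dy
        s = det.beam_center_slow + sa * dx + ca * dy
        _gaussian_stamp(photons / n_sub, f, s, sigma, image, rng)


# ---------------------------------------------------------------------------
# frame container

@dataclass
class FrameStack:
    """A stack of photon-count images plus geometry and optional truth.

    In memory the images are a (n, slow, fast) uint32 array; on disk the
    container is an HDF5 file with dataset ``data``, a JSON geometry
    descriptor in the ``geometry`` attribute, and the truth sidecar as a
    separate CSV with columns %s.
    """ % (TRUTH_COLUMNS,)

    images: np.ndarray
    detector: DetectorSpec
    beam: BeamSpec
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("images must be (n, slow, fast)")
        if self.images.shape[1:] != (self.detector.n_slow, self.detector.n_fast):
            raise ValueError("image dimensions do not match the detector")

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.images[i]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        geometry = {
            "detector": self.detector.__dict__,
            "beam": self.beam.__dict__,
            "conventions": "0-based pixels; fast=axis1, slow=axis0; mm from beam center",
        }
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.images, dtype="uint32",
                              chunks=(1,) + self.images.shape[1:], compression="gzip")
            fh.attrs["geometry"] = json.dumps(geometry)
        if self.truth is not None:
            self.truth.to_csv(path.with_suffix(".truth.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "FrameStack":
        path = Path(path)
        with h5py.File(path, "r") as fh:
            images = fh["data"][...]
            geometry = json.loads(fh.attrs["geometry"])
        truth_path = path.with_suffix(".truth.csv")
        truth = pd.read_csv(truth_path) if truth_path.exists() else None
        return cls(images=images,
                   detector=DetectorSpec(**geometry["detector"]),
                   beam=BeamSpec(**geometry["beam"]),
                   truth=truth)


def iter_simulated_frames(config: PipelineConfig, n_frames: int, seed,
                          force_singles: bool = False):
    """Generator of ``(index, image, truth, events)`` — the streaming
    core behind :func:`simulate_dataset`; deterministic given the seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + n_frames)
    sf = sample_structure_factors(config.cell, config.symmetry,
                                  config.simulation.d_min,
                                  config.simulation.wilson_b, children[0])
    events = sample_crystal_events(config, n_frames, children[1],
                                   force_singles=force_singles)
    for i in range(n_frames):
        image, truth = render_frame(events[i], sf, config, children[2 + i],
                                    frame_index=i)
        yield i, image, truth, events[i]


def simulate_dataset(config: PipelineConfig, n_frames: int, seed,
                     out: str | Path | None = None,
                     force_singles: bool = False,
                     max_memory_bytes: int = 2 << 30) -> FrameStack | Path:
    """Simulate a frame stack. Returns an in-memory :class:`FrameStack`,
    or writes to ``out`` (HDF5 + truth CSV) and returns the path when
    given.  Refuses in-memory stacks estimated above ``max_memory_bytes``."""
    det = config.detector
    nbytes = n_frames * det.n_fast * det.n_slow * 4
    if out is None and nbytes > max_memory_bytes:
        raise MemoryError(
            f"stack would need {nbytes/1e9:.1f} GB; pass out= to stream to disk")
    frames = []
    truths = []
    for _, image, truth, _ in iter_simulated_frames(config, n_frames, seed,
                                                    force_singles=force_singles):
        frames.append(image)
        truths.append(truth)
    truth_df = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(columns=TRUTH_COLUMNS)
    stack = FrameStack(images=np.stack(frames) if frames else
                       np.zeros((0, det.n_slow, det.n_fast), dtype=np.uint32),
                       detector=det, beam=config.beam, truth=truth_df)
    if out is not None:
        stack.save(out)
        return Path(out)
    return stack


# ---------------------------------------------------------------------------
# measurement-level simulation

def simulate_measurements(config: PipelineConfig, n_patterns: int, seed,
                          d_min: float | None = None) -> pd.DataFrame:
    """Measurement-level shortcut: per-pattern integrated reflection
    measurements without rendering or re-detecting images.

    For convergence and merging studies only the per-pattern measurement
    scatter matters, so this path predicts reflections per random
    orientation, draws Poisson counts for spot + integration-disc
    background, and subtracts an annulus background estimate — exactly
    the statistics the image pipeline would produce, at a tiny fraction
    of the cost.  Columns: pattern, h, k, l, I, sigma.
    """
    sim, integ = config.simulation, config.integration
    d_min = sim.d_min if d_min is None else d_min
    ss = np.random.SeedSequence(seed)
    sf_seed, ev_seed, ms_seed = ss.spawn(3)
    sf = sample_structure_factors(config.cell, config.symmetry, d_min,
                                  sim.wilson_b, sf_seed)
    rng = np.random.default_rng(ms_seed)
    ev_rng = np.random.default_rng(ev_seed)
    rots = random_rotation(ev_rng, n_patterns)
    transit = _sample_transit_ms(ev_rng, sim, n_patterns)
    size = ev_rng.lognormal(mean=-sim.size_scale_sigma ** 2 / 2.0,
                            sigma=sim.size_scale_sigma, size=n_patterns)
    # per-pixel background near the ring is flat + a fraction of the
    # ring amplitude; one representative level keeps this path cheap
    bg_px = sim.background_flat + 0.3 * sim.ring_amplitude
    n_disc, n_ann = 13, 208  # center-of-pixel counts for r=2 and 4..8
    rows = []
    for p in range(n_patterns):
        pred = predict_still(rots[p], config.cell, config.symmetry,
                             config.beam, config.detector, d_min=d_min,
                             mosaicity_deg=sim.mosaicity_deg,
                             cut_sigma=sim.partiality_cut_sigma)
        keep = pred.on_panel
        if not keep.any():
            continue
        hkl = pred.hkl[keep]
        intensity = sf.intensity_lookup(hkl)
        photons = (pred.partiality[keep] * intensity * sim.spot_scale
                   * (transit[p] / sim.reference_transit_ms) * size[p])
        disc = rng.poisson(photons + n_disc * bg_px)
        ann = rng.poisson(n_ann * bg_px)
        bg_est = ann / n_ann
        i_meas = disc - n_disc * bg_est
        sigma = np.sqrt(np.maximum(disc, 1.0) + n_disc ** 2 * bg_est / n_ann)
        for j in range(len(hkl)):
            rows.append((p, int(hkl[j, 0]), int(hkl[j, 1]), int(hkl[j, 2]),
                         float(i_meas[j]), float(sigma[j])))
    return pd.DataFrame(rows, columns=["pattern", "h", "k", "l", "I", "sigma"])
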