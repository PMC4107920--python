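"""Closed-form beamline and microfluidics arithmetic.

Everything a serial-crystallography experiment plan needs before a
single frame is collected: photon energy ↔ wavelength, capillary flow
(Poiseuille profile, Reynolds number, crystal transit time across the
focus), a simplified absorbed-dose estimate, detector-edge resolution,
crystal unit-cell counts and acquisition (frame budget / dead time /
sample consumption) arithmetic.

Public interfaces carry the units conventional at a beamline (eV, Å,
µm, mm, µl·min⁻¹, mm·s⁻¹, ms, MGy); conversion to SI happens inside
each function.

The dose model is a deliberate simplification of full radiation-damage
codes: a monochromatic beam, a thin sample, and the
mass energy-absorption approximation

    dose = fluence × E_photon × (µ_en/ρ)

with a caller-supplied µ_en/ρ defaulting to tabulated values for water
(log-log interpolated on a 5–20 keV grid).  Photoelectron escape and
solvent/heavy-atom composition are ignored; for micron-size crystals in
aqueous suspension near 10 keV this is accurate at the tens-of-percent
level, which matches how dose figures are quoted in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

HC_EV_ANGSTROM = 12398.42  # eV·Å
EV_TO_JOULE = 1.602176634e-19

# Mass energy-absorption coefficient of liquid water, µ_en/ρ in cm²/g,
# on a 5–20 keV grid (NIST-style tabulation; log-log interpolation).
_WATER_MU_EN_KEV = np.array([5.0, 6.0, 8.0, 10.0, 15.0, 20.0])
_WATER_MU_EN = np.array([41.9, 24.9, 9.92, 4.94, 1.37, 0.550])

__all__ = [
    "BeamSpec",
    "DetectorSpec",
    "CapillaryFlow",
    "FlowProfile",
    "DoseEstimate",
    "CrystalSpec",
    "AcquisitionBudget",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "water_mass_energy_absorption",
    "mean_flow_velocity",
    "poiseuille_velocity",
    "flow_profile",
    "transit_time",
    "reynolds_number",
    "estimate_dose",
    "edge_resolution",
    "unit_cell_count",
    "acquisition_budget",
    "rotational_diffusion_deg",
]


def energy_to_wavelength(photon_energy_ev: float) -> float:
    """Wavelength in Å for a photon energy in eV (λ = hc/E)."""
    if photon_energy_ev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_EV_ANGSTROM / photon_energy_ev


def wavelength_to_energy(wavelength_angstrom: float) -> float:
    """Photon energy in eV for a wavelength in Å."""
    if wavelength_angstrom <= 0:
        raise ValueError("wavelength must be positive")
    return HC_EV_ANGSTROM / wavelength_angstrom


def water_mass_energy_absorption(photon_energy_ev: float) -> float:
    """µ_en/ρ of water (cm²/g) at the given energy, 5–20 keV range."""
    kev = photon_energy_ev / 1000.0
    if not _WATER_MU_EN_KEV[0] <= kev <= _WATER_MU_EN_KEV[-1]:
        raise ValueError("water µ_en/ρ table covers 5–20 keV only")
    return float(
        np.exp(np.interp(np.log(kev), np.log(_WATER_MU_EN_KEV), np.log(_WATER_MU_EN)))
    )


@dataclass(frozen=True)
class BeamSpec:
    """Monochromatic X-ray beam at the sample position.

    Defaults describe a third-generation synchrotron microfocus
    beamline: 9.8 keV, 2×10¹² ph/s focused to 9 µm × 6 µm, 0.01%
    bandwidth and 1 mrad divergence.
    """

    photon_energy: float = 9800.0  # eV
    flux: float = 2.0e12  # photons/s
    focus_h: float = 9.0  # µm
    focus_v: float = 6.0  # µm
    bandwidth: float = 1.0e-4  # fractional ΔE/E
    divergence: float = 1.0e-3  # rad

    def __post_init__(self) -> None:
        if self.photon_energy <= 0 or self.flux <= 0:
            raise ValueError("photon energy and flux must be positive")
        if self.focus_h <= 0 or self.focus_v <= 0:
            raise ValueError("focus size must be positive")
        if not 0 < self.bandwidth < 0.1:
            raise ValueError("bandwidth must lie in (0, 0.1)")
        if not 0 < self.divergence < 0.1:
            raise ValueError("divergence must lie in (0, 0.1) rad")

    @property
    def wavelength(self) -> float:
        """Wavelength in Å."""
        return energy_to_wavelength(self.photon_energy)


@dataclass(frozen=True)
class DetectorSpec:
    """Flat pixel-array detector normal to the beam.

    Defaults are a Pilatus 6M-like panel (2463×2527 pixels of 172 µm)
    at 300 mm, beam centered.
    """

    n_fast: int = 2463
    n_slow: int = 2527
    pixel_size: float = 0.172  # mm
    distance: float = 300.0  # mm
    beam_center_fast: float = 1231.5  # pixels
    beam_center_slow: float = 1263.5  # pixels

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.pixel_size <= 0:
            raise ValueError("distance and pixel size must be positive")
        if not (0 <= self.beam_center_fast <= self.n_fast and 0 <= self.beam_center_slow <= self.n_slow):
            raise ValueError("beam center must lie inside the panel")


@dataclass(frozen=True)
class CapillaryFlow:
    """Pressure-driven flow of crystal suspension through a capillary."""

    inner_diameter: float = 100.0  # µm
    flow_rate: float = 2.5  # µl/min
    viscosity: float = 1.0  # mPa·s (water default; suspensions are higher)
    density: float = 1000.0  # kg/m³

    def __post_init__(self) -> None:
        for name in ("inner_diameter", "flow_rate", "viscosity", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def mean_flow_velocity(flow: CapillaryFlow) -> float:
    """Cross-section-averaged velocity in mm/s: Q / (π R²)."""
    q_m3_s = flow.flow_rate * 1e-9 / 60.0
    r_m = flow.inner_diameter * 1e-6 / 2.0
    v_m_s = q_m3_s / (math.pi * r_m * r_m)
    return v_m_s * 1e3


def poiseuille_velocity(flow: CapillaryFlow, r_um: float) -> float:
    """Laminar (parabolic) velocity at radial offset r (µm), in mm/s.

    v(r) = 2 v_mean (1 − (r/R)²); no-slip at the wall.
    """
    radius = flow.inner_diameter / 2.0
    if not 0.0 <= r_um <= radius:
        raise ValueError("radial offset must lie in [0, inner radius]")
    return 2.0 * mean_flow_velocity(flow) * (1.0 - (r_um / radius) ** 2)


@dataclass(frozen=True)
class FlowProfile:
    """Derived laminar-flow summary for a capillary."""

    flow: CapillaryFlow
    mean_velocity: float  # mm/s
    centerline_velocity: float  # mm/s
    reynolds: float

    def velocity_at(self, r_um: float) -> float:
        return poiseuille_velocity(self.flow, r_um)


def reynolds_number(flow: CapillaryFlow) -> float:
    """Re = ρ v_mean D / µ (dimensionless)."""
    v_m_s = mean_flow_velocity(flow) * 1e-3
    d_m = flow.inner_diameter * 1e-6
    mu_pa_s = flow.viscosity * 1e-3
    return flow.density * v_m_s * d_m / mu_pa_s


def flow_profile(flow: CapillaryFlow) -> FlowProfile:
    v = mean_flow_velocity(flow)
    return FlowProfile(flow=flow, mean_velocity=v, centerline_velocity=2.0 * v,
                       reynolds=reynolds_number(flow))


def transit_time(beam: BeamSpec, velocity_mm_s: float) -> float:
    """Time (ms) for a crystal moving at ``velocity_mm_s`` to cross the
    horizontal focus."""
    if velocity_mm_s <= 0:
        raise ValueError("velocity must be positive")
    return beam.focus_h / velocity_mm_s  # µm / (mm/s) = ms


@dataclass(frozen=True)
class DoseEstimate:
    """Absorbed dose from the thin-sample mass-energy-absorption model."""

    exposure_time: float  # s
    fluence: float  # photons/cm²
    energy_fluence: float  # J/cm²
    mass_energy_absorption: float  # cm²/g
    dose: float  # MGy


def estimate_dose(beam: BeamSpec, exposure_time: float,
                  mass_energy_absorption: float | None = None) -> DoseEstimate:
    """Absorbed dose for a crystal sitting in the focus for ``exposure_time`` s.

    fluence = flux·t / focus area; dose = fluence · E_photon · µ_en/ρ.
    1 MGy = 10³ J/g. µ_en/ρ defaults to the tabulated water value at the
    beam energy. Exactly linear in exposure time.
    """
    if exposure_time < 0:
        raise ValueError("exposure time must be non-negative")
    if mass_energy_absorption is None:
        mass_energy_absorption = water_mass_energy_absorption(beam.photon_energy)
    if mass_energy_absorption <= 0:
        raise ValueError("µ_en/ρ must be positive")
    area_cm2 = beam.focus_h * 1e-4 * beam.focus_v * 1e-4
    fluence = beam.flux * exposure_time / area_cm2
    energy_fluence = fluence * beam.photon_energy * EV_TO_JOULE
    dose_j_g = energy_fluence * mass_energy_absorption
    return DoseEstimate(
        exposure_time=exposure_time,
        fluence=fluence,
        energy_fluence=energy_fluence,
        mass_energy_absorption=mass_energy_absorption,
        dose=dose_j_g / 1e3,
    )


def edge_resolution(det: DetectorSpec, beam: BeamSpec, corner: bool = False) -> float:
    """Resolution d (Å) at the detector edge closest to the beam center
    (or at the farthest corner with ``corner=True``): d = λ / (2 sin θ),
    2θ = atan(s / distance)."""
    dist_f = [det.beam_center_fast, det.n_fast - det.beam_center_fast]
    dist_s = [det.beam_center_slow, det.n_slow - det.beam_center_slow]
    if corner:
        s_px = math.hypot(max(dist_f), max(dist_s))
    else:
        s_px = min(min(dist_f), min(dist_s))
    s_mm = s_px * det.pixel_size
    two_theta = math.atan2(s_mm, det.distance)
    return beam.wavelength / (2.0 * math.sin(two_theta / 2.0))


@dataclass(frozen=True)
class CrystalSpec:
    """Microcrystal morphology and contents."""

    cell_volume: float  # Å³ (unit-cell volume)
    volume: float = 135.0  # µm³ (crystal volume)
    edge_length: float = 3.0  # µm
    long_axis: float = 6.0  # µm
    space_group: str = "P43212"

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.cell_volume <= 0:
            raise ValueError("volumes must be positive")

    @property
    def n_unit_cells(self) -> float:
        return unit_cell_count(self)


def unit_cell_count(crystal: CrystalSpec) -> float:
    """Number of unit cells in the crystal: V_crystal / V_cell
    (1 µm³ = 10¹² Å³)."""
    return crystal.volume * 1e12 / crystal.cell_volume


@dataclass(frozen=True)
class AcquisitionBudget:
    """Frame-budget arithmetic for a fixed-rate acquisition."""

    frame_rate: float  # Hz
    exposure_time_per_frame: float  # s
    n_frames: int
    total_time: float  # s
    dead_time_fraction: float
    consumed_volume: float  # µl


def acquisition_budget(frame_rate: float, exposure: float, n_frames: int,
                       flow: CapillaryFlow) -> AcquisitionBudget:
    """Total time, detector dead-time fraction and sample consumption
    for ``n_frames`` at ``frame_rate`` Hz with per-frame exposure
    ``exposure`` s."""
    if frame_rate <= 0 or exposure <= 0:
        raise ValueError("frame rate and exposure must be positive")
    if frame_rate * exposure > 1.0 + 1e-12:
        raise ValueError("exposure longer than the frame period")
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    total_time = n_frames / frame_rate
    return AcquisitionBudget(
        frame_rate=frame_rate,
        exposure_time_per_frame=exposure,
        n_frames=n_frames,
        total_time=total_time,
        dead_time_fraction=1.0 - exposure * frame_rate,
        consumed_volume=flow.flow_rate * total_time / 60.0,
    )


def rotational_diffusion_deg(viscosity_mpa_s: float, radius_um: float,
                             time_s: float, temperature_k: float = 293.0) -> float:
    """Order-of-magnitude RMS Brownian rotation (degrees) in ``time_s``.

    D_r = kT / (8 π µ r³); rms angle ≈ sqrt(2 D_r t). A helper for
    judging whether tumbling blurs stills; not a quantitative model.
    """
    kb = 1.380649e-23
    mu = viscosity_mpa_s * 1e-3
    r = radius_um * 1e-6
    d_r = kb * temperature_k / (8.0 * math.pi * mu * r ** 3)
    return math.degrees(math.sqrt(2.0 * d_r * time_s))
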