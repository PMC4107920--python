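"""Experiment and pipeline configuration.

Every default that the experiment defines is encoded here once: 9800 eV
beam, 300 mm Pilatus-6M-like detector, 100 µm capillary at 2.5 µl/min,
tetragonal lysozyme cell 79.5 × 79.4 × 38.4 Å in P4(3)2(1)2, 25-photon
peak threshold, 15/200 hit bounds, 2/4/8-pixel integration radii.
Configs round-trip through YAML for the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .crystal import UnitCell, SymmetryInfo
from .physics import BeamSpec, CapillaryFlow, CrystalSpec, DetectorSpec

__all__ = [
    "SimulationParams",
    "PeakFindParams",
    "IndexingParams",
    "IntegrationParams",
    "MergeParams",
    "PipelineConfig",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic frame generator.

    The generator emulates the flowing-microcrystal experiment:
    Poisson crystal arrivals per frame, orientations uniform on SO(3),
    Wilson-distributed intensities with an overall B factor,
    transit-time exposure spread from the laminar flow profile, a
    flat + water-ring background, and occasional azimuthal "rolling"
    arc smear of ~5°.
    """

    wilson_b: float = 44.1          # Å²; overall intensity falloff
    d_min: float = 2.0              # Å; generation limit
    mosaicity_deg: float = 0.05     # effective rocking width term
    mean_crystals_per_frame: float = 0.3
    spot_scale: float = 4000.0      # expected photons of an average
                                    # low-resolution full reflection at
                                    # the reference transit time
    transit_time_range_ms: tuple[float, float] = (1.0, 3.0)
    reference_transit_ms: float = 3.0
    rolling_fraction: float = 0.1   # crystals showing arc smear
    arc_angle_deg: float = 5.0
    psf_sigma_px: float = 1.0
    background_flat: float = 0.5    # photons/pixel
    ring_amplitude: float = 2.5     # photons/pixel at ring peak
    ring_d: float = 3.5             # Å; water-ring pseudo-resolution
    ring_width_s: float = 0.02      # Å⁻¹; Gaussian width in s = 1/d
    partiality_cut_sigma: float = 3.0
    size_scale_sigma: float = 0.3   # lognormal spread of crystal volumes
    count_ceiling: int = 1 << 20    # detector counter saturation


@dataclass(frozen=True)
class PeakFindParams:
    threshold: float = 25.0     # photon counts above local background
    k_sigma: float = 3.0        # region-growing level in background sigmas
    window_radius: int = 8      # px; local-background annulus outer radius
    region_radius: int = 4      # px; max growth radius around a maximum
    border: int = 2             # px; exclusion band at panel edges
    min_peaks: int = 15         # classification bounds, strict inequalities
    max_peaks: int = 200


@dataclass(frozen=True)
class IndexingParams:
    min_peaks: int = 16
    min_indexed_fraction: float = 0.5
    n_seed_peaks: int = 10        # lowest-|q| peaks used for pair matching
    length_tolerance: float = 2.5e-3   # Å⁻¹ on |q| for candidate nodes
    cos_angle_tolerance: float = 6.0e-3
    q_tolerance_factor: float = 0.8    # × minimum node half-spacing
    d_min_candidates: float = 3.0      # Å; node table for seed matching
    refine_iterations: int = 3


@dataclass(frozen=True)
class IntegrationParams:
    r_disc: float = 2.0
    r_bg_inner: float = 4.0
    r_bg_outer: float = 8.0
    d_min: float = 2.0           # integrate to the detector edge region
    background_statistic: str = "mean"   # or "median"; the median of a
    # low-count Poisson annulus is integer-quantized and biased low,
    # which swamps few-photon high-resolution reflections
    mosaicity_deg: float = 0.05  # prediction window term, matches simulator


@dataclass(frozen=True)
class MergeParams:
    n_shells: int = 10
    d_min: float = 2.09
    d_max: float = 39.65
    shell_scheme: str = "equal_volume"  # or "equal_count"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the simulator and the processing chain need."""

    beam: BeamSpec = field(default_factory=BeamSpec)
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    flow: CapillaryFlow = field(default_factory=CapillaryFlow)
    cell: UnitCell = field(default_factory=lambda: UnitCell(79.5, 79.4, 38.4))
    symmetry: SymmetryInfo = field(default_factory=SymmetryInfo)
    crystal_volume: float = 135.0  # µm³
    simulation: SimulationParams = field(default_factory=SimulationParams)
    peakfind: PeakFindParams = field(default_factory=PeakFindParams)
    indexing: IndexingParams = field(default_factory=IndexingParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    merge: MergeParams = field(default_factory=MergeParams)
    seed: int = 0

    @property
    def crystal(self) -> CrystalSpec:
        return CrystalSpec(cell_volume=self.cell.volume, volume=self.crystal_volume,
                           space_group=self.symmetry.space_group)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTION_TYPES = {
    "beam": BeamSpec,
    "detector": DetectorSpec,
    "flow": CapillaryFlow,
    "cell": UnitCell,
    "symmetry": SymmetryInfo,
    "simulation": SimulationParams,
    "peakfind": PeakFindParams,
    "indexing": IndexingParams,
    "integration": IntegrationParams,
    "merge": MergeParams,
}


def _build_section(cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a plain mapping
    (as loaded from YAML).  Unknown sections or keys raise ValueError."""
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value or {})
        elif key in ("crystal_volume", "seed"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config section: {key}")
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; ``None`` or an empty file give the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
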