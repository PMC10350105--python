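"""Experiment configuration: versioned YAML schema with strict validation.

Unknown keys are rejected; every stochastic stage has an explicit seed; the
config hash (SHA-256 of the canonical JSON) is stamped into every artifact
so outputs are traceable to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AtomConfig(_Strict):
    element: str
    frac_coords: tuple[float, float, float]
    b_factor: float = Field(2.0, ge=0)
    occupancy: float = Field(1.0, ge=0, le=1)
    anomalous: bool = False


class CrystalConfig(_Strict):
    cell: tuple[float, float, float, float, float, float] = (9.0, 10.0, 11.0, 90.0, 90.0, 90.0)
    atoms: Optional[list[AtomConfig]] = None  # None -> bundled default toy
    pdb_path: Optional[str] = None
    anomalous_elements: tuple[str, ...] = ("Mn",)


class SpectrumConfig(_Strict):
    center_ev: float = 6550.0
    fwhm_ev: float = Field(30.0, gt=0)
    n_channels: int = Field(30, ge=1)
    span_ev: float = Field(90.0, gt=0)


class DetectorConfig(_Strict):
    distance_mm: float = Field(150.0, gt=0)
    pixel_size_mm: float = Field(0.5, gt=0)
    n_fast: int = Field(1024, ge=16)
    n_slow: int = Field(1024, ge=16)
    beam_center: Optional[tuple[float, float]] = None  # default: panel center


class MosaicConfig(_Strict):
    n_domains: int = Field(20, ge=1)
    angular_spread_mrad: float = Field(0.5, ge=0)
    domain_cells: tuple[int, int, int] = (20, 20, 20)
    normalize_domains: bool = True


class ModelErrorConfig(_Strict):
    kind: Literal["pixel_gain_field", "mosaic_misspecification", "background_gradient"]
    magnitude: float = 0.1


class SimulationConfig(_Strict):
    n_shots: int = Field(200, ge=0)
    seed: int = 0
    edge_shift_ev: float = 2.0
    background_rate: float = Field(2.0, ge=0)
    flux: float = Field(0.016, gt=0)
    box_size: int = Field(9, ge=3)
    noise: bool = True
    scale_sigma: float = Field(0.3, ge=0)
    cell_jitter: float = Field(1e-3, ge=0)
    scale_est_sigma: float = Field(0.05, ge=0)
    orientation_est_mrad: float = Field(0.5, ge=0)
    max_shoeboxes_per_shot: int = Field(12, ge=1)
    d_min: float = Field(2.0, gt=0)
    model_error: Optional[ModelErrorConfig] = None


class FitConfig(_Strict):
    max_iter: int = Field(2000, ge=1)
    gtol: float = 1e-6
    ftol: float = 1e-9
    interval_method: Optional[Literal["profile", "bootstrap"]] = "profile"
    interval_level: float = Field(0.9, gt=0, lt=1)
    seed: int = 0


class PvaeConfig(_Strict):
    correction: bool = True
    deviation_penalty_weight: float = Field(1.0, ge=0)
    n_epochs: int = Field(150, ge=1)
    lr: float = Field(0.02, gt=0)
    hidden: int = Field(48, ge=1)
    corr_hidden: int = Field(16, ge=1)
    val_fraction: float = Field(0.1, gt=0, lt=1)
    patience: int = Field(30, ge=1)
    seed: int = 0
    n_posterior_samples: int = Field(1000, ge=0)


class ExperimentConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    crystal: CrystalConfig = CrystalConfig()
    spectrum: SpectrumConfig = SpectrumConfig()
    detector: DetectorConfig = DetectorConfig()
    mosaic: MosaicConfig = MosaicConfig()
    simulation: SimulationConfig = SimulationConfig()
    fit: FitConfig = FitConfig()
    pvae: PvaeConfig = PvaeConfig()
    output_dir: str = "spread_run"

    @model_validator(mode="after")
    def _check_version(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        return self

    def content_hash(self) -> str:
        """Hash of the scientific content; output paths are excluded so the
        same experiment written to two directories shares one hash."""
        payload = self.model_dump(mode="json")
        payload.pop("output_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML config; unknown keys are reported by path."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(raw)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


# --------------------------------------------------------------------------
# construction of model objects from config


def build_objects(config: ExperimentConfig):
    """Instantiate (crystal, detector, mosaic, spectrum) from a config."""
    from .scattering import AtomSite, CrystalModel, UnitCell, synthetic_mn_curve
    from .simulator import Detector, MosaicModel, Spectrum, default_crystal

    sp = config.spectrum
    spectrum = Spectrum.gaussian(sp.center_ev, sp.fwhm_ev, sp.n_channels, sp.span_ev)
    d = config.detector
    detector = Detector(
        distance_mm=d.distance_mm,
        pixel_size_mm=d.pixel_size_mm,
        n_fast=d.n_fast,
        n_slow=d.n_slow,
        beam_center=d.beam_center or (d.n_fast / 2.0, d.n_slow / 2.0),
    )
    m = config.mosaic
    mosaic = MosaicModel(
        n_domains=m.n_domains,
        angular_spread_mrad=m.angular_spread_mrad,
        domain_cells=m.domain_cells,
        normalize_domains=m.normalize_domains,
    )
    c = config.crystal
    curve = synthetic_mn_curve()
    if c.pdb_path is not None:
        from .io import read_crystal_from_pdb

        crystal = read_crystal_from_pdb(c.pdb_path, c.anomalous_elements, curve)
    elif c.atoms is not None:
        cell = UnitCell(*c.cell)
        atoms = tuple(
            AtomSite(
                element=a.element,
                frac_coords=a.frac_coords,
                b_factor=a.b_factor,
                occupancy=a.occupancy,
                anomalous_curve=curve if a.anomalous else None,
            )
            for a in c.atoms
        )
        crystal = CrystalModel(cell=cell, atoms=atoms)
    else:
        crystal = default_crystal(curve)
    return crystal, detector, mosaic, spectrum
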