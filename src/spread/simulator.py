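"""Toy nanoBragg-style forward model for serial femtosecond crystallography.

Renders per-spot "shoeboxes" (small pixel neighbourhoods around predicted
diffraction spots) for still shots of a P1 toy crystal: the expected count
in each pixel is a sum over the polychromatic spectrum and over explicit
mosaic domains of |F_h(E)|^2 times a Gaussian lattice-interference profile,
scaled by a per-shot factor and the pixel solid angle, plus background,
with optional Poisson noise.  Doubles as the fixture generator for the
inference modules: every dataset comes with a ground-truth sidecar that the
inference code never reads.

Geometry conventions: beam along +z, |k| = 1/lambda (A^-1, crystallographic
convention), single flat detector panel perpendicular to the beam at
``distance`` mm, fast axis along lab x, pixel centers at half-integer
offsets, reciprocal vectors q = U B h with B from the cell (|q| = 1/d).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .scattering import (
    HC_EV_ANGSTROM,
    AnomalousCurve,
    CrystalModel,
    UnitCell,
    anomalous_decomposition,
)

__all__ = [
    "Spectrum",
    "MosaicModel",
    "Detector",
    "Shoebox",
    "StillShot",
    "GroundTruth",
    "SimulatedDataset",
    "ModelError",
    "PredictionError",
    "random_orientation",
    "small_random_rotation",
    "predict_reflections",
    "lattice_profile",
    "lattice_profile_sigma",
    "simulate_shoebox",
    "simulate_dataset",
    "inject_model_error",
    "expected_counts",
    "default_crystal",
]


class PredictionError(ValueError):
    pass


# Incident-flux normalization: with the default toy crystal, detector and
# mosaic model this puts the median integrated spot at a few thousand
# photons above background, a typical well-exposed SFX spot.
DEFAULT_FLUX = 0.016


# --------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class Spectrum:
    """Discrete incident spectrum: energies in eV with normalized weights."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)
        if e.shape != w.shape or e.ndim != 1 or e.size == 0:
            raise ValueError("energies and weights must be matching 1-D arrays")
        if np.any(w < 0):
            raise ValueError("spectrum weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum weights must sum to 1 (within 1e-9)")

    @classmethod
    def gaussian(
        cls,
        center_ev: float = 6550.0,
        fwhm_ev: float = 30.0,
        n_channels: int = 30,
        span_ev: float = 90.0,
    ) -> "Spectrum":
        e = np.linspace(center_ev - span_ev / 2, center_ev + span_ev / 2, n_channels)
        sigma = fwhm_ev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        w = np.exp(-0.5 * ((e - center_ev) / sigma) ** 2)
        return cls(energies=e, weights=w / w.sum())

    @property
    def central_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))

    @property
    def sigma_ev(self) -> float:
        c = self.central_energy
        return float(np.sqrt(np.sum(self.weights * (self.energies - c) ** 2)))


@dataclass(frozen=True)
class MosaicModel:
    """Mosaic-domain description: count, misorientation spread, domain size.

    ``normalize_domains`` keeps the expected intensity invariant under the
    number of domains (incoherent mean rather than raw sum).
    """

    n_domains: int = 20
    angular_spread_mrad: float = 0.5
    domain_cells: tuple[int, int, int] = (20, 20, 20)
    normalize_domains: bool = True

    def __post_init__(self):
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.angular_spread_mrad < 0:
            raise ValueError("angular_spread must be >= 0")
        if any(n < 1 for n in self.domain_cells):
            raise ValueError("domain_cells must each be >= 1")


@dataclass(frozen=True)
class Detector:
    """Single flat panel perpendicular to the beam."""

    distance_mm: float = 150.0
    pixel_size_mm: float = 0.5
    n_fast: int = 1024
    n_slow: int = 1024
    beam_center: tuple[float, float] = (512.0, 512.0)

    def __post_init__(self):
        if self.distance_mm <= 0 or self.pixel_size_mm <= 0:
            raise ValueError("distance and pixel size must be positive")
        cf, cs = self.beam_center
        if not (0 <= cf < self.n_fast and 0 <= cs < self.n_slow):
            raise ValueError("beam center must lie inside the panel")

    def pixel_lab_position(self, fast, slow) -> np.ndarray:
        """Lab coordinates (mm) of pixel centers; beam along +z."""
        f = np.asarray(fast, dtype=float)
        s = np.asarray(slow, dtype=float)
        x = (f + 0.5 - self.beam_center[0]) * self.pixel_size_mm
        y = (s + 0.5 - self.beam_center[1]) * self.pixel_size_mm
        z = np.broadcast_to(self.distance_mm, np.broadcast_shapes(f.shape, s.shape))
        return np.stack(np.broadcast_arrays(x, y, z), axis=-1)

    def lab_to_pixel(self, xy) -> tuple[np.ndarray, np.ndarray]:
        xy = np.asarray(xy, dtype=float)
        f = xy[..., 0] / self.pixel_size_mm + self.beam_center[0] - 0.5
        s = xy[..., 1] / self.pixel_size_mm + self.beam_center[1] - 0.5
        return f, s

    def solid_angle(self, fast, slow) -> np.ndarray:
        """Per-pixel geometric factor: area * cos(obliquity) / r^2 (sr)."""
        pos = self.pixel_lab_position(fast, slow)
        r = np.linalg.norm(pos, axis=-1)
        return self.pixel_size_mm**2 * self.distance_mm / r**3


@dataclass
class Shoebox:
    """Pixel-count grid around one predicted spot, plus DIALS-like metadata."""

    bbox: tuple[int, int, int, int]  # (fast_min, fast_max, slow_min, slow_max), half-open
    counts: np.ndarray  # shape (fast_max-fast_min, slow_max-slow_min)
    hkl: tuple[int, int, int]
    metadata: dict

    def __post_init__(self):
        fmin, fmax, smin, smax = self.bbox
        if fmax <= fmin or smax <= smin:
            raise ValueError("bbox must have positive area")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (fmax - fmin, smax - smin):
            raise ValueError("counts shape does not match bbox")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def center_pixel(self) -> tuple[float, float]:
        fmin, fmax, smin, smax = self.bbox
        return ((fmin + fmax) / 2.0, (smin + smax) / 2.0)

    def perimeter_mean(self) -> float:
        """Mean count on the bbox border; standard local background estimate."""
        c = self.counts
        if min(c.shape) <= 2:
            return float(c.mean())
        border = np.concatenate([c[0, :], c[-1, :], c[1:-1, 0], c[1:-1, -1]])
        return float(border.mean())


@dataclass
class StillShot:
    """One SFX exposure.  ``orientation``/``scale`` are simulation truth;
    the DIALS-like estimates live in ``metadata`` and in each shoebox."""

    shot_id: int
    orientation: np.ndarray  # true U, 3x3
    scale: float  # true g
    cell: UnitCell
    shoeboxes: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        u = np.asarray(self.orientation, dtype=float)
        if u.shape != (3, 3) or np.max(np.abs(u.T @ u - np.eye(3))) > 1e-9 or np.linalg.det(u) < 0:
            raise ValueError("orientation must be a proper rotation (to 1e-9)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.orientation = u


@dataclass
class GroundTruth:
    """Sidecar record of everything inference is not allowed to see."""

    edge_shift_ev: float
    scales: np.ndarray
    orientations: np.ndarray
    cells: list
    model_error: Optional["ModelError"]
    seed: int
    domain_rotations: list = field(default_factory=list)


@dataclass
class SimulatedDataset:
    """Container the inference stages consume (plus simulation truth inside
    each shot; the HDF5 writer separates estimates from the truth sidecar)."""

    shots: list
    spectrum: Spectrum
    crystal: CrystalModel  # nominal crystal with the *unshifted* reference curve
    detector: Detector
    mosaic: MosaicModel

    @property
    def n_shoeboxes(self) -> int:
        return sum(len(s.shoeboxes) for s in self.shots)


@dataclass(frozen=True)
class ModelError:
    """A deliberate deviation of the data-generating process from the
    nominal forward model that inference assumes."""

    kind: str
    magnitude: float
    params: dict = field(default_factory=dict)

    KINDS = ("pixel_gain_field", "mosaic_misspecification", "background_gradient")


def inject_model_error(kind: str, magnitude: float, rng: np.random.Generator) -> ModelError:
    """Realize a model error of the given kind and magnitude.

    pixel_gain_field: smooth multiplicative per-pixel gain in
    [1-magnitude, 1+magnitude] (product of two low-frequency sinusoids with
    random phases).  mosaic_misspecification: data generated with the
    mosaic angular spread inflated by (1+magnitude).  background_gradient:
    background replaced by a linear ramp along the fast axis with relative
    slope ``magnitude`` across the panel.
    """
    if kind not in ModelError.KINDS:
        raise ValueError(f"unknown model error {kind!r}; options: {ModelError.KINDS}")
    params = {}
    if kind == "pixel_gain_field":
        params = {
            "phase_fast": float(rng.uniform(0, 2 * np.pi)),
            "phase_slow": float(rng.uniform(0, 2 * np.pi)),
            "k_fast": 2.0,
            "k_slow": 2.0,
        }
    return ModelError(kind=kind, magnitude=float(magnitude), params=params)


def gain_field(err: ModelError, detector: Detector, fast, slow) -> np.ndarray:
    """Evaluate the multiplicative gain field of a pixel_gain_field error."""
    f = np.asarray(fast, dtype=float)
    s = np.asarray(slow, dtype=float)
    p = err.params
    return 1.0 + err.magnitude * np.sin(
        2 * np.pi * p["k_fast"] * f / detector.n_fast + p["phase_fast"]
    ) * np.sin(2 * np.pi * p["k_slow"] * s / detector.n_slow + p["phase_slow"])


# --------------------------------------------------------------------------
# orientations


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation via a normalized Gaussian quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def small_random_rotation(rng: np.random.Generator, angle_std_rad: float) -> np.ndarray:
    """Rotation with uniform axis and N(0, angle_std) angle (radians)."""
    if angle_std_rad == 0:
        return np.eye(3)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, angle_std_rad)
    return Rotation.from_rotvec(angle * axis).as_matrix()


# --------------------------------------------------------------------------
# lattice profile


def lattice_profile_sigma(domain_cells: Sequence[int], cell: UnitCell) -> float:
    """Reciprocal-space width (A^-1) of the Gaussian domain-size profile.

    sigma = 1 / (sqrt(2 pi) * Nbar * abar) with Nbar*abar the geometric mean
    of the domain edge lengths; matches the central-lobe integral of the 1-D
    Laue interference function at the preserved peak value.
    """
    na, nb, nc = domain_cells
    edge = (na * cell.a * nb * cell.b * nc * cell.c) ** (1.0 / 3.0)
    return 1.0 / (np.sqrt(2.0 * np.pi) * edge)


def lattice_profile(offset, domain_cells: Sequence[int], cell: UnitCell) -> np.ndarray:
    """Isotropic Gaussian approximation to the Laue interference function.

    Peak value (Na*Nb*Nc)^2 at zero offset from the Bragg condition,
    characteristic width 1/(N*a) in reciprocal space.
    """
    off = np.asarray(offset, dtype=float)
    if np.any(off < 0):
        raise ValueError("offset must be nonnegative")
    na, nb, nc = domain_cells
    sigma = lattice_profile_sigma(domain_cells, cell)
    return float(na * nb * nc) ** 2 * np.exp(-0.5 * (off / sigma) ** 2)


# --------------------------------------------------------------------------
# reflection prediction


def _beam_wavevector(energy_ev: float) -> np.ndarray:
    return np.array([0.0, 0.0, energy_ev / HC_EV_ANGSTROM])


def predict_reflections(
    shot: StillShot,
    crystal: CrystalModel,
    detector: Detector,
    mosaic: MosaicModel,
    spectrum: Spectrum,
    d_min: float = 2.0,
    shell_sigmas: float = 3.0,
    margin_px: int = 5,
):
    """Miller indices near the Ewald sphere whose rays hit the panel.

    The acceptance shell around the monochromatic Bragg condition combines
    the spectral bandwidth (2 sigma_E), the mosaic angular spread and the
    domain-size broadening (``shell_sigmas`` profile widths).  Returns
    ``[(hkl, (fast, slow)), ...]`` with predicted impact positions in pixels.
    """
    cell = shot.cell
    A = shot.orientation @ cell.reciprocal_matrix
    q_max = 1.0 / d_min
    hmax = np.ceil(q_max * np.array([cell.a, cell.b, cell.c])).astype(int)
    h, k, l = np.meshgrid(
        np.arange(-hmax[0], hmax[0] + 1),
        np.arange(-hmax[1], hmax[1] + 1),
        np.arange(-hmax[2], hmax[2] + 1),
        indexing="ij",
    )
    H = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    H = H[np.any(H != 0, axis=1)]
    q = H @ A.T
    qn = np.linalg.norm(q, axis=1)
    in_res = qn <= q_max
    H, q, qn = H[in_res], q[in_res], qn[in_res]

    e0 = spectrum.central_energy
    k0 = e0 / HC_EV_ANGSTROM
    kin = _beam_wavevector(e0)
    kout = q + kin
    excess = np.abs(np.linalg.norm(kout, axis=1) - k0)
    sigma_rl = lattice_profile_sigma(mosaic.domain_cells, cell)
    bw = 2.0 * spectrum.sigma_ev / e0
    shell = qn * bw + qn * mosaic.angular_spread_mrad * 1e-3 + shell_sigmas * sigma_rl
    near = excess <= shell
    H, kout = H[near], kout[near]

    forward = kout[:, 2] > 1e-9
    H, kout = H[forward], kout[forward]
    t = detector.distance_mm / kout[:, 2]
    xy = kout[:, :2] * t[:, None]
    f, s = detector.lab_to_pixel(xy)
    inside = (
        (f >= margin_px)
        & (f < detector.n_fast - margin_px)
        & (s >= margin_px)
        & (s < detector.n_slow - margin_px)
    )
    return [
        (tuple(int(x) for x in H[i]), (float(f[i]), float(s[i])))
        for i in np.flatnonzero(inside)
    ]


# --------------------------------------------------------------------------
# shoebox simulation


def _pixel_q(detector: Detector, fast_idx, slow_idx, energies) -> np.ndarray:
    """q = k_out - k_in for each (pixel, energy); shape (npix, nE, 3)."""
    pos = detector.pixel_lab_position(fast_idx, slow_idx)  # (npix, 3)
    direction = pos / np.linalg.norm(pos, axis=-1, keepdims=True)
    kmag = np.asarray(energies, dtype=float) / HC_EV_ANGSTROM  # (nE,)
    kout = direction[:, None, :] * kmag[None, :, None]
    kin = np.zeros((1, kmag.size, 3))
    kin[..., 2] = kmag
    return kout - kin


def _intensity_table(crystal: CrystalModel, hkl, energies, edge_shift_ev: float = 0.0):
    """|F_hkl(E)|^2 per spectrum channel, with all anomalous curves shifted
    by ``edge_shift_ev`` (the simulation ground truth)."""
    atoms = crystal.atoms
    C, A = anomalous_decomposition(crystal.cell, atoms, hkl)
    curves = [a.anomalous_curve for a in atoms if a.anomalous_curve is not None]
    if curves:
        # translating the curve by the edge shift and evaluating at E is the
        # same as evaluating the unshifted tabulation at E - shift; doing it
        # in one interpolation avoids a lossy regrid of the cusp
        f1, f2 = curves[0].evaluate(np.asarray(energies, dtype=float) - edge_shift_ev)
    else:
        f1 = f2 = np.zeros(len(energies))
    return (
        np.abs(C) ** 2
        + 2.0 * (f1 * np.real(np.conj(C) * A) - f2 * np.imag(np.conj(C) * A))
        + (f1**2 + f2**2) * np.abs(A) ** 2
    )


def expected_counts(
    shot: StillShot,
    hkl,
    bbox,
    crystal: CrystalModel,
    detector: Detector,
    mosaic: MosaicModel,
    spectrum: Spectrum,
    domain_rotations: np.ndarray,
    background_rate: float,
    flux: float,
    edge_shift_ev: float = 0.0,
    model_error: Optional[ModelError] = None,
) -> np.ndarray:
    """Noise-free expected counts on the bbox pixel grid.

    mu[px] = g * flux * Omega[px] * sum_E w_E |F(E)|^2
                 * mean_domains profile(|q_px(E) - R_d q_hkl|) + background,
    optionally perturbed by an injected model error.
    """
    fmin, fmax, smin, smax = bbox
    ff, ss = np.meshgrid(np.arange(fmin, fmax), np.arange(smin, smax), indexing="ij")
    fflat, sflat = ff.ravel(), ss.ravel()
    qpix = _pixel_q(detector, fflat, sflat, spectrum.energies)  # (npix, nE, 3)

    mos = mosaic
    true_spread = mos.angular_spread_mrad
    if model_error is not None and model_error.kind == "mosaic_misspecification":
        true_spread = mos.angular_spread_mrad * (1.0 + model_error.magnitude)
        # the realized rotations are already drawn at the inflated spread

    q0 = shot.orientation @ shot.cell.reciprocal_matrix @ np.asarray(hkl, dtype=float)
    qd = np.einsum("dij,j->di", domain_rotations, q0)  # (nD, 3)
    off2 = np.sum((qpix[:, :, None, :] - qd[None, None, :, :]) ** 2, axis=-1)
    sigma = lattice_profile_sigma(mos.domain_cells, shot.cell)
    na, nb, nc = mos.domain_cells
    peak = float(na * nb * nc) ** 2
    prof = peak * np.exp(-0.5 * off2 / sigma**2)
    prof = prof.mean(axis=2) if mos.normalize_domains else prof.sum(axis=2)

    s_e = _intensity_table(crystal, hkl, spectrum.energies, edge_shift_ev)
    omega = detector.solid_angle(fflat, sflat)
    signal = shot.scale * flux * omega * np.sum(spectrum.weights * s_e * prof, axis=1)

    bg = np.full(fflat.shape, float(background_rate))
    if model_error is not None:
        if model_error.kind == "background_gradient":
            bg = background_rate * (
                1.0 + model_error.magnitude * 2.0 * (fflat / detector.n_fast - 0.5)
            )
        mu = signal + bg
        if model_error.kind == "pixel_gain_field":
            mu = mu * gain_field(model_error, detector, fflat, sflat)
    else:
        mu = signal + bg
    return mu.reshape(fmax - fmin, smax - smin)


def simulate_shoebox(
    shot: StillShot,
    hkl,
    crystal: CrystalModel,
    detector: Detector,
    mosaic: MosaicModel,
    spectrum: Spectrum,
    domain_rotations: np.ndarray,
    rng: np.random.Generator,
    background_rate: float = 2.0,
    flux: float = DEFAULT_FLUX,
    box_size: int = 9,
    noise: bool = True,
    edge_shift_ev: float = 0.0,
    model_error: Optional[ModelError] = None,
    scale_est_sigma: float = 0.05,
    predicted_position: Optional[tuple[float, float]] = None,
) -> Shoebox:
    """Render one shoebox (default 9x9) centered on the predicted impact pixel."""
    if predicted_position is None:
        preds = dict(
            (h, pos)
            for h, pos in predict_reflections(shot, crystal, detector, mosaic, spectrum)
        )
        key = tuple(int(x) for x in hkl)
        if key not in preds:
            raise PredictionError(f"hkl {key} is not predicted to diffract for this shot")
        predicted_position = preds[key]
    half = box_size // 2
    cf = int(round(predicted_position[0]))
    cs = int(round(predicted_position[1]))
    bbox = (
        max(cf - half, 0),
        min(cf + half + 1, detector.n_fast),
        max(cs - half, 0),
        min(cs + half + 1, detector.n_slow),
    )
    mu = expected_counts(
        shot, hkl, bbox, crystal, detector, mosaic, spectrum,
        domain_rotations, background_rate, flux, edge_shift_ev, model_error,
    )
    counts = rng.poisson(mu).astype(np.int64) if noise else mu
    q = shot.cell.q_magnitude(hkl)
    scale_est = shot.metadata.get(
        "scale_estimate", shot.scale * float(np.exp(rng.normal(0.0, scale_est_sigma)))
    )
    meta = {
        "shot_id": shot.shot_id,
        "position": (float(predicted_position[0]), float(predicted_position[1])),
        "resolution": float("inf") if q == 0 else 1.0 / q,
        "scale_estimate": float(scale_est),
        "orientation_estimate": shot.metadata.get("orientation_estimate", shot.orientation),
    }
    return Shoebox(bbox=bbox, counts=counts, hkl=tuple(int(x) for x in hkl), metadata=meta)


# --------------------------------------------------------------------------
# dataset generation


def default_crystal(curve: Optional[AnomalousCurve] = None) -> CrystalModel:
    """Default toy crystal: orthorhombic 9 x 10 x 11 A cell, six atoms, one
    Mn-like anomalous site."""
    from .scattering import AtomSite, synthetic_mn_curve

    if curve is None:
        curve = synthetic_mn_curve()
    atoms = (
        AtomSite("Mn", (0.20, 0.30, 0.40), b_factor=1.5, anomalous_curve=curve),
        AtomSite("S", (0.85, 0.15, 0.55), b_factor=2.0),
        AtomSite("O", (0.10, 0.80, 0.30), b_factor=2.0),
        AtomSite("N", (0.50, 0.10, 0.70), b_factor=2.0),
        AtomSite("C", (0.70, 0.60, 0.20), b_factor=2.0),
        AtomSite("C", (0.35, 0.55, 0.85), b_factor=2.0),
    )
    return CrystalModel(cell=UnitCell(9.0, 10.0, 11.0), atoms=atoms)


def simulate_dataset(
    crystal: Optional[CrystalModel] = None,
    detector: Optional[Detector] = None,
    mosaic: Optional[MosaicModel] = None,
    spectrum: Optional[Spectrum] = None,
    n_shots: int = 200,
    seed: int = 0,
    edge_shift_ev: float = 0.0,
    background_rate: float = 2.0,
    flux: float = DEFAULT_FLUX,
    box_size: int = 9,
    noise: bool = True,
    scale_sigma: float = 0.3,
    cell_jitter: float = 1e-3,
    scale_est_sigma: float = 0.05,
    orientation_est_mrad: float = 0.5,
    max_shoeboxes_per_shot: int = 12,
    d_min: float = 2.0,
    model_error: Optional[ModelError] = None,
) -> tuple[SimulatedDataset, GroundTruth]:
    """Simulate ``n_shots`` still shots and return (dataset, ground truth).

    Per shot: Haar-random orientation, log-normal scale (sigma of log =
    ``scale_sigma``), relative cell-length jitter, fresh mosaic-domain
    rotations; every predicted reflection (strongest first, capped) is
    rendered as a shoebox.  The ground-truth sidecar records the injected
    edge shift, true scales/orientations and the model error; inference
    consumes only shoebox counts + DIALS-like metadata.
    """
    crystal = crystal if crystal is not None else default_crystal()
    detector = detector if detector is not None else Detector()
    mosaic = mosaic if mosaic is not None else MosaicModel()
    spectrum = spectrum if spectrum is not None else Spectrum.gaussian()
    rng = np.random.default_rng(seed)

    spread = mosaic.angular_spread_mrad
    if model_error is not None and model_error.kind == "mosaic_misspecification":
        spread = spread * (1.0 + model_error.magnitude)

    shots: list[StillShot] = []
    truth_scales, truth_orients, truth_cells, truth_domains = [], [], [], []
    for shot_id in range(n_shots):
        u = random_orientation(rng)
        g = float(np.exp(rng.normal(0.0, scale_sigma)))
        jitter = 1.0 + rng.normal(0.0, cell_jitter, size=3) if cell_jitter > 0 else np.ones(3)
        cell = UnitCell(
            crystal.cell.a * jitter[0],
            crystal.cell.b * jitter[1],
            crystal.cell.c * jitter[2],
            crystal.cell.alpha,
            crystal.cell.beta,
            crystal.cell.gamma,
        )
        domains = np.stack(
            [small_random_rotation(rng, spread * 1e-3) for _ in range(mosaic.n_domains)]
        )
        g_est = g * float(np.exp(rng.normal(0.0, scale_est_sigma))) if scale_est_sigma > 0 else g
        u_est = u @ small_random_rotation(rng, orientation_est_mrad * 1e-3)
        shot = StillShot(
            shot_id=shot_id,
            orientation=u,
            scale=g,
            cell=cell,
            metadata={"scale_estimate": g_est, "orientation_estimate": u_est},
        )
        preds = predict_reflections(shot, crystal, detector, mosaic, spectrum, d_min=d_min)
        if preds:
            strengths = [
                _intensity_table(crystal, h, [spectrum.central_energy], edge_shift_ev)[0]
                for h, _ in preds
            ]
            order = np.argsort(strengths)[::-1][:max_shoeboxes_per_shot]
            for i in sorted(order):  # deterministic order over detector
                h, pos = preds[i]
                shot.shoeboxes.append(
                    simulate_shoebox(
                        shot, h, crystal, detector, mosaic, spectrum, domains, rng,
                        background_rate=background_rate, flux=flux, box_size=box_size,
                        noise=noise, edge_shift_ev=edge_shift_ev, model_error=model_error,
                        predicted_position=pos,
                    )
                )
        shots.append(shot)
        truth_scales.append(g)
        truth_orients.append(u)
        truth_cells.append(cell)
        truth_domains.append(domains)

    dataset = SimulatedDataset(
        shots=shots, spectrum=spectrum, crystal=crystal, detector=detector, mosaic=mosaic
    )
    truth = GroundTruth(
        edge_shift_ev=float(edge_shift_ev),
        scales=np.array(truth_scales),
        orientations=np.stack(truth_orients) if truth_orients else np.zeros((0, 3, 3)),
        cells=truth_cells,
        model_error=model_error,
        seed=seed,
        domain_rotations=truth_domains,
    )
    return dataset, truth
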