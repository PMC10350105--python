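"""Inference-side forward model with analytic edge-shift dependence.

The per-pixel expectation factorizes as

    mu[box, px] = g_shot * sum_E w_E |F_hkl(E; dE)|^2 K[box, px, E] + b_box

where K collects everything that does not depend on the anomalous curve or
the nuisance parameters: flux, pixel solid angle and the (mosaic-smeared)
lattice-interference profile evaluated with the DIALS-like orientation
estimate.  With a single shared anomalous curve the intensity further
splits as |F|^2 = |C|^2 + 2 [f' Re(C~A) - f'' Im(C~A)] + (f'^2 + f''^2)|A|^2,
with complex constants C (all-atom non-anomalous sum) and A (anomalous
phase sum) per reflection, so evaluating a candidate edge shift dE touches
only the 1-D curve interpolants f'(E - dE), f''(E - dE).

The curve is interpolated with a cubic spline here (the tabulation is
linearly interpolated elsewhere) so that gradients with respect to dE are
smooth; the two interpolants differ by O(1e-3) electrons on the 1 eV grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .scattering import AnomalousCurve, CrystalModel, anomalous_decomposition
from .simulator import (
    DEFAULT_FLUX,
    Detector,
    MosaicModel,
    SimulatedDataset,
    Spectrum,
    _pixel_q,
    lattice_profile_sigma,
)

__all__ = ["ShoeboxTables", "build_tables"]


@dataclass
class ShoeboxTables:
    """Stacked per-shoebox arrays for fast likelihood evaluation."""

    counts: np.ndarray  # (Nbox, npix)
    kernel: np.ndarray  # (Nbox, npix, nE)
    shot_index: np.ndarray  # (Nbox,)
    c2: np.ndarray  # |C|^2, (Nbox,)
    rca: np.ndarray  # Re(conj(C) A), (Nbox,)
    ica: np.ndarray  # Im(conj(C) A), (Nbox,)
    a2: np.ndarray  # |A|^2, (Nbox,)
    b_init: np.ndarray  # per-box background init (perimeter mean), (Nbox,)
    g_init: np.ndarray  # per-shot scale estimate, (Nshot,)
    energies: np.ndarray  # (nE,)
    weights: np.ndarray  # (nE,)
    f1_spline: object  # CubicSpline or _LinearInterpolant
    f2_spline: object
    n_shots: int
    box_shape: tuple[int, int]
    # encoder features
    meta: np.ndarray  # (Nbox, n_meta) normalized metadata
    pixel_features: np.ndarray  # (Nbox, npix, n_pixfeat)

    @property
    def n_boxes(self) -> int:
        return int(self.counts.shape[0])

    @property
    def npix(self) -> int:
        return int(self.counts.shape[1])

    def curve_at(self, delta_e: float) -> tuple[np.ndarray, np.ndarray]:
        """(f', f'') on the spectrum channels for edge shift ``delta_e``."""
        e = self.energies - delta_e
        return self.f1_spline(e), self.f2_spline(e)

    def curve_derivative_at(self, delta_e: float) -> tuple[np.ndarray, np.ndarray]:
        """d(f', f'')/d(delta_e) on the spectrum channels (note the minus)."""
        e = self.energies - delta_e
        return -self.f1_spline(e, 1), -self.f2_spline(e, 1)

    def intensities(self, delta_e: float) -> np.ndarray:
        """|F(E; dE)|^2 for every (box, energy channel)."""
        f1, f2 = self.curve_at(delta_e)
        return (
            self.c2[:, None]
            + 2.0 * (f1[None, :] * self.rca[:, None] - f2[None, :] * self.ica[:, None])
            + (f1**2 + f2**2)[None, :] * self.a2[:, None]
        )

    def intensities_gradient(self, delta_e: float) -> np.ndarray:
        """d|F|^2/d(dE) for every (box, energy channel)."""
        f1, f2 = self.curve_at(delta_e)
        d1, d2 = self.curve_derivative_at(delta_e)
        return (
            2.0 * (d1[None, :] * self.rca[:, None] - d2[None, :] * self.ica[:, None])
            + 2.0 * (f1 * d1 + f2 * d2)[None, :] * self.a2[:, None]
        )

    def spectral_signal(self, delta_e: float) -> np.ndarray:
        """sum_E w_E |F|^2 K -> (Nbox, npix); multiply by g and add b for mu."""
        s = self.intensities(delta_e) * self.weights[None, :]
        return np.einsum("bpe,be->bp", self.kernel, s)

    def expected(self, delta_e: float, g_box: np.ndarray, b_box: np.ndarray) -> np.ndarray:
        return g_box[:, None] * self.spectral_signal(delta_e) + b_box[:, None]


class _LinearInterpolant:
    """np.interp-backed stand-in for CubicSpline: value and derivative."""

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self._dy = np.gradient(self.y, self.x)

    def __call__(self, e, nu: int = 0):
        return np.interp(e, self.x, self.y if nu == 0 else self._dy)


def build_tables(
    dataset: SimulatedDataset,
    flux: float = DEFAULT_FLUX,
    curve: Optional[AnomalousCurve] = None,
    background_floor: float = 0.1,
    curve_interp: str = "cubic",
) -> ShoeboxTables:
    """Precompute kernels and structure-factor constants for a dataset.

    Only DIALS-like information is used: shoebox counts/bbox/hkl, per-shot
    orientation and scale estimates, the per-shot cell, the nominal crystal
    (with the unshifted reference curve), spectrum, detector, and mosaic
    parameters.  The simulation ground truth is never touched.
    """
    crystal = dataset.crystal
    detector = dataset.detector
    mosaic = dataset.mosaic
    spectrum = dataset.spectrum
    if curve is None:
        curves = [a.anomalous_curve for a in crystal.atoms if a.anomalous_curve is not None]
        if not curves:
            raise ValueError("crystal has no anomalous curve to parameterize")
        curve = curves[0]

    energies = spectrum.energies
    weights = spectrum.weights
    counts_l, kernel_l, shot_idx_l = [], [], []
    c2_l, rca_l, ica_l, a2_l, b_l = [], [], [], [], []
    meta_l, pixfeat_l = [], []
    g_init = np.empty(len(dataset.shots))
    box_shape = None

    for s_i, shot in enumerate(dataset.shots):
        u_est = np.asarray(shot.metadata.get("orientation_estimate", shot.orientation))
        g_init[s_i] = float(shot.metadata.get("scale_estimate", shot.scale))
        B = shot.cell.reciprocal_matrix
        sigma_rl = lattice_profile_sigma(mosaic.domain_cells, shot.cell)
        na, nb, nc = mosaic.domain_cells
        peak = float(na * nb * nc) ** 2
        spread = mosaic.angular_spread_mrad * 1e-3
        for box in shot.shoeboxes:
            fmin, fmax, smin, smax = box.bbox
            if box_shape is None:
                box_shape = (fmax - fmin, smax - smin)
            ff, ss = np.meshgrid(
                np.arange(fmin, fmax), np.arange(smin, smax), indexing="ij"
            )
            fflat, sflat = ff.ravel(), ss.ravel()
            qpix = _pixel_q(detector, fflat, sflat, energies)
            q0 = u_est @ B @ np.asarray(box.hkl, dtype=float)
            qn = np.linalg.norm(q0)
            # mosaic smearing folded into an effective isotropic width
            sigma_eff2 = sigma_rl**2 + (spread * qn) ** 2
            off2 = np.sum((qpix - q0[None, None, :]) ** 2, axis=-1)
            prof = peak * np.exp(-0.5 * off2 / sigma_eff2)
            omega = detector.solid_angle(fflat, sflat)
            kernel_l.append(flux * omega[:, None] * prof)
            counts_l.append(np.asarray(box.counts, dtype=float).ravel())
            shot_idx_l.append(s_i)
            C, A = anomalous_decomposition(shot.cell, crystal.atoms, box.hkl)
            c2_l.append(abs(C) ** 2)
            rca_l.append(float(np.real(np.conj(C) * A)))
            ica_l.append(float(np.imag(np.conj(C) * A)))
            a2_l.append(abs(A) ** 2)
            b_l.append(max(box.perimeter_mean(), background_floor))
            res = box.metadata.get("resolution", 1.0 / qn if qn > 0 else np.inf)
            pos = box.metadata.get("position", box.center_pixel)
            meta_l.append(
                [
                    1.0 / max(res, 1e-6),  # 1/d in A^-1, O(0.5)
                    pos[0] / detector.n_fast - 0.5,
                    pos[1] / detector.n_slow - 0.5,
                    np.log(g_init[s_i]),
                    np.log(max(b_l[-1], background_floor)),
                ]
            )
            # absolute detector position only: restricts the learned
            # correction to smooth detector-space fields (gain, vignetting)
            # instead of letting it re-shape spot profiles pixel by pixel
            pixfeat_l.append(
                np.stack(
                    [
                        fflat / detector.n_fast - 0.5,
                        sflat / detector.n_slow - 0.5,
                    ],
                    axis=1,
                )
            )

    if not counts_l:
        raise ValueError("dataset contains no shoeboxes")
    e_grid = curve.grid.energies
    if curve_interp == "cubic":
        f1_i, f2_i = CubicSpline(e_grid, curve.f_prime), CubicSpline(e_grid, curve.f_double_prime)
    elif curve_interp == "linear":
        # matches the tabulation's own linear interpolation exactly (at the
        # cost of a piecewise-constant gradient)
        f1_i = _LinearInterpolant(e_grid, curve.f_prime)
        f2_i = _LinearInterpolant(e_grid, curve.f_double_prime)
    else:
        raise ValueError("curve_interp must be 'cubic' or 'linear'")
    return ShoeboxTables(
        counts=np.stack(counts_l),
        kernel=np.stack(kernel_l),
        shot_index=np.asarray(shot_idx_l, dtype=int),
        c2=np.asarray(c2_l),
        rca=np.asarray(rca_l),
        ica=np.asarray(ica_l),
        a2=np.asarray(a2_l),
        b_init=np.asarray(b_l),
        g_init=g_init,
        energies=energies,
        weights=weights,
        f1_spline=f1_i,
        f2_spline=f2_i,
        n_shots=len(dataset.shots),
        box_shape=box_shape if box_shape is not None else (0, 0),
        meta=np.asarray(meta_l),
        pixel_features=np.stack(pixfeat_l),
    )
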