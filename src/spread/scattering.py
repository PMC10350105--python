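"""Atomic scattering physics for anomalous-dispersion experiments.

Energy (eV) is the canonical spectral variable everywhere in this package;
wavelength is derived as lambda[A] = 12398.42 / E[eV] only where geometry
needs it.  The scattering-vector convention is |Q| = 1/d_hkl (A^-1), so the
Debye-Waller factor is exp(-B |Q|^2 / 4) with B in A^2.  This differs by
(2 pi)^2 in the exponent from the |Q| = 2 pi / d convention; we state it
here once because getting it wrong silently rescales every B factor.

The complex structure factor of a P1 crystal at Miller index h and photon
energy E is

    F_h(E) = sum_m occ_m * [f0_m(|Q|) + df'_m(E) + i df''_m(E)]
                 * exp(2 pi i r_m . h) * exp(-B_m |Q|^2 / 4)

where the anomalous terms df', df'' are nonzero only for atoms that carry an
:class:`AnomalousCurve`.  df' and df'' are Hilbert-transform partners
(Kramers-Kronig); :func:`kramers_kronig` implements the finite-grid
transform used both to build the bundled reference curve and to enforce
consistency in per-channel fits.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "HC_EV_ANGSTROM",
    "EnergyGrid",
    "AnomalousCurve",
    "AtomSite",
    "UnitCell",
    "CrystalModel",
    "InvalidCellError",
    "UnknownElementError",
    "EnergyOutOfRangeError",
    "GridError",
    "scattering_vector_magnitude",
    "eval_f0",
    "kramers_kronig",
    "shift_edge",
    "structure_factor",
    "anomalous_decomposition",
    "energy_to_wavelength",
    "synthetic_mn_curve",
    "read_curve",
    "write_curve",
]

HC_EV_ANGSTROM = 12398.42


def energy_to_wavelength(energy_ev: float | np.ndarray) -> float | np.ndarray:
    """lambda[A] = hc / E with hc = 12398.42 eV*A."""
    return HC_EV_ANGSTROM / np.asarray(energy_ev, dtype=float)


class InvalidCellError(ValueError):
    pass


class UnknownElementError(KeyError):
    pass


class EnergyOutOfRangeError(ValueError):
    pass


class GridError(ValueError):
    pass


# --------------------------------------------------------------------------
# grids and curves


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing, uniformly spaced photon energies in eV."""

    energies: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if e.ndim != 1 or e.size < 3:
            raise GridError("energy grid needs at least 3 points")
        if np.any(e <= 0):
            raise GridError("photon energies must be positive")
        d = np.diff(e)
        if np.any(d <= 0):
            raise GridError("energies must be strictly increasing")
        if np.max(np.abs(d - d[0])) > 1e-9 * d[0]:
            raise GridError("energy grid must be uniform to 1e-9 relative")

    @property
    def spacing(self) -> float:
        return float(self.energies[1] - self.energies[0])

    @property
    def span(self) -> float:
        return float(self.energies[-1] - self.energies[0])

    def __len__(self) -> int:
        return int(self.energies.size)

    def contains(self, energy: float | np.ndarray) -> bool:
        e = np.asarray(energy, dtype=float)
        return bool(np.all(e >= self.energies[0]) and np.all(e <= self.energies[-1]))


def kramers_kronig(f_double_prime: np.ndarray, grid: EnergyGrid | None = None) -> np.ndarray:
    """Finite-grid Kramers-Kronig (Hilbert) transform of df'' -> df'.

    Convention: f'(E) = (1/pi) PV int f''(E') / (E - E') dE', which places
    the characteristic negative cusp of f' at an absorption edge.  The
    principal value is evaluated with the odd-sample discrete Hilbert
    kernel, K(m) = 2 / (pi m) for odd offsets m and 0 for even offsets:
    a pure convolution, hence exactly linear and translation-equivariant
    on-grid.  Accuracy degrades within a few linewidths of the grid edges
    where the truncated tail of the 1/m kernel is missing.
    """
    f2 = np.asarray(f_double_prime, dtype=float)
    if grid is not None and len(grid) != f2.size:
        raise GridError("f'' length does not match grid")
    if f2.ndim != 1 or f2.size < 3:
        raise GridError("need a 1-D array of at least 3 samples")
    if not np.all(np.isfinite(f2)):
        raise GridError("f'' must be finite")
    n = f2.size
    m = np.arange(-(n - 1), n, dtype=float)
    with np.errstate(divide="ignore"):
        kernel = np.where(np.arange(-(n - 1), n) % 2 != 0, 2.0 / (np.pi * m), 0.0)
    return np.convolve(f2, kernel)[n - 1 : 2 * n - 1]


@dataclass(frozen=True)
class AnomalousCurve:
    """Tabulated anomalous scattering factors df'(E), df''(E) for one species.

    Values are in electron units on a uniform eV grid; linear interpolation
    between samples.  ``edge_energy`` records the nominal K-edge position.
    """

    grid: EnergyGrid
    f_prime: np.ndarray
    f_double_prime: np.ndarray
    edge_energy: float

    def __post_init__(self):
        f1 = np.asarray(self.f_prime, dtype=float)
        f2 = np.asarray(self.f_double_prime, dtype=float)
        object.__setattr__(self, "f_prime", f1)
        object.__setattr__(self, "f_double_prime", f2)
        if f1.shape != self.grid.energies.shape or f2.shape != self.grid.energies.shape:
            raise GridError("curve arrays must match the energy grid")
        if np.any(f2 < 0):
            raise ValueError("df'' must be nonnegative at every grid point")
        if not self.grid.contains(self.edge_energy):
            raise ValueError("edge_energy outside the tabulated grid")

    def evaluate(self, energy: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of (df', df'') at ``energy`` (eV)."""
        e = np.asarray(energy, dtype=float)
        if not self.grid.contains(e):
            raise EnergyOutOfRangeError(
                f"energy outside curve grid [{self.grid.energies[0]}, {self.grid.energies[-1]}] eV"
            )
        return (
            np.interp(e, self.grid.energies, self.f_prime),
            np.interp(e, self.grid.energies, self.f_double_prime),
        )


def shift_edge(curve: AnomalousCurve, delta_e: float) -> AnomalousCurve:
    """Translate a curve along energy by ``delta_e`` eV (positive = edge moves up).

    Both df' and df'' are resampled on the unchanged grid by linear
    interpolation, clamped at the grid ends; ``edge_energy`` is incremented.
    """
    if abs(delta_e) >= curve.grid.span:
        raise EnergyOutOfRangeError(
            f"|delta_e|={abs(delta_e)} eV exceeds the grid span {curve.grid.span} eV"
        )
    e = curve.grid.energies
    return AnomalousCurve(
        grid=curve.grid,
        f_prime=np.interp(e - delta_e, e, curve.f_prime),
        f_double_prime=np.interp(e - delta_e, e, curve.f_double_prime),
        edge_energy=curve.edge_energy + delta_e,
    )


def synthetic_mn_curve(
    e_min: float = 6400.0,
    e_max: float = 6700.0,
    spacing: float = 1.0,
    edge_energy: float = 6550.0,
    edge_height: float = 3.8,
    edge_width: float = 2.0,
    white_line_amp: float = 2.5,
    white_line_sigma: float = 3.0,
    white_line_offset: float = 5.0,
    f_prime_offset: float = -1.0,
) -> AnomalousCurve:
    """Bundled Mn-like reference curve.

    df'' is a smoothed step (logistic, width ``edge_width`` eV) of height
    ``edge_height`` electrons at the K edge plus a white-line Gaussian just
    above it; df' is derived from df'' by :func:`kramers_kronig` plus a
    constant far-from-edge offset.  The shape is synthetic: it reproduces
    the qualitative near-edge features (absorption step, white line,
    negative f' cusp) that drive edge-shift recovery, not tabulated Mn data.
    """
    grid = EnergyGrid(np.arange(e_min, e_max + 0.5 * spacing, spacing))
    e = grid.energies
    f2 = edge_height / (1.0 + np.exp(-(e - edge_energy) / edge_width))
    f2 = f2 + white_line_amp * np.exp(
        -0.5 * ((e - edge_energy - white_line_offset) / white_line_sigma) ** 2
    )
    f1 = kramers_kronig(f2) + f_prime_offset
    return AnomalousCurve(grid=grid, f_prime=f1, f_double_prime=f2, edge_energy=edge_energy)


def write_curve(curve: AnomalousCurve, path_or_file) -> None:
    """Write a curve as 3-column text: energy_eV f_prime f_double_prime."""
    header = (
        "# anomalous scattering curve\n"
        f"# edge_energy_eV = {curve.edge_energy!r}\n"
        "# energy_eV f_prime f_double_prime\n"
    )
    body = np.column_stack([curve.grid.energies, curve.f_prime, curve.f_double_prime])
    if hasattr(path_or_file, "write"):
        path_or_file.write(header)
        np.savetxt(path_or_file, body, fmt="%.10g")
    else:
        with open(path_or_file, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.10g")


def read_curve(path_or_file) -> AnomalousCurve:
    """Read a 3-column curve file written by :func:`write_curve`."""
    if hasattr(path_or_file, "read"):
        text = path_or_file.read()
    else:
        with open(path_or_file) as fh:
            text = fh.read()
    edge = None
    for line in text.splitlines():
        if line.startswith("#") and "edge_energy_eV" in line:
            edge = float(line.split("=")[1])
    data = np.loadtxt(_io.StringIO(text))
    grid = EnergyGrid(data[:, 0])
    if edge is None:
        edge = float(data[np.argmax(np.gradient(data[:, 2])), 0])
    return AnomalousCurve(grid=grid, f_prime=data[:, 1], f_double_prime=data[:, 2], edge_energy=edge)


# --------------------------------------------------------------------------
# cells, atoms, structure factors


@dataclass(frozen=True)
class UnitCell:
    """Unit cell: lengths in Angstrom, angles in degrees. P1 throughout."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180) degrees")
        try:
            g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        except Exception as exc:  # pragma: no cover - gemmi rejects rare degenerate inputs
            raise InvalidCellError(str(exc)) from exc
        if g.volume <= 0 or not np.isfinite(g.volume):
            raise InvalidCellError("degenerate cell (non-positive volume)")
        orth = np.array(g.orth.mat.tolist(), dtype=float)
        # q(h) = B h with B = inv(orth)^T; |q| = 1/d. Positive definiteness of the
        # metric follows from volume > 0, but check anyway for near-degenerate input.
        if np.linalg.det(orth) <= 1e-9 * self.a * self.b * self.c:
            raise InvalidCellError("degenerate cell (singular orthogonalization)")
        object.__setattr__(self, "_gemmi", g)
        object.__setattr__(self, "_recip", np.linalg.inv(orth).T)

    @property
    def volume(self) -> float:
        return float(self._gemmi.volume)

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """3x3 matrix B such that q = B @ (h,k,l) in A^-1 (|q| = 1/d)."""
        return self._recip.copy()

    def d_spacing(self, hkl) -> float:
        q = self.q_magnitude(hkl)
        return float("inf") if q == 0 else 1.0 / q

    def q_magnitude(self, hkl) -> float:
        h = np.asarray(hkl, dtype=float)
        return float(np.linalg.norm(self._recip @ h))


def scattering_vector_magnitude(cell: UnitCell, hkl) -> float:
    """|Q| = 1/d_hkl in A^-1; zero only for (0,0,0)."""
    return cell.q_magnitude(hkl)


def _it92(element: str):
    try:
        el = gemmi.Element(element)
    except Exception:
        el = gemmi.Element("X")
    if el.name == "X" or not el.it92.get_coefs():
        known = "H, C, N, O, S, Mn, Fe, ... (any element symbol with IT92 coefficients)"
        raise UnknownElementError(f"no form-factor entry for {element!r}; available: {known}")
    return el


def eval_f0(element: str, q_mag: float | np.ndarray) -> float | np.ndarray:
    """Non-anomalous atomic form factor f0(|Q|) in electrons.

    Four-Gaussian IT92 (Cromer-Mann) parameterization evaluated at
    sin(theta)/lambda = |Q|/2.  At |Q| = 0 this equals the electron count
    within the fit's accuracy.
    """
    el = _it92(element)
    coefs = el.it92
    a = np.asarray(coefs.a, dtype=float)
    b = np.asarray(coefs.b, dtype=float)
    q = np.asarray(q_mag, dtype=float)
    stol2 = (q / 2.0) ** 2
    out = np.sum(a * np.exp(-b * stol2[..., None]), axis=-1) + coefs.c
    return float(out) if np.isscalar(q_mag) else out


@dataclass(frozen=True)
class AtomSite:
    """One atom in the unit cell (fractional coordinates, reduced mod 1)."""

    element: str
    frac_coords: tuple[float, float, float]
    b_factor: float = 0.0
    occupancy: float = 1.0
    anomalous_curve: Optional[AnomalousCurve] = None

    def __post_init__(self):
        fc = tuple(float(x) % 1.0 for x in self.frac_coords)
        object.__setattr__(self, "frac_coords", fc)
        if self.b_factor < 0:
            raise ValueError("b_factor must be nonnegative")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        _it92(self.element)  # fail early for unknown species


@dataclass(frozen=True)
class CrystalModel:
    """Unit cell plus atom sites (P1; no symmetry expansion)."""

    cell: UnitCell
    atoms: tuple[AtomSite, ...]

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.atoms:
            raise ValueError("crystal needs at least one atom")

    @property
    def anomalous_atoms(self) -> tuple[AtomSite, ...]:
        return tuple(a for a in self.atoms if a.anomalous_curve is not None)


def anomalous_decomposition(cell: UnitCell, atoms: Sequence[AtomSite], hkl):
    """Split F_h(E) = C + (df'(E) + i df''(E)) * A for a single shared curve.

    C collects every atom's f0 contribution (including the anomalous atoms'
    f0); A is the phase- and B-weighted occupancy sum over anomalous atoms.
    Valid when all anomalous atoms reference the same curve shape, which is
    the default toy configuration; :func:`structure_factor` handles the
    general case.
    """
    q = scattering_vector_magnitude(cell, hkl)
    h = np.asarray(hkl, dtype=float)
    c_sum = 0.0 + 0.0j
    a_sum = 0.0 + 0.0j
    for atom in atoms:
        phase = np.exp(2j * np.pi * np.dot(atom.frac_coords, h))
        damp = np.exp(-atom.b_factor * q * q / 4.0)
        w = atom.occupancy * phase * damp
        c_sum += w * eval_f0(atom.element, q)
        if atom.anomalous_curve is not None:
            a_sum += w
    return c_sum, a_sum


def structure_factor(cell: UnitCell, atoms: Sequence[AtomSite], hkl, energy: float) -> complex:
    """Complex structure factor F_h(E) in electrons (P1 sum over atoms)."""
    if not atoms:
        raise ValueError("atom list must be non-empty")
    q = scattering_vector_magnitude(cell, hkl)
    h = np.asarray(hkl, dtype=float)
    total = 0.0 + 0.0j
    for atom in atoms:
        f = eval_f0(atom.element, q) + 0.0j
        if atom.anomalous_curve is not None:
            if not atom.anomalous_curve.grid.contains(energy):
                raise EnergyOutOfRangeError(
                    f"energy {energy} eV outside the anomalous curve grid of atom {atom.element}"
                )
            f1, f2 = atom.anomalous_curve.evaluate(energy)
            f += float(f1) + 1j * float(f2)
        phase = np.exp(2j * np.pi * np.dot(atom.frac_coords, h))
        damp = np.exp(-atom.b_factor * q * q / 4.0)
        total += atom.occupancy * f * phase * damp
    return complex(total)
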