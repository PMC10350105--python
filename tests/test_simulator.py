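"""Forward simulator: orientations, profiles, prediction, shoeboxes."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from spread.scattering import (
    HC_EV_ANGSTROM,
    AtomSite,
    CrystalModel,
    UnitCell,
    structure_factor,
)
from spread.simulator import (
    DEFAULT_FLUX,
    Detector,
    ModelError,
    MosaicModel,
    Spectrum,
    expected_counts,
    inject_model_error,
    lattice_profile,
    lattice_profile_sigma,
    predict_reflections,
    random_orientation,
    simulate_dataset,
    simulate_shoebox,
    small_random_rotation,
)
from spread.simulator import StillShot, gain_field


class TestRandomOrientation:
    def test_proper_rotation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u = random_orientation(rng)
            assert np.max(np.abs(u.T @ u - np.eye(3))) < 1e-12
            assert np.linalg.det(u) == pytest.approx(1.0, abs=1e-12)

    def test_reproducible(self):
        a = random_orientation(np.random.default_rng(123))
        b = random_orientation(np.random.default_rng(123))
        assert np.array_equal(a, b)

    def test_haar_mean_is_zero(self):
        """Monte-Carlo: entries of the Haar mean vanish like 1/sqrt(n)."""
        rng = np.random.default_rng(7)
        n = 10_000
        total = sum(random_orientation(rng) for _ in range(n))
        assert np.max(np.abs(total / n)) < 3 * 0.6 / np.sqrt(n)


class TestLatticeProfile:
    def test_peak_value(self):
        cell = UnitCell(10, 10, 10)
        assert lattice_profile(0.0, (5, 5, 5), cell) == pytest.approx(125**2)

    def test_monotone_decay(self):
        cell = UnitCell(10, 10, 10)
        offs = np.linspace(0, 0.05, 40)
        vals = lattice_profile(offs, (5, 5, 5), cell)
        assert np.all(np.diff(vals) < 0)

    def test_integral_matches_gaussian_normalization(self):
        """3-D integral over reciprocal space vs (2 pi)^{3/2} sigma^3 peak."""
        cell = UnitCell(9, 10, 11)
        cells = (6, 5, 7)
        sigma = lattice_profile_sigma(cells, cell)
        integral, _ = quad(
            lambda r: lattice_profile(r, cells, cell) * 4 * np.pi * r**2, 0, 30 * sigma
        )
        expected = np.prod(cells) ** 2 * (2 * np.pi) ** 1.5 * sigma**3
        assert integral == pytest.approx(expected, rel=1e-2)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            lattice_profile(-0.1, (5, 5, 5), UnitCell(10, 10, 10))


def _orientation_for_bragg(cell: UnitCell, hkl, energy_ev: float) -> np.ndarray:
    """Rotation placing hkl exactly on the Ewald sphere at ``energy_ev``,
    diffracting toward the +x side of the detector."""
    k0 = energy_ev / HC_EV_ANGSTROM
    q = cell.reciprocal_matrix @ np.asarray(hkl, dtype=float)
    qn = np.linalg.norm(q)
    # place q in the x-z plane with q_z = -qn^2/(2 k0) (elastic condition)
    qz = -(qn**2) / (2 * k0)
    qx = np.sqrt(qn**2 - qz**2)
    target = np.array([qx, 0.0, qz])
    v1, v2 = q / qn, target / qn
    axis = np.cross(v1, v2)
    if np.linalg.norm(axis) < 1e-12:
        return np.eye(3)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(np.clip(np.dot(v1, v2), -1, 1))
    return Rotation.from_rotvec(angle * axis).as_matrix()


class TestPrediction:
    def test_constructed_bragg_reflection_is_predicted(self, toy_crystal):
        det = Detector()
        spec = Spectrum.gaussian()
        mos = MosaicModel()
        u = _orientation_for_bragg(toy_crystal.cell, (1, 0, 0), spec.central_energy)
        shot = StillShot(shot_id=0, orientation=u, scale=1.0, cell=toy_crystal.cell)
        preds = predict_reflections(shot, toy_crystal, det, mos, spec)
        assert (1, 0, 0) in [h for h, _ in preds]

    def test_widening_shell_grows_set(self, toy_crystal):
        det = Detector()
        spec = Spectrum.gaussian()
        mos = MosaicModel()
        rng = np.random.default_rng(5)
        shot = StillShot(
            shot_id=0, orientation=random_orientation(rng), scale=1.0, cell=toy_crystal.cell
        )
        narrow = {h for h, _ in predict_reflections(shot, toy_crystal, det, mos, spec, shell_sigmas=1.0)}
        wide = {h for h, _ in predict_reflections(shot, toy_crystal, det, mos, spec, shell_sigmas=5.0)}
        assert narrow <= wide

    def test_measure_zero_bragg_condition(self, toy_crystal):
        """Zero bandwidth + zero mosaic spread leaves only the domain-size
        term: generic orientations see few reflections."""
        det = Detector()
        mono = Spectrum(energies=np.array([6550.0]), weights=np.array([1.0]))
        mos = MosaicModel(n_domains=1, angular_spread_mrad=0.0, domain_cells=(60, 60, 60))
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(10):
            shot = StillShot(
                shot_id=0, orientation=random_orientation(rng), scale=1.0, cell=toy_crystal.cell
            )
            counts.append(
                len(predict_reflections(shot, toy_crystal, det, mos, mono, shell_sigmas=1.0))
            )
        assert np.mean(counts) < 2.0


def _triple_loop_expected(shot, hkl, crystal, detector, mosaic, spectrum, domains,
                          background, flux):
    """Brute-force per-pixel reference: explicit loops over pixels, spectrum
    channels and mosaic domains, built from scratch."""
    fmin, fmax, smin, smax = _bbox_for(shot, hkl, crystal, detector, mosaic, spectrum)
    na, nb, nc = mosaic.domain_cells
    edge = (na * shot.cell.a * nb * shot.cell.b * nc * shot.cell.c) ** (1 / 3)
    sigma = 1.0 / (np.sqrt(2 * np.pi) * edge)
    peak = (na * nb * nc) ** 2
    out = np.zeros((fmax - fmin, smax - smin))
    q0 = shot.orientation @ shot.cell.reciprocal_matrix @ np.asarray(hkl, float)
    for i, f in enumerate(range(fmin, fmax)):
        for j, s in enumerate(range(smin, smax)):
            x = (f + 0.5 - detector.beam_center[0]) * detector.pixel_size_mm
            y = (s + 0.5 - detector.beam_center[1]) * detector.pixel_size_mm
            z = detector.distance_mm
            r = np.sqrt(x * x + y * y + z * z)
            omega = detector.pixel_size_mm**2 * detector.distance_mm / r**3
            acc = 0.0
            for e_ev, w in zip(spectrum.energies, spectrum.weights):
                lam = HC_EV_ANGSTROM / e_ev
                kout = np.array([x, y, z]) / r / lam
                qpix = kout - np.array([0, 0, 1.0 / lam])
                s_e = abs(structure_factor(shot.cell, crystal.atoms, hkl, e_ev)) ** 2
                dom_acc = 0.0
                for rot in domains:
                    off = np.linalg.norm(qpix - rot @ q0)
                    dom_acc += peak * np.exp(-0.5 * (off / sigma) ** 2)
                acc += w * s_e * dom_acc / len(domains)
            out[i, j] = shot.scale * flux * omega * acc + background
    return out, (fmin, fmax, smin, smax)


def _bbox_for(shot, hkl, crystal, detector, mosaic, spectrum, half=3):
    preds = dict(predict_reflections(shot, crystal, detector, mosaic, spectrum))
    pos = preds[tuple(hkl)]
    cf, cs = int(round(pos[0])), int(round(pos[1]))
    return (cf - half, cf + half + 1, cs - half, cs + half + 1)


class TestShoeboxSimulation:
    def test_matches_triple_loop_oracle(self, toy_crystal):
        """Vectorized kernel vs an independent triple loop (3 energies x 3
        domains x 7x7 pixels) to 1e-10 relative."""
        det = Detector()
        spec = Spectrum(
            energies=np.array([6540.0, 6550.0, 6560.0]),
            weights=np.array([0.25, 0.5, 0.25]),
        )
        mos = MosaicModel(n_domains=3, angular_spread_mrad=0.3)
        u = _orientation_for_bragg(toy_crystal.cell, (1, 2, 1), 6550.0)
        shot = StillShot(shot_id=0, orientation=u, scale=1.3, cell=toy_crystal.cell)
        rng = np.random.default_rng(3)
        domains = np.stack([small_random_rotation(rng, 0.3e-3) for _ in range(3)])
        ref, bbox = _triple_loop_expected(
            shot, (1, 2, 1), toy_crystal, det, mos, spec, domains, 2.0, DEFAULT_FLUX
        )
        mu = expected_counts(
            shot, (1, 2, 1), bbox, toy_crystal, det, mos, spec, domains, 2.0, DEFAULT_FLUX
        )
        assert np.max(np.abs(mu - ref) / np.maximum(ref, 1e-12)) < 1e-10

    def test_zero_occupancy_gives_pure_background(self, mn_curve):
        crystal = CrystalModel(
            cell=UnitCell(9, 10, 11),
            atoms=(AtomSite("Mn", (0.2, 0.3, 0.4), occupancy=0.0, anomalous_curve=mn_curve),),
        )
        det = Detector()
        spec = Spectrum.gaussian()
        mos = MosaicModel()
        u = _orientation_for_bragg(crystal.cell, (1, 0, 0), spec.central_energy)
        shot = StillShot(shot_id=0, orientation=u, scale=1.0, cell=crystal.cell)
        domains = np.stack([np.eye(3)] * mos.n_domains)
        mu = expected_counts(
            shot, (1, 0, 0), (500, 509, 500, 509), crystal, det, mos, spec, domains, 2.0, DEFAULT_FLUX
        )
        assert np.allclose(mu, 2.0, atol=1e-12)

    def test_linear_in_scale(self, toy_crystal):
        det = Detector()
        spec = Spectrum.gaussian()
        mos = MosaicModel(n_domains=1, angular_spread_mrad=0.0)
        u = _orientation_for_bragg(toy_crystal.cell, (1, 2, 1), spec.central_energy)
        domains = np.stack([np.eye(3)])
        args = ((1, 2, 1), None, toy_crystal, det, mos, spec)
        shot1 = StillShot(shot_id=0, orientation=u, scale=1.0, cell=toy_crystal.cell)
        shot2 = StillShot(shot_id=0, orientation=u, scale=2.0, cell=toy_crystal.cell)
        bbox = _bbox_for(shot1, (1, 2, 1), toy_crystal, det, mos, spec)
        mu1 = expected_counts(shot1, (1, 2, 1), bbox, toy_crystal, det, mos, spec, domains, 0.5, DEFAULT_FLUX)
        mu2 = expected_counts(shot2, (1, 2, 1), bbox, toy_crystal, det, mos, spec, domains, 0.5, DEFAULT_FLUX)
        assert np.allclose(mu2 - 0.5, 2.0 * (mu1 - 0.5), rtol=1e-12)

    def test_poisson_noise_mean(self, toy_crystal):
        """Sample mean of replicate draws of one pixel within 4 standard
        errors of the expectation."""
        det = Detector()
        spec = Spectrum.gaussian()
        mos = MosaicModel(n_domains=1, angular_spread_mrad=0.0)
        u = _orientation_for_bragg(toy_crystal.cell, (1, 2, 1), spec.central_energy)
        shot = StillShot(shot_id=0, orientation=u, scale=1.0, cell=toy_crystal.cell)
        domains = np.stack([np.eye(3)])
        bbox = _bbox_for(shot, (1, 2, 1), toy_crystal, det, mos, spec)
        mu = expected_counts(shot, (1, 2, 1), bbox, toy_crystal, det, mos, spec, domains, 2.0, DEFAULT_FLUX)
        i, j = np.unravel_index(np.argmax(mu), mu.shape)
        expect = mu[i, j]
        rng = np.random.default_rng(11)
        n = 10_000
        draws = rng.poisson(expect, size=n)
        se = np.sqrt(expect / n)
        assert abs(draws.mean() - expect) < 4 * se

    def test_friedel_mate_shoeboxes(self, mn_curve):
        """Mirror-constructed Friedel mates have equal expected integrated
        intensity without anomalous scattering; the Mn-like f'' breaks it."""
        det = Detector()
        spec = Spectrum.gaussian()
        mos = MosaicModel(n_domains=1, angular_spread_mrad=0.0)
        cell = UnitCell(9, 10, 11)
        hkl = np.array([1, 2, 1])
        for anomalous, should_differ in ((False, False), (True, True)):
            atoms = (
                AtomSite("Mn", (0.2, 0.3, 0.4), b_factor=1.5,
                         anomalous_curve=mn_curve if anomalous else None),
                AtomSite("O", (0.1, 0.8, 0.3), b_factor=2.0),
            )
            crystal = CrystalModel(cell=cell, atoms=atoms)
            u = _orientation_for_bragg(cell, hkl, spec.central_energy)
            # rotate by pi about an axis perpendicular to q so that -h lands
            # exactly where +h did: identical geometry, mirrored index
            q = u @ cell.reciprocal_matrix @ hkl.astype(float)
            axis = np.cross(q, [0.0, 1.0, 0.0])
            axis /= np.linalg.norm(axis)
            flip = Rotation.from_rotvec(np.pi * axis).as_matrix()
            u2 = flip @ u
            q2 = u2 @ cell.reciprocal_matrix @ (-hkl.astype(float))
            assert np.allclose(q2, q, atol=1e-12)
            domains = np.stack([np.eye(3)])
            shot1 = StillShot(shot_id=0, orientation=u, scale=1.0, cell=cell)
            shot2 = StillShot(shot_id=1, orientation=u2, scale=1.0, cell=cell)
            bbox = _bbox_for(shot1, tuple(hkl), crystal, det, mos, spec)
            i1 = expected_counts(shot1, tuple(hkl), bbox, crystal, det, mos, spec,
                                 domains, 0.0, DEFAULT_FLUX).sum()
            i2 = expected_counts(shot2, tuple(-hkl), bbox, crystal, det, mos, spec,
                                 domains, 0.0, DEFAULT_FLUX).sum()
            rel = abs(i1 - i2) / i1
            if should_differ:
                assert rel > 1e-3
            else:
                assert rel < 1e-8


class TestDataset:
    def test_empty_dataset(self):
        ds, truth = simulate_dataset(n_shots=0, seed=0)
        assert ds.shots == [] and ds.n_shoeboxes == 0
        assert truth.scales.size == 0

    def test_fixed_seed_bit_identical(self):
        a, _ = simulate_dataset(n_shots=4, seed=9)
        b, _ = simulate_dataset(n_shots=4, seed=9)
        for sa, sb in zip(a.shots, b.shots):
            assert np.array_equal(sa.orientation, sb.orientation)
            assert sa.scale == sb.scale
            for ba, bb in zip(sa.shoeboxes, sb.shoeboxes):
                assert np.array_equal(ba.counts, bb.counts)
                assert ba.hkl == bb.hkl

    def test_degenerate_jitters_share_parameters(self):
        ds, truth = simulate_dataset(n_shots=4, seed=1, scale_sigma=0.0, cell_jitter=0.0)
        assert np.allclose(truth.scales, truth.scales[0])
        cells = [(s.cell.a, s.cell.b, s.cell.c) for s in ds.shots]
        assert all(c == cells[0] for c in cells)

    def test_sidecar_never_fed_to_inference(self, small_noisy_dataset):
        """The dataset container holds estimates; truth lives only in the
        sidecar object."""
        ds, truth = small_noisy_dataset
        ests = np.array([s.metadata["scale_estimate"] for s in ds.shots])
        # estimates are perturbed versions of the truth, not copies of it
        assert not np.any(ests == truth.scales)
        assert np.allclose(ests, truth.scales, rtol=0.5)


class TestModelErrors:
    def test_unknown_kind_lists_options(self):
        with pytest.raises(ValueError, match="pixel_gain_field"):
            inject_model_error("bad_kind", 0.1, np.random.default_rng(0))

    def test_zero_magnitude_is_identity(self, toy_crystal):
        det = Detector()
        spec = Spectrum.gaussian()
        mos = MosaicModel(n_domains=1, angular_spread_mrad=0.0)
        u = _orientation_for_bragg(toy_crystal.cell, (1, 2, 1), spec.central_energy)
        shot = StillShot(shot_id=0, orientation=u, scale=1.0, cell=toy_crystal.cell)
        domains = np.stack([np.eye(3)])
        bbox = _bbox_for(shot, (1, 2, 1), toy_crystal, det, mos, spec)
        err = inject_model_error("pixel_gain_field", 0.0, np.random.default_rng(1))
        mu0 = expected_counts(shot, (1, 2, 1), bbox, toy_crystal, det, mos, spec, domains, 2.0, DEFAULT_FLUX)
        mu1 = expected_counts(shot, (1, 2, 1), bbox, toy_crystal, det, mos, spec, domains, 2.0, DEFAULT_FLUX, model_error=err)
        assert np.max(np.abs(mu1 - mu0)) < 1e-12

    def test_gain_field_bounded(self):
        err = inject_model_error("pixel_gain_field", 0.1, np.random.default_rng(2))
        det = Detector()
        ff, ss = np.meshgrid(np.arange(0, 1024, 16), np.arange(0, 1024, 16))
        g = gain_field(err, det, ff.ravel(), ss.ravel())
        assert np.all(g >= 0.9 - 1e-12) and np.all(g <= 1.1 + 1e-12)

    def test_background_gradient_monotone_columns(self, toy_crystal):
        det = Detector()
        spec = Spectrum.gaussian()
        mos = MosaicModel(n_domains=1, angular_spread_mrad=0.0)
        u = _orientation_for_bragg(toy_crystal.cell, (1, 2, 1), spec.central_energy)
        shot = StillShot(shot_id=0, orientation=u, scale=0.0 + 1e-12, cell=toy_crystal.cell)
        domains = np.stack([np.eye(3)])
        err = ModelError(kind="background_gradient", magnitude=0.3)
        mu = expected_counts(shot, (1, 2, 1), (600, 609, 500, 509), toy_crystal, det,
                             mos, spec, domains, 2.0, 0.0, model_error=err)
        col_means = mu.mean(axis=1)
        assert np.all(np.diff(col_means) > 0)
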