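"""Radial distributions and distance-dependent electrostatic potentials."""

import warnings

import numpy as np
import pytest

from loopstate.constants import COULOMB_KCAL
from loopstate.electro import (
    ChargedParticleSet,
    RDFProfile,
    ReferencePoint,
    lfer_free_energy,
    phi_from_rdf,
    phi_particle_sum,
    phi_solvent,
    rdf,
    reference_point_from_structure,
)
from loopstate.synthetic import gen_ionic_config, gen_toy_structure


def single_particle_set(pos, q, label="X", box=None, density=0.0):
    return ChargedParticleSet(
        [np.asarray(pos, dtype=float).reshape(-1, 3)],
        [np.atleast_1d(np.asarray(q, dtype=float))],
        [np.asarray([label] * np.atleast_2d(pos).shape[0], dtype=object)],
        {label: density},
        box,
    )


class TestRdf:
    def test_ideal_gas_unity(self):
        """Uniform Poisson frames give g(r) = 1 within Monte-Carlo error."""
        dens = {"X": 0.002}
        ps = gen_ionic_config(40.0, dens, {"X": 1.0}, n_frames=400, seed=1)
        ref = ReferencePoint(np.array([20.0, 20.0, 20.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = rdf(ps, ref, dr=0.5, r_max=20.0)
        far = prof.r >= 5.0
        g = prof.g["X"][far]
        # per-shell Poisson sigma; E|g-1| ~ 0.8 sigma, so 3 sigma bounds it
        shell_vol = 4 * np.pi * prof.r[far] ** 2 * 0.5
        sigma = 1.0 / np.sqrt(prof.n_frames * dens["X"] * shell_vol)
        assert np.mean(np.abs(g - 1.0)) <= 3.0 * np.mean(sigma)
        assert np.abs(g - 1.0).max() <= 5.0 * sigma.max()

    def test_absent_species_zero(self):
        ps = single_particle_set([[5.0, 0, 0]], [1.0], label="X")
        ps.densities["Y"] = 0.0
        prof = rdf(ps, ReferencePoint(np.zeros(3)), dr=1.0, r_max=10.0)
        assert np.all(prof.g["Y"] == 0.0)

    def test_hand_placed_shell_counts(self):
        """Counts per shell equal a brute-force distance tally."""
        pos = np.array([[1.2, 0, 0], [0, 2.7, 0], [0, 0, 2.9], [3.3, 0, 0]])
        ps = single_particle_set(pos, np.ones(4), density=0.001)
        prof = rdf(ps, ReferencePoint(np.zeros(3)), dr=1.0, r_max=5.0)
        d = np.linalg.norm(pos, axis=1)
        expected = np.histogram(d, bins=np.arange(0, 5.5, 1.0))[0]
        np.testing.assert_array_equal(prof.shell_counts["X"], expected)

    def test_rmax_beyond_half_box(self):
        ps = single_particle_set([[1.0, 0, 0]], [1.0], box=20.0)
        with pytest.raises(ValueError):
            rdf(ps, ReferencePoint(np.zeros(3)), dr=0.5, r_max=15.0)


class TestPhiParticleSum:
    def test_single_point_charge_closed_form(self):
        """+1 e at 5 Å gives k_C/5 = 66.41 kcal/(mol e) for R >= 5."""
        ps = single_particle_set([[5.0, 0, 0]], [1.0])
        prof = phi_particle_sum(ps, ReferencePoint(np.zeros(3)), dr=0.5, r_max=10)
        assert prof.phi[-1] == pytest.approx(COULOMB_KCAL / 5.0)
        assert np.all(prof.phi[prof.r < 5.0] == 0.0)

    def test_no_particles(self):
        ps = ChargedParticleSet([np.zeros((0, 3))], [np.zeros(0)],
                                [np.array([], dtype=object)], {}, None)
        prof = phi_particle_sum(ps, ReferencePoint(np.zeros(3)), dr=1, r_max=5)
        assert np.all(prof.phi == 0.0)

    def test_particle_at_reference_degenerate(self):
        ps = single_particle_set([[0.0, 0, 0]], [1.0])
        with pytest.raises(ValueError, match="reference point"):
            phi_particle_sum(ps, ReferencePoint(np.zeros(3)), dr=1, r_max=5)

    def test_close_approach_frame_rejected_with_warning(self):
        frames = ChargedParticleSet(
            [np.array([[0.3, 0, 0]]), np.array([[5.0, 0, 0]])],
            [np.array([1.0]), np.array([1.0])],
            [np.array(["X"], dtype=object), np.array(["X"], dtype=object)],
            {}, None,
        )
        with pytest.warns(UserWarning, match="rejected"):
            prof = phi_particle_sum(frames, ReferencePoint(np.zeros(3)), dr=1, r_max=10)
        assert prof.phi[-1] == pytest.approx(COULOMB_KCAL / 5.0)

    def test_neutral_salt_phi_within_noise_of_zero(self):
        """Uniform neutral 2:1 salt: Phi(R) is 0 within 3 sigma for all R."""
        dens = {"Ca2+": 0.0004, "Cl-": 0.0008}
        ps = gen_ionic_config(40.0, dens, {"Ca2+": 2.0, "Cl-": -1.0},
                              n_frames=600, seed=4)
        ref = ReferencePoint(np.array([20.0, 20.0, 20.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = phi_particle_sum(ps, ref, dr=0.5, r_max=20.0)
        nz = prof.errors > 0
        assert np.all(np.abs(prof.phi[nz]) <= 3.0 * prof.errors[nz])

    def test_positive_charges_monotone_cumulative(self):
        rng = np.random.default_rng(8)
        pos = rng.uniform(-10, 10, size=(50, 3))
        ps = single_particle_set(pos, np.ones(50))
        prof = phi_particle_sum(ps, ReferencePoint(np.zeros(3)), dr=0.2, r_max=12)
        assert np.all(np.diff(prof.phi) >= 0.0)

    def test_superposition_exact(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(2, 10, size=(20, 3))
        b = rng.uniform(2, 10, size=(30, 3))
        qa, qb = rng.normal(size=20), rng.normal(size=30)
        ref = ReferencePoint(np.zeros(3))
        pa = phi_particle_sum(single_particle_set(a, qa), ref, 0.5, 20)
        pb = phi_particle_sum(single_particle_set(b, qb), ref, 0.5, 20)
        pab = phi_particle_sum(
            single_particle_set(np.vstack([a, b]), np.concatenate([qa, qb])),
            ref, 0.5, 20,
        )
        np.testing.assert_allclose(pab.phi, pa.phi + pb.phi, atol=1e-9)


class TestPhiFromRdf:
    def test_uniform_g_closed_form(self):
        """g = 1 for one species: Phi(R) = 2 pi rho q k_C R^2 exactly."""
        r = np.arange(0.05, 20, 0.1)
        prof = RDFProfile(r, {"X": np.ones(len(r))}, {"X": np.ones(len(r))}, 0.1, 1)
        out = phi_from_rdf(prof, {"X": 0.001}, {"X": 1.0})
        np.testing.assert_allclose(
            out.phi, 2 * np.pi * 0.001 * COULOMB_KCAL * out.r**2, atol=1e-9
        )

    def test_zero_density_zero(self):
        r = np.arange(0.05, 10, 0.1)
        prof = RDFProfile(r, {"X": np.ones(len(r))}, {"X": np.ones(len(r))}, 0.1, 1)
        out = phi_from_rdf(prof, {"X": 0.0}, {"X": 1.0})
        assert np.all(out.phi == 0.0)

    def test_dual_path_equivalence(self):
        """Particle summation and the RDF integral agree on the same ideal
        ionic frames (~1e5 particle-frames) within 2% / 0.5 kcal/(mol e)."""
        dens = {"Ca2+": 0.0005, "Cl-": 0.001}
        charges = {"Ca2+": 2.0, "Cl-": -1.0}
        ps = gen_ionic_config(40.0, dens, charges, n_frames=1000, seed=3)
        ref = ReferencePoint(np.array([20.0, 20.0, 20.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direct = phi_particle_sum(ps, ref, dr=0.1, r_max=20.0)
            integral = phi_from_rdf(rdf(ps, ref, dr=0.1, r_max=20.0), dens, charges)
        np.testing.assert_allclose(direct.r, integral.r)
        diff = np.abs(direct.phi - integral.phi)
        scale = np.maximum(np.abs(direct.phi), 1e-12)
        assert np.all((diff <= 0.5) | (diff / scale <= 0.02))


class TestPhiSolvent:
    def test_far_water_zero(self):
        w = np.array([[100.0, 0, 0], [100.9, 0, 0], [100.5, 0.8, 0]])
        ps = ChargedParticleSet(
            [w], [np.array([-0.834, 0.417, 0.417])],
            [np.array(["O", "H", "H"], dtype=object)], {}, None,
        )
        prof = phi_solvent(ps, ReferencePoint(np.zeros(3)), dr=0.5, r_max=20)
        assert np.all(prof.phi == 0.0)

    def test_three_term_coulomb_sum(self):
        """One TIP3P water fully inside R: sum of three point charges."""
        w = np.array([[5.0, 0, 0], [5.8, 0.6, 0], [5.8, -0.6, 0]])
        ps = ChargedParticleSet(
            [w], [np.array([-0.834, 0.417, 0.417])],
            [np.array(["O", "H", "H"], dtype=object)], {}, None,
        )
        prof = phi_solvent(ps, ReferencePoint(np.zeros(3)), dr=0.1, r_max=10)
        r = np.linalg.norm(w, axis=1)
        expected = COULOMB_KCAL * (-0.834 / r[0] + 0.417 / r[1] + 0.417 / r[2])
        assert prof.phi[-1] == pytest.approx(expected)

    def test_random_distant_waters_decay(self):
        """Randomly oriented distant dipoles: |Phi| stays small (dipolar)."""
        rng = np.random.default_rng(12)
        frames_pos, frames_q = [], []
        for _ in range(200):
            centers = rng.uniform(15, 18, size=(30, 1)) * _unit(rng, 30)
            orient = 0.5 * _unit(rng, 30)
            pos = np.concatenate(
                [centers, centers + orient, centers - orient], axis=0
            )
            q = np.concatenate(
                [np.full(30, -0.834), np.full(30, 0.417), np.full(30, 0.417)]
            )
            frames_pos.append(pos)
            frames_q.append(q)
        ps = ChargedParticleSet(
            frames_pos, frames_q,
            [np.array(["W"] * 90, dtype=object)] * 200, {}, None,
        )
        prof = phi_particle_sum(ps, ReferencePoint(np.zeros(3)), dr=1.0, r_max=20)
        # monopole of one charge at 16 Å would be ~8.7; dipoles cancel 10x
        assert np.abs(prof.phi[-1]) < 1.0


def _unit(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestLfer:
    def test_zero_potential(self):
        assert lfer_free_energy(-1.0, 0.0) == 0.0

    def test_direct_product(self):
        assert lfer_free_energy(-1.0, 10.0) == pytest.approx(-5.0)

    def test_linearity(self):
        assert lfer_free_energy(-1.0, 20.0) == 2 * lfer_free_energy(-1.0, 10.0)


class TestReferencePoint:
    def test_from_structure(self, layout):
        s = gen_toy_structure("open", layout)
        ref = reference_point_from_structure(s)
        # E17/N18 Cα sit at j; M20 has no Cα in the toy roster
        assert ref.charge == -1.0

    def test_invalid_position(self):
        with pytest.raises(ValueError):
            ReferencePoint(np.array([np.nan, 0, 0]))
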