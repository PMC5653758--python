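"""Coarse-grained mechanics: energies, forces, minimizer, Langevin sampling."""

import numpy as np
import pytest

from glycodyn.constants import KB
from glycodyn.errors import SimulationError, TopologyError
from glycodyn.system import (
    BeadSystem,
    RestraintSet,
    Trajectory,
    forces,
    langevin_integrate,
    minimize,
    potential_energy,
)
from glycodyn.toy import ToyComplexSpec, build_toy_complex, glycan_groups


def harmonic_bead(k=10.0):
    system = BeadSystem(labels=["p0"], masses=np.array([100.0]),
                        positions=np.zeros((1, 3))).finalize()
    restraints = RestraintSet(indices=np.array([0]), r0=np.zeros((1, 3)), k=k)
    return system, restraints


class TestToyComplex:
    def test_default_spec_carries_canonical_glycan_labels(self):
        toy = build_toy_complex()
        groups = glycan_groups(toy.system.labels)
        assert set(groups) == {"Fc-A", "Fc-B", "Asn45", "Asn162"}
        asn162 = {toy.system.labels[i].split("/")[1] for i in groups["Asn162"]}
        assert asn162 == {"GlcNAc1", "GlcNAc2", "Man3", "Man4", "GlcNAc5",
                          "Gal6", "Man4'", "GlcNAc5'", "Gal6'", "Fuc"}

    def test_fucosylation_flag_adds_one_bead_per_fc_glycan(self):
        non = build_toy_complex(ToyComplexSpec(fc_fucosylated=False))
        fuc = build_toy_complex(ToyComplexSpec(fc_fucosylated=True))
        assert fuc.system.n_beads - non.system.n_beads == 2
        assert "Fc-A/Fuc" in fuc.system.labels and "Fc-A/Fuc" not in non.system.labels

    def test_restraints_cover_scaffold_not_glycans(self):
        toy = build_toy_complex()
        restrained_labels = {toy.system.labels[i] for i in toy.restraints.indices}
        assert all("/bb" in lab for lab in restrained_labels)
        assert toy.restraints.k == 10.0

    def test_glycan_free_spec_is_simulable(self):
        toy = build_toy_complex(ToyComplexSpec(sites=()))
        traj = langevin_integrate(toy.system, toy.restraints, toy.system.positions,
                                  300.0, n_steps=200, stride=20, seed=0)
        assert traj.n_frames == 10

    def test_unknown_site_rejected(self):
        with pytest.raises(TopologyError):
            ToyComplexSpec(sites=("Fc-A", "Asn999"))


class TestEnergies:
    def test_restraint_term_arithmetic(self):
        system, restraints = harmonic_bead(k=10.0)
        e0, terms0 = potential_energy(system, restraints, np.zeros((1, 3)))
        assert terms0["restraint"] == 0.0
        # displacement of 1 Å with k = 10: E = k·d² = 10 kcal/mol
        e1, terms1 = potential_energy(system, restraints, np.array([[1.0, 0, 0]]))
        assert terms1["restraint"] == pytest.approx(10.0)

    def test_bond_at_rest_length_is_zero(self):
        system = BeadSystem(
            labels=["a", "b"], masses=np.ones(2),
            positions=np.array([[0.0, 0, 0], [5.0, 0, 0]]),
            bond_index=np.array([[0, 1]]), bond_k=np.array([50.0]),
            bond_b0=np.array([5.0]),
        ).finalize()
        _, terms = potential_energy(system, RestraintSet.empty(), system.positions)
        assert terms["bonds"] == pytest.approx(0.0)

    def test_nonfinite_coordinates_rejected(self):
        system, restraints = harmonic_bead()
        with pytest.raises(SimulationError):
            potential_energy(system, restraints, np.array([[np.nan, 0, 0]]))


class TestForces:
    def test_restraint_force_is_2k_d_toward_reference(self):
        system, restraints = harmonic_bead(k=10.0)
        f = forces(system, restraints, np.array([[0.0, 0.0, 0.5]]))
        assert np.allclose(f, [[0.0, 0.0, -2 * 10.0 * 0.5]])

    def test_unrestrained_isolated_bead_feels_nothing(self):
        system = BeadSystem(
            labels=["a", "b"], masses=np.ones(2),
            positions=np.array([[0.0, 0, 0], [50.0, 0, 0]]),
            nb_epsilon=np.full(2, 0.2), nb_sigma=np.full(2, 5.0), cutoff=10.0,
        ).finalize()
        f = forces(system, RestraintSet.empty(), system.positions)
        assert np.allclose(f, 0.0)

    @pytest.mark.parametrize("fuc", [False, True])
    def test_finite_difference_consistency_full_toy(self, fuc, toy_complexes):
        toy, coords = toy_complexes[fuc]
        rng = np.random.default_rng(12)
        x = coords + 0.3 * rng.standard_normal(coords.shape)
        f = forces(toy.system, toy.restraints, x)
        h = 1e-6
        sample = rng.choice(toy.system.n_beads, size=8, replace=False)
        for i in sample:
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                ep, _ = potential_energy(toy.system, toy.restraints, xp)
                em, _ = potential_energy(toy.system, toy.restraints, xm)
                num = -(ep - em) / (2 * h)
                assert num == pytest.approx(f[i, d], abs=1e-4 + 1e-5 * abs(f[i, d]))


class TestMinimize:
    def test_already_at_minimum_returns_unchanged(self):
        system, restraints = harmonic_bead()
        x, info = minimize(system, restraints, np.zeros((1, 3)), tol=1e-6)
        assert info["converged"]
        assert np.allclose(x, 0.0, atol=1e-6)

    def test_stretched_bond_relaxes_to_rest_length(self):
        system = BeadSystem(
            labels=["a", "b"], masses=np.ones(2),
            positions=np.array([[0.0, 0, 0], [8.0, 0, 0]]),
            bond_index=np.array([[0, 1]]), bond_k=np.array([50.0]),
            bond_b0=np.array([5.0]),
        ).finalize()
        x, info = minimize(system, RestraintSet.empty(), system.positions,
                           max_steps=5000, tol=1e-6)
        d = np.linalg.norm(x[1] - x[0])
        assert d == pytest.approx(5.0, abs=1e-4)

    def test_energy_decreases_monotonically_from_random_starts(self, toy_complexes):
        toy, coords = toy_complexes[False]
        rng = np.random.default_rng(5)
        x = coords + 0.5 * rng.standard_normal(coords.shape)
        e_prev, _ = potential_energy(toy.system, toy.restraints, x)
        for _ in range(5):
            x, info = minimize(toy.system, toy.restraints, x, max_steps=20, tol=0.0)
            assert info["energy"] <= e_prev + 1e-12
            e_prev = info["energy"]


class TestLangevin:
    def test_equipartition_in_harmonic_well(self, harmonic_bead_system):
        # per-coordinate variance k_B·T/(2k); the restraint convention
        # E = k·d² doubles the usual spring constant
        system, restraints = harmonic_bead_system
        traj = langevin_integrate(system, restraints, np.zeros((12, 3)), 300.0,
                                  friction_ps=5.0, dt_fs=2.0, n_steps=60_000,
                                  stride=10, seed=11)
        prod = traj.discard_burn_in(0.2)
        var = prod.frames.reshape(-1, 3).var(axis=0).mean()
        assert var == pytest.approx(KB * 300.0 / (2 * 10.0), rel=0.05)

    def test_zero_temperature_stays_at_minimum(self):
        system, restraints = harmonic_bead()
        traj = langevin_integrate(system, restraints, np.zeros((1, 3)), 0.0,
                                  n_steps=500, stride=10, seed=1)
        assert np.abs(traj.frames).max() < 1e-6

    def test_same_seed_is_bit_identical(self, toy_complexes):
        toy, coords = toy_complexes[False]
        t1 = langevin_integrate(toy.system, toy.restraints, coords, 300.0,
                                n_steps=500, stride=10, seed=7)
        t2 = langevin_integrate(toy.system, toy.restraints, coords, 300.0,
                                n_steps=500, stride=10, seed=7)
        assert np.array_equal(t1.frames, t2.frames)

    def test_nonpositive_friction_rejected(self):
        system, restraints = harmonic_bead()
        with pytest.raises(SimulationError):
            langevin_integrate(system, restraints, np.zeros((1, 3)), 300.0,
                               friction_ps=0.0, n_steps=10, seed=0)


class TestTrajectoryContainer:
    def test_npz_round_trip(self, tmp_path):
        frames = np.arange(24, dtype=float).reshape(4, 2, 3)
        traj = Trajectory(frames=frames, dt_ps=0.02, temperature=300.0,
                         labels=["a", "b"], masses=np.array([1.0, 2.0]),
                         seed_info="test", metadata={"truth": {"x": 1}})
        p = tmp_path / "t.npz"
        traj.save(p)
        back = Trajectory.load(p)
        assert np.array_equal(back.frames, frames)
        assert back.labels == ["a", "b"]
        assert back.metadata["truth"] == {"x": 1}

    def test_burn_in_discard(self):
        frames = np.zeros((10, 1, 3))
        traj = Trajectory(frames=frames, dt_ps=1.0, temperature=300.0,
                         labels=["a"], masses=np.ones(1))
        assert traj.discard_burn_in(0.5).n_frames == 5
        with pytest.raises(ValueError):
            traj.discard_burn_in(1.0)

    def test_multimodel_pdb_export_reimports(self, tmp_path):
        from glycodyn.structure import read_structure

        frames = np.arange(18, dtype=float).reshape(3, 2, 3)
        traj = Trajectory(frames=frames, dt_ps=1.0, temperature=300.0,
                         labels=["a", "b"], masses=np.ones(2))
        p = tmp_path / "t.pdb"
        traj.to_pdb(p)
        model = read_structure(p)  # first model only
        assert np.allclose(model.coords(), frames[0])
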