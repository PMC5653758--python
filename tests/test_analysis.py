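"""Trajectory analyses: RMSF, PCA, free-energy landscapes, distances, χ1."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glycodyn.analysis import (
    aggregate_rmsf,
    chi1_series,
    compute_rmsf,
    dihedral_angles,
    distance_distribution,
    free_energy_landscape,
    group_by_label_prefix,
    landscape_locate,
    msf_to_bfactor,
    pca,
    residue_centers,
)
from glycodyn.constants import KB
from glycodyn.errors import AnalysisError
from glycodyn.synth import gen_gaussian_traj, gen_two_state_traj
from glycodyn.system import Trajectory


def make_traj(frames, labels=None, masses=None):
    frames = np.asarray(frames, float)
    n = frames.shape[1]
    return Trajectory(
        frames=frames,
        dt_ps=1.0,
        temperature=300.0,
        labels=labels or [f"p{i}" for i in range(n)],
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
    )


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        traj = make_traj(np.zeros((5, 3, 3)))
        assert np.allclose(compute_rmsf(traj).rmsf, 0.0)

    def test_two_point_alternation(self):
        # equal time in two points 2 Å apart: variance d²/4 -> ρ = 1 Å
        frames = np.zeros((100, 1, 3))
        frames[::2, 0, 0] = 2.0
        assert compute_rmsf(make_traj(frames)).rmsf[0] == pytest.approx(1.0)

    def test_gaussian_jitter_recovers_sigma_sqrt3(self):
        traj = gen_gaussian_traj(np.zeros((4, 3)), 0.5, 20_000, seed=2)
        rho = compute_rmsf(traj).rmsf
        truth = np.asarray(traj.metadata["truth"]["rmsf"])
        assert np.allclose(rho, truth, rtol=0.02)

    def test_single_frame_errors(self):
        with pytest.raises(AnalysisError):
            compute_rmsf(make_traj(np.zeros((1, 2, 3))))

    def test_fit_removes_rigid_body_noise(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((6, 3)) * 4
        frames = []
        for _ in range(300):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            frames.append(base @ q.T + rng.standard_normal(3) * 5)
        traj = make_traj(np.array(frames))
        fitted = compute_rmsf(traj, fit_reference=base)
        assert np.all(fitted.rmsf < 1e-8)


class TestAggregate:
    def test_constant_group_mean(self):
        prof = compute_rmsf(make_traj(np.zeros((3, 4, 3))))
        prof.rmsf = np.array([2.0, 2.0, 1.0, 3.0])
        agg = aggregate_rmsf(prof, {"a": [0, 1], "b": [2, 3]})
        assert agg == {"a": 2.0, "b": 2.0}

    def test_empty_group_flagged_missing(self):
        prof = compute_rmsf(make_traj(np.zeros((3, 2, 3))))
        agg = aggregate_rmsf(prof, {"present": [0, 1], "absent": []})
        assert math.isnan(agg["absent"]) and agg["present"] == 0.0

    def test_sigma_ladder_ordering_recovered(self):
        sigmas = np.array([0.2, 0.4, 0.8, 1.6])
        traj = gen_gaussian_traj(np.zeros((4, 3)), sigmas, 5000, seed=3,
                                 labels=[f"g{i}/res" for i in range(4)])
        prof = compute_rmsf(traj)
        agg = aggregate_rmsf(prof, group_by_label_prefix(prof))
        order = sorted(agg, key=agg.get)
        assert order == ["g0", "g1", "g2", "g3"]

    def test_bfactor_conversion_closed_form(self):
        assert msf_to_bfactor(0.0) == 0.0
        assert msf_to_bfactor(1.0) == pytest.approx(8 * math.pi ** 2 / 3, rel=1e-12)
        rho = np.linspace(0.1, 3, 20)
        assert np.all(np.diff(msf_to_bfactor(rho)) > 0)


class TestPca:
    def make_planted(self, n=10_000, lam=(9.0, 1.0), seed=7):
        rng = np.random.default_rng(seed)
        lat = rng.standard_normal((n, 2)) * np.sqrt(lam)
        dirs = np.array([[1, 0, 0, 0, 0, 0], [0, 0, 0, 0, 1, 0]], float)
        return make_traj((lat @ dirs).reshape(n, 2, 3))

    def test_planted_two_mode_eigenvalues(self):
        traj = self.make_planted()
        res = pca(traj, mass_weighted=False, fit=False)
        assert res.eigenvalues[0] == pytest.approx(9.0, rel=0.05)
        assert res.eigenvalues[1] == pytest.approx(1.0, rel=0.05)
        # projection variance equals the eigenvalue
        assert res.projections[:, 0].var() == pytest.approx(res.eigenvalues[0], rel=1e-9)

    def test_trace_conservation_and_orthonormality(self):
        traj = self.make_planted(n=2000)
        res = pca(traj, mass_weighted=False, fit=False)
        total_var = res.eigenvalues.sum()
        dev = traj.frames - traj.frames.mean(axis=0)
        trace = (dev.reshape(2000, -1) ** 2).mean(axis=0).sum()
        assert total_var == pytest.approx(trace, rel=1e-6)
        g = res.eigenvectors.T @ res.eigenvectors
        assert np.allclose(g, np.eye(g.shape[0]), atol=1e-8)

    def test_projections_uncorrelated(self):
        res = pca(self.make_planted(), mass_weighted=False, fit=False)
        r = np.corrcoef(res.projections[:, 0], res.projections[:, 1])[0, 1]
        assert abs(r) < 0.02

    def test_mass_weighting_scales_uniform_masses(self):
        traj = self.make_planted(n=1500)
        unw = pca(traj, mass_weighted=False, fit=False)
        traj.masses = np.full(2, 4.0)
        mw = pca(traj, mass_weighted=True, fit=False)
        # uniform masses only rescale the spectrum
        assert np.allclose(mw.eigenvalues[:2], 4.0 * unw.eigenvalues[:2], rtol=1e-9)

    def test_too_few_frames_errors(self):
        with pytest.raises(AnalysisError):
            pca(make_traj(np.zeros((1, 2, 3))))


class TestFreeEnergyLandscape:
    def test_equal_populations_have_equal_g(self):
        phi1 = np.array([-1.0] * 500 + [1.0] * 500)
        phi2 = np.zeros(1000)
        fel = free_energy_landscape(phi1, phi2, 300.0, bins=2,
                                    edges=(np.array([-2.0, 0.0, 2.0]),
                                           np.array([-1.0, 1.0])))
        assert fel.delta_g[0, 0] == pytest.approx(fel.delta_g[1, 0])
        assert fel.probability.sum() == pytest.approx(1.0, abs=1e-12)

    def test_four_to_one_population_gap(self):
        phi1 = np.array([-1.0] * 800 + [1.0] * 200)
        fel = free_energy_landscape(phi1, np.zeros(1000), 300.0,
                                    edges=(np.array([-2.0, 0.0, 2.0]),
                                           np.array([-1.0, 1.0])))
        gap = fel.delta_g[1, 0] - fel.delta_g[0, 0]
        assert gap == pytest.approx(KB * 300.0 * math.log(4.0), abs=1e-6)
        assert gap == pytest.approx(0.8264, abs=2e-4)

    def test_two_state_generator_recovery(self):
        gaps = []
        for seed in range(1, 11):
            traj = gen_two_state_traj(np.zeros((1, 3)), np.array([[8.0, 0, 0]]),
                                      0.7, 0.5, 4000, seed)
            fel = free_energy_landscape(traj.frames[:, 0, 0], traj.frames[:, 0, 1],
                                        300.0, edges=(np.array([-4.0, 4.0, 12.0]),
                                                      np.array([-10.0, 10.0])))
            gaps.append(fel.delta_g[1, 0] - fel.delta_g[0, 0])
        truth = traj.metadata["truth"]["delta_delta_g"]
        se = np.std(gaps, ddof=1) / math.sqrt(len(gaps))
        assert np.mean(gaps) == pytest.approx(truth, abs=3 * se + 1e-9)

    def test_single_bin_landscape_is_valid(self):
        fel = free_energy_landscape(np.zeros(50), np.zeros(50), 300.0, bins=1)
        occupied = fel.probability > 0
        assert occupied.sum() == 1
        assert fel.delta_g[occupied][0] == 0.0

    def test_empty_bins_are_undefined_not_zero(self):
        phi = np.array([-1.0] * 10 + [1.0] * 10)
        fel = free_energy_landscape(phi, phi, 300.0, bins=4)
        assert np.isnan(fel.delta_g[fel.probability == 0]).all()

    def test_locate_reference(self):
        phi1 = np.array([-1.0] * 800 + [1.0] * 200)
        fel = free_energy_landscape(phi1, np.zeros(1000),
                                    300.0, edges=(np.array([-2.0, 0.0, 2.0]),
                                                  np.array([-1.0, 1.0])))
        major = landscape_locate(fel, (-1.0, 0.0))
        assert major["rank"] == 1 and major["delta_g"] == 0.0
        minor = landscape_locate(fel, (1.0, 0.0))
        assert minor["rank"] == 2
        assert minor["delta_g"] == pytest.approx(KB * 300 * math.log(4), abs=1e-9)
        out = landscape_locate(fel, (10.0, 0.0))
        assert out["in_range"] is False


class TestDistances:
    def test_center_conventions(self):
        traj = make_traj(np.array([[[0.0, 0, 0], [3.0, 0, 0]]]), masses=[2.0, 1.0])
        centers = residue_centers(traj, {"pair": [0, 1], "single": [0]})
        assert centers["pair"][0, 0] == pytest.approx(1.0)  # 2:1 weighted mean
        assert np.allclose(centers["single"][0], [0.0, 0, 0])
        with pytest.raises(AnalysisError):
            residue_centers(traj, {"empty": []})

    def test_static_trajectory_single_occupied_bin(self):
        frames = np.repeat(np.array([[[0.0, 0, 0], [4.0, 0, 0]]]), 50, axis=0)
        dist = distance_distribution(make_traj(frames), [0], [1], bins=10)
        assert np.all(dist.distances == 4.0)
        assert (dist.density > 0).sum() == 1

    def test_same_group_distance_zero(self):
        frames = np.random.default_rng(0).standard_normal((20, 3, 3))
        dist = distance_distribution(make_traj(frames), [0, 1, 2], [0, 1, 2])
        assert np.allclose(dist.distances, 0.0)

    def test_bimodal_generator_modes_at_planted_locations(self):
        traj = gen_two_state_traj(np.zeros((2, 3)),
                                  np.array([[0.0, 0, 0], [9.0, 0, 0]]),
                                  0.5, 0.3, 4000, seed=8)
        # particle 1 sits either on particle 0 or 9 Å away
        dist = distance_distribution(traj, [0], [1],
                                     edges=np.linspace(-0.5, 12.0, 26))
        centers = 0.5 * (dist.edges[:-1] + dist.edges[1:])
        density = dist.density
        # two local modes: near 0 and near 9 (within a bin width)
        top2 = centers[np.argsort(density)[-2:]]
        assert (np.abs(top2 - 0.0) < 1.0).any()
        assert (np.abs(top2 - 9.0) < 1.0).any()
        assert np.sum(density * np.diff(dist.edges)) == pytest.approx(1.0, abs=1e-9)


class TestChi1:
    def _quad(self, angle_deg):
        p0 = np.array([1.0, 0.0, -1.0])
        p1 = np.array([0.0, 0.0, -1.0])
        p2 = np.array([0.0, 0.0, 1.0])
        a = math.radians(angle_deg)
        p3 = np.array([math.cos(a), math.sin(a), 1.0])
        return p0, p1, p2, p3

    def test_cis_is_zero(self):
        assert dihedral_angles(*self._quad(0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_staggered_plus_60(self):
        assert dihedral_angles(*self._quad(60.0)) == pytest.approx(60.0, abs=1e-6)

    def test_wrapped_convention_186_is_minus_174(self):
        # a rotamer printed as 186° lies at −174° in the (−180, 180] convention
        assert dihedral_angles(*self._quad(186.0)) == pytest.approx(-174.0, abs=1e-6)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_range_reversal_and_mirror_symmetries(self, seed):
        # a signed torsion is invariant under reversal of the atom order and
        # negated (mod 360) by a mirror reflection of the coordinates
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((4, 3)) * 3
        fwd = float(dihedral_angles(*pts))
        rev = float(dihedral_angles(*pts[::-1]))
        mir = float(dihedral_angles(*(pts * np.array([1.0, 1.0, -1.0]))))
        assert -180.0 < fwd <= 180.0
        assert rev == pytest.approx(fwd, abs=1e-6)
        assert (fwd + mir) % 360.0 == pytest.approx(0.0, abs=1e-6) or \
               (fwd + mir) % 360.0 == pytest.approx(360.0, abs=1e-6)

    def test_series_from_trajectory_and_missing_site(self):
        frames = np.repeat(np.array(self._quad(60.0))[None, :, :], 5, axis=0)
        traj = make_traj(frames)
        series = chi1_series(traj, {"N": 0, "CA": 1, "CB": 2, "G": 3}, residue="Tyr296")
        assert np.allclose(series.angles, 60.0, atol=1e-6)
        with pytest.raises(AnalysisError, match="CB"):
            chi1_series(traj, {"N": 0, "CA": 1, "G": 3})
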