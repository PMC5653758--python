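"""Ensemble analyses of coordinate trajectories.

Implements the chain used to characterize glycan dynamics:

* RMSF per particle, ρ_i = sqrt(⟨(r_i − ⟨r_i⟩)²⟩), with per-residue or
  per-glycan aggregation and conversion to isotropic B-factors.
* Mass-weighted principal component analysis of the fitted coordinate
  covariance, C = ⟨Δr Δrᵀ⟩ over mass-weighted Cartesian coordinates.
* Two-dimensional free-energy landscape over the first two principal
  components, ΔG(Φ1, Φ2) = −k_B T ln P(Φ1, Φ2), shifted so the global
  minimum is zero.
* Distance distributions between mass-weighted residue centers.
* χ1 side-chain dihedral series (N–Cα–Cβ–γ), degrees in (−180, 180].

Averages are taken with uniform weight over the frames handed in; discard
burn-in before calling (see :meth:`glycodyn.system.Trajectory.discard_burn_in`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import B_FACTOR_PREFACTOR, KB
from .errors import AnalysisError
from .structure import superpose
from .system import Trajectory

__all__ = [
    "RmsfProfile",
    "PcaResult",
    "FreeEnergyLandscape",
    "DistanceDistribution",
    "DihedralSeries",
    "compute_rmsf",
    "aggregate_rmsf",
    "msf_to_bfactor",
    "pca",
    "free_energy_landscape",
    "landscape_locate",
    "residue_centers",
    "distance_distribution",
    "dihedral_angles",
    "chi1_series",
]


# --------------------------------------------------------------------------- RMSF

@dataclass
class RmsfProfile:
    """Per-particle root-mean-square fluctuation, Å."""

    rmsf: np.ndarray
    labels: list[str]
    indices: np.ndarray  # particle indices within the source trajectory

    def to_tsv(self) -> str:
        lines = ["particle\tlabel\trmsf_A"]
        for i, (idx, lab) in enumerate(zip(self.indices, self.labels)):
            lines.append(f"{int(idx)}\t{lab}\t{self.rmsf[i]:.6f}")
        return "\n".join(lines) + "\n"


def _fit_frames(frames: np.ndarray, reference: np.ndarray, fit_indices) -> np.ndarray:
    fitted = np.empty_like(frames)
    idx = np.asarray(fit_indices, int)
    for f in range(frames.shape[0]):
        res = superpose(frames[f, idx], reference[idx])
        fitted[f] = res.apply(frames[f])
    return fitted


def compute_rmsf(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    fit_reference: np.ndarray | None = None,
    fit_selection: Sequence[int] | None = None,
) -> RmsfProfile:
    """RMSF of each selected particle about its ensemble-average position.

    No superposition is applied by default — appropriate when the simulation
    itself restrained the frame of reference (harmonically restrained
    protein surrogate). For unrestrained inputs pass ``fit_reference`` (and
    optionally ``fit_selection``) to least-squares-fit each frame first.
    """
    if traj.n_frames < 2:
        raise AnalysisError("RMSF undefined for fewer than 2 frames")
    frames = traj.frames
    if fit_reference is not None:
        fit_idx = fit_selection if fit_selection is not None else range(traj.n_beads)
        frames = _fit_frames(frames, np.asarray(fit_reference, float), fit_idx)
    idx = np.arange(traj.n_beads) if selection is None else np.asarray(selection, int)
    sub = frames[:, idx, :]
    mean = sub.mean(axis=0)
    msf = np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0)
    return RmsfProfile(
        rmsf=np.sqrt(msf),
        labels=[traj.labels[i] for i in idx],
        indices=idx,
    )


def aggregate_rmsf(
    profile: RmsfProfile, grouping: Mapping[str, Sequence[int]]
) -> dict[str, float]:
    """Unweighted mean RMSF per group.

    ``grouping`` maps group name → positions within the profile. A group
    with no members is reported as NaN (missing), never as zero.
    """
    out: dict[str, float] = {}
    for name, members in grouping.items():
        members = list(members)
        out[name] = float(np.mean(profile.rmsf[members])) if members else float("nan")
    return out


def group_by_label_prefix(profile: RmsfProfile, sep: str = "/") -> dict[str, list[int]]:
    """Group profile positions by the label prefix before ``sep``."""
    groups: dict[str, list[int]] = {}
    for pos, lab in enumerate(profile.labels):
        groups.setdefault(lab.split(sep)[0], []).append(pos)
    return groups


def msf_to_bfactor(rmsf: np.ndarray | float) -> np.ndarray | float:
    """Isotropic Debye–Waller conversion B = (8π²/3)·ρ², Å²."""
    return B_FACTOR_PREFACTOR * np.square(rmsf)


# --------------------------------------------------------------------------- PCA

@dataclass
class PcaResult:
    """Eigendecomposition of the (optionally mass-weighted) coordinate covariance."""

    mean_coords: np.ndarray  # (m, 3) unweighted mean of the fitted frames
    eigenvectors: np.ndarray  # (3m, k), columns are components
    eigenvalues: np.ndarray  # (k,), descending; amu·Å² when mass-weighted
    projections: np.ndarray  # (n_frames, k)
    mass_weighted: bool
    masses: np.ndarray

    def validate(self, rtol: float = 1e-6) -> None:
        if np.any(np.diff(self.eigenvalues) > 0):
            raise AnalysisError("eigenvalues must be descending")
        g = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(g, np.eye(g.shape[0]), atol=1e-8):
            raise AnalysisError("eigenvectors not orthonormal")


def pca(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    mass_weighted: bool = True,
    fit: bool = True,
    fit_iterations: int = 2,
    n_components: int | None = None,
) -> PcaResult:
    """Principal component analysis of coordinate fluctuations.

    Frames are iteratively least-squares fitted to their average coordinate
    (``fit_iterations`` rounds) before building the variance-covariance
    matrix of mass-weighted deviations; its eigenvectors are the collective
    modes and the projections Φ_p = V_p·R are returned per frame.
    """
    if traj.n_frames < 2:
        raise AnalysisError("PCA undefined for fewer than 2 frames")
    idx = np.arange(traj.n_beads) if selection is None else np.asarray(selection, int)
    frames = traj.frames[:, idx, :].astype(float)
    if fit:
        for _ in range(fit_iterations):
            frames = _fit_frames(frames, frames.mean(axis=0), range(len(idx)))
    mean = frames.mean(axis=0)
    masses = traj.masses[idx]
    w = np.sqrt(masses) if mass_weighted else np.ones(len(idx))
    dev = (frames - mean) * w[None, :, None]
    x = dev.reshape(traj.n_frames, -1)  # (F, 3m)
    cov = (x.T @ x) / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    floor = -1e-10 * max(evals[0], 0.0)
    evals = np.where(evals < 0, np.maximum(evals, floor), evals)
    if n_components is not None:
        evals = evals[:n_components]
        evecs = evecs[:, :n_components]
    proj = x @ evecs
    result = PcaResult(
        mean_coords=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        projections=proj,
        mass_weighted=mass_weighted,
        masses=masses,
    )
    result.validate()
    return result


# ----------------------------------------------------------- free-energy landscape

@dataclass
class FreeEnergyLandscape:
    """Binned ΔG(Φ1, Φ2) = −k_B T ln P surface; empty bins are NaN."""

    edges1: np.ndarray
    edges2: np.ndarray
    probability: np.ndarray  # (b1, b2), sums to 1 over occupied bins
    delta_g: np.ndarray  # kcal·mol⁻¹, min 0; NaN where unoccupied
    temperature: float

    def to_tsv(self) -> str:
        c1 = 0.5 * (self.edges1[:-1] + self.edges1[1:])
        c2 = 0.5 * (self.edges2[:-1] + self.edges2[1:])
        lines = ["phi1\tphi2\tprobability\tdelta_g_kcal_mol"]
        for i, a in enumerate(c1):
            for j, b in enumerate(c2):
                g = self.delta_g[i, j]
                gtxt = "undefined" if np.isnan(g) else f"{g:.6f}"
                lines.append(f"{a:.6f}\t{b:.6f}\t{self.probability[i, j]:.9f}\t{gtxt}")
        return "\n".join(lines) + "\n"


def _padded_edges(values: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:  # all samples identical along this axis
        lo, hi = lo - 0.5, hi + 0.5
    pad = (hi - lo) / bins
    return np.linspace(lo - pad, hi + pad, bins + 1)


def free_energy_landscape(
    phi1: np.ndarray,
    phi2: np.ndarray,
    temperature: float,
    bins: int = 50,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
) -> FreeEnergyLandscape:
    """ΔG surface over two collective coordinates at temperature T (K).

    The default binning spans the sample range padded by one bin on each
    side; pass explicit ``edges`` to align landscapes across systems.
    """
    phi1 = np.asarray(phi1, float).ravel()
    phi2 = np.asarray(phi2, float).ravel()
    if phi1.shape != phi2.shape:
        raise AnalysisError("projection series must have equal length")
    if temperature <= 0:
        raise AnalysisError("temperature must be positive")
    if edges is None:
        e1 = _padded_edges(phi1, bins)
        e2 = _padded_edges(phi2, bins)
    else:
        e1, e2 = np.asarray(edges[0], float), np.asarray(edges[1], float)
    counts, e1, e2 = np.histogram2d(phi1, phi2, bins=(e1, e2))
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -KB * temperature * np.log(np.where(p > 0, p, 1.0)), np.nan)
    g = g - np.nanmin(g)
    return FreeEnergyLandscape(
        edges1=e1, edges2=e2, probability=p, delta_g=g, temperature=temperature
    )


def landscape_locate(
    landscape: FreeEnergyLandscape, reference: tuple[float, float]
) -> dict:
    """Locate a reference projection on the landscape.

    Returns the containing bin, its ΔG and its occupancy rank among
    occupied bins (rank 1 = most populated); out-of-range references are
    flagged rather than clamped.
    """
    r1, r2 = float(reference[0]), float(reference[1])
    e1, e2 = landscape.edges1, landscape.edges2
    if not (e1[0] <= r1 <= e1[-1] and e2[0] <= r2 <= e2[-1]):
        return {"in_range": False, "bin": None, "delta_g": None, "rank": None}
    i = min(int(np.searchsorted(e1, r1, side="right")) - 1, len(e1) - 2)
    j = min(int(np.searchsorted(e2, r2, side="right")) - 1, len(e2) - 2)
    p_bin = landscape.probability[i, j]
    occupied = landscape.probability[landscape.probability > 0]
    rank = int(np.sum(occupied > p_bin)) + 1 if p_bin > 0 else None
    g = landscape.delta_g[i, j]
    return {
        "in_range": True,
        "bin": (i, j),
        "delta_g": None if np.isnan(g) else float(g),
        "occupied": bool(p_bin > 0),
        "rank": rank,
    }


# ------------------------------------------------------------ distances & dihedrals

@dataclass
class DistanceDistribution:
    """Per-frame distance between two group centers and its histogram."""

    label_a: str
    label_b: str
    distances: np.ndarray  # (n_frames,), Å
    edges: np.ndarray
    density: np.ndarray  # integrates to 1
    reference_distance: float | None = None

    def to_tsv(self) -> str:
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        lines = [f"# {self.label_a} vs {self.label_b}", "distance_A\tdensity"]
        for c, d in zip(centers, self.density):
            lines.append(f"{c:.4f}\t{d:.8f}")
        return "\n".join(lines) + "\n"


def residue_centers(
    traj: Trajectory, groups: Mapping[str, Sequence[int]]
) -> dict[str, np.ndarray]:
    """Mass-weighted center of each group per frame, (n_frames, 3)."""
    out = {}
    for name, members in groups.items():
        members = np.asarray(list(members), int)
        if members.size == 0:
            raise AnalysisError(f"group {name!r} is empty")
        m = traj.masses[members]
        out[name] = np.einsum(
            "fbx,b->fx", traj.frames[:, members, :], m
        ) / m.sum()
    return out


def distance_distribution(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    bins: int = 50,
    edges: np.ndarray | None = None,
    label_a: str = "A",
    label_b: str = "B",
    reference_distance: float | None = None,
) -> DistanceDistribution:
    """Distribution of the distance between two group centers across frames."""
    centers = residue_centers(traj, {"a": group_a, "b": group_b})
    d = np.linalg.norm(centers["a"] - centers["b"], axis=1)
    if edges is None:
        lo, hi = float(d.min()), float(d.max())
        if hi == lo:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
    density, edges = np.histogram(d, bins=edges, density=True)
    return DistanceDistribution(
        label_a=label_a,
        label_b=label_b,
        distances=d,
        edges=edges,
        density=density,
        reference_distance=reference_distance,
    )


@dataclass
class DihedralSeries:
    """Per-frame signed dihedral of one residue, degrees in (−180, 180]."""

    residue: str
    angles: np.ndarray

    def histogram(self, bins: int = 72) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.angles, bins=bins, range=(-180.0, 180.0), density=True)

    def to_tsv(self) -> str:
        lines = [f"# chi1 of {self.residue}", "frame\tchi1_deg"]
        for f, a in enumerate(self.angles):
            lines.append(f"{f}\t{a:.4f}")
        return "\n".join(lines) + "\n"


def dihedral_angles(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Signed dihedral of four sites via the atan2 construction, degrees.

    Accepts (..., 3) arrays; the result lies in (−180, 180] with −180
    mapped to +180 (half-open convention).
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(b2n, n1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


CHI1_SITES = ("N", "CA", "CB", "G")


def chi1_series(
    traj: Trajectory, atom_map: Mapping[str, int], residue: str = ""
) -> DihedralSeries:
    """χ1 (N–Cα–Cβ–γ) time series for one residue.

    ``atom_map`` names the four defining sites: keys "N", "CA", "CB" and
    "G" (the residue-specific γ atom — Cγ for Tyr). A missing site raises
    an error naming it.
    """
    for site in CHI1_SITES:
        if site not in atom_map:
            raise AnalysisError(f"missing chi1-defining site {site!r} for {residue or 'residue'}")
    p = [traj.frames[:, atom_map[s], :] for s in CHI1_SITES]
    return DihedralSeries(residue=residue, angles=dihedral_angles(*p))
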