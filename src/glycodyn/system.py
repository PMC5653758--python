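"""Coarse-grained bead mechanics: energies, forces, minimization, Langevin dynamics.

One bead per sugar residue (or protein surrogate site). The potential is

    E = Σ_bonds  k_b (d − b0)²
      + Σ_angles k_a (θ − θ0)²
      + Σ_pairs  4ε[(σ/r)¹² − (σ/r)⁶]          (truncated at the cutoff)
      + Σ_restrained k (r − r0)²

The positional restraint is the harmonic form E = k(r − r0)² with
k in kcal·mol⁻¹·Å⁻² applied to protein-surrogate beads; note the absence of
the conventional ½, which doubles the effective spring constant: a single
restrained bead samples per-coordinate variance k_B·T/(2k).

All force kernels operate on coordinate arrays of shape (..., n_beads, 3) so
a ladder of replicas propagates in one vectorized call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import ACCEL, FS_PER_PS, KB
from .errors import SimulationError, TopologyError

__all__ = [
    "BeadSystem",
    "RestraintSet",
    "Trajectory",
    "potential_energy",
    "forces",
    "minimize",
    "langevin_integrate",
]


@dataclass
class BeadSystem:
    """Particles, bonded terms and nonbonded parameters of a coarse model."""

    labels: list[str]
    masses: np.ndarray  # (n,), amu
    positions: np.ndarray  # (n, 3), Å — build/reference coordinates
    bond_index: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))  # kcal/mol/Å²
    bond_b0: np.ndarray = field(default_factory=lambda: np.zeros(0))  # Å
    angle_index: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))  # kcal/mol/rad²
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))  # rad
    nb_epsilon: np.ndarray | None = None  # (n,), kcal/mol
    nb_sigma: np.ndarray | None = None  # (n,), Å
    cutoff: float = 10.0  # Å

    # derived nonbonded pair list (1-2 and 1-3 excluded)
    _pair_index: np.ndarray | None = field(default=None, repr=False)
    _pair_eps: np.ndarray | None = field(default=None, repr=False)
    _pair_sigma: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_beads(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        n = self.n_beads
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise TopologyError("masses must be positive, one per bead")
        if self.positions.shape != (n, 3):
            raise TopologyError("positions must be (n_beads, 3)")
        if np.any(self.bond_k < 0) or np.any(self.angle_k < 0):
            raise TopologyError("force constants must be non-negative")
        if self.nb_sigma is not None and self.cutoff <= float(np.max(self.nb_sigma)):
            raise TopologyError("cutoff must exceed the largest nonbonded σ")

    def finalize(self) -> "BeadSystem":
        """Validate and build the exclusion-filtered nonbonded pair list."""
        self.validate()
        if self.nb_epsilon is None or self.nb_sigma is None:
            self._pair_index = np.zeros((0, 2), int)
            self._pair_eps = np.zeros(0)
            self._pair_sigma = np.zeros(0)
            return self
        excl = set()
        adj: dict[int, set[int]] = {}
        for i, j in self.bond_index:
            excl.add((min(i, j), max(i, j)))
            adj.setdefault(int(i), set()).add(int(j))
            adj.setdefault(int(j), set()).add(int(i))
        for i in adj:  # 1-3 through the bond graph
            for j in adj[i]:
                for k in adj[j]:
                    if k != i:
                        excl.add((min(i, k), max(i, k)))
        pairs = [
            (i, j)
            for i in range(self.n_beads)
            for j in range(i + 1, self.n_beads)
            if (i, j) not in excl
        ]
        self._pair_index = np.array(pairs, int).reshape(-1, 2)
        i, j = self._pair_index.T if len(pairs) else (np.zeros(0, int), np.zeros(0, int))
        self._pair_eps = np.sqrt(self.nb_epsilon[i] * self.nb_epsilon[j])
        self._pair_sigma = 0.5 * (self.nb_sigma[i] + self.nb_sigma[j])
        return self

    @property
    def pairs(self) -> np.ndarray:
        if self._pair_index is None:
            self.finalize()
        return self._pair_index


@dataclass
class RestraintSet:
    """Harmonic positional restraints E = k Σ |r − r0|² over selected beads."""

    indices: np.ndarray  # (m,)
    r0: np.ndarray  # (m, 3), Å
    k: float = 10.0  # kcal·mol⁻¹·Å⁻²

    def validate(self, n_beads: int) -> None:
        if self.k < 0:
            raise TopologyError("restraint k must be non-negative")
        if not np.all(np.isfinite(self.r0)):
            raise TopologyError("restraint reference coordinates must be finite")
        if len(self.indices) and (self.indices.min() < 0 or self.indices.max() >= n_beads):
            raise TopologyError("restrained ids must be a subset of bead ids")

    @classmethod
    def empty(cls) -> "RestraintSet":
        return cls(indices=np.zeros(0, int), r0=np.zeros((0, 3)), k=0.0)


@dataclass
class Trajectory:
    """Ordered frames of bead coordinates with provenance metadata."""

    frames: np.ndarray  # (n_frames, n_beads, 3), Å
    dt_ps: float  # time between stored frames, ps
    temperature: float  # K
    labels: list[str]
    masses: np.ndarray  # amu
    seed_info: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def validate(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise SimulationError("frames must be (n_frames, n_beads, 3)")
        if self.dt_ps <= 0:
            raise SimulationError("frame spacing must be positive")

    def discard_burn_in(self, fraction: float) -> "Trajectory":
        """Drop the leading ``fraction`` of frames (thermalization)."""
        if not 0 <= fraction < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")
        start = int(round(self.n_frames * fraction))
        return Trajectory(
            frames=self.frames[start:],
            dt_ps=self.dt_ps,
            temperature=self.temperature,
            labels=self.labels,
            masses=self.masses,
            seed_info=self.seed_info,
            metadata={**self.metadata, "burn_in_discarded": start},
        )

    def save(self, path: str | Path) -> None:
        """Persist as an .npz frame container with a JSON metadata header."""
        np.savez_compressed(
            path,
            frames=self.frames,
            masses=self.masses,
            header=json.dumps(
                {
                    "dt_ps": self.dt_ps,
                    "temperature": self.temperature,
                    "labels": self.labels,
                    "seed_info": self.seed_info,
                    "metadata": self.metadata,
                }
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            return cls(
                frames=data["frames"],
                masses=data["masses"],
                dt_ps=header["dt_ps"],
                temperature=header["temperature"],
                labels=header["labels"],
                seed_info=header["seed_info"],
                metadata=header["metadata"],
            )

    def to_pdb(self, path: str | Path) -> None:
        """Write frames as a multi-model PDB (one HETATM per bead)."""
        lines = []
        for f in range(self.n_frames):
            lines.append(f"MODEL     {f + 1:4d}")
            for b in range(self.n_beads):
                x, y, z = self.frames[f, b]
                lines.append(
                    f"HETATM{b + 1:5d}  C   BEA A{b + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")


def _check_coords(system: BeadSystem, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2:] != (system.n_beads, 3):
        raise SimulationError(
            f"coordinate shape {coords.shape} does not match {system.n_beads} beads"
        )
    if not np.all(np.isfinite(coords)):
        raise SimulationError("non-finite coordinates")
    return coords


def _energy_terms(system: BeadSystem, restraints: RestraintSet, coords: np.ndarray):
    """Per-term energies for coordinates of shape (..., n, 3)."""
    batch = coords.shape[:-2]
    e_bond = np.zeros(batch)
    e_angle = np.zeros(batch)
    e_nb = np.zeros(batch)
    e_res = np.zeros(batch)
    if len(system.bond_index):
        i, j = system.bond_index.T
        d = np.linalg.norm(coords[..., i, :] - coords[..., j, :], axis=-1)
        e_bond = np.sum(system.bond_k * (d - system.bond_b0) ** 2, axis=-1)
    if len(system.angle_index):
        i, j, k = system.angle_index.T
        u = coords[..., i, :] - coords[..., j, :]
        v = coords[..., k, :] - coords[..., j, :]
        cos = np.sum(u * v, axis=-1) / (
            np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
        )
        theta = np.arccos(np.clip(cos, -1.0, 1.0))
        e_angle = np.sum(system.angle_k * (theta - system.angle_theta0) ** 2, axis=-1)
    pairs = system.pairs
    if len(pairs):
        i, j = pairs.T
        r = np.linalg.norm(coords[..., i, :] - coords[..., j, :], axis=-1)
        sr6 = (system._pair_sigma / r) ** 6
        e = 4.0 * system._pair_eps * (sr6 ** 2 - sr6)
        e = np.where(r < system.cutoff, e, 0.0)
        e_nb = np.sum(e, axis=-1)
    if len(restraints.indices):
        dr = coords[..., restraints.indices, :] - restraints.r0
        e_res = restraints.k * np.sum(dr ** 2, axis=(-1, -2))
    return e_bond, e_angle, e_nb, e_res


def potential_energy(
    system: BeadSystem, restraints: RestraintSet, coords: np.ndarray
) -> tuple[float, dict[str, float]]:
    """Total potential energy and its per-term breakdown, kcal·mol⁻¹."""
    coords = _check_coords(system, coords)
    eb, ea, en, er = _energy_terms(system, restraints, coords)
    terms = {
        "bonds": float(np.sum(eb)) if eb.ndim == 0 else eb,
        "angles": float(np.sum(ea)) if ea.ndim == 0 else ea,
        "nonbonded": float(np.sum(en)) if en.ndim == 0 else en,
        "restraint": float(np.sum(er)) if er.ndim == 0 else er,
    }
    total = eb + ea + en + er
    return (float(total) if total.ndim == 0 else total), terms


def forces(
    system: BeadSystem, restraints: RestraintSet, coords: np.ndarray
) -> np.ndarray:
    """Analytic −∇E, kcal·mol⁻¹·Å⁻¹, batched over leading axes of ``coords``."""
    coords = _check_coords(system, coords)
    f = np.zeros_like(coords)
    if len(system.bond_index):
        i, j = system.bond_index.T
        rij = coords[..., i, :] - coords[..., j, :]
        d = np.linalg.norm(rij, axis=-1)
        mag = -2.0 * system.bond_k * (d - system.bond_b0) / d  # force on i along rij
        fv = mag[..., None] * rij
        np.add.at(f, (..., i, slice(None)), fv)
        np.add.at(f, (..., j, slice(None)), -fv)
    if len(system.angle_index):
        i, j, k = system.angle_index.T
        u = coords[..., i, :] - coords[..., j, :]
        v = coords[..., k, :] - coords[..., j, :]
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        cos = np.sum(u * v, axis=-1) / (nu * nv)
        cos = np.clip(cos, -1.0 + 1e-12, 1.0 - 1e-12)
        theta = np.arccos(cos)
        sin = np.sqrt(1.0 - cos ** 2)
        dedt = 2.0 * system.angle_k * (theta - system.angle_theta0)
        # dθ/dri and dθ/drk; dθ/drj closes the triple by translation invariance
        dthe_di = (cos[..., None] * u / nu[..., None] ** 2 - v / (nu * nv)[..., None]) / sin[..., None]
        dthe_dk = (cos[..., None] * v / nv[..., None] ** 2 - u / (nu * nv)[..., None]) / sin[..., None]
        fi = -dedt[..., None] * dthe_di
        fk = -dedt[..., None] * dthe_dk
        np.add.at(f, (..., i, slice(None)), fi)
        np.add.at(f, (..., k, slice(None)), fk)
        np.add.at(f, (..., j, slice(None)), -(fi + fk))
    pairs = system.pairs
    if len(pairs):
        i, j = pairs.T
        rij = coords[..., i, :] - coords[..., j, :]
        r = np.linalg.norm(rij, axis=-1)
        sr6 = (system._pair_sigma / r) ** 6
        # −dE/dr · 1/r, zero beyond the cutoff
        mag = np.where(
            r < system.cutoff,
            4.0 * system._pair_eps * (12.0 * sr6 ** 2 - 6.0 * sr6) / r ** 2,
            0.0,
        )
        fv = mag[..., None] * rij
        np.add.at(f, (..., i, slice(None)), fv)
        np.add.at(f, (..., j, slice(None)), -fv)
    if len(restraints.indices):
        dr = coords[..., restraints.indices, :] - restraints.r0
        np.add.at(f, (..., restraints.indices, slice(None)), -2.0 * restraints.k * dr)
    return f


def minimize(
    system: BeadSystem,
    restraints: RestraintSet,
    coords: np.ndarray,
    max_steps: int = 2000,
    tol: float = 1e-4,
) -> tuple[np.ndarray, dict]:
    """Steepest descent with backtracking line search.

    Returns the relaxed coordinates and a report with convergence status,
    steps taken and the final gradient max-norm (kcal·mol⁻¹·Å⁻¹).
    """
    x = _check_coords(system, coords).copy()
    e, _ = potential_energy(system, restraints, x)
    step = 0.1
    for it in range(max_steps):
        f = forces(system, restraints, x)
        gmax = float(np.abs(f).max())
        if gmax <= tol:
            return x, {"converged": True, "steps": it, "grad_max": gmax, "energy": e}
        direction = f / max(gmax, 1e-30)
        trial_step = step
        for _ in range(40):
            x_new = x + trial_step * direction
            e_new, _ = potential_energy(system, restraints, x_new)
            if e_new < e:
                break
            trial_step *= 0.5
        else:
            # line search exhausted: at a (numerically) flat minimum this is
            # normal termination; with a large gradient it is divergence
            if gmax > 1.0:
                raise SimulationError(
                    f"minimization diverged at step {it}: energy {e:.6g} cannot "
                    f"decrease along the gradient (|g|max = {gmax:.3g})"
                )
            return x, {"converged": gmax <= tol, "steps": it, "grad_max": gmax,
                       "energy": e, "stalled": True}
        x, e = x_new, e_new
        step = min(trial_step * 2.0, 1.0)
    f = forces(system, restraints, x)
    return x, {
        "converged": False,
        "steps": max_steps,
        "grad_max": float(np.abs(f).max()),
        "energy": e,
    }


def _maxwell_velocities(masses: np.ndarray, temps, shape, rng) -> np.ndarray:
    """Maxwell–Boltzmann velocities, Å·fs⁻¹; ``temps`` broadcasts over replicas."""
    t = np.asarray(temps, dtype=float).reshape(-1, 1, 1)
    sigma = np.sqrt(KB * t * ACCEL / masses[None, :, None])
    return (sigma * rng.standard_normal(shape)).reshape(shape)


def baoab_propagate(
    system: BeadSystem,
    restraints: RestraintSet,
    x: np.ndarray,
    v: np.ndarray,
    temps: np.ndarray,
    friction_ps: float,
    dt_fs: float,
    n_steps: int,
    rng: np.random.Generator,
    record_stride: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """BAOAB Langevin propagation of (R, n, 3) replica coordinate batches.

    Returns final (x, v) and, if ``record_stride`` > 0, recorded frames of
    shape (R, n_recorded, n, 3) taken every ``record_stride`` steps.
    """
    gamma = friction_ps / FS_PER_PS  # fs⁻¹
    c1 = np.exp(-gamma * dt_fs)
    minv = (1.0 / system.masses)[None, :, None]
    t = np.asarray(temps, dtype=float).reshape(-1, 1, 1)
    noise_sigma = np.sqrt(KB * t * ACCEL * (1.0 - c1 ** 2) * minv)
    half = 0.5 * dt_fs
    recorded = [] if record_stride else None
    f = forces(system, restraints, x)
    for step in range(1, n_steps + 1):
        v = v + half * ACCEL * f * minv
        x = x + half * v
        v = c1 * v + noise_sigma * rng.standard_normal(v.shape)
        x = x + half * v
        f = forces(system, restraints, x)
        if not np.all(np.isfinite(f)):
            raise SimulationError(f"non-finite forces at step {step}")
        v = v + half * ACCEL * f * minv
        if record_stride and step % record_stride == 0:
            recorded.append(x.copy())
    frames = np.stack(recorded, axis=1) if recorded else None
    return x, v, frames


def langevin_integrate(
    system: BeadSystem,
    restraints: RestraintSet,
    coords: np.ndarray,
    temperature: float,
    friction_ps: float = 1.0,
    dt_fs: float = 2.0,
    n_steps: int = 1000,
    stride: int = 10,
    seed: int = 0,
) -> Trajectory:
    """Single-temperature Langevin dynamics (NVT) with the BAOAB splitting.

    The collision frequency ``friction_ps`` plays the role of the Langevin
    thermostat coupling; identical seed and inputs give bit-identical frames.
    For stability dt should stay well below the fastest bond period
    (≈ 2πsqrt(m/(2·k_bond·ACCEL)) fs).
    """
    system.finalize()
    restraints.validate(system.n_beads)
    if friction_ps <= 0:
        raise SimulationError("friction must be positive for thermostatted runs")
    rng = np.random.default_rng(seed)
    x = _check_coords(system, coords)[None, ...].copy()
    v = _maxwell_velocities(system.masses, [temperature], x.shape, rng)
    _, _, frames = baoab_propagate(
        system, restraints, x, v, np.array([temperature]), friction_ps, dt_fs,
        n_steps, rng, record_stride=stride,
    )
    if frames is None:
        raise SimulationError("no frames recorded: n_steps < stride")
    return Trajectory(
        frames=frames[0],
        dt_ps=dt_fs * stride / FS_PER_PS,
        temperature=temperature,
        labels=system.labels,
        masses=system.masses,
        seed_info=f"langevin:seed={seed}",
        metadata={"dt_fs": dt_fs, "friction_ps": friction_ps, "n_steps": n_steps},
    )
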