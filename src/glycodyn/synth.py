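"""Synthetic trajectory and structure generators with closed-form ground truth.

Every generator attaches a machine-readable truth record to the output
(``Trajectory.metadata["truth"]`` or a JSON side-car) so recovery tests read
expectations from the data, not from constants. Frames are i.i.d. across
time — there is no autocorrelation — which makes standard-error formulas
exact when setting tolerances.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .constants import KB
from .errors import TopologyError
from .glycans import CANONICAL_TEMPLATE
from .structure import Atom, StructureModel, write_structure
from .system import BeadSystem, Trajectory
from .toy import NONA_LABELS, RESIDUE_MASSES, make_glycan_tree, _topology_for_site

__all__ = [
    "gen_gaussian_traj",
    "gen_two_state_traj",
    "gen_boltzmann_harmonic",
    "gen_toy_glycan",
    "gen_fixture_pdb",
    "fixture_disaccharide",
    "fixture_glycan_model",
    "write_truth",
]


def write_truth(path: str | Path, truth: dict) -> None:
    """Persist a truth record as JSON beside a generated output."""
    Path(path).write_text(json.dumps(truth, indent=2, default=float) + "\n")


def _labels(n: int, labels) -> list[str]:
    return list(labels) if labels is not None else [f"p{i}" for i in range(n)]


def gen_gaussian_traj(
    ref_coords: np.ndarray,
    sigma: float | np.ndarray,
    n_frames: int,
    seed: int,
    labels: list[str] | None = None,
    masses: np.ndarray | None = None,
    temperature: float = 300.0,
) -> Trajectory:
    """Isotropic i.i.d. Gaussian jitter about reference coordinates.

    Per-coordinate standard deviation ``sigma`` (scalar or per particle)
    gives ground-truth RMSF σ√3, recorded in the truth metadata.
    """
    ref = np.atleast_2d(np.asarray(ref_coords, float))
    n = ref.shape[0]
    sig = np.broadcast_to(np.asarray(sigma, float), (n,)).astype(float)
    rng = np.random.default_rng(seed)
    frames = ref[None, :, :] + sig[None, :, None] * rng.standard_normal((n_frames, n, 3))
    return Trajectory(
        frames=frames,
        dt_ps=1.0,
        temperature=temperature,
        labels=_labels(n, labels),
        masses=masses if masses is not None else np.ones(n),
        seed_info=f"gaussian:seed={seed}",
        metadata={
            "truth": {
                "kind": "gaussian",
                "sigma": sig.tolist(),
                "rmsf": (sig * np.sqrt(3.0)).tolist(),
                "seed": seed,
            }
        },
    )


def gen_two_state_traj(
    center_a: np.ndarray,
    center_b: np.ndarray,
    p: float,
    sigma: float,
    n_frames: int,
    seed: int,
    temperature: float = 300.0,
    labels: list[str] | None = None,
) -> Trajectory:
    """Two-basin conformational mixture with Bernoulli(p) basin choice.

    The truth record carries the free-energy gap of the minor basin,
    ΔΔG = −k_B·T·ln((1−p)/p), and the per-frame basin assignment.
    """
    if not 0 < p < 1:
        raise ValueError("population p must lie strictly between 0 and 1")
    a = np.atleast_2d(np.asarray(center_a, float))
    b = np.atleast_2d(np.asarray(center_b, float))
    if a.shape != b.shape:
        raise ValueError("basin centers must have identical shapes")
    rng = np.random.default_rng(seed)
    basin = rng.random(n_frames) < p  # True -> basin A
    centers = np.where(basin[:, None, None], a[None], b[None])
    frames = centers + sigma * rng.standard_normal((n_frames,) + a.shape)
    truth = {
        "kind": "two_state",
        "p": p,
        "sigma": sigma,
        "temperature": temperature,
        "delta_delta_g": -KB * temperature * np.log((1.0 - p) / p),
        "basin_a_fraction": float(np.mean(basin)),
        "separation": float(np.linalg.norm(a - b)),
        "seed": seed,
        "basin": basin.astype(int).tolist(),
    }
    if truth["separation"] < 2.0 * sigma:
        truth["warning"] = "basins overlap (< 2 sigma separation); populations not identifiable"
    return Trajectory(
        frames=frames,
        dt_ps=1.0,
        temperature=temperature,
        labels=_labels(a.shape[0], labels),
        masses=np.ones(a.shape[0]),
        seed_info=f"two_state:seed={seed}",
        metadata={"truth": truth},
    )


def gen_boltzmann_harmonic(
    k: float,
    temperatures,
    n_frames: int,
    seed: int,
    n_particles: int = 1,
) -> list[Trajectory]:
    """Exact Boltzmann ensembles of independent harmonic wells E = k·|r−0|².

    Per-coordinate variance is k_B·T/(2k) — the factor 2 follows from the
    restraint convention without the ½. One exactly-sampled trajectory per
    ladder temperature; an independent oracle for the REMD sampling contract.
    """
    if k <= 0:
        raise ValueError("spring constant must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for t in np.atleast_1d(np.asarray(temperatures, float)):
        std = np.sqrt(KB * t / (2.0 * k))
        frames = std * rng.standard_normal((n_frames, n_particles, 3))
        out.append(
            Trajectory(
                frames=frames,
                dt_ps=1.0,
                temperature=float(t),
                labels=[f"p{i}" for i in range(n_particles)],
                masses=np.ones(n_particles),
                seed_info=f"boltzmann_harmonic:seed={seed}",
                metadata={
                    "truth": {
                        "kind": "boltzmann_harmonic",
                        "k": k,
                        "temperature": float(t),
                        "var_per_coordinate": KB * t / (2.0 * k),
                        "seed": seed,
                    }
                },
            )
        )
    return out


def gen_toy_glycan(
    arm_labels: tuple[str, ...] = NONA_LABELS,
    fucosylated: bool = False,
    site: str = "Fc-A",
):
    """Standalone labeled glycan bead tree (no protein scaffold).

    Returns (BeadSystem, GlycanTopology); the fucosylated flag adds the
    core-fucose bead on GlcNAc1.
    """
    labels, pos, parents = make_glycan_tree(arm_labels, fucosylated)
    order = list(labels)
    coords = np.array([pos[l] for l in order])
    bonds = []
    for i, lab in enumerate(order):
        par = parents[lab]
        if par is not None:
            bonds.append((order.index(par), i))
    bond_index = np.array(bonds, int).reshape(-1, 2)
    system = BeadSystem(
        labels=[f"{site}/{l}" for l in order],
        masses=np.array([RESIDUE_MASSES[CANONICAL_TEMPLATE[l][0]] for l in order]),
        positions=coords,
        bond_index=bond_index,
        bond_k=np.full(len(bonds), 50.0),
        bond_b0=np.full(len(bonds), 5.0),
        nb_epsilon=np.full(len(order), 0.2),
        nb_sigma=np.full(len(order), 5.0),
        cutoff=10.0,
    ).finalize()
    return system, _topology_for_site(site, order, parents)


def gen_fixture_pdb(records: list[dict], path: str | Path, name: str = "fixture") -> StructureModel:
    """Write a fixed-column PDB fixture from explicit atom records.

    Each record needs chain, resnum, resname, atom, x, y, z; element,
    b (B-factor), occ and hetero are optional. Returns the in-memory model.
    """
    atoms = [
        Atom(
            chain_id=r["chain"],
            residue_number=int(r["resnum"]),
            residue_name=r["resname"],
            atom_name=r["atom"],
            element=r.get("element", r["atom"][0]),
            x=float(r["x"]),
            y=float(r["y"]),
            z=float(r["z"]),
            b_factor=float(r.get("b", 20.0)),
            occupancy=float(r.get("occ", 1.0)),
            is_hetero=bool(r.get("hetero", False)),
        )
        for r in records
    ]
    model = StructureModel(atoms=atoms, name=name)
    write_structure(model, path)
    return model


def fixture_disaccharide(
    c1_o4_distance: float = 1.4, attach_asn: bool = True
) -> list[dict]:
    """Atom records for a NAG–NAG chitobiose fixture.

    The second GlcNAc's anomeric C1 sits ``c1_o4_distance`` Å from the
    first GlcNAc's O4 — below the 1.8 Å glycosidic cutoff the residues are
    linked, above it the second residue is an orphan fragment.
    """
    records = []
    if attach_asn:
        records += [
            {"chain": "A", "resnum": 297, "resname": "ASN", "atom": "CB",
             "x": -2.9, "y": 0.0, "z": 0.0, "element": "C"},
            {"chain": "A", "resnum": 297, "resname": "ASN", "atom": "ND2",
             "x": -1.45, "y": 0.0, "z": 0.0, "element": "N"},
        ]
    records += [
        {"chain": "G", "resnum": 1, "resname": "NAG", "atom": "C1",
         "x": 0.0, "y": 0.0, "z": 0.0, "element": "C", "hetero": True, "b": 30.0},
        {"chain": "G", "resnum": 1, "resname": "NAG", "atom": "O4",
         "x": 2.8, "y": 0.0, "z": 0.0, "element": "O", "hetero": True, "b": 30.0},
        {"chain": "G", "resnum": 2, "resname": "NAG", "atom": "C1",
         "x": 2.8 + c1_o4_distance, "y": 0.0, "z": 0.0, "element": "C",
         "hetero": True, "b": 40.0},
        {"chain": "G", "resnum": 2, "resname": "NAG", "atom": "O4",
         "x": 5.6 + c1_o4_distance, "y": 0.0, "z": 0.0, "element": "O",
         "hetero": True, "b": 40.0},
    ]
    return records


def fixture_glycan_model(
    arm_labels: tuple[str, ...] = NONA_LABELS,
    fucosylated: bool = False,
    chain: str = "A",
    sequon: int = 297,
    glycan_chain: str = "G",
    b_factors: dict[str, float] | None = None,
) -> list[dict]:
    """Atom records for an attached glycan whose covalent geometry is
    consistent with the glycosidic-bond cutoff rule.

    Each sugar residue gets an anomeric C1 placed 1.4 Å from its parent's
    linkage oxygen, so tree inference recovers the intended topology; the
    root C1 sits 1.45 Å from the asparagine ND2.
    """
    labels, pos, parents = make_glycan_tree(arm_labels, fucosylated, b0=6.0)
    bf = b_factors or {}
    records = [
        {"chain": chain, "resnum": sequon, "resname": "ASN", "atom": "CB",
         "x": 0.0, "y": -7.5, "z": 0.0, "element": "C"},
        {"chain": chain, "resnum": sequon, "resname": "ASN", "atom": "ND2",
         "x": 0.0, "y": -2.55, "z": 0.0, "element": "N"},
    ]
    resnum = {lab: i + 1 for i, lab in enumerate(labels)}
    for lab in labels:
        center = pos[lab]
        par = parents[lab]
        b = float(bf.get(lab, 25.0))
        # anomeric carbon points back toward the attachment: the Asn ND2 for
        # the root, the parent's linkage oxygen otherwise
        tgt = np.array([0.0, -2.55, 0.0]) if par is None else pos[par]
        v = tgt - center
        v = v / np.linalg.norm(v)
        c1 = (tgt - 1.45 * v) if par is None else (center + 2.0 * v)
        records.append(
            {"chain": glycan_chain, "resnum": resnum[lab], "resname":
             CANONICAL_TEMPLATE[lab][0], "atom": "C1", "x": c1[0], "y": c1[1],
             "z": c1[2], "element": "C", "hetero": True, "b": b}
        )
        if par is not None:
            # parent's linkage oxygen, 1.4 Å covalent C1–O bond
            o = c1 + 1.4 * v
            oname = "O" + CANONICAL_TEMPLATE[lab][2].split("-")[1]
            records.append(
                {"chain": glycan_chain, "resnum": resnum[par], "resname":
                 CANONICAL_TEMPLATE[par][0], "atom": oname, "x": o[0], "y": o[1],
                 "z": o[2], "element": "O", "hetero": True,
                 "b": float(bf.get(par, 25.0))}
            )
        # a ring-center marker so every residue has >1 atom for B averaging
        records.append(
            {"chain": glycan_chain, "resnum": resnum[lab], "resname":
             CANONICAL_TEMPLATE[lab][0], "atom": "C3", "x": center[0],
             "y": center[1], "z": center[2], "element": "C", "hetero": True, "b": b}
        )
    return records
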