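"""Coarse-grained toy model of the IgG1-Fc / sFcγRIIIa glyco-complex.

One bead per sugar residue and one bead per protein-surrogate site. The
layout emulates the crystallographic arrangement at bead resolution: two Fc
chains each carrying an Asn297 glycan that grows into the cleft between the
domains, and a receptor chain carrying the Asn45 and Asn162 glycans, with
the Asn162 glycan facing the Fc chain-A glycan across the interface.
Protein-surrogate backbone beads are harmonically restrained to their build
positions; the anchor beads at the glycosylation sites and all sugar beads
move freely, mirroring a protocol that restrains the protein backbone
except around the sequons.

Bead parameters are invented desk-scale stand-ins for an all-atom model:
bond k = 50 kcal·mol⁻¹·Å⁻² with b0 = 5 Å between linked sugar beads,
angle k = 5 kcal·mol⁻¹·rad⁻² at the built geometry, nonbonded ε = 0.2
kcal·mol⁻¹ and σ = 5 Å truncated at 10 Å, restraint k = 10 kcal·mol⁻¹·Å⁻².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError
from .glycans import CANONICAL_TEMPLATE, GlycanResidue, GlycanTopology
from .system import BeadSystem, RestraintSet

__all__ = [
    "ToyComplexSpec",
    "RESIDUE_MASSES",
    "make_glycan_tree",
    "build_toy_complex",
    "glycan_groups",
]

#: Monosaccharide residue masses (glycosidic-linked), amu.
RESIDUE_MASSES = {"NAG": 203.2, "BMA": 162.1, "MAN": 162.1, "GAL": 162.1, "FUC": 146.1}
PROTEIN_BEAD_MASS = 110.0

BOND_K = 50.0
BOND_B0 = 5.0
ANGLE_K = 5.0
NB_EPS = 0.2
NB_SIGMA = 5.0
CUTOFF = 10.0
RESTRAINT_K = 10.0

#: Nonasaccharide arm labels (the canonical template minus the core fucose).
NONA_LABELS = tuple(l for l in CANONICAL_TEMPLATE if l != "Fuc")

#: Site name -> (chain id, sequon residue number)
SITES = {"Fc-A": ("A", 297), "Fc-B": ("B", 297), "Asn45": ("C", 45), "Asn162": ("C", 162)}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Which glycans to attach and whether the Fc glycans carry core fucose.

    The receptor glycans (Asn45, Asn162) always carry their own core fucose,
    matching the biantenna­ry Gal2GlcNAc2Man3GlcNAc2(Fuc) receptor glycoform;
    ``fc_fucosylated`` toggles the fucose on the two Fc glycans only.
    """

    sites: tuple[str, ...] = ("Fc-A", "Fc-B", "Asn45", "Asn162")
    fc_fucosylated: bool = False

    def __post_init__(self) -> None:
        for s in self.sites:
            if s not in SITES:
                raise TopologyError(f"unknown glycan site {s!r} (known: {list(SITES)})")


def _template_subset(labels: tuple[str, ...], fucosylated: bool) -> list[str]:
    labels = list(labels)
    if fucosylated and "Fuc" not in labels:
        labels.append("Fuc")
    if not fucosylated and "Fuc" in labels:
        labels.remove("Fuc")
    for lab in labels:
        if lab not in CANONICAL_TEMPLATE:
            raise TopologyError(f"label {lab!r} not in the canonical glycan template")
        parent = CANONICAL_TEMPLATE[lab][1]
        if parent is not None and parent not in labels:
            raise TopologyError(f"label {lab!r} requires its parent {parent!r} in the arm spec")
    if "Fuc" in labels and CANONICAL_TEMPLATE["Fuc"][1] != "GlcNAc1":
        raise TopologyError("core fucose must be a child of GlcNAc1")
    # template order
    return [l for l in CANONICAL_TEMPLATE if l in labels]


def make_glycan_tree(
    arm_labels: tuple[str, ...] = NONA_LABELS,
    fucosylated: bool = False,
    anchor: np.ndarray = np.zeros(3),
    growth: np.ndarray = np.array([0.0, 1.0, 0.0]),
    lateral: np.ndarray = np.array([1.0, 0.0, 0.0]),
    b0: float = BOND_B0,
) -> tuple[list[str], dict[str, np.ndarray], dict[str, str | None]]:
    """Place a labeled glycan bead tree in space.

    Returns (labels in template order, label -> position, label -> parent).
    The core grows along ``growth`` from ``anchor``; the α1-3 / α1-6 arms
    splay ±50° into the (growth, lateral) plane; the fucose leaves GlcNAc1
    perpendicular to that plane.
    """
    labels = _template_subset(arm_labels, fucosylated)
    g = growth / np.linalg.norm(growth)
    x = lateral / np.linalg.norm(lateral)
    z = np.cross(x, g)
    c, s = np.cos(np.radians(50.0)), np.sin(np.radians(50.0))
    u1 = c * g + s * x  # α1-3 arm direction
    u2 = c * g - s * x  # α1-6 arm direction
    dirs = {
        "GlcNAc1": g, "GlcNAc2": g, "Man3": g,
        "Man4": u1, "GlcNAc5": u1, "Gal6": u1,
        "Man4'": u2, "GlcNAc5'": u2, "Gal6'": u2,
        "Fuc": z,
    }
    pos: dict[str, np.ndarray] = {}
    parents: dict[str, str | None] = {}
    for lab in labels:
        parent = CANONICAL_TEMPLATE[lab][1]
        parents[lab] = parent
        base = anchor if parent is None else pos[parent]
        pos[lab] = base + b0 * dirs[lab]
    return labels, pos, parents


def _topology_for_site(site: str, labels: list[str], parents: dict) -> GlycanTopology:
    chain, seq = SITES[site]
    residues = [
        GlycanResidue(
            node_id=f"{site}/{lab}",
            code=CANONICAL_TEMPLATE[lab][0],
            label=lab,
            parent=f"{site}/{parents[lab]}" if parents[lab] else None,
            linkage=CANONICAL_TEMPLATE[lab][2],
            chain_id=chain,
            residue_number=seq,
        )
        for lab in labels
    ]
    topo = GlycanTopology(attachment=(chain, seq), residues=residues, root=f"{site}/GlcNAc1")
    topo.validate()
    return topo


@dataclass
class ToyComplex:
    system: BeadSystem
    restraints: RestraintSet
    topologies: dict[str, GlycanTopology] = field(default_factory=dict)


def build_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> ToyComplex:
    """Assemble the bead system, restraint set and glycan topologies."""
    labels: list[str] = []
    positions: list[np.ndarray] = []
    masses: list[float] = []
    bonds: list[tuple[int, int]] = []
    restrained: list[int] = []

    def add_bead(label: str, pos, mass: float, restrain: bool = False) -> int:
        labels.append(label)
        positions.append(np.asarray(pos, float))
        masses.append(mass)
        if restrain:
            restrained.append(len(labels) - 1)
        return len(labels) - 1

    # protein-surrogate scaffolds: 4 restrained backbone beads per chain
    scaffold_y = {"A": -14.0, "B": -14.0, "C": 20.0}
    scaffold_z = {"A": -5.0, "B": 5.0, "C": 0.0}
    scaffold_idx: dict[str, list[int]] = {}
    for chain in ("A", "B", "C"):
        scaffold_idx[chain] = [
            add_bead(
                f"{chain}/bb{i}",
                (-12.0 + 8.0 * i, scaffold_y[chain], scaffold_z[chain]),
                PROTEIN_BEAD_MASS,
                restrain=True,
            )
            for i in range(4)
        ]
        for a, b in zip(scaffold_idx[chain], scaffold_idx[chain][1:]):
            bonds.append((a, b))

    # glycosylation-site anchors (unrestrained protein beads) and growth frames
    anchor_geometry = {
        "Fc-A": ((0.0, -9.0, -5.0), (0.0, 1.0, 0.0), (1.0, 0.0, 0.0)),
        "Fc-B": ((0.0, -9.0, 5.0), (0.0, 1.0, 0.0), (1.0, 0.0, 0.0)),
        "Asn162": ((3.0, 15.0, -2.0), (0.0, -1.0, 0.0), (1.0, 0.0, 0.0)),
        "Asn45": ((-18.0, 15.0, 3.0), (0.0, -1.0, 0.0), (-1.0, 0.0, 0.0)),
    }
    topologies: dict[str, GlycanTopology] = {}
    for site in spec.sites:
        apos, growth, lateral = (np.asarray(v, float) for v in anchor_geometry[site])
        chain = SITES[site][0]
        anchor = add_bead(f"{site}/Asn", apos, PROTEIN_BEAD_MASS)
        near = min(scaffold_idx[chain], key=lambda i: np.linalg.norm(positions[i] - apos))
        bonds.append((near, anchor))
        fucosylated = spec.fc_fucosylated if site.startswith("Fc") else True
        glabels, gpos, gparents = make_glycan_tree(
            NONA_LABELS, fucosylated, anchor=apos, growth=growth, lateral=lateral
        )
        bead_of: dict[str, int] = {}
        for lab in glabels:
            code = CANONICAL_TEMPLATE[lab][0]
            bead_of[lab] = add_bead(f"{site}/{lab}", gpos[lab], RESIDUE_MASSES[code])
        for lab in glabels:
            parent = gparents[lab]
            bonds.append((anchor if parent is None else bead_of[parent], bead_of[lab]))
        topologies[site] = _topology_for_site(site, glabels, gparents)

    n = len(labels)
    pos = np.array(positions)
    bond_index = np.array(bonds, int)
    # angles for every bonded triple, θ0 at the built geometry
    adj: dict[int, list[int]] = {}
    for a, b in bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    triples = []
    for j in sorted(adj):
        nb = sorted(adj[j])
        for ai in range(len(nb)):
            for bi in range(ai + 1, len(nb)):
                triples.append((nb[ai], j, nb[bi]))
    angle_index = np.array(triples, int).reshape(-1, 3)
    theta0 = np.zeros(len(triples))
    for t, (i, j, k) in enumerate(triples):
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        theta0[t] = np.arccos(
            np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        )

    system = BeadSystem(
        labels=labels,
        masses=np.array(masses),
        positions=pos,
        bond_index=bond_index,
        bond_k=np.full(len(bonds), BOND_K),
        bond_b0=np.linalg.norm(pos[bond_index[:, 0]] - pos[bond_index[:, 1]], axis=1),
        angle_index=angle_index,
        angle_k=np.full(len(triples), ANGLE_K),
        angle_theta0=theta0,
        nb_epsilon=np.full(n, NB_EPS),
        nb_sigma=np.full(n, NB_SIGMA),
        cutoff=CUTOFF,
    ).finalize()
    restraints = RestraintSet(
        indices=np.array(restrained, int), r0=pos[restrained].copy(), k=RESTRAINT_K
    )
    restraints.validate(n)
    return ToyComplex(system=system, restraints=restraints, topologies=topologies)


def glycan_groups(labels: list[str]) -> dict[str, list[int]]:
    """Sugar-bead indices per glycan site, keyed by site name."""
    sugar = set(CANONICAL_TEMPLATE)
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        if "/" in lab:
            site, res = lab.split("/", 1)
            if res in sugar:
                groups.setdefault(site, []).append(i)
    return groups
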