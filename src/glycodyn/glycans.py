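"""Glycan-tree identification and nomenclature.

An N-glycan is represented as a rooted tree of monosaccharide residues
attached at an asparagine sequon. Residues are named with the standard
biantennary complex-type nomenclature: the chitobiose core GlcNAc1-GlcNAc2,
the branching mannose Man3, the α1-3 arm Man4-GlcNAc5-Gal6, the α1-6 arm
Man4'-GlcNAc5'-Gal6', and the core fucose Fuc α1,6-linked to GlcNAc1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError
from .structure import StructureModel

__all__ = [
    "GlycanResidue",
    "GlycanTopology",
    "CANONICAL_TEMPLATE",
    "CANONICAL_LABELS",
    "DEFAULT_CARB_CODES",
    "identify_glycans",
    "bfactor_profile",
]

#: Canonical fucosylated biantennary template:
#: label -> (PDB residue code, parent label, linkage text)
CANONICAL_TEMPLATE: dict[str, tuple[str, str | None, str]] = {
    "GlcNAc1": ("NAG", None, "1-ND2"),
    "GlcNAc2": ("NAG", "GlcNAc1", "1-4"),
    "Man3": ("BMA", "GlcNAc2", "1-4"),
    "Man4": ("MAN", "Man3", "1-3"),
    "GlcNAc5": ("NAG", "Man4", "1-2"),
    "Gal6": ("GAL", "GlcNAc5", "1-4"),
    "Man4'": ("MAN", "Man3", "1-6"),
    "GlcNAc5'": ("NAG", "Man4'", "1-2"),
    "Gal6'": ("GAL", "GlcNAc5'", "1-4"),
    "Fuc": ("FUC", "GlcNAc1", "1-6"),
}

CANONICAL_LABELS: tuple[str, ...] = tuple(CANONICAL_TEMPLATE)

#: PDB residue codes recognized as carbohydrates by default. Extendable at
#: call sites because carbohydrate codes in the PDB changed over remediation.
DEFAULT_CARB_CODES: frozenset[str] = frozenset(
    {"NAG", "NDG", "BMA", "MAN", "GAL", "GLA", "GLC", "BGC", "FUC", "FUL"}
)

FUCOSE_CODES = frozenset({"FUC", "FUL"})

#: Covalent C–O glycosidic bonds are ~1.4 Å; next-nearest contacts exceed
#: 2.4 Å, so 1.8 Å separates the two cleanly.
GLYCOSIDIC_BOND_CUTOFF = 1.8


@dataclass(frozen=True)
class GlycanResidue:
    node_id: str
    code: str
    label: str
    parent: str | None
    linkage: str
    chain_id: str = ""
    residue_number: int = 0


@dataclass
class GlycanTopology:
    """Rooted tree of carbohydrate residues at one sequon.

    ``attachment`` is the (chain_id, residue_number) of the asparagine, or
    ``None`` for an orphan fragment with no resolvable protein attachment.
    """

    attachment: tuple[str, int] | None
    residues: list[GlycanResidue] = field(default_factory=list)
    root: str = ""

    @property
    def is_orphan(self) -> bool:
        return self.attachment is None

    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    def node(self, label: str) -> GlycanResidue:
        for r in self.residues:
            if r.label == label:
                return r
        raise KeyError(label)

    def n_bonds(self) -> int:
        return sum(1 for r in self.residues if r.parent is not None)

    def validate(self) -> None:
        ids = [r.node_id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise TopologyError("duplicate node ids in glycan tree")
        roots = [r for r in self.residues if r.parent is None]
        if len(roots) != 1 or roots[0].node_id != self.root:
            raise TopologyError("glycan tree must have exactly one root")
        # walk up from every node; a cycle would never reach the root
        parent_of = {r.node_id: r.parent for r in self.residues}
        for nid in ids:
            seen = set()
            cur: str | None = nid
            while cur is not None:
                if cur in seen:
                    raise TopologyError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = parent_of.get(cur)

    def report(self) -> str:
        """One line per residue: label, code, parent label, linkage."""
        parent_label = {r.node_id: r.label for r in self.residues}
        lines = ["label\tcode\tparent\tlinkage"]
        for r in self.residues:
            par = parent_label.get(r.parent, "-") if r.parent else "Asn"
            lines.append(f"{r.label}\t{r.code}\t{par}\t{r.linkage}")
        return "\n".join(lines)


def _anomeric_carbon(model: StructureModel, atom_idx: list[int]) -> int | None:
    names = {model.atoms[i].atom_name: i for i in atom_idx}
    for name in ("C1", "C2"):
        if name in names:
            return names[name]
    return None


def identify_glycans(
    model: StructureModel,
    carb_codes: frozenset[str] | set[str] = DEFAULT_CARB_CODES,
    bond_cutoff: float = GLYCOSIDIC_BOND_CUTOFF,
) -> list[GlycanTopology]:
    """Infer glycan trees from inter-residue covalent geometry.

    Glycosidic connectivity is inferred from anomeric-carbon-to-exocyclic-
    oxygen distances below ``bond_cutoff``; each tree is rooted at the
    residue bonded to an asparagine ND2. Fragments without an Asn
    attachment are returned as orphans rather than dropped.
    """
    carb_res = [
        (cid, num, name)
        for (cid, num, name) in model.residues()
        if name.upper() in carb_codes
    ]
    if not carb_res:
        return []

    carb_keys = [(cid, num) for cid, num, _ in carb_res]
    atom_lists = {key: model.residue_atoms(*key) for key in carb_keys}

    # acceptor oxygens: exocyclic O2/O3/O4/O6 of carbohydrate residues
    acceptor_idx: list[int] = []
    acceptor_res: list[tuple[str, int]] = []
    for key in carb_keys:
        for i in atom_lists[key]:
            if model.atoms[i].atom_name in ("O2", "O3", "O4", "O6"):
                acceptor_idx.append(i)
                acceptor_res.append(key)
    # asparagine ND2 attachment points
    asn_idx = [
        i
        for i, a in enumerate(model.atoms)
        if a.residue_name == "ASN" and a.atom_name == "ND2"
    ]

    acceptor_xyz = model.coords(acceptor_idx) if acceptor_idx else np.zeros((0, 3))
    asn_xyz = model.coords(asn_idx) if asn_idx else np.zeros((0, 3))

    parent: dict[tuple[str, int], tuple[str, int] | None] = {}
    linkage_o: dict[tuple[str, int], str] = {}
    attachment: dict[tuple[str, int], tuple[str, int]] = {}
    for key in carb_keys:
        ai = _anomeric_carbon(model, atom_lists[key])
        parent[key] = None
        if ai is None:
            continue
        pos = model.atoms[ai].xyz
        anum = model.atoms[ai].atom_name[1:]
        if len(acceptor_idx) > 0:
            d = np.linalg.norm(acceptor_xyz - pos, axis=1)
            d[[acceptor_res[j] == key for j in range(len(acceptor_res))]] = np.inf
            j = int(np.argmin(d))
            if d[j] < bond_cutoff:
                parent[key] = acceptor_res[j]
                oxy = model.atoms[acceptor_idx[j]].atom_name
                linkage_o[key] = f"{anum}-{oxy[1:]}"
                continue
        if len(asn_idx) > 0:
            d = np.linalg.norm(asn_xyz - pos, axis=1)
            j = int(np.argmin(d))
            if d[j] < bond_cutoff:
                asn = model.atoms[asn_idx[j]]
                attachment[key] = (asn.chain_id, asn.residue_number)
                linkage_o[key] = f"{anum}-ND2"

    children: dict[tuple[str, int], list[tuple[str, int]]] = {k: [] for k in carb_keys}
    roots = []
    for key in carb_keys:
        if parent[key] is None:
            roots.append(key)
        else:
            children[parent[key]].append(key)

    out: list[GlycanTopology] = []
    for root in roots:
        topo = _build_tree(model, root, children, parent, linkage_o, attachment.get(root))
        topo.validate()
        out.append(topo)
    return out


def _build_tree(model, root, children, parent, linkage_o, attachment) -> GlycanTopology:
    node_id = lambda k: f"{k[0]}/{k[1]}"
    res_name = {(c, n): name for c, n, name in model.residues()}

    labels: dict[tuple[str, int], str] = {}

    def assign(key, parent_label: str | None, via: str) -> str:
        code = res_name[key].upper()
        if parent_label is None:
            lab = "GlcNAc1" if attachment is not None else f"{code}@{key[1]}"
        elif parent_label == "GlcNAc1":
            lab = "Fuc" if code in FUCOSE_CODES else "GlcNAc2"
        elif parent_label == "GlcNAc2":
            lab = "Man3"
        elif parent_label == "Man3":
            lab = "Man4'" if via.endswith("-6") else "Man4"
        elif parent_label == "Man4":
            lab = "GlcNAc5"
        elif parent_label == "Man4'":
            lab = "GlcNAc5'"
        elif parent_label == "GlcNAc5":
            lab = "Gal6"
        elif parent_label == "GlcNAc5'":
            lab = "Gal6'"
        else:
            lab = f"{code}@{key[1]}"
        # guarantee uniqueness for non-canonical trees
        base, n = lab, 2
        while lab in labels.values():
            lab = f"{base}#{n}"
            n += 1
        return lab

    residues: list[GlycanResidue] = []
    stack: list[tuple[tuple[str, int], str | None]] = [(root, None)]
    while stack:
        key, plabel = stack.pop(0)
        via = linkage_o.get(key, "?")
        lab = assign(key, plabel, via)
        labels[key] = lab
        residues.append(
            GlycanResidue(
                node_id=node_id(key),
                code=res_name[key].upper(),
                label=lab,
                parent=node_id(parent[key]) if parent[key] is not None else None,
                linkage=via,
                chain_id=key[0],
                residue_number=key[1],
            )
        )
        # deterministic child order: by residue number
        for child in sorted(children[key], key=lambda k: (k[0], k[1])):
            stack.append((child, lab))
    return GlycanTopology(attachment=attachment, residues=residues, root=node_id(root))


def bfactor_profile(
    model: StructureModel,
    glycan: GlycanTopology,
    disorder_value: float = 200.0,
    template: tuple[str, ...] = CANONICAL_LABELS,
) -> list[tuple[str, float]]:
    """Per-residue mean B-factor over a canonical glycan template.

    Residues of the template absent from the model (crystallographically
    disordered) receive ``disorder_value`` — the convention used when
    plotting B-factors of unobserved sugar residues.
    """
    by_label = {r.label: r for r in glycan.residues}
    out: list[tuple[str, float]] = []
    for label in template:
        if label in by_label:
            r = by_label[label]
            idx = model.residue_atoms(r.chain_id, r.residue_number)
            bs = [model.atoms[i].b_factor for i in idx if not model.atoms[i].is_hydrogen]
            out.append((label, float(np.mean(bs))))
        else:
            out.append((label, float(disorder_value)))
    for r in glycan.residues:  # non-template residues, if any, come last
        if r.label not in template:
            idx = model.residue_atoms(r.chain_id, r.residue_number)
            bs = [model.atoms[i].b_factor for i in idx if not model.atoms[i].is_hydrogen]
            out.append((r.label, float(np.mean(bs))))
    return out
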