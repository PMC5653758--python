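"""PDB structure I/O, atom selection and rigid-body superposition.

Coordinates follow the PDB convention throughout: 1-based author residue
numbering, chain identifiers as deposited, lengths in Å, B-factors in Å².
Parsing and serialization are delegated to gemmi; this module defines the
flat in-memory model the rest of the package works with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    SelectionError,
    StructureFormatError,
    SuperpositionError,
)

__all__ = [
    "Atom",
    "StructureModel",
    "SuperpositionResult",
    "read_structure",
    "write_structure",
    "select_atoms",
    "parse_selection",
    "superpose",
    "matched_ca_indices",
]


@dataclass(frozen=True)
class Atom:
    """One atom record after alternate-location resolution."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    b_factor: float
    occupancy: float
    is_hetero: bool
    alt_loc: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class StructureModel:
    """A flat list of atoms from one model of a coordinate file."""

    atoms: list[Atom] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """(n, 3) coordinate array, optionally restricted to ``indices``."""
        sel = self.atoms if indices is None else [self.atoms[i] for i in indices]
        if not sel:
            return np.zeros((0, 3))
        return np.array([[a.x, a.y, a.z] for a in sel], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_number, residue_name) triples."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_number, a.residue_name), None)
        return list(seen)

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid-body fit of a mobile onto a reference coordinate set.

    ``rotation`` is proper (det = +1); the fitted mobile coordinates are
    ``mobile @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _resolve_altlocs(raw: list[Atom]) -> list[Atom]:
    """Keep one atom per (chain, residue, atom name): highest occupancy,
    first listed on ties."""
    best: dict[tuple[str, int, str], tuple[int, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for idx, atom in enumerate(raw):
        key = (atom.chain_id, atom.residue_number, atom.atom_name)
        if key not in best:
            best[key] = (idx, atom)
            order.append(key)
        elif atom.occupancy > best[key][1].occupancy:
            best[key] = (idx, atom)
    return [best[k][1] for k in order]


def read_structure(path: str | Path) -> StructureModel:
    """Read the first model of a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (first listed wins ties); hydrogens are retained and flagged via
    :attr:`Atom.is_hydrogen`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    raw: list[Atom] = []
    for chain in model:
        for residue in chain:
            is_het = residue.het_flag == "H"
            for atom in residue:
                raw.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        b_factor=atom.b_iso,
                        occupancy=atom.occ,
                        is_hetero=is_het,
                        alt_loc=atom.altloc if atom.altloc != "\x00" else "",
                    )
                )
    if not raw:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    resolved = [replace(a, alt_loc="") for a in _resolve_altlocs(raw)]
    return StructureModel(atoms=resolved, name=path.stem)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as a fixed-column PDB file.

    Round-trips through :func:`read_structure` preserve coordinates to
    3 decimals and B-factors to 2 decimals (the format's precision).
    """
    if len(model) == 0:
        raise EmptyStructureError("refusing to write an empty model")
    for a in model.atoms:
        # classic fixed-column PDB allots columns 18-20 to the residue name;
        # the 4-character codes of the remediated CCD do not fit this dialect
        if len(a.residue_name) > 3:
            raise ValueError(
                f"residue name {a.residue_name!r} exceeds the 3-character "
                "PDB column width"
            )
        if len(a.atom_name) > 4:
            raise ValueError(f"atom name {a.atom_name!r} exceeds 4 characters")
        if len(a.chain_id) > 1:
            raise ValueError(f"chain id {a.chain_id!r} exceeds 1 character")
    # group atoms by chain and residue first: gemmi containers copy on add,
    # so objects must be complete before insertion
    chain_order: list[str] = []
    residues: dict[str, list[tuple[tuple[int, str], list[Atom]]]] = {}
    for a in model.atoms:
        if a.chain_id not in residues:
            residues[a.chain_id] = []
            chain_order.append(a.chain_id)
        rlist = residues[a.chain_id]
        rkey = (a.residue_number, a.residue_name)
        if not rlist or rlist[-1][0] != rkey:
            rlist.append((rkey, []))
        rlist[-1][1].append(a)
    st = gemmi.Structure()
    st.name = model.name or "model"
    gm = gemmi.Model("1")
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for (num, rname), atoms in residues[cid]:
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(num, " ")
            res.het_flag = "H" if atoms[0].is_hetero else "A"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(a.x, a.y, a.z)
                at.b_iso = a.b_factor
                at.occ = a.occupancy
                res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def _as_ranges(residues) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for r in residues:
        if isinstance(r, int):
            out.append((r, r))
        else:
            lo, hi = r
            out.append((int(lo), int(hi)))
    return out


def select_atoms(
    model: StructureModel,
    chain: str | None = None,
    residues: Iterable[int | tuple[int, int]] | None = None,
    names: Iterable[str] | None = None,
    heavy_only: bool = False,
    hetero: bool | None = None,
    residue_names: Iterable[str] | None = None,
) -> list[int]:
    """Order-preserving atom index selection.

    Residue ranges are inclusive at both ends; disjoint ranges concatenate.
    An empty result triggers a warning, not an error.
    """
    if chain is not None and chain not in model.chains():
        raise SelectionError(f"chain {chain!r} not in model (chains: {model.chains()})")
    ranges = _as_ranges(residues) if residues is not None else None
    name_set = {n.upper() for n in names} if names is not None else None
    rname_set = {n.upper() for n in residue_names} if residue_names is not None else None
    out: list[int] = []
    for i, a in enumerate(model.atoms):
        if chain is not None and a.chain_id != chain:
            continue
        if ranges is not None and not any(lo <= a.residue_number <= hi for lo, hi in ranges):
            continue
        if name_set is not None and a.atom_name.upper() not in name_set:
            continue
        if rname_set is not None and a.residue_name.upper() not in rname_set:
            continue
        if heavy_only and a.is_hydrogen:
            continue
        if hetero is not None and a.is_hetero != hetero:
            continue
        out.append(i)
    if not out:
        warnings.warn("selection matched no atoms", stacklevel=2)
    return out


def parse_selection(text: str) -> dict:
    """Parse the selection mini-language into :func:`select_atoms` keywords.

    Clauses joined by ``and``:

    * ``chain A``
    * ``resi 233-239,247-292`` (inclusive ranges, comma-separated)
    * ``name CA,CB``
    * ``resn NAG,FUC``
    * ``heavy`` / ``hetero`` / ``protein``
    """
    kwargs: dict = {}
    for clause in text.split(" and "):
        clause = clause.strip()
        if not clause:
            continue
        parts = clause.split(None, 1)
        key = parts[0].lower()
        if key == "chain":
            kwargs["chain"] = parts[1].strip()
        elif key == "resi":
            ranges: list[int | tuple[int, int]] = []
            for item in parts[1].split(","):
                if "-" in item.strip().lstrip("-"):
                    lo, hi = item.strip().rsplit("-", 1)
                    ranges.append((int(lo), int(hi)))
                else:
                    ranges.append(int(item))
            kwargs["residues"] = ranges
        elif key == "name":
            kwargs["names"] = [n.strip() for n in parts[1].split(",")]
        elif key == "resn":
            kwargs["residue_names"] = [n.strip() for n in parts[1].split(",")]
        elif key == "heavy":
            kwargs["heavy_only"] = True
        elif key == "hetero":
            kwargs["hetero"] = True
        elif key == "protein":
            kwargs["hetero"] = False
        else:
            raise SelectionError(f"unknown selection clause {clause!r}")
    return kwargs


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    pairing: Sequence[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Kabsch least-squares rigid-body fit of ``mobile`` onto ``reference``.

    ``pairing`` optionally gives (mobile_index, reference_index) pairs;
    without it the arrays are assumed already paired row-by-row. Reflections
    are excluded, so the returned rotation is always proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pairing is not None:
        mi = [p[0] for p in pairing]
        ri = [p[1] for p in pairing]
        mobile = mobile[mi]
        reference = reference[ri]
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SuperpositionError(
            f"paired coordinate sets must have matching (n, 3) shapes, "
            f"got {mobile.shape} and {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 paired atoms, got {n}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    # collinear point sets leave the rotation about the line undetermined
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise SuperpositionError("degenerate (collinear) coordinate geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def matched_ca_indices(
    model_a: StructureModel, model_b: StructureModel
) -> tuple[list[int], list[int]]:
    """Sequence-matched Cα pairing between two models.

    Pairs Cα atoms of residues present in both models with identical chain
    id and author residue number (hydrogens and heteroatoms excluded).
    """

    def ca_map(m: StructureModel) -> dict[tuple[str, int], int]:
        out = {}
        for i, a in enumerate(m.atoms):
            if a.atom_name == "CA" and not a.is_hetero and not a.is_hydrogen:
                out.setdefault((a.chain_id, a.residue_number), i)
        return out

    map_a = ca_map(model_a)
    map_b = ca_map(model_b)
    keys = [k for k in map_a if k in map_b]
    return [map_a[k] for k in keys], [map_b[k] for k in keys]
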