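"""PDB structure handling: parsing, chain stripping, contacts, and burial.

Structures back two curation rules: a mutated residue is rejected when any
of its atoms lies within a cutoff (default 5 Å) of a foreign atom — an atom
on another chain or a non-water heteroatom — and a residue is called Buried
or Surface by its relative solvent accessibility (20% threshold).

Hydrogens are ignored throughout (most deposited structures lack them);
water (HOH/WAT/DOD) never counts as a contact partner.  Only the first
model of a multi-model file is read, and for alternate conformations the
highest-occupancy altloc is kept (ties broken alphabetically).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import gemmi
import numpy as np
from biotite.structure import AtomArray, sasa as _shrake_rupley
from scipy.spatial import cKDTree

from .taxonomy import ValidationError

__all__ = [
    "Atom",
    "Structure",
    "BurialLabel",
    "read_pdb",
    "write_pdb",
    "strip_to_chain",
    "has_foreign_contact",
    "relative_sasa",
    "chain_sequence",
    "MAX_SASA",
    "VDW_RADII",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: van der Waals radii (Å) used for SASA; unknown elements fall back to 1.80.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.80

#: Theoretical maximum solvent accessibility per residue (Å², Tien et al. 2013),
#: the denominator of relative SASA.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    chain: str
    position: str          # residue number + optional insertion code
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    het: bool = False      # HETATM record


@dataclass
class Structure:
    """Ordered atomic coordinates of one model."""

    atoms: list[Atom]
    model_number: int = 1
    name: str = ""

    def __post_init__(self):
        for a in self.atoms:
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise ValidationError(f"non-finite coordinates on atom {a}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float).reshape(-1, 3)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residue_atoms(self, chain: str, position: str) -> list[Atom]:
        position = str(position).strip()
        return [
            a for a in self.atoms
            if a.chain == chain and a.position == position and not a.het
        ]


class PDBParseError(ValueError):
    pass


def _is_hydrogen(element: str, atom_name: str) -> bool:
    return element.upper() in ("H", "D") or (not element and atom_name.startswith("H"))


def _position_str(seqid: gemmi.SeqId) -> str:
    icode = seqid.icode.strip()
    return f"{seqid.num}{icode}"


def read_pdb(path) -> Structure:
    """Parse a PDB file into a :class:`Structure` (model 1, heavy atoms).

    Altlocs are resolved to the highest-occupancy conformer (ties broken
    alphabetically by altloc id).  Malformed files raise
    :class:`PDBParseError` carrying gemmi's line diagnostic.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            # pick one conformer per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                if _is_hydrogen(at.element.name, at.name):
                    continue
                prev = by_name.get(at.name)
                if prev is None or (at.occ, -ord(at.altloc or "~")) > (
                    prev.occ, -ord(prev.altloc or "~")
                ):
                    by_name[at.name] = at
            order = {at.name: i for i, at in enumerate(res)}
            for name in sorted(by_name, key=order.get):
                at = by_name[name]
                atoms.append(
                    Atom(
                        chain=chain.name,
                        position=_position_str(res.seqid),
                        res_name=res.name,
                        atom_name=at.name,
                        element=at.element.name.upper(),
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        het=het,
                    )
                )
    return Structure(atoms=atoms, model_number=1, name=Path(path).stem)


def write_pdb(structure: Structure, path) -> None:
    """Write a :class:`Structure` to PDB via gemmi."""
    # gemmi's add_residue/add_chain copy their argument, so each level must
    # be fully populated before being added to its parent
    grouped: dict[str, list[tuple[tuple[str, str], list[Atom]]]] = {}
    for a in structure.atoms:
        residues = grouped.setdefault(a.chain, [])
        key = (a.position, a.res_name)
        if not residues or residues[-1][0] != key:
            residues.append((key, []))
        residues[-1][1].append(a)

    st = gemmi.Structure()
    st.name = structure.name or "ddgbench"
    model = gemmi.Model("1")
    for chain_name in structure.chains():
        chain = gemmi.Chain(chain_name)
        for (position, res_name), res_atoms in grouped[chain_name]:
            res = gemmi.Residue()
            res.name = res_name
            num, icode = position, " "
            if num and num[-1].isalpha():
                num, icode = num[:-1], num[-1]
            res.seqid = gemmi.SeqId(int(num), icode)
            res.het_flag = "H" if res_atoms[0].het else "A"
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element.capitalize())
                at.pos = gemmi.Position(a.x, a.y, a.z)
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def strip_to_chain(structure: Structure, chain: str) -> Structure:
    """Keep only the ATOM records of one chain (waters and HETATMs removed)."""
    if chain not in structure.chains():
        raise LookupError(f"chain {chain!r} not in structure (has {structure.chains()})")
    kept = [
        a for a in structure.atoms
        if a.chain == chain and not a.het and a.res_name not in WATER_NAMES
    ]
    return Structure(atoms=kept, model_number=structure.model_number,
                     name=structure.name)


def has_foreign_contact(
    structure: Structure, chain: str, position: str, cutoff: float = 5.0
) -> bool:
    """True if any atom of the residue is within ``cutoff`` Å of a foreign atom.

    Foreign atoms are (a) atoms on any other chain, or (b) non-water HETATM
    atoms on any chain (ligands of the same chain count); water never counts.
    """
    res_atoms = structure.residue_atoms(chain, position)
    if not res_atoms:
        raise LookupError(f"residue {chain}/{position} not found")
    foreign = [
        a for a in structure.atoms
        if a.res_name not in WATER_NAMES and (a.chain != chain or a.het)
    ]
    if not foreign:
        return False
    res_xyz = np.array([[a.x, a.y, a.z] for a in res_atoms])
    tree = cKDTree(np.array([[a.x, a.y, a.z] for a in foreign]))
    dists, _ = tree.query(res_xyz, k=1)
    return bool(np.min(dists) <= cutoff)


@dataclass(frozen=True)
class BurialLabel:
    """Relative solvent accessibility of a residue with its Buried/Surface call."""

    relative_sasa: float
    label: str  # "Buried" or "Surface"

    BURIED_MAX = 0.20  # relative SASA ≤ 20% → Buried, > 20% → Surface

    @classmethod
    def from_relative(cls, rel: float) -> "BurialLabel":
        return cls(relative_sasa=rel, label="Buried" if rel <= cls.BURIED_MAX else "Surface")


def _sasa_per_atom(structure: Structure, point_number: int = 960,
                   probe_radius: float = 1.4) -> np.ndarray:
    """Shrake–Rupley SASA (Å²) for every non-water heavy atom, in atom order."""
    atoms = [a for a in structure.atoms if a.res_name not in WATER_NAMES]
    n = len(atoms)
    if n == 0:
        raise ValidationError("structure has no non-water heavy atoms")
    arr = AtomArray(n)
    arr.coord = np.array([[a.x, a.y, a.z] for a in atoms], dtype=np.float32)
    arr.chain_id[:] = [a.chain[:4] for a in atoms]
    arr.res_name[:] = [a.res_name[:5] for a in atoms]
    arr.atom_name[:] = [a.atom_name[:6] for a in atoms]
    arr.element[:] = [a.element[:2] for a in atoms]
    arr.res_id[:] = np.arange(n)  # unused; sasa only needs coords + radii
    radii = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_VDW) for a in atoms])
    return _shrake_rupley(
        arr, probe_radius=probe_radius, point_number=point_number, vdw_radii=radii
    )


def relative_sasa(
    structure: Structure, chain: str, position: str, point_number: int = 960
) -> BurialLabel:
    """Relative solvent accessibility of one residue in the given structure.

    The residue's summed atomic SASA is divided by the theoretical maximum
    for its residue type (``MAX_SASA``); since the maxima are tabulated in
    tripeptide context, an isolated residue can exceed them slightly and
    the ratio is capped at 1.  Callers wanting monomer burial should strip
    to the mutated chain first.
    """
    res_atoms = structure.residue_atoms(chain, position)
    if not res_atoms:
        raise LookupError(f"residue {chain}/{position} not found")
    res_name = res_atoms[0].res_name
    if res_name not in MAX_SASA:
        raise ValidationError(f"no reference maximum SASA for residue {res_name!r}")
    atoms = [a for a in structure.atoms if a.res_name not in WATER_NAMES]
    per_atom = _sasa_per_atom(structure, point_number=point_number)
    mask = np.array(
        [a.chain == chain and a.position == str(position).strip() and not a.het
         for a in atoms]
    )
    rel = min(1.0, float(per_atom[mask].sum() / MAX_SASA[res_name]))
    return BurialLabel.from_relative(rel)


def residue_relative_sasa_map(
    structure: Structure, chain: str, point_number: int = 960
) -> dict[str, BurialLabel]:
    """Burial labels for every standard residue of a chain in one SASA pass.

    Equivalent to calling :func:`relative_sasa` per residue but computes the
    atomic SASA of the structure once, which matters when labelling every
    mutation site of a large parent.
    """
    atoms = [a for a in structure.atoms if a.res_name not in WATER_NAMES]
    per_atom = _sasa_per_atom(structure, point_number=point_number)
    sums: dict[str, float] = {}
    names: dict[str, str] = {}
    for a, s in zip(atoms, per_atom):
        if a.chain != chain or a.het:
            continue
        sums[a.position] = sums.get(a.position, 0.0) + float(s)
        names.setdefault(a.position, a.res_name)
    out: dict[str, BurialLabel] = {}
    for pos, total in sums.items():
        if names[pos] in MAX_SASA:
            out[pos] = BurialLabel.from_relative(min(1.0, total / MAX_SASA[names[pos]]))
    return out


def chain_sequence(structure: Structure, chain: str) -> tuple[str, list[str]]:
    """One-letter sequence of a chain plus the parallel list of positions.

    Non-standard residues are skipped; the positions list maps sequence
    index → author numbering, which curation uses to align positions
    between homologous parents.
    """
    seq: list[str] = []
    positions: list[str] = []
    seen: set[str] = set()
    for a in structure.atoms:
        if a.chain != chain or a.het or a.res_name not in THREE_TO_ONE:
            continue
        if a.position in seen:
            continue
        seen.add(a.position)
        seq.append(THREE_TO_ONE[a.res_name])
        positions.append(a.position)
    return "".join(seq), positions
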