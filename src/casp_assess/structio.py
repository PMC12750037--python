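"""Structure I/O: parsing, evaluation-unit extraction, residue correspondence, χ-angles.

Structures are held in light dataclasses carrying exactly what the assessment
metrics need: author numbering, named heavy atoms, coordinates in Å, and the
B-factor column (which carries predictor pLDDT in submitted models).  Parsing
and writing of PDB/mmCIF is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "EUDefinition",
    "Correspondence",
    "FormatError",
    "parse_structure",
    "write_structure",
    "extract_eu",
    "map_residues",
    "chi_angles",
    "dihedral",
    "CHI_ATOMS",
    "SYMMETRIC_CHI",
    "STANDARD_AA",
]

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Nonstandard residues mapped to their parent standard residue for metric purposes.
NONSTANDARD_PARENT = {
    "MSE": "MET",
    "SEC": "CYS",
    "PYL": "LYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

#: χ-angle atom quadruples per residue type, conventional rotamer definitions.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
        ("CD", "NE", "CZ", "NH1"),
    ],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

#: χ index (1-based) whose terminal group is 2-fold symmetric: compared modulo 180°.
SYMMETRIC_CHI = {"ASP": 2, "GLU": 3, "PHE": 2, "TYR": 2, "ARG": 5}


class FormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class AtomRecord:
    """One heavy atom: PDB atom name, element, coordinates in Å, B-factor, occupancy.

    In predicted models the B-factor column carries the predictor's pLDDT on a
    0–100 scale; in experimental targets it is the temperature factor.
    """

    atom_name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.atom_name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def parent_name(self) -> str:
        """Standard parent residue name (MSE → MET etc.)."""
        return NONSTANDARD_PARENT.get(self.res_name, self.res_name)

    @property
    def is_standard(self) -> bool:
        return self.parent_name in STANDARD_AA

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coord


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"structure {self.id}: duplicate residue identifiers")

    def residue_map(self) -> dict[tuple[str, int, str], Residue]:
        return {r.key: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class EUDefinition:
    """One evaluation unit: residue ranges of a target scored as a unit.

    ``weight`` is 1/N for a target split into N units so each target counts
    equally in the final sum.  ``versions`` lists the structure ids of
    alternative conformations; metrics take the maximum over versions.
    """

    target_id: str
    eu_id: str
    ranges: list[tuple[str, int, int]]
    weight: float = 1.0
    versions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ranges:
            raise ValueError(f"EU {self.eu_id}: empty range list")
        for chain, start, end in self.ranges:
            if end < start:
                raise ValueError(f"EU {self.eu_id}: inverted range {chain}:{start}-{end}")

    def contains(self, chain: str, number: int) -> bool:
        return any(c == chain and s <= number <= e for c, s, e in self.ranges)


@dataclass
class Correspondence:
    """One-to-one pairing of target and model residue indices."""

    pairs: list[tuple[int, int]]
    coverage: float
    mismatched_names: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.pairs = sorted(self.pairs)
        t_idx = [p[0] for p in self.pairs]
        m_idx = [p[1] for p in self.pairs]
        if len(set(t_idx)) != len(t_idx) or len(set(m_idx)) != len(m_idx):
            raise ValueError("correspondence is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Parsing / writing


def _prescan_pdb(text: str) -> None:
    # gemmi's error text does not name the offending line for bad coordinate
    # fields, so validate the fixed coordinate columns up front.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: unparseable coordinate field {fieldtxt!r}"
                    ) from None


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to first in file."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        name = atom.name
        if name not in best:
            best[name] = atom
            order.append(name)
        elif atom.occ > best[name].occ:
            best[name] = atom
    return [best[n] for n in order]


def _from_gemmi(st: gemmi.Structure, structure_id: str) -> Structure:
    residues: list[Residue] = []
    ligands: list[Residue] = []
    if len(st) == 0:
        raise FormatError("empty structure: no models")
    model = st[0]
    for chain in model:
        for gres in chain:
            atoms = [
                AtomRecord(
                    atom_name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    bfactor=a.b_iso,
                    occupancy=a.occ,
                )
                for a in _resolve_altlocs(gres)
                if not a.is_hydrogen()
            ]
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            res = Residue(
                chain_id=chain.name,
                seq_number=gres.seqid.num,
                insertion_code=icode,
                res_name=gres.name,
                atoms=atoms,
            )
            is_polymer = gres.het_flag == "A" or res.parent_name in STANDARD_AA
            if gres.name == "HOH":
                continue
            if is_polymer:
                residues.append(res)
            else:
                ligands.append(res)
    if not residues and not ligands:
        raise FormatError("empty structure: no atoms parsed")
    if not residues:
        raise FormatError("structure contains no polymer residues")
    return Structure(id=structure_id, residues=residues, ligands=ligands)


def parse_structure(text: str, format: str = "pdb", structure_id: str = "") -> Structure:
    """Parse PDB or mmCIF text into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy copy (ties to
    the first in file); HETATM groups other than water are routed to
    ``ligands``; hydrogens are dropped.
    """
    if not text.strip():
        raise FormatError("empty input text")
    if format == "pdb":
        _prescan_pdb(text)
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as exc:
            raise FormatError(f"PDB parse failed: {exc}") from exc
    elif format in ("mmcif", "cif"):
        try:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        except (RuntimeError, ValueError) as exc:
            raise FormatError(f"mmCIF parse failed: {exc}") from exc
    else:
        raise FormatError(f"unsupported format {format!r}")
    st.setup_entities()
    return _from_gemmi(st, structure_id or st.name or "structure")


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def add(res: Residue, het: str) -> None:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        gres.het_flag = het
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.atom_name
            ga.element = gemmi.Element(a.element or a.atom_name[0])
            ga.pos = gemmi.Position(*a.coord)
            ga.b_iso = a.bfactor
            ga.occ = a.occupancy
            gres.add_atom(ga)
        chains[res.chain_id].add_residue(gres)

    for res in s.residues:
        add(res, "A" if res.parent_name in STANDARD_AA else "H")
    for res in s.ligands:
        add(res, "H")
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_structure(s: Structure) -> str:
    """Render a :class:`Structure` as PDB text (round-trips through ``parse_structure``)."""
    st = _to_gemmi(s)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# EU extraction and residue correspondence


def extract_eu(s: Structure, eu: EUDefinition, ligand_cutoff: float = 5.0) -> Structure:
    """Restrict a structure to one evaluation unit.

    Keeps exactly the residues whose (chain, author number) fall in the EU's
    inclusive ranges, order preserved.  Ligands are retained only if any of
    their atoms lies within ``ligand_cutoff`` Å of a kept residue.
    """
    present_chains = {r.chain_id for r in s.residues}
    for chain, _, _ in eu.ranges:
        if chain not in present_chains:
            raise ValueError(f"EU {eu.eu_id}: chain {chain!r} absent from structure {s.id}")
    kept = [r for r in s.residues if eu.contains(r.chain_id, r.seq_number)]
    if not kept:
        raise ValueError(f"EU {eu.eu_id}: no residues selected from {s.id}")
    kept_xyz = np.array([a.coord for r in kept for a in r.atoms])
    ligands = []
    for lig in s.ligands:
        lig_xyz = np.array([a.coord for a in lig.atoms])
        d2 = ((lig_xyz[:, None, :] - kept_xyz[None, :, :]) ** 2).sum(-1)
        if d2.min() <= ligand_cutoff**2:
            ligands.append(lig)
    return Structure(id=f"{s.id}:{eu.eu_id}", residues=kept, ligands=ligands)


def map_residues(target: Structure, model: Structure) -> Correspondence:
    """Pair residues by identical (chain, author number, insertion code).

    CASP models share the target's numbering, so no sequence alignment is
    attempted; residue-name mismatches at paired positions are recorded.
    """
    if not target.residues or not model.residues:
        raise ValueError("cannot map empty structures")
    model_index = {r.key: i for i, r in enumerate(model.residues)}
    pairs: list[tuple[int, int]] = []
    mismatched: list[tuple[str, int, str]] = []
    for ti, tres in enumerate(target.residues):
        mi = model_index.get(tres.key)
        if mi is None:
            continue
        pairs.append((ti, mi))
        if model.residues[mi].parent_name != tres.parent_name:
            mismatched.append(tres.key)
    if not pairs:
        raise ValueError(
            f"no common residue numbering between {target.id} and {model.id}"
        )
    return Correspondence(
        pairs=pairs,
        coverage=len(pairs) / len(target.residues),
        mismatched_names=mismatched,
    )


# ---------------------------------------------------------------------------
# Dihedrals


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (−180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def chi_angles(r: Residue) -> list[float]:
    """Sidechain χ1..χk in degrees per the conventional rotamer quadruples.

    Gly/Ala (and residues with no χ definition) return []; a missing sidechain
    atom truncates the list at the first undefined angle.
    """
    quads = CHI_ATOMS.get(r.parent_name)
    if not quads:
        return []
    out: list[float] = []
    for quad in quads:
        coords = [r.coord(name) for name in quad]
        if any(c is None for c in coords):
            break
        out.append(dihedral(*coords))
    return out
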