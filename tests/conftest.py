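"""Shared fixtures and structure-building helpers."""

import numpy as np
import pytest

from casp_assess.structio import AtomRecord, Residue, Structure

TINY_PDB = """ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00           C
ATOM      2  CA  ALA A   2      12.560   8.700  -4.200  1.00  0.00           C
END
"""

TINY_MMCIF = """data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
ATOM 1 C CA . ALA A 1 1 A 11.104 6.134 -6.504 1.00 0.00
ATOM 2 C CA . ALA A 2 2 A 12.560 8.700 -4.200 1.00 0.00
"""


def ca_structure(coords, sid="toy", chain="A", start=1, res_name="ALA", bfactors=None):
    """Structure of single-Cα residues at the given coordinates."""
    residues = []
    for i, xyz in enumerate(np.asarray(coords, dtype=float)):
        b = 0.0 if bfactors is None else float(bfactors[i])
        residues.append(
            Residue(chain, start + i, "", res_name,
                    [AtomRecord("CA", "C", xyz, bfactor=b)])
        )
    return Structure(id=sid, residues=residues)


def noncollinear_chain(n, spacing=3.8, wobble=1.2, seed=0):
    """A Cα trace with generic (non-degenerate) geometry."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        step = rng.normal(size=3)
        step = step / np.linalg.norm(step) * spacing
        pts.append(pts[-1] + step + rng.normal(0, wobble * 0.1, 3))
    return np.array(pts)


def random_rotation(seed=0):
    """A uniformly random proper rotation matrix."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def transform_structure(s, R, t):
    """Return a copy of s with R·x + t applied to every atom."""
    out_res = []
    for r in s.residues:
        atoms = [
            AtomRecord(a.atom_name, a.element, R @ a.coord + t, a.bfactor, a.occupancy)
            for a in r.atoms
        ]
        out_res.append(Residue(r.chain_id, r.seq_number, r.insertion_code, r.res_name, atoms))
    return Structure(id=s.id + "_moved", residues=out_res, ligands=s.ligands)


@pytest.fixture
def tiny_pdb():
    return TINY_PDB


@pytest.fixture
def tiny_mmcif():
    return TINY_MMCIF


@pytest.fixture
def helix30():
    from casp_assess.synthetic import SyntheticSpec, build_target

    spec = SyntheticSpec(
        n_res=30, topology=[("helix", 10), ("coil", 10), ("strand", 10)], seed=11
    )
    return build_target(spec)
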