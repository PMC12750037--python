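"""Synthetic targets, decoys, and score tables for exercising the pipeline.

``build_target`` constructs a toy protein from ideal internal coordinates
(standard bond lengths/angles, segment-typed φ/ψ, template rotamers for a
curated sidechain palette).  ``make_decoy`` degrades a target with Gaussian
coordinate noise, χ-angle perturbation (rebuilding distal atoms by rotation
about the χ bond), and a noisy per-residue self-estimate written into the
B-factor column on the pLDDT 0–100 convention.  ``simulate_experiment``
draws full score tables from a latent group-skill × target-difficulty model
with missing submissions, for testing the ranking machinery.

All randomness flows from a single seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranking import RANKING_METRICS, SCORE_COLUMNS
from .structio import CHI_ATOMS, AtomRecord, Residue, Structure

__all__ = [
    "SyntheticSpec",
    "LatentExperiment",
    "build_target",
    "make_decoy",
    "simulate_experiment",
    "place_atom",
]

# Ideal backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.4
OMEGA = 180.0

#: φ/ψ per segment type; coil is sampled uniformly within these ranges.
SEGMENT_PHIPSI = {
    "helix": ((-57.0, -57.0), (-47.0, -47.0)),
    "strand": ((-120.0, -120.0), (120.0, 120.0)),
    "coil": ((-150.0, -60.0), (-50.0, 150.0)),
}

# Sidechain topology: atom → ((ref_a, ref_b, ref_c), bond, angle, dihedral spec).
# The dihedral spec is ("chi", k, offset) or a fixed value in degrees.
SIDECHAIN_TOPOLOGY: dict[str, list] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 122.6)),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.3, 0.0),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, ("chi", 5, 0.0)),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, ("chi", 5, 180.0)),
    ],
}

#: Template rotamer χ values per palette residue.
TEMPLATE_CHI = {
    "SER": [-65.0],
    "LEU": [-60.0, 175.0],
    "PHE": [-65.0, 90.0],
    "ARG": [-60.0, 180.0, 180.0, 180.0, 0.0],
    "ALA": [],
    "GLY": [],
}

#: Atoms distal to each χ bond (rotate when the χ is perturbed).
CHI_ROTATING_ATOMS = {
    "SER": {1: ["OG"]},
    "LEU": {1: ["CG", "CD1", "CD2"], 2: ["CD1", "CD2"]},
    "PHE": {
        1: ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        2: ["CD1", "CD2", "CE1", "CE2", "CZ"],
    },
    "ARG": {
        1: ["CG", "CD", "NE", "CZ", "NH1", "NH2"],
        2: ["CD", "NE", "CZ", "NH1", "NH2"],
        3: ["NE", "CZ", "NH1", "NH2"],
        4: ["CZ", "NH1", "NH2"],
        5: ["NH1", "NH2"],
    },
}

_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], "C")


@dataclass
class SyntheticSpec:
    """Parameters of the toy target/decoy generative model."""

    n_res: int = 30
    topology: list = field(default_factory=lambda: [("helix", 30)])
    residue_palette: list = field(
        default_factory=lambda: ["SER", "LEU", "PHE", "ARG", "ALA", "GLY"]
    )
    sigma_xyz: float = 0.0      # Å, i.i.d. Gaussian coordinate noise
    sigma_chi: float = 0.0      # degrees, Gaussian χ perturbation
    plddt_tau: float = 0.0      # pLDDT noise sd on the 0–100 scale
    seed: int = 0

    def __post_init__(self):
        if self.n_res != sum(length for _, length in self.topology):
            raise ValueError("n_res must equal the sum of segment lengths")
        if min(self.sigma_xyz, self.sigma_chi, self.plddt_tau) < 0:
            raise ValueError("noise parameters must be ≥ 0")


@dataclass
class LatentExperiment:
    """Latent skill × difficulty model behind simulated score tables.

    Metric values are clip(scale × (base + skill_g − difficulty_t + model
    noise + metric noise), 0, 100); MolProbity is emitted on its inverted
    scale (lower = better).  Whole (group, EU) submissions are dropped with
    probability ``p_missing``.
    """

    n_groups: int = 20
    n_targets: int = 30
    eus_per_target: int = 1
    skill_sd: float = 10.0       # spread of latent group skill (2× noise_sd)
    difficulty_sd: float = 10.0
    noise_sd: float = 5.0
    p_missing: float = 0.1
    n_models: int = 5
    base: float = 70.0
    metric_loadings: dict = field(
        default_factory=lambda: {m: (1.0, 1.0) for m in RANKING_METRICS}
    )
    skill: np.ndarray | None = None
    difficulty: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Internal-coordinate building (NeRF)


def place_atom(a, b, c, bond: float, angle: float, dih: float) -> np.ndarray:
    """Position atom D bonded to C with |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = dih (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(dih)
    d_local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor), -bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _phi_psi(spec: SyntheticSpec, rng: np.random.Generator):
    phis, psis = [], []
    for kind, length in spec.topology:
        if kind not in SEGMENT_PHIPSI:
            raise ValueError(f"unknown segment type {kind!r}")
        (plo, phi_hi), (qlo, qhi) = SEGMENT_PHIPSI[kind]
        for _ in range(length):
            phis.append(rng.uniform(plo, phi_hi) if plo != phi_hi else plo)
            psis.append(rng.uniform(qlo, qhi) if qlo != qhi else qlo)
    return phis, psis


def build_target(spec: SyntheticSpec) -> Structure:
    """Build a toy target from ideal internal coordinates, deterministically.

    Backbone from segment-typed φ/ψ (helix ≈ −57/−47, strand ≈ −120/+120,
    coil sampled in allowed ranges); sidechains from template rotamers of the
    residue palette.  Chain A, residues numbered from 1, B-factors 0.
    """
    rng = np.random.default_rng(spec.seed)
    phis, psis = _phi_psi(spec, rng)
    n = spec.n_res

    # backbone trace
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psis[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phis[i])

    residues = []
    for i in range(n):
        res_name = spec.residue_palette[i % len(spec.residue_palette)]
        if res_name not in SIDECHAIN_TOPOLOGY:
            raise ValueError(f"residue {res_name!r} not in the curated palette")
        coords = {"N": N[i], "CA": CA[i], "C": C[i]}
        psi_ref = psis[i] if i < n - 1 else psis[i]
        nxt = N[i + 1] if i < n - 1 else place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi_ref)
        coords["O"] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi_ref + 180.0)
        if res_name != "GLY":
            coords["CB"] = place_atom(C[i], N[i], CA[i], B_CA_CB, A_N_CA_CB, 122.6)
        chi = TEMPLATE_CHI[res_name]
        for atom_name, refs, bond, angle, dspec in SIDECHAIN_TOPOLOGY[res_name]:
            if isinstance(dspec, tuple):
                _, k, offset = dspec
                dih = chi[k - 1] + offset
            else:
                dih = dspec
            coords[atom_name] = place_atom(
                coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, angle, dih
            )
        atoms = [
            AtomRecord(name, _element_of(name), xyz, bfactor=0.0)
            for name, xyz in coords.items()
        ]
        residues.append(Residue("A", i + 1, "", res_name, atoms))
    return Structure(id=f"synth_{spec.seed}", residues=residues)


# ---------------------------------------------------------------------------
# Decoys


def _rotate_about_axis(xyz: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float):
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)
    return (xyz - origin) @ R.T + origin


def make_decoy(
    target: Structure,
    spec: SyntheticSpec,
    swap_segment: tuple[int, int, float] | None = None,
) -> Structure:
    """Degrade a target into a model with graded accuracy and a pLDDT estimate.

    χ-angles are perturbed first (rotating distal atoms about the χ bond by a
    Gaussian of sd ``sigma_chi``), then i.i.d. Gaussian noise of sd
    ``sigma_xyz`` is added to every atom.  Optionally a residue range
    ``swap_segment = (start, end, angle)`` is rigidly rotated about its own
    first principal axis, emulating a domain-orientation error.  Per-residue
    pLDDT = clamp(realized lDDT + N(0, plddt_tau), 0, 100) is written to
    every atom's B-factor.
    """
    rng = np.random.default_rng(spec.seed + 1)
    residues = []
    for res in target.residues:
        coords = {a.atom_name: a.coord.copy() for a in res.atoms}
        if spec.sigma_chi > 0:
            for k, moving in sorted(CHI_ROTATING_ATOMS.get(res.res_name, {}).items()):
                quad = CHI_ATOMS[res.res_name][k - 1]
                if any(q not in coords for q in quad):
                    continue
                delta = rng.normal(0.0, spec.sigma_chi)
                origin = coords[quad[1]]
                axis = coords[quad[2]] - origin
                for name in moving:
                    if name in coords:
                        coords[name] = _rotate_about_axis(
                            coords[name][None, :], origin, axis, delta
                        )[0]
        atoms = [
            AtomRecord(
                name,
                _element_of(name),
                xyz + rng.normal(0.0, spec.sigma_xyz, size=3),
            )
            for name, xyz in coords.items()
        ]
        residues.append(Residue(res.chain_id, res.seq_number, res.insertion_code, res.res_name, atoms))
    model = Structure(id=f"{target.id}_decoy", residues=residues)

    if swap_segment is not None:
        start, end, angle = swap_segment
        seg = [r for r in model.residues if start <= r.seq_number <= end]
        xyz = np.array([a.coord for r in seg for a in r.atoms])
        origin = xyz.mean(axis=0)
        axis = np.linalg.svd(xyz - origin)[2][0]
        k = 0
        rotated = _rotate_about_axis(xyz, origin, axis, angle)
        for r in seg:
            for a in r.atoms:
                a.coord = rotated[k]
                k += 1

    # realized per-residue lDDT → noisy pLDDT in the B-factor column
    from .metrics import lddt
    from .structio import map_residues

    corr = map_residues(target, model)
    _, per_res = lddt(target, model, corr)
    for res in model.residues:
        true_lddt = per_res.get(res.key, 0.0)
        plddt = float(np.clip(true_lddt + rng.normal(0.0, spec.plddt_tau), 0.0, 100.0))
        for a in res.atoms:
            a.bfactor = plddt
    return model


# ---------------------------------------------------------------------------
# Latent score-table simulation


def simulate_experiment(x: LatentExperiment, seed: int = 0) -> pd.DataFrame:
    """Draw a long-form score table from the latent skill/difficulty model.

    Returns a DataFrame with the standard columns (group, target, eu, phase,
    model, metric, value).  Latent skills/difficulties are drawn unless
    supplied on the experiment; group order follows skill order g01, g02, …
    """
    rng = np.random.default_rng(seed)
    skill = (
        np.asarray(x.skill, dtype=float)
        if x.skill is not None
        else rng.normal(0.0, x.skill_sd, size=x.n_groups)
    )
    difficulty = (
        np.asarray(x.difficulty, dtype=float)
        if x.difficulty is not None
        else rng.normal(0.0, x.difficulty_sd, size=x.n_targets)
    )
    records = []
    for g in range(x.n_groups):
        for t in range(x.n_targets):
            for e in range(x.eus_per_target):
                eu_id = f"T{t:03d}-D{e + 1}"
                if rng.uniform() < x.p_missing:
                    continue
                for model in range(1, x.n_models + 1):
                    eps_model = rng.normal(0.0, x.noise_sd)
                    latent = x.base + skill[g] - difficulty[t] + eps_model
                    for metric, (scale, mnoise) in x.metric_loadings.items():
                        q = latent + rng.normal(0.0, x.noise_sd * mnoise)
                        if metric == "MolProbity":
                            value = float(np.clip(6.0 - q * scale / 20.0, 0.0, 6.0))
                        else:
                            value = float(np.clip(q * scale, 0.0, 100.0))
                        records.append(
                            (f"g{g + 1:02d}", f"T{t:03d}", eu_id, 1, model, metric, value)
                        )
    df = pd.DataFrame(records, columns=SCORE_COLUMNS)
    df.attrs["skill"] = [float(v) for v in skill]
    df.attrs["difficulty"] = [float(v) for v in difficulty]
    return df
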