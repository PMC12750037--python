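"""Structure-comparison metrics.

All superposition-based scores (GDT family, GDC family, AL0_P) are computed
on a rigid Kabsch superposition with reflections forbidden.  The GDT search
uses a seed-and-extend heuristic validated against an exhaustive subset
oracle at small sizes.  lDDT is superposition-free.  ASE quantifies the
agreement between a model's submitted per-residue confidence (pLDDT, from
the B-factor column) and the realized per-residue lDDT.  AAA scores
sidechain χ-angle accuracy with a 40° tolerance.

Scores are on a 0–100 scale throughout (100 = perfect).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .structio import (
    CHI_ATOMS,
    SYMMETRIC_CHI,
    Correspondence,
    Residue,
    Structure,
    chi_angles,
)

__all__ = [
    "SuperpositionResult",
    "GDTResult",
    "kabsch_superpose",
    "gdt",
    "gdc",
    "al0_p",
    "lddt",
    "ase",
    "aaa",
    "site_mean",
    "compute_metrics",
    "GDT_TS_CUTOFFS",
    "GDT_HA_CUTOFFS",
    "SC_CHARACTERISTIC_ATOM",
    "INTERNAL_METRICS",
]

GDT_TS_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_CUTOFFS = (0.5, 1.0, 2.0, 4.0)

#: Characteristic distal sidechain atom per residue type for GDC_SC (Gly has none).
SC_CHARACTERISTIC_ATOM = {
    "ALA": "CB", "ARG": "NH1", "ASN": "OD1", "ASP": "OD1", "CYS": "SG",
    "GLN": "OE1", "GLU": "OE1", "HIS": "NE2", "ILE": "CD1", "LEU": "CD1",
    "LYS": "NZ", "MET": "CE", "PHE": "CZ", "PRO": "CG", "SER": "OG",
    "THR": "OG1", "TRP": "CH2", "TYR": "OH", "VAL": "CG1",
}

MAINCHAIN_ATOMS = ("N", "CA", "C", "O")

#: Metrics this module computes internally (ranking also consumes external ones).
INTERNAL_METRICS = (
    "GDT_TS", "GDT_HA", "GDC_SC", "GDC_MC", "GDC_ALL", "AL0_P", "lDDT", "QSE", "AAA",
)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray          # 3x3 proper rotation
    translation: np.ndarray       # 3-vector, Å
    rmsd: float
    support: frozenset = field(default_factory=frozenset)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def kabsch_superpose(P: np.ndarray, Q: np.ndarray, support=None) -> SuperpositionResult:
    """Least-squares rigid superposition of points Q onto P (no reflection).

    Returns rotation R and translation t minimizing ||R q + t − p||; the
    reported rmsd is the minimized value over the fitted points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required for a rigid superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: rank of either centred set < 2
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)
    diff = Q @ R.T + t - P
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd,
        support=frozenset(support) if support is not None else frozenset(range(n)),
    )


# ---------------------------------------------------------------------------
# GDT


@dataclass
class GDTResult:
    score: float                       # 100 × mean of per-cutoff fractions
    fractions: dict                    # cutoff → best fraction
    superposition: SuperpositionResult  # best Cα superposition found
    n_residues: int                    # denominator (paired target residues)


def _paired_ca(target: Structure, model: Structure, corr: Correspondence):
    """Cα coordinates for correspondence pairs; rows with missing model Cα dropped
    from the fit but retained in the denominator."""
    P, Q, idx = [], [], []
    n_denom = 0
    for k, (ti, mi) in enumerate(corr.pairs):
        tca = target.residues[ti].coord("CA")
        if tca is None:
            continue
        n_denom += 1
        mca = model.residues[mi].coord("CA")
        if mca is None:
            continue
        P.append(tca)
        Q.append(mca)
        idx.append(k)
    if n_denom == 0:
        raise ValueError("no paired Cα atoms")
    return np.array(P), np.array(Q), idx, n_denom


def _count_within(P, Q, sup, cutoff) -> np.ndarray:
    dev = np.linalg.norm(sup.apply(Q) - P, axis=1)
    return dev <= cutoff


def gdt(
    target: Structure,
    model: Structure,
    corr: Correspondence,
    cutoffs=GDT_TS_CUTOFFS,
    mode: str = "heuristic",
) -> GDTResult:
    """Global distance test over Cα atoms.

    For each cutoff, searches for the rigid superposition maximizing the
    number of paired Cα atoms within the cutoff.  The production search
    (``heuristic``) is exact by subset enumeration when n ≤ 12 (where that
    is affordable) and a windowed seed-and-extend otherwise: contiguous
    windows of length 3, 5, 7 and the full chain seed fits that are
    iteratively recomputed on the residues within the cutoff (with a refit
    margin), capped at 10 iterations.  ``windows`` forces the seed-and-extend
    path at any size (used to validate it); ``exhaustive`` fits on every
    residue subset of size ≥ 3 and is only permitted for ≤ 12 residues; it
    is the oracle the windowed search is compared against.

    The returned superposition is the candidate with the largest total
    within-cutoff count summed over cutoffs (ties to lower rmsd); it is the
    fixed frame for GDC and AL0_P.
    """
    if not corr.pairs:
        raise ValueError("empty correspondence")
    cutoffs = tuple(cutoffs)
    if any(c <= 0 for c in cutoffs) or list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be positive and ascending")
    if mode not in ("heuristic", "windows", "exhaustive"):
        raise ValueError(f"unknown GDT mode {mode!r}")
    P, Q, _, n_denom = _paired_ca(target, model, corr)
    n = len(P)

    if n < 3:
        # cannot superpose: all counted as failures
        zero = SuperpositionResult(np.eye(3), np.zeros(3), float("inf"))
        return GDTResult(0.0, {c: 0.0 for c in cutoffs}, zero, n_denom)
    if mode == "exhaustive" and n > 12:
        raise ValueError("exhaustive GDT mode limited to ≤ 12 residues")

    carr = np.asarray(cutoffs)
    best_count = {c: 0 for c in cutoffs}
    best_sup = {c: None for c in cutoffs}
    best_total = -1
    best_rep = None

    def consider(sup):
        nonlocal best_total, best_rep
        dev = np.linalg.norm(sup.apply(Q) - P, axis=1)
        counts = (dev[:, None] <= carr[None, :]).sum(axis=0)
        for c, cnt in zip(cutoffs, counts):
            cnt = int(cnt)
            if cnt > best_count[c]:
                best_count[c] = cnt
                best_sup[c] = sup
        total = int(counts.sum())
        if total > best_total or (total == best_total and best_rep is not None
                                  and sup.rmsd < best_rep.rmsd):
            best_total = total
            best_rep = sup
        return dev

    # exact subset enumeration: always for the exhaustive oracle, and for the
    # production search whenever it is affordable (n ≤ 12)
    if mode == "exhaustive" or (mode == "heuristic" and n <= 12):
        for size in range(3, n + 1):
            for s in itertools.combinations(range(n), size):
                try:
                    consider(kabsch_superpose(P[list(s)], Q[list(s)], support=s))
                except ValueError:
                    continue  # collinear subset

    # windowed seed-and-extend: contiguous windows of length 3/5/7 and the
    # full chain seed a fit; the fit is iteratively re-computed on the
    # residues within the cutoff (optionally widened by a margin) until the
    # selected set is stable, at most 10 iterations
    if mode in ("windows",) or (mode == "heuristic" and n > 12):
        seeds = []
        for w in (3, 5, 7, n):
            if w > n:
                continue
            seeds.extend(list(range(s, s + w)) for s in range(n - w + 1))
        for seed in seeds:
            try:
                sup0 = kabsch_superpose(P[seed], Q[seed], support=seed)
            except ValueError:
                continue
            dev0 = consider(sup0)
            for c in cutoffs:
                for margin in (0.0, 1.0):
                    sup, dev = sup0, dev0
                    prev = frozenset(seed)
                    for _ in range(10):
                        sel = frozenset(np.flatnonzero(dev <= c + margin))
                        if len(sel) < 3 or sel == prev:
                            break
                        prev = sel
                        try:
                            sup = kabsch_superpose(P[list(sel)], Q[list(sel)], support=sel)
                        except ValueError:
                            break
                        dev = consider(sup)

    fractions = {c: best_count[c] / n_denom for c in cutoffs}
    score = 100.0 * float(np.mean([fractions[c] for c in cutoffs]))
    rep = best_rep if best_rep is not None else SuperpositionResult(
        np.eye(3), np.zeros(3), float("inf")
    )
    return GDTResult(score, fractions, rep, n_denom)


# ---------------------------------------------------------------------------
# GDC


def _selected_atoms(res: Residue, selector: str) -> list[str]:
    if selector == "sc":
        name = SC_CHARACTERISTIC_ATOM.get(res.parent_name)
        return [name] if name else []
    if selector == "mc":
        return [n for n in MAINCHAIN_ATOMS if res.atom(n) is not None]
    if selector == "all":
        return [a.atom_name for a in res.atoms]
    raise ValueError(f"unknown GDC selector {selector!r}")


def gdc(
    target: Structure,
    model: Structure,
    corr: Correspondence,
    atom_selector: str = "all",
    sup: SuperpositionResult | None = None,
):
    """Global distance calculation over selected atoms under a fixed superposition.

    GDC = 100 × Σ_{k=1..10} (11−k)·P_k / 55 where P_k is the fraction of
    selected target atoms whose model counterpart lies within k·0.5 Å under
    ``sup`` (conventionally the GDT_TS-optimal Cα superposition).  Selector
    ``sc`` uses one characteristic distal sidechain atom per residue type,
    ``mc`` the backbone N/CA/C/O, ``all`` every heavy atom.  Atoms missing
    from the model count as failures at every threshold.

    Returns ``(score, per_residue)`` where ``per_residue`` maps residue key
    to its own GDC over its selected atoms.
    """
    if sup is None:
        sup = gdt(target, model, corr, GDT_TS_CUTOFFS).superposition
    weights = np.array([11 - k for k in range(1, 11)], dtype=float)  # sums to 55
    thresholds = np.array([0.5 * k for k in range(1, 11)])

    per_residue: dict = {}
    passes = []  # one row of 10 booleans per selected target atom
    res_of_atom = []
    for ti, mi in corr.pairs:
        tres, mres = target.residues[ti], model.residues[mi]
        for name in _selected_atoms(tres, atom_selector):
            tc = tres.coord(name)
            if tc is None:
                continue
            mc = mres.coord(name)
            if mc is None:
                row = np.zeros(10, dtype=bool)
            else:
                d = float(np.linalg.norm(sup.apply(mc[None, :])[0] - tc))
                row = d <= thresholds
            passes.append(row)
            res_of_atom.append(tres.key)
    if not passes:
        raise ValueError(f"no atoms selected for GDC selector {atom_selector!r}")
    passes = np.array(passes)
    fractions = passes.mean(axis=0)
    score = 100.0 * float(weights @ fractions) / 55.0
    for key in set(res_of_atom):
        rows = passes[[i for i, k in enumerate(res_of_atom) if k == key]]
        per_residue[key] = 100.0 * float(weights @ rows.mean(axis=0)) / 55.0
    return score, per_residue


# ---------------------------------------------------------------------------
# AL0_P


def al0_p(
    target: Structure,
    model: Structure,
    corr: Correspondence,
    sup: SuperpositionResult | None = None,
    cutoff: float = 3.8,
) -> float:
    """Percentage of residues correctly aligned under the Cα superposition.

    Residue i counts iff the superposed model Cα_i lies within ``cutoff`` Å
    of target Cα_i and target Cα_i is the nearest target Cα to model Cα_i.
    """
    if not corr.pairs:
        raise ValueError("empty correspondence")
    if sup is None:
        sup = gdt(target, model, corr, GDT_TS_CUTOFFS).superposition
    t_ca = np.array([
        r.coord("CA") for r in target.residues if r.coord("CA") is not None
    ])
    count = 0
    n_denom = 0
    for ti, mi in corr.pairs:
        tc = target.residues[ti].coord("CA")
        if tc is None:
            continue
        n_denom += 1
        mc = model.residues[mi].coord("CA")
        if mc is None:
            continue
        mc_sup = sup.apply(mc[None, :])[0]
        d = float(np.linalg.norm(mc_sup - tc))
        if d > cutoff:
            continue
        dists = np.linalg.norm(t_ca - mc_sup, axis=1)
        if np.isclose(dists.min(), d, rtol=0, atol=1e-9):
            count += 1
    if n_denom == 0:
        raise ValueError("no paired Cα atoms")
    return 100.0 * count / n_denom


# ---------------------------------------------------------------------------
# lDDT


def lddt(
    target: Structure,
    model: Structure,
    corr: Correspondence,
    inclusion_radius: float = 15.0,
    thresholds=(0.5, 1.0, 2.0, 4.0),
):
    """Local distance difference test, superposition-free.

    The reference set is every heavy-atom pair from different target residues
    closer than ``inclusion_radius``.  A pair is preserved at threshold t iff
    |d_model − d_target| ≤ t; pairs with either atom absent from the model are
    not preserved.  Per-residue lDDT is the mean over thresholds of the
    preserved fraction among pairs involving that residue (0–100); the global
    score is the mean of per-residue values.

    Returns ``(global_score, per_residue)``.
    """
    if len(corr.pairs) < 2:
        raise ValueError("lDDT requires at least 2 paired residues")
    model_of = {ti: mi for ti, mi in corr.pairs}
    t_xyz, m_xyz, res_idx = [], [], []
    for ti, tres in enumerate(target.residues):
        mres = model.residues[model_of[ti]] if ti in model_of else None
        for atom in tres.atoms:
            t_xyz.append(atom.coord)
            res_idx.append(ti)
            mc = mres.coord(atom.atom_name) if mres is not None else None
            m_xyz.append(mc if mc is not None else np.full(3, np.nan))
    t_xyz = np.array(t_xyz)
    m_xyz = np.array(m_xyz)
    res_idx = np.array(res_idx)

    dT = np.linalg.norm(t_xyz[:, None, :] - t_xyz[None, :, :], axis=-1)
    with np.errstate(invalid="ignore"):
        dM = np.linalg.norm(m_xyz[:, None, :] - m_xyz[None, :, :], axis=-1)
    iu = np.triu_indices(len(t_xyz), k=1)
    mask = (dT[iu] < inclusion_radius) & (res_idx[iu[0]] != res_idx[iu[1]])
    if not mask.any():
        raise ValueError("no reference atom pairs within the inclusion radius")
    ai, aj = iu[0][mask], iu[1][mask]
    diff = np.abs(dM[ai, aj] - dT[ai, aj])  # NaN where model atom missing

    thresholds = np.asarray(thresholds, dtype=float)
    with np.errstate(invalid="ignore"):
        preserved = diff[:, None] <= thresholds[None, :]  # NaN → False

    per_residue: dict = {}
    for ti in np.unique(res_idx):
        involve = (res_idx[ai] == ti) | (res_idx[aj] == ti)
        if not involve.any():
            continue
        frac = preserved[involve].mean(axis=0)  # per-threshold preserved fraction
        per_residue[target.residues[int(ti)].key] = 100.0 * float(frac.mean())
    global_score = float(np.mean(list(per_residue.values())))
    return global_score, per_residue


# ---------------------------------------------------------------------------
# ASE (self-estimate agreement, the assessment's QSE)


def ase(model: Structure, lddt_per_res: dict) -> float:
    """Agreement between submitted pLDDT and realized lDDT.

    ASE = 100 − mean_i |pLDDT_i − lDDT_i|, clamped to [0, 100]; pLDDT is read
    from the model's Cα B-factor on the 0–100 scale.
    """
    plddt = {}
    for r in model.residues:
        a = r.atom("CA")
        if a is not None:
            plddt[r.key] = a.bfactor
    if not plddt or all(v == 0 for v in plddt.values()):
        raise ValueError("model carries no self-estimate (all B-factors zero/absent)")
    diffs = [
        abs(plddt[key] - score)
        for key, score in lddt_per_res.items()
        if key in plddt
    ]
    if not diffs:
        raise ValueError("no residues with both pLDDT and lDDT")
    return float(np.clip(100.0 - np.mean(diffs), 0.0, 100.0))


# ---------------------------------------------------------------------------
# AAA (sidechain χ-angle accuracy)


def _circular_diff(a: float, b: float, period: float = 360.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def aaa(
    target: Structure,
    model: Structure,
    corr: Correspondence,
    tolerance: float = 40.0,
) -> float:
    """Average sidechain χ-angle accuracy.

    Per residue: 100 × (χ-angles within ``tolerance``° of the target) /
    (χ-angles defined in the target); the comprehensive score is the
    unweighted mean over residues with ≥ 1 target χ-angle.  Dihedrals of
    2-fold-symmetric terminal groups (Asp/Phe/Tyr χ2, Glu χ3, Arg χ5) are
    compared modulo 180°.
    """
    per_res = []
    for ti, mi in corr.pairs:
        tres, mres = target.residues[ti], model.residues[mi]
        t_chi = chi_angles(tres)
        if not t_chi:
            continue
        m_chi = chi_angles(mres) if mres.parent_name == tres.parent_name else []
        sym_idx = SYMMETRIC_CHI.get(tres.parent_name)
        hits = 0
        for k, tval in enumerate(t_chi, start=1):
            if k > len(m_chi):
                break
            period = 180.0 if k == sym_idx else 360.0
            if _circular_diff(tval, m_chi[k - 1], period) <= tolerance:
                hits += 1
        per_res.append(100.0 * hits / len(t_chi))
    if not per_res:
        raise ValueError("no paired residues with χ-angles")
    return float(np.mean(per_res))


# ---------------------------------------------------------------------------
# Site aggregation


def site_mean(per_res: dict, site: set):
    """Mean per-residue score over a residue set and over its complement.

    Site members absent from ``per_res`` are ignored with a warning.
    Returns ``(site_mean, complement_mean)``; the complement mean is NaN when
    every scored residue is in the site.
    """
    members = [k for k in site if k in per_res]
    missing = [k for k in site if k not in per_res]
    if missing:
        warnings.warn(f"{len(missing)} site residues not scored; ignored")
    if not members:
        raise ValueError("site has no scored residues")
    others = [k for k in per_res if k not in site]
    smean = float(np.mean([per_res[k] for k in members]))
    cmean = float(np.mean([per_res[k] for k in others])) if others else float("nan")
    return smean, cmean


# ---------------------------------------------------------------------------
# Convenience: full internal metric vector


def compute_metrics(target: Structure, model: Structure, corr: Correspondence | None = None) -> dict:
    """All internally computed metrics for one model against one target.

    Returns GDT_TS, GDT_HA, GDC_SC, GDC_MC, GDC_ALL, AL0_P, lDDT, QSE (= ASE),
    and AAA on the 0–100 scale.  Metrics whose preconditions fail (e.g. no
    χ-bearing residues for AAA, no pLDDT for QSE) are reported as NaN.
    """
    from .structio import map_residues

    if corr is None:
        corr = map_residues(target, model)
    out: dict = {}
    ts = gdt(target, model, corr, GDT_TS_CUTOFFS)
    ha = gdt(target, model, corr, GDT_HA_CUTOFFS)
    out["GDT_TS"] = ts.score
    out["GDT_HA"] = ha.score
    sup = ts.superposition
    for key, selector in (("GDC_SC", "sc"), ("GDC_MC", "mc"), ("GDC_ALL", "all")):
        try:
            out[key], per_res = gdc(target, model, corr, selector, sup)
            if key == "GDC_ALL":
                out["_gdc_all_per_res"] = per_res
        except ValueError:
            out[key] = float("nan")
    out["AL0_P"] = al0_p(target, model, corr, sup)
    glob, per_res_lddt = lddt(target, model, corr)
    out["lDDT"] = glob
    out["_lddt_per_res"] = per_res_lddt
    try:
        out["QSE"] = ase(model, per_res_lddt)
    except ValueError:
        out["QSE"] = float("nan")
    try:
        out["AAA"] = aaa(target, model, corr)
    except ValueError:
        out["AAA"] = float("nan")
    return out
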