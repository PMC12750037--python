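"""Structure-comparison metrics: superposition, GDT/GDC, AL0_P, lDDT, ASE, AAA."""

import numpy as np
import pytest
from scipy.optimize import minimize

from casp_assess.metrics import (
    GDT_HA_CUTOFFS,
    GDT_TS_CUTOFFS,
    SuperpositionResult,
    aaa,
    al0_p,
    ase,
    compute_metrics,
    gdc,
    gdt,
    kabsch_superpose,
    lddt,
    site_mean,
)
from casp_assess.structio import AtomRecord, Residue, Structure, map_residues
from casp_assess.synthetic import SyntheticSpec, build_target, make_decoy

from conftest import ca_structure, noncollinear_chain, random_rotation, transform_structure

IDENTITY_SUP = SuperpositionResult(np.eye(3), np.zeros(3), 0.0)


def brute_force_rotation_rmsd(P, Q):
    """Oracle: minimize RMSD over proper rotations parameterized by quaternions."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rot(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def cost(q):
        return np.sqrt(((Qc @ rot(q).T - Pc) ** 2).sum() / len(P))

    rng = np.random.default_rng(0)
    best = np.inf
    for _ in range(40):
        res = minimize(cost, rng.normal(size=4), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self):
        P = noncollinear_chain(5)
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_translation_recovered(self):
        P = noncollinear_chain(5)
        Q = P + [5.0, 0.0, 0.0]
        res = kabsch_superpose(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.translation, [-5.0, 0.0, 0.0], atol=1e-9)

    def test_mirror_image_no_reflection(self):
        P = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0.4, 0.4, 1.5]])
        Q = P * [1, 1, -1]  # mirror of a chiral set
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1
        assert res.rmsd == pytest.approx(brute_force_rotation_rmsd(P, Q), abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear(self):
        P = np.arange(12, dtype=float).reshape(4, 3)
        P = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(P, P)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_recovers_random_rigid_motion(self, seed):
        P = noncollinear_chain(8, seed=seed)
        R = random_rotation(seed)
        Q = (P - [1, 2, 3]) @ R.T  # some rigid placement of the same shape
        res = kabsch_superpose(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)


def displaced_six():
    """6-residue target; model identical except residue 6's Cα moved far away
    (beyond every GDT cutoff under any superposition of the rest)."""
    pts = noncollinear_chain(6, seed=3)
    t = ca_structure(pts, sid="t")
    mpts = pts.copy()
    mpts[5] += [30.0, 0.0, 0.0]
    m = ca_structure(mpts, sid="m")
    return t, m, map_residues(t, m)


class TestGDT:
    def test_identity_is_100(self, helix30):
        corr = map_residues(helix30, helix30)
        for cuts in (GDT_TS_CUTOFFS, GDT_HA_CUTOFFS):
            assert gdt(helix30, helix30, corr, cuts).score == 100.0

    @pytest.mark.parametrize("mode", ["heuristic", "exhaustive"])
    def test_one_displaced_residue(self, mode):
        t, m, corr = displaced_six()
        for cuts in (GDT_TS_CUTOFFS, GDT_HA_CUTOFFS):
            res = gdt(t, m, corr, cuts, mode)
            assert res.score == pytest.approx(100 * 5 / 6, abs=1e-6)

    def test_heuristic_equals_oracle_on_random_toys(self):
        rng = np.random.default_rng(10)
        for i in range(20):
            spec0 = SyntheticSpec(n_res=8, topology=[("coil", 8)], residue_palette=["ALA"], seed=600 + i)
            t = build_target(spec0)
            spec = SyntheticSpec(n_res=8, topology=[("coil", 8)], residue_palette=["ALA"],
                                 sigma_xyz=float(rng.uniform(0.3, 3.0)), seed=600 + i)
            m = make_decoy(t, spec)
            corr = map_residues(t, m)
            h = gdt(t, m, corr, GDT_TS_CUTOFFS, "heuristic").score
            e = gdt(t, m, corr, GDT_TS_CUTOFFS, "exhaustive").score
            assert h == pytest.approx(e, abs=1e-9)

    def test_windowed_search_bounded_by_oracle(self):
        """The large-size windowed search never exceeds, and closely tracks, the oracle."""
        gaps = []
        for i in range(15):
            spec0 = SyntheticSpec(n_res=8, topology=[("coil", 8)], residue_palette=["ALA"], seed=700 + i)
            t = build_target(spec0)
            spec = SyntheticSpec(n_res=8, topology=[("coil", 8)], residue_palette=["ALA"],
                                 sigma_xyz=1.0, seed=700 + i)
            m = make_decoy(t, spec)
            corr = map_residues(t, m)
            w = gdt(t, m, corr, GDT_TS_CUTOFFS, "windows").score
            e = gdt(t, m, corr, GDT_TS_CUTOFFS, "exhaustive").score
            assert w <= e + 1e-9
            gaps.append(e - w)
        assert np.mean(gaps) < 5.0

    def test_exhaustive_size_limit(self):
        pts = noncollinear_chain(13)
        s = ca_structure(pts)
        corr = map_residues(s, s)
        with pytest.raises(ValueError, match="12"):
            gdt(s, s, corr, GDT_TS_CUTOFFS, "exhaustive")

    def test_rigid_motion_invariance(self, helix30):
        corr = map_residues(helix30, helix30)
        moved = transform_structure(helix30, random_rotation(9), np.array([3.0, 4.0, 5.0]))
        assert gdt(helix30, moved, corr, GDT_TS_CUTOFFS).score == pytest.approx(100.0, abs=1e-6)


def one_atom_target(displacement):
    t = Structure(id="t", residues=[
        Residue("A", 1, "", "ALA", [AtomRecord("CB", "C", [0.0, 0.0, 0.0])]),
    ])
    m = Structure(id="m", residues=[
        Residue("A", 1, "", "ALA", [AtomRecord("CB", "C", [displacement, 0.0, 0.0])]),
    ])
    return t, m, map_residues(t, m)


class TestGDC:
    def test_identity_all_selectors(self, helix30):
        corr = map_residues(helix30, helix30)
        for sel in ("sc", "mc", "all"):
            score, _ = gdc(helix30, helix30, corr, sel, IDENTITY_SUP)
            assert score == 100.0

    def test_single_atom_displaced_2p2(self):
        # 2.2 Å passes thresholds 2.5..5.0 (k = 5..10): Σ(11−k) = 21 → 100·21/55
        t, m, corr = one_atom_target(2.2)
        score, per_res = gdc(t, m, corr, "sc", IDENTITY_SUP)
        assert score == pytest.approx(100 * 21 / 55, abs=1e-9)
        assert per_res[("A", 1, "")] == pytest.approx(score)

    def test_beyond_5A_is_zero(self):
        t, m, corr = one_atom_target(5.5)
        score, _ = gdc(t, m, corr, "sc", IDENTITY_SUP)
        assert score == 0.0

    def test_all_gly_sc_errors(self):
        t = ca_structure(noncollinear_chain(4), res_name="GLY")
        corr = map_residues(t, t)
        with pytest.raises(ValueError, match="no atoms"):
            gdc(t, t, corr, "sc", IDENTITY_SUP)

    def test_missing_model_atom_counts_as_failure(self, helix30):
        model = transform_structure(helix30, np.eye(3), np.zeros(3))
        model.residues[0].atoms = [a for a in model.residues[0].atoms if a.atom_name != "CA"]
        corr = map_residues(helix30, model)
        score, _ = gdc(helix30, model, corr, "mc", IDENTITY_SUP)
        assert score < 100.0


class TestAL0P:
    def test_identity(self, helix30):
        corr = map_residues(helix30, helix30)
        assert al0_p(helix30, helix30, corr, IDENTITY_SUP) == 100.0

    def test_one_displaced(self):
        t, m, corr = displaced_six()
        assert al0_p(t, m, corr, IDENTITY_SUP) == pytest.approx(100 * 5 / 6)

    def test_register_shift_scores_zero(self):
        # model Cα_i placed exactly on target Cα_{i+1} (cyclic): nearest-neighbor
        # condition fails everywhere
        n = 8
        ang = 2 * np.pi * np.arange(n) / n
        radius = 3.0 / (2 * np.sin(np.pi / n))  # chord between neighbors = 3.0 Å
        pts = np.c_[radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)]
        t = ca_structure(pts)
        m = ca_structure(np.roll(pts, -1, axis=0))
        corr = map_residues(t, m)
        assert al0_p(t, m, corr, IDENTITY_SUP) == 0.0


def triangle_structures():
    """3 single-atom residues: target distances (5, 7, 6), model (5, 10, 6)."""
    t = ca_structure([[0, 0, 0], [5, 0, 0], [3.8, 5.8788, 0]])
    m = ca_structure([[0, 0, 0], [5, 0, 0], [8.9, 4.5596, 0]])
    return t, m, map_residues(t, m)


class TestLDDT:
    def test_identity(self, helix30):
        corr = map_residues(helix30, helix30)
        glob, per_res = lddt(helix30, helix30, corr)
        assert glob == 100.0
        assert all(v == 100.0 for v in per_res.values())

    def test_hand_enumerated_triangle(self):
        t, m, corr = triangle_structures()
        assert np.linalg.norm(t.residues[2].coord("CA") - t.residues[0].coord("CA")) == pytest.approx(7.0, abs=1e-3)
        assert np.linalg.norm(m.residues[2].coord("CA") - m.residues[0].coord("CA")) == pytest.approx(10.0, abs=1e-3)
        glob, per_res = lddt(t, m, corr)
        # the 3 Å error on pair (1,3) passes only the 4 Å threshold
        assert per_res[("A", 1, "")] == pytest.approx(62.5, abs=0.1)
        assert per_res[("A", 2, "")] == pytest.approx(100.0, abs=0.1)
        assert per_res[("A", 3, "")] == pytest.approx(62.5, abs=0.1)
        assert glob == pytest.approx(75.0, abs=0.1)

    def test_missing_model_atom_penalized(self, helix30):
        model = transform_structure(helix30, np.eye(3), np.zeros(3))
        model.residues[2].atoms = model.residues[2].atoms[:2]
        corr = map_residues(helix30, model)
        glob, _ = lddt(helix30, model, corr)
        assert glob < 100.0

    def test_superposition_free(self, helix30):
        corr = map_residues(helix30, helix30)
        moved = transform_structure(helix30, random_rotation(4), np.array([10.0, 0.0, 0.0]))
        glob, _ = lddt(helix30, moved, corr)
        assert glob == 100.0  # exactly invariant to model rigid motion

    def test_far_apart_residues_error(self):
        t = ca_structure([[0, 0, 0], [100, 0, 0], [0, 100, 0]])
        corr = map_residues(t, t)
        with pytest.raises(ValueError, match="no reference"):
            lddt(t, t, corr)


class TestASE:
    def make(self, plddt, lddt_vals):
        m = ca_structure(noncollinear_chain(len(plddt)), bfactors=plddt)
        per_res = {r.key: v for r, v in zip(m.residues, lddt_vals)}
        return m, per_res

    def test_perfect_agreement(self):
        m, per_res = self.make([70, 80, 90], [70, 80, 90])
        assert ase(m, per_res) == 100.0

    def test_constant_offset_10(self):
        m, per_res = self.make([80, 90, 60], [70, 80, 50])
        assert ase(m, per_res) == pytest.approx(90.0)

    def test_maximal_disagreement(self):
        m, per_res = self.make([100, 100, 100], [0, 0, 0])
        assert ase(m, per_res) == 0.0

    def test_no_self_estimate_errors(self):
        m, per_res = self.make([0, 0, 0], [50, 50, 50])
        with pytest.raises(ValueError, match="self-estimate"):
            ase(m, per_res)


def single_chi_pair(res_name, target_chi, model_chi):
    """Target/model pair with one sidechain-bearing residue at given χs."""
    spec = SyntheticSpec(n_res=1, topology=[("helix", 1)], residue_palette=[res_name], seed=0)
    from casp_assess.synthetic import TEMPLATE_CHI

    saved = TEMPLATE_CHI[res_name][:]
    try:
        TEMPLATE_CHI[res_name][: len(target_chi)] = target_chi
        t = build_target(spec)
        TEMPLATE_CHI[res_name][: len(model_chi)] = model_chi
        m = build_target(spec)
    finally:
        TEMPLATE_CHI[res_name][:] = saved
    m = Structure(id="m", residues=m.residues)
    return t, m, map_residues(t, m)


class TestAAA:
    def test_identity(self, helix30):
        corr = map_residues(helix30, helix30)
        assert aaa(helix30, helix30, corr) == 100.0

    @pytest.mark.parametrize("offset,expected", [(39.0, 100.0), (41.0, 0.0)])
    def test_ser_threshold_boundary(self, offset, expected):
        t, m, corr = single_chi_pair("SER", [-65.0], [-65.0 + offset])
        assert aaa(t, m, corr) == pytest.approx(expected)

    def test_leu_half_within(self):
        t, m, corr = single_chi_pair("LEU", [-60.0, 175.0], [-50.0, 175.0 - 90.0])
        assert aaa(t, m, corr) == pytest.approx(50.0)

    def test_symmetric_terminal_modulo_180(self):
        # Phe χ2 ring flip (180° apart) counts as correct
        t, m, corr = single_chi_pair("PHE", [-65.0, 90.0], [-65.0, -90.0])
        assert aaa(t, m, corr) == pytest.approx(100.0)

    def test_no_chi_residues_error(self):
        t = ca_structure(noncollinear_chain(4), res_name="GLY")
        corr = map_residues(t, t)
        with pytest.raises(ValueError, match="χ"):
            aaa(t, t, corr)

    def test_circular_difference_wraps(self):
        t, m, corr = single_chi_pair("SER", [170.0], [-170.0])  # 20° apart through the wrap
        assert aaa(t, m, corr) == pytest.approx(100.0)


class TestSiteMean:
    def test_uniform(self):
        smean, cmean = site_mean({"A": 100.0, "B": 100.0}, {"A"})
        assert smean == 100.0 and cmean == 100.0

    def test_arithmetic(self):
        smean, cmean = site_mean({"A": 80.0, "B": 60.0, "C": 100.0}, {"A", "B"})
        assert smean == pytest.approx(70.0)
        assert cmean == pytest.approx(100.0)

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            site_mean({"A": 80.0}, {"Z"})

    def test_unknown_members_warn(self):
        with pytest.warns(UserWarning):
            site_mean({"A": 80.0, "B": 60.0}, {"A", "Z"})


def test_compute_metrics_identity_all_100(helix30):
    spec = SyntheticSpec(n_res=30, topology=[("helix", 10), ("coil", 10), ("strand", 10)], seed=11)
    model = make_decoy(helix30, spec)  # zero noise: exact copy with pLDDT = lDDT
    vals = compute_metrics(helix30, model)
    for key in ("GDT_TS", "GDT_HA", "GDC_SC", "GDC_MC", "GDC_ALL", "AL0_P", "lDDT", "QSE", "AAA"):
        assert vals[key] == 100.0, key
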