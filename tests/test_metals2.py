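"""Superposition: units, poses, correspondence, score, refinement."""
from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mfskit import (
    SiteSpec,
    decompose_units,
    enumerate_poses,
    make_fes4_cluster,
    make_site,
    match_correspondence,
    refine_pose,
    score_alignment,
    superpose,
)
from mfskit.config import DEFAULT_CONFIG
from mfskit.metals2 import Correspondence, Pose, ResiduePair, pose_rmsd
from mfskit.site_extraction import MFS, MetalSite
from mfskit.structure_model import Atom, Residue

from conftest import FIG1_SPEC, NOISE_SD_03, first_mfs

W111 = DEFAULT_CONFIG.replace(weights=(1.0, 1.0, 1.0))


def transformed_copy(spec, seed):
    """The same site under a random proper rigid motion."""
    stc = make_site(spec)
    rot = Rotation.random(random_state=np.random.RandomState(seed))
    shift = np.random.default_rng(seed).uniform(-25, 25, 3)
    for r in stc.residues:
        for a in r.atoms:
            a.coords = rot.apply(a.coords) + shift
    return stc, rot.as_matrix(), shift


# --------------------------------------------------------------------------
# stubs for direct score arithmetic
# --------------------------------------------------------------------------

def _aa(chain, seq, name, with_cb=True):
    atoms = [Atom("CA", "C", np.array([float(seq), 0.0, 0.0]))]
    if with_cb:
        atoms.append(Atom("CB", "C", np.array([float(seq), 1.5, 0.0])))
    return Residue(chain, seq, "", name, "amino_acid", atoms)


def _stub_mfs(residues, with_metal=False):
    metals = []
    if with_metal:
        met = Residue("M", 900, "", "ZN", "other_hetero",
                      [Atom("ZN", "Zn", np.zeros(3))])
        metals = [met.atoms[0]]
    site = MetalSite(metals=metals, donor_atoms=[], endogenous_ligands=[],
                     exogenous_ligands=[], site_id="stub")
    return MFS(site=site, environment=list(residues))


def _pair(q, t, secondary=False):
    sec = (q.atom("CB"), t.atom("CB")) if secondary else None
    return ResiduePair(q, t, "CA", (q.atom("CA"), t.atom("CA")), sec)


class TestScoreArithmetic:
    def test_hand_computed_example(self):
        """F=2 fragments of lengths (6,4), N=10, c=10, C_max=12,
        S/S_max=0.8 at unit weights: total = (1/6+1/4)/10 + ln(12/10)
        + 0.2 = 0.423988."""
        q_names = ["GLY"] * 9 + ["TRP"]
        q_seqs = list(range(1, 7)) + list(range(10, 14))
        t_seqs = list(range(1, 7)) + list(range(20, 24))
        # query: 10 CA + exactly 2 CB -> 12 matchable atoms (smaller site)
        q_res = [_aa("A", s, n, with_cb=(i < 2))
                 for i, (s, n) in enumerate(zip(q_seqs, q_names))]
        # target: 11 residues, 13 matchable atoms
        t_res = [_aa("B", s, "GLY", with_cb=(i < 2))
                 for i, s in enumerate(t_seqs)]
        t_res.append(_aa("B", 50, "GLY", with_cb=False))
        query, target = _stub_mfs(q_res), _stub_mfs(t_res)
        corr = Correspondence([_pair(q, t) for q, t in zip(q_res, t_res)])
        sb = score_alignment(corr, query, target, weights=(1, 1, 1))
        assert sb.F == 2 and sb.n_f == (6, 4) and sb.N == 10
        assert sb.c == 10 and sb.C_max == 12
        assert sb.S / sb.S_max == pytest.approx(0.8)
        assert sb.total == pytest.approx(0.423988, abs=1e-6)

    def test_perfect_self_alignment_single_fragment(self):
        res = [_aa("A", s, "ALA") for s in range(1, 21)]
        mfs = _stub_mfs(res)
        corr = Correspondence([_pair(r, r, secondary=True) for r in res])
        sb = score_alignment(corr, mfs, mfs, weights=(1, 1, 1))
        assert sb.term_coverage == 0.0 and sb.term_similarity == 0.0
        assert sb.total == pytest.approx(0.0025)

    def test_fragmentation_term_convexity(self):
        res = [_aa("A", s, "ALA") for s in range(1, 11)]
        mfs = _stub_mfs(res)
        one_run = Correspondence([_pair(r, r, True) for r in res])
        t_res = ([_aa("B", s, "ALA") for s in range(1, 6)]
                 + [_aa("B", s, "ALA") for s in range(20, 25)])
        split = Correspondence([_pair(q, t, True)
                                for q, t in zip(res, t_res)])
        f1 = score_alignment(one_run, mfs, mfs, weights=(1, 0, 0))
        f2 = score_alignment(split, mfs, _stub_mfs(t_res), weights=(1, 0, 0))
        assert f1.total == pytest.approx(0.01)
        assert f2.total == pytest.approx(0.04)

    def test_empty_correspondence_is_worst_score(self):
        mfs = _stub_mfs([_aa("A", 1, "ALA")])
        sb = score_alignment(Correspondence([]), mfs, mfs)
        assert sb.total == math.inf


class TestUnitsAndPoses:
    def test_unit_count_is_donor_pairs(self, fig1_mfs):
        assert len(decompose_units(fig1_mfs)) == 6    # C(4,2)

    def test_two_donor_site_gives_one_unit(self):
        spec = SiteSpec(metal="Cu", donor_geometry="linear",
                        ligands=(("CYS", "SG"), ("CYS", "SG")),
                        layout=(("A", 1, "L"), ("A", 9, "L")), seed=0)
        mfs = first_mfs(make_site(spec))
        assert len(decompose_units(mfs)) == 1

    def test_polymetallic_apex_is_metal_center(self):
        mfs = first_mfs(make_fes4_cluster())
        units = decompose_units(mfs)
        fe = np.array([m.coords for m in mfs.site.metals])
        np.testing.assert_allclose(units[0].apex, fe.mean(axis=0), atol=1e-12)

    def test_identity_rotation_among_self_poses(self, fig1_mfs):
        poses = enumerate_poses(fig1_mfs, fig1_mfs)
        devs = [np.max(np.abs(p.rotation - np.eye(3))) for p in poses]
        assert min(devs) < 1e-9

    def test_known_rotation_recovered(self, fig1_mfs):
        stc, rot, _ = transformed_copy(FIG1_SPEC, seed=5)
        target = first_mfs(stc)
        poses = enumerate_poses(fig1_mfs, target)
        # pose maps target onto query: best rotation ~ rot^T
        devs = [np.max(np.abs(p.rotation - rot.T)) for p in poses]
        assert min(devs) < 1e-6

    def test_single_donor_fallback_warns(self):
        spec = SiteSpec(metal="Zn", donor_geometry="linear",
                        ligands=(("HIS", "NE2"),),
                        layout=(("A", 1, "..L.."),), seed=0)
        mfs = first_mfs(make_site(spec))
        with pytest.warns(UserWarning, match="single donor"):
            units = decompose_units(mfs)
        assert len(units) == 1 and units[0].d2 is None
        res = superpose(mfs, mfs)
        assert res.score.term_coverage == 0.0
        assert res.rmsd < 1e-9


class TestCorrespondence:
    def test_self_pose_matches_everything_at_zero(self, fig1_mfs):
        pose = Pose(rotation=np.eye(3), translation=np.zeros(3))
        corr = match_correspondence(fig1_mfs, fig1_mfs, pose)
        n_polymer = len(fig1_mfs.polymer_residues)
        assert len(corr) == n_polymer
        for rp in corr.residue_pairs:
            assert rp.query.key == rp.target.key
            assert np.allclose(rp.primary[0].coords, rp.primary[1].coords)

    def test_ca_beyond_2A_unmatched_ligand_within_5A_matched(self):
        # one ligand pair at 4.5 A (matched via the relaxed threshold)
        # and one non-ligand pair at 2.1 A (not matched)
        def site(dx_lig, dx_env, chain):
            met = Residue("M", 900, "", "ZN", "other_hetero",
                          [Atom("ZN", "Zn", np.zeros(3))])
            lig = Residue(chain, 1, "", "CYS", "amino_acid", [
                Atom("CA", "C", np.array([4.0 + dx_lig, 0.0, 0.0])),
                Atom("SG", "S", np.array([2.0, 0.0, 0.0])),
            ])
            env = Residue(chain, 10, "", "GLY", "amino_acid", [
                Atom("CA", "C", np.array([0.0, 6.0 + dx_env, 0.0]))])
            ms = MetalSite(metals=[met.atoms[0]],
                           donor_atoms=[lig.atoms[1]],
                           endogenous_ligands=[lig], exogenous_ligands=[],
                           site_id=f"s{chain}")
            return MFS(site=ms, environment=[env])

        q = site(0.0, 0.0, "A")
        t = site(4.5, 2.1, "B")
        pose = Pose(rotation=np.eye(3), translation=np.zeros(3))
        corr = match_correspondence(q, t, pose)
        matched = {(rp.query.seq_pos, rp.category)
                   for rp in corr.residue_pairs}
        assert (1, "ligand") in matched
        assert all(cat == "ligand" for _, cat in matched)

    def test_ligands_only_match_ligands(self, fig1_mfs):
        pose = Pose(rotation=np.eye(3), translation=np.zeros(3))
        corr = match_correspondence(fig1_mfs, fig1_mfs, pose)
        lig_keys = {r.key for r in fig1_mfs.site.ligands}
        for rp in corr.residue_pairs:
            assert (rp.query.key in lig_keys) == (rp.target.key in lig_keys)


class TestRefinement:
    def test_self_refinement_rmsd_zero(self, fig1_mfs):
        res = superpose(fig1_mfs, fig1_mfs)
        assert res.rmsd <= 1e-9

    def test_exact_rigid_copy_recovers_transform(self, fig1_mfs):
        stc, rot, _ = transformed_copy(FIG1_SPEC, seed=8)
        res = superpose(fig1_mfs, first_mfs(stc))
        assert res.rmsd <= 1e-6
        np.testing.assert_allclose(res.best_pose.rotation, rot.T, atol=1e-6)

    def test_refined_rmsd_beats_random_transforms(self):
        spec = FIG1_SPEC.replace(noise_sd=0.2)
        noisy = make_site(spec.replace(seed=77))
        q = first_mfs(make_site(FIG1_SPEC))
        t = first_mfs(noisy)
        res = superpose(q, t)
        corr = res.correspondence
        t_pts = np.array([ta.coords for _, ta, _ in corr.pairs] + [t.center])
        q_pts = np.array([qa.coords for qa, _, _ in corr.pairs] + [q.center])
        rng = np.random.default_rng(1)
        best_random = math.inf
        for k in range(300):
            rot = Rotation.random(random_state=np.random.RandomState(k)).as_matrix()
            t0 = q_pts.mean(axis=0) - rot @ t_pts.mean(axis=0) \
                + rng.normal(0, 0.3, 3)
            pose = Pose(rotation=rot, translation=t0)
            best_random = min(best_random,
                              pose_rmsd(pose, corr, q, t))
        refined, rmsd = refine_pose(res.best_pose, corr, q, t)
        assert rmsd <= best_random

    def test_collinear_correspondence_falls_back(self):
        res = [_aa("A", s, "ALA", with_cb=False) for s in (1, 2)]
        mfs = _stub_mfs(res, with_metal=True)   # metal on the same axis
        corr = Correspondence([_pair(r, r) for r in res])
        pose = Pose(rotation=np.eye(3), translation=np.zeros(3))
        with pytest.warns(UserWarning, match="collinear"):
            out, _ = refine_pose(pose, corr, mfs, mfs)
        assert out is pose


class TestSuperpose:
    def test_self_superposition_terms(self, fig1_mfs):
        res = superpose(fig1_mfs, fig1_mfs, W111)
        sb = res.score
        assert sb.term_coverage == 0.0 and sb.term_similarity == 0.0
        expected = sum(1.0 / n for n in sb.n_f) / sb.N
        assert sb.total == pytest.approx(expected)

    def test_rigid_invariance_sample(self, fig1_mfs):
        base = superpose(fig1_mfs, fig1_mfs)
        for seed in range(10):
            stc, _, _ = transformed_copy(FIG1_SPEC, seed=seed)
            res = superpose(fig1_mfs, first_mfs(stc))
            assert abs(res.score.total - base.score.total) <= 1e-6
            assert res.rmsd <= 1e-6

    def test_near_duplicate_scores_low_unrelated_high(self, fig1_mfs):
        from mfskit.fixture_gen import make_family, unrelated_spec_pair

        a, b = make_family(FIG1_SPEC, 2, mutation_rate=0.1,
                           coord_noise_sd=NOISE_SD_03, seed=3)
        near = superpose(first_mfs(a), first_mfs(b)).score.total
        sa, sb_ = unrelated_spec_pair(12)
        unrel = superpose(first_mfs(make_site(sa)),
                          first_mfs(make_site(sb_))).score.total
        assert near <= 2.25 < 3.0 <= unrel

    def test_deterministic_result(self, fig1_mfs, znf_mfs):
        r1 = superpose(fig1_mfs, znf_mfs)
        r2 = superpose(fig1_mfs, znf_mfs)
        assert r1.score.total == r2.score.total
        np.testing.assert_array_equal(r1.best_pose.rotation,
                                      r2.best_pose.rotation)

    def test_no_donor_site_raises(self):
        met = Residue("M", 900, "", "ZN", "other_hetero",
                      [Atom("ZN", "Zn", np.zeros(3))])
        ms = MetalSite(metals=[met.atoms[0]], donor_atoms=[],
                       endogenous_ligands=[], exogenous_ligands=[],
                       site_id="bare")
        bare = MFS(site=ms, environment=[])
        with pytest.raises(ValueError, match="donor"):
            superpose(bare, bare)
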