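"""Pairwise structural superposition of minimal functional sites.

The algorithm keeps the metal (or polymetallic geometric center) of the
two sites coincident throughout:

1. each site is decomposed into triangle units (metal center + a pair
   of donor atoms);
2. every unit of the query is overlapped with every unit of the target
   (both donor pairings), giving candidate rigid poses with coincident
   metal centers;
3. each pose is scored through a three-term quality function
   (alignment fragmentation + coverage + biochemical similarity of the
   matched residues; lower is better);
4. the best-scoring poses are refined by a least-squares fit over the
   matched CA/CB pairs plus the metal centers, re-matched, re-scored
   and re-ranked; the best refined pose is returned.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .site_extraction import MFS, mfs_to_structure
from .structure_model import Atom, Residue, Structure

INFINITE_SCORE = float("inf")


# --------------------------------------------------------------------------
# substitution scores
# --------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def residue_similarity(a: Residue, b: Residue) -> tuple[float, float]:
    """(score, max self-score) of a matched residue pair: BLOSUM62 for
    amino acids, identity (1/0, self-score 1) for nucleotides."""
    if a.kind == "nucleotide" or b.kind == "nucleotide":
        same = a.name.strip() == b.name.strip()
        return (1.0 if same else 0.0), 1.0
    m = _blosum62()
    la, lb = a.one_letter, b.one_letter
    la = la if la in m.alphabet else "X"
    lb = lb if lb in m.alphabet else "X"
    return float(m[la, lb]), float(max(m[la, la], m[lb, lb]))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TriangleUnit:
    apex: tuple[float, float, float]
    d1: tuple[float, float, float]
    d2: tuple[float, float, float] | None   # None => single-donor fallback


@dataclass
class Pose:
    rotation: np.ndarray
    translation: np.ndarray
    source_units: tuple = ()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def apply_atom(self, atom: Atom) -> np.ndarray:
        return self.rotation @ atom.coords + self.translation


@dataclass
class ResiduePair:
    query: Residue
    target: Residue
    category: str                 # "CA" | "C1" | "ligand"
    primary: tuple[Atom, Atom]
    secondary: tuple[Atom, Atom] | None = None


@dataclass
class Correspondence:
    residue_pairs: list[ResiduePair] = field(default_factory=list)

    @property
    def pairs(self) -> list[tuple[Atom, Atom, str]]:
        out = []
        for rp in self.residue_pairs:
            out.append((rp.primary[0], rp.primary[1], rp.category))
            if rp.secondary is not None:
                cat = "CB" if rp.query.kind == "amino_acid" else "N_base"
                out.append((rp.secondary[0], rp.secondary[1], cat))
        return out

    @property
    def n_atom_pairs(self) -> int:
        return sum(1 for _ in self.pairs)

    def __len__(self) -> int:
        return len(self.residue_pairs)


@dataclass
class ScoreBreakdown:
    term_fragmentation: float
    term_coverage: float
    term_similarity: float
    weights: tuple[float, float, float]
    total: float
    F: int
    n_f: tuple[int, ...]
    N: int
    C_max: int
    c: int
    S: float
    S_max: float

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "term_fragmentation": self.term_fragmentation,
            "term_coverage": self.term_coverage,
            "term_similarity": self.term_similarity,
            "weights": list(self.weights),
            "F": self.F, "n_f": list(self.n_f), "N": self.N,
            "C_max": self.C_max, "c": self.c,
            "S": self.S, "S_max": self.S_max,
        }


def worst_score(weights: tuple[float, float, float]) -> ScoreBreakdown:
    """Sentinel for an empty correspondence."""
    return ScoreBreakdown(
        term_fragmentation=math.inf, term_coverage=math.inf,
        term_similarity=1.0, weights=tuple(weights), total=INFINITE_SCORE,
        F=0, n_f=(), N=0, C_max=0, c=0, S=0.0, S_max=0.0,
    )


@dataclass
class SuperpositionResult:
    best_pose: Pose
    score: ScoreBreakdown
    rmsd: float
    correspondence: Correspondence
    transformed_target: Structure | None = None

    def to_dict(self) -> dict:
        return {
            "score": self.score.to_dict(),
            "rmsd": self.rmsd,
            "rotation": self.best_pose.rotation.tolist(),
            "translation": self.best_pose.translation.tolist(),
            "matched_pairs": [
                {
                    "query": rp.query.label, "target": rp.target.label,
                    "category": rp.category,
                    "has_secondary": rp.secondary is not None,
                }
                for rp in self.correspondence.residue_pairs
            ],
        }


# --------------------------------------------------------------------------
# matchable atoms
# --------------------------------------------------------------------------

_PURINES = {"A", "G", "DA", "DG"}


@dataclass
class _Entry:
    residue: Residue
    primary: Atom
    secondary: Atom | None
    is_ligand: bool
    category: str


def _match_entries(mfs: MFS) -> list[_Entry]:
    """CA/CB (proteins) and C1'/N9-N1 (nucleic acids) matchable atoms of
    the MFS polymer residues."""
    ligand_keys = {r.key for r in mfs.site.ligands}
    entries = []
    for r in mfs.polymer_residues:
        if r.kind == "amino_acid":
            ca = r.atom("CA")
            if ca is None:
                continue
            entries.append(_Entry(r, ca, r.atom("CB"), r.key in ligand_keys,
                                  "CA"))
        else:
            c1 = r.atom("C1'") or r.atom("C1*")
            if c1 is None:
                continue
            base = r.atom("N9") if r.name.strip() in _PURINES else r.atom("N1")
            entries.append(_Entry(r, c1, base, r.key in ligand_keys, "C1"))
    return entries


def site_atom_count(mfs: MFS) -> int:
    """Total number of matchable primary+secondary atoms of the site."""
    n = 0
    for e in _match_entries(mfs):
        n += 1 + (e.secondary is not None)
    return n


# --------------------------------------------------------------------------
# pose enumeration
# --------------------------------------------------------------------------

def decompose_units(mfs: MFS) -> list[TriangleUnit]:
    """One triangle unit per unordered donor pair, apex at the metal
    center; single-donor sites fall back to one degenerate unit."""
    apex = tuple(float(v) for v in mfs.center)
    donors = mfs.site.donor_atoms
    if len(donors) < 2:
        if not donors:
            raise ValueError(f"site {mfs.mfs_id} has no donor atoms")
        warnings.warn(
            f"site {mfs.mfs_id} has a single donor; using axis-alignment "
            "fallback", stacklevel=2)
        return [TriangleUnit(apex, tuple(map(float, donors[0].coords)), None)]
    units = []
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            units.append(TriangleUnit(
                apex,
                tuple(map(float, donors[i].coords)),
                tuple(map(float, donors[j].coords)),
            ))
    return units


def _kabsch_vectors(t_vecs: np.ndarray, q_vecs: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing sum |q_i - R t_i|^2 (no centering)."""
    h = t_vecs.T @ q_vecs
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def _unit_vectors(unit: TriangleUnit, swap: bool) -> np.ndarray:
    apex = np.array(unit.apex)
    v1 = np.array(unit.d1) - apex
    v2 = (np.array(unit.d2) - apex) if unit.d2 is not None else None
    if swap and v2 is not None:
        v1, v2 = v2, v1
    n1 = v1 / np.linalg.norm(v1)
    if v2 is None:
        return np.array([n1])
    n2 = v2 / np.linalg.norm(v2)
    cr = np.cross(n1, n2)
    nc = np.linalg.norm(cr)
    if nc < 1e-8:                        # collinear donors: plane undefined
        return np.array([n1, n2])
    return np.array([n1, n2, cr / nc])


def _axis_fallback_rotations(t_dir: np.ndarray, q_dir: np.ndarray,
                             n_steps: int = 12) -> list[np.ndarray]:
    from scipy.spatial.transform import Rotation

    base = _kabsch_vectors(np.array([t_dir]), np.array([q_dir]))
    out = []
    for k in range(n_steps):
        spin = Rotation.from_rotvec(q_dir * (2 * np.pi * k / n_steps)).as_matrix()
        out.append(spin @ base)
    return out


def enumerate_poses(query: MFS, target: MFS,
                    config: Config = DEFAULT_CONFIG) -> list[Pose]:
    """Candidate poses from all unit pairs and both donor pairings,
    metal centers pinned coincident; near-duplicate rotations removed."""
    q_units = decompose_units(query)
    t_units = decompose_units(target)
    q_apex = query.center
    t_apex = target.center

    rotations: list[np.ndarray] = []
    sources: list[tuple] = []
    for qi, qu in enumerate(q_units):
        for ti, tu in enumerate(t_units):
            single = qu.d2 is None or tu.d2 is None
            pairings = (False,) if single else (False, True)
            for swap in pairings:
                qv = _unit_vectors(qu, False)
                tv = _unit_vectors(tu, swap)
                m = min(len(qv), len(tv))
                if m == 1:
                    cands = _axis_fallback_rotations(tv[0], qv[0])
                else:
                    base = _kabsch_vectors(tv[:m], qv[:m])
                    cands = [base]
                    # near-collinear donor pairs leave the spin about the
                    # common axis ill-determined: sample it
                    if min(np.linalg.norm(np.cross(qv[0], qv[1])),
                           np.linalg.norm(np.cross(tv[0], tv[1]))) < 0.7:
                        from scipy.spatial.transform import Rotation

                        for k in range(1, 12):
                            spin = Rotation.from_rotvec(
                                qv[0] * (2 * np.pi * k / 12)).as_matrix()
                            cands.append(spin @ base)
                for rot in cands:
                    rotations.append(rot)
                    sources.append((qi, ti, int(swap)))

    poses: list[Pose] = []
    buf = np.empty((len(rotations), 9))
    count = 0
    for rot, src in zip(rotations, sources):
        flat = rot.reshape(9)
        if count and np.min(
            np.max(np.abs(buf[:count] - flat), axis=1)
        ) < config.pose_dedup_tol:
            continue
        buf[count] = flat
        count += 1
        poses.append(Pose(rotation=rot,
                          translation=q_apex - rot @ t_apex,
                          source_units=src))
    return poses


# --------------------------------------------------------------------------
# correspondence
# --------------------------------------------------------------------------

def match_correspondence(query: MFS, target: MFS, pose: Pose,
                         config: Config = DEFAULT_CONFIG) -> Correspondence:
    """Greedy one-to-one nearest-neighbor matching of CA (C1') atoms by
    ascending distance.  Metal-binding residues are matched only to
    metal-binding residues, with a relaxed 5 A threshold; all other
    residues use the 2 A threshold.  Secondary (CB / base-N) atoms are
    paired only within an existing primary pair and the same threshold."""
    q_entries = _match_entries(query)
    t_entries = _match_entries(target)
    if not q_entries or not t_entries:
        return Correspondence()

    t_primary = pose.apply(np.array([e.primary.coords for e in t_entries]))
    q_primary = np.array([e.primary.coords for e in q_entries])

    q_lig = np.array([e.is_ligand for e in q_entries])
    t_lig = np.array([e.is_ligand for e in t_entries])
    q_cat = np.array([e.category for e in q_entries])
    t_cat = np.array([e.category for e in t_entries])
    diff = q_primary[:, None, :] - t_primary[None, :, :]
    dmat = np.sqrt(np.sum(diff * diff, axis=2))
    allowed = (q_lig[:, None] == t_lig[None, :]) \
        & (q_cat[:, None] == t_cat[None, :])
    thr = np.where(q_lig[:, None], config.ligand_ca_threshold,
                   config.ca_threshold)
    ii, jj = np.nonzero(allowed & (dmat <= thr))
    order = np.lexsort((jj, ii, dmat[ii, jj]))

    used_q: set[int] = set()
    used_t: set[int] = set()
    pairs: list[ResiduePair] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_q or j in used_t:
            continue
        used_q.add(i)
        used_t.add(j)
        qe, te = q_entries[i], t_entries[j]
        secondary = None
        if qe.secondary is not None and te.secondary is not None:
            thr = config.ligand_ca_threshold if qe.is_ligand \
                else config.ca_threshold
            d2 = float(np.linalg.norm(
                qe.secondary.coords - pose.apply_atom(te.secondary)))
            if d2 <= thr:
                secondary = (qe.secondary, te.secondary)
        category = "ligand" if qe.is_ligand else qe.category
        pairs.append(ResiduePair(qe.residue, te.residue, category,
                                 (qe.primary, te.primary), secondary))
    pairs.sort(key=lambda rp: (rp.query.chain_id, rp.query.seq_pos,
                               rp.query.icode))
    return Correspondence(residue_pairs=pairs)


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def _alignment_fragments(corr: Correspondence) -> list[int]:
    """Lengths of maximal runs of matched residue pairs consecutive in
    sequence in BOTH sites (a break in either chain ends the run)."""
    lengths = []
    run = 0
    prev = None
    for rp in corr.residue_pairs:
        if prev is not None and (
            rp.query.chain_id == prev.query.chain_id
            and rp.query.seq_pos - prev.query.seq_pos == 1
            and rp.target.chain_id == prev.target.chain_id
            and rp.target.seq_pos - prev.target.seq_pos == 1
        ):
            run += 1
        else:
            if run:
                lengths.append(run)
            run = 1
        prev = rp
    if run:
        lengths.append(run)
    return lengths


def score_alignment(corr: Correspondence, query: MFS, target: MFS,
                    weights: tuple[float, float, float] | None = None,
                    config: Config = DEFAULT_CONFIG) -> ScoreBreakdown:
    """Three-term superposition quality (lower is better):
    ``w1*(sum_f 1/n_f)/N + w2*ln(C_max/c) + w3*max(0, 1 - S/S_max)``."""
    w = tuple(weights) if weights is not None else tuple(config.weights)
    if len(corr) == 0:
        return worst_score(w)

    n_f = _alignment_fragments(corr)
    big_n = len(corr.residue_pairs)
    term_frag = sum(1.0 / n for n in n_f) / big_n

    c_max = min(site_atom_count(query), site_atom_count(target))
    c = corr.n_atom_pairs
    term_cov = math.log(c_max / c) if c > 0 else math.inf

    s_sum = 0.0
    s_max = 0.0
    for rp in corr.residue_pairs:
        s, smax = residue_similarity(rp.query, rp.target)
        s_sum += s
        s_max += smax
    term_sim = max(0.0, 1.0 - s_sum / s_max) if s_max > 0 else 0.0

    total = w[0] * term_frag + w[1] * term_cov + w[2] * term_sim
    return ScoreBreakdown(
        term_fragmentation=term_frag, term_coverage=term_cov,
        term_similarity=term_sim, weights=w, total=total,
        F=len(n_f), n_f=tuple(n_f), N=big_n, C_max=c_max, c=c,
        S=s_sum, S_max=s_max,
    )


# --------------------------------------------------------------------------
# refinement
# --------------------------------------------------------------------------

def _kabsch_points(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """(R, t, ok) minimizing |q - (R p + t)|; ok=False for degenerate
    (collinear) point sets."""
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    ok = bool(s[0] <= 0 or s[1] / max(s[0], 1e-300) > 1e-9) if len(s) > 1 else False
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - rot @ pc
    return rot, t, ok


def _paired_points(corr: Correspondence, query: MFS, target: MFS
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Matched atom coordinates plus the metal-center virtual pair,
    target first (untransformed), query second."""
    q_pts = [qa.coords for qa, _, _ in corr.pairs]
    t_pts = [ta.coords for _, ta, _ in corr.pairs]
    q_pts.append(query.center)
    t_pts.append(target.center)
    return np.array(t_pts), np.array(q_pts)


def pose_rmsd(pose: Pose, corr: Correspondence, query: MFS,
              target: MFS) -> float:
    """RMSD over the matched CA/CB pairs plus the metal-center pair."""
    if len(corr) == 0:
        return math.inf
    t_pts, q_pts = _paired_points(corr, query, target)
    diff = q_pts - pose.apply(t_pts)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def refine_pose(pose: Pose, corr: Correspondence, query: MFS, target: MFS
                ) -> tuple[Pose, float]:
    """Least-squares optimal rigid fit over the matched atom pairs plus
    the metal centers; the metals may drift slightly off coincidence."""
    if len(corr) == 0:
        return pose, math.inf
    t_pts, q_pts = _paired_points(corr, query, target)
    if len(t_pts) < 3:
        return pose, pose_rmsd(pose, corr, query, target)
    rot, t, ok = _kabsch_points(t_pts, q_pts)
    if not ok:
        warnings.warn("degenerate (collinear) correspondence; keeping "
                      "unrefined pose", stacklevel=2)
        return pose, pose_rmsd(pose, corr, query, target)
    refined = Pose(rotation=rot, translation=t, source_units=pose.source_units)
    return refined, pose_rmsd(refined, corr, query, target)


# --------------------------------------------------------------------------
# full superposition
# --------------------------------------------------------------------------

def superpose(query: MFS, target: MFS,
              config: Config = DEFAULT_CONFIG) -> SuperpositionResult:
    """Run the full pose-enumeration / scoring / refinement pipeline and
    return the best re-ranked pose.  Deterministic for fixed inputs."""
    poses = enumerate_poses(query, target, config)

    scored = []
    for idx, pose in enumerate(poses):
        corr = match_correspondence(query, target, pose, config)
        sb = score_alignment(corr, query, target, config=config)
        scored.append((sb.total, idx, pose, corr, sb))
    scored.sort(key=lambda t: (t[0], t[1]))

    best = None
    for total, idx, pose, corr, sb in scored[: config.top_k]:
        if len(corr) == 0:
            cand = (sb.total, math.inf, idx, pose, corr, sb)
        else:
            # iterate refine/re-match to convergence: the initial pose
            # from a noisy donor triangle has a short lever arm, and a
            # single pass can leave most of the site unmatched
            cur_pose, cur_corr = pose, corr
            for _ in range(8):
                refined, _ = refine_pose(cur_pose, cur_corr, query, target)
                corr2 = match_correspondence(query, target, refined, config)
                if len(corr2) == 0:
                    break
                same = ([(rp.query.key, rp.target.key)
                         for rp in corr2.residue_pairs]
                        == [(rp.query.key, rp.target.key)
                            for rp in cur_corr.residue_pairs])
                cur_pose, cur_corr = refined, corr2
                if same:
                    break
            sb2 = score_alignment(cur_corr, query, target, config=config)
            rmsd2 = pose_rmsd(cur_pose, cur_corr, query, target)
            cand = (sb2.total, rmsd2, idx, cur_pose, cur_corr, sb2)
        if best is None or cand[:3] < best[:3]:
            best = cand

    if best is None:                     # no poses at all (cannot happen
        raise ValueError("no poses generated")   # once units exist)
    total, rmsd, _, pose, corr, sb = best
    transformed = None
    if target.source is not None:
        tst = mfs_to_structure(target)
        for r in tst.residues:
            for a in r.atoms:
                a.coords = pose.rotation @ a.coords + pose.translation
        tst.id = f"{target.mfs_id}_on_{query.mfs_id}"
        transformed = tst
    return SuperpositionResult(
        best_pose=pose, score=sb,
        rmsd=rmsd if len(corr) else math.inf,
        correspondence=corr, transformed_target=transformed,
    )


def symmetric_score(a: MFS, b: MFS, config: Config = DEFAULT_CONFIG) -> float:
    """Mean of the two directed superposition scores; the symmetric
    dissimilarity used for clustering."""
    return 0.5 * (superpose(a, b, config).score.total
                  + superpose(b, a, config).score.total)
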