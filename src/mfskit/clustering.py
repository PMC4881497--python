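"""Equistructural grouping and two-stage hierarchical clustering of MFSs.

Stage 0 (grouping): MFSs from chains that are superposable (>= 50%
global sequence identity, or a shared user-supplied fold label) and
whose site centers fall within 3.5 A of each other after the chain
fit belong to one *equistructural group*; groups split by metal
content and nuclearity give *equivalent* sites.

Stage 1 (intra-group): within each group, complete-linkage clustering
of the superposition scores cut at a stringent threshold (default
2.25); each cluster is represented by the member with the lowest
cumulative score to the rest of its cluster.

Stage 2 (inter-group): average-linkage clustering of the representatives
cut at a relaxed threshold (default 2.75), free to merge across folds.

The superposition score is mildly asymmetric, so the dissimilarity used
throughout is the mean of the two directed scores.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import Config, DEFAULT_CONFIG
from .metals2 import _kabsch_points, symmetric_score
from .site_extraction import MFS
from .structure_model import Structure

#: finite stand-in for an infinite score (empty correspondence) so the
#: linkage arithmetic stays well defined; far above any real threshold.
SCORE_CAP = 1.0e3


# --------------------------------------------------------------------------
# sequence alignment helpers
# --------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def chain_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise sequence identity in percent: identical aligned
    pairs over the alignment length (gap columns included)."""
    if not seq_a or not seq_b:
        return 0.0
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def _aligned_index_pairs(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    aln = _aligner().align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def primary_chain(mfs: MFS) -> str:
    """Chain holding most of the MFS's endogenous ligands (ties:
    lexicographic)."""
    counts: dict[str, int] = {}
    for r in mfs.site.endogenous_ligands or mfs.polymer_residues:
        counts[r.chain_id] = counts.get(r.chain_id, 0) + 1
    return min(counts, key=lambda c: (-counts[c], c))


def _chain_ca(structure: Structure, chain_id: str):
    res = [r for r in structure.residues
           if r.chain_id == chain_id and r.kind == "amino_acid"]
    cas = [(r, r.atom("CA")) for r in res]
    return [(r, a) for r, a in cas if a is not None]


def center_distance_after_fit(mfs_a: MFS, mfs_b: MFS) -> float:
    """Distance between the two site centers after a least-squares CA
    fit of the primary chains guided by their global sequence alignment."""
    ca_a = _chain_ca(mfs_a.source, primary_chain(mfs_a))
    ca_b = _chain_ca(mfs_b.source, primary_chain(mfs_b))
    seq_a = "".join(r.one_letter for r, _ in ca_a)
    seq_b = "".join(r.one_letter for r, _ in ca_b)
    pairs = _aligned_index_pairs(seq_a, seq_b)
    if len(pairs) < 3:
        return float("inf")
    pa = np.array([ca_a[i][1].coords for i, _ in pairs])
    pb = np.array([ca_b[j][1].coords for _, j in pairs])
    rot, t, ok = _kabsch_points(pb, pa)
    if not ok:
        return float("inf")
    moved_center = rot @ mfs_b.center + t
    return float(np.linalg.norm(mfs_a.center - moved_center))


# --------------------------------------------------------------------------
# equistructural / equivalent grouping
# --------------------------------------------------------------------------

@dataclass
class EquistructuralGroup:
    members: list[MFS]
    identities: dict[tuple[str, str], float] = field(default_factory=dict)
    center_distances: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def group_equistructural(mfs_list: list[MFS],
                         fold_labels: dict[str, str] | None = None,
                         config: Config = DEFAULT_CONFIG
                         ) -> list[EquistructuralGroup]:
    """Transitive closure of the pairwise criterion: chains >= 50%
    identical (or same fold label) AND site centers < 3.5 A apart after
    chain superposition.  Chains shorter than 10 residues cannot be
    aligned reliably and yield singleton groups."""
    import networkx as nx

    n = len(mfs_list)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    idents: dict[tuple[str, str], float] = {}
    cdists: dict[tuple[str, str], float] = {}
    seqs = []
    for m in mfs_list:
        seqs.append(m.source.chain_sequence(primary_chain(m))
                    if m.source is not None else "")
    for i in range(n):
        if len(seqs[i]) < 10:
            warnings.warn(f"{mfs_list[i].mfs_id}: chain shorter than 10 "
                          "residues; singleton group", stacklevel=2)
    for i in range(n):
        for j in range(i + 1, n):
            if len(seqs[i]) < 10 or len(seqs[j]) < 10:
                continue
            ident = chain_identity(seqs[i], seqs[j])
            key = (mfs_list[i].mfs_id, mfs_list[j].mfs_id)
            idents[key] = ident
            same_fold = False
            if fold_labels is not None:
                la = fold_labels.get(mfs_list[i].mfs_id)
                lb = fold_labels.get(mfs_list[j].mfs_id)
                same_fold = la is not None and la == lb
            if ident < config.identity_cutoff and not same_fold:
                continue
            cd = center_distance_after_fit(mfs_list[i], mfs_list[j])
            cdists[key] = cd
            if cd < config.center_distance_cutoff:
                g.add_edge(i, j)
    groups = []
    for comp in sorted(nx.connected_components(g), key=min):
        members = [mfs_list[i] for i in sorted(comp)]
        groups.append(EquistructuralGroup(
            members=members,
            identities={k: v for k, v in idents.items()
                        if k[0] in {m.mfs_id for m in members}},
            center_distances={k: v for k, v in cdists.items()
                              if k[0] in {m.mfs_id for m in members}},
        ))
    return groups


def split_equivalent(group: EquistructuralGroup) -> list[list[MFS]]:
    """Partition a group by (sorted metal multiset, nuclearity)."""
    buckets: dict[tuple, list[MFS]] = {}
    for m in group.members:
        key = (m.site.elements, m.site.nuclearity)
        buckets.setdefault(key, []).append(m)
    return [buckets[k] for k in sorted(buckets)]


# --------------------------------------------------------------------------
# two-stage clustering
# --------------------------------------------------------------------------

def score_matrix(members: list[MFS],
                 config: Config = DEFAULT_CONFIG) -> np.ndarray:
    """Symmetric dissimilarity matrix (mean of the two directed scores;
    infinities capped at SCORE_CAP)."""
    n = len(members)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = symmetric_score(members[i], members[j], config)
            d[i, j] = d[j, i] = min(s, SCORE_CAP)
    return d


@dataclass
class Cluster:
    members: list[MFS]
    representative: MFS | None = None

    @property
    def member_ids(self) -> list[str]:
        return [m.mfs_id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    intra_clusters: list[Cluster] = field(default_factory=list)
    inter_clusters: list[Cluster] = field(default_factory=list)
    intra_threshold: float = 0.0
    inter_threshold: float = 0.0

    @property
    def representatives(self) -> list[MFS]:
        return [c.representative for c in self.intra_clusters]

    def to_dict(self) -> dict:
        return {
            "intra_threshold": self.intra_threshold,
            "inter_threshold": self.inter_threshold,
            "intra_clusters": [
                {"members": c.member_ids,
                 "representative": c.representative.mfs_id}
                for c in self.intra_clusters
            ],
            "inter_clusters": [
                {"representatives": c.member_ids} for c in self.inter_clusters
            ],
        }


def _flat_clusters(d: np.ndarray, threshold: float, method: str) -> list[list[int]]:
    n = len(d)
    if n == 1:
        return [[0]]
    z = linkage(squareform(d, checks=False), method=method)
    labels = fcluster(z, t=threshold, criterion="distance")
    out: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(int(lab), []).append(i)
    return [sorted(v) for v in sorted(out.values(), key=min)]


def _representative(members: list[MFS], idx: list[int], d: np.ndarray) -> MFS:
    """Member minimizing the sum of scores to the rest of its cluster;
    ties broken by site id."""
    best = min(idx, key=lambda i: (float(d[i, idx].sum()), members[i].mfs_id))
    return members[best]


def cluster_intra(members: list[MFS], threshold: float | None = None,
                  config: Config = DEFAULT_CONFIG,
                  d: np.ndarray | None = None) -> list[Cluster]:
    """Complete-linkage clustering cut at the stringent threshold; every
    resulting cluster has max internal pairwise score <= threshold."""
    if not members:
        return []
    thr = config.intra_threshold if threshold is None else threshold
    if d is None:
        d = score_matrix(members, config)
    clusters = []
    for idx in _flat_clusters(d, thr, "complete"):
        clusters.append(Cluster(
            members=[members[i] for i in idx],
            representative=_representative(members, idx, d),
        ))
    return clusters


def cluster_inter(representatives: list[MFS], threshold: float | None = None,
                  config: Config = DEFAULT_CONFIG,
                  d: np.ndarray | None = None) -> list[Cluster]:
    """Average-linkage clustering of representatives at the relaxed
    threshold; clusters may span different folds."""
    if not representatives:
        return []
    thr = config.inter_threshold if threshold is None else threshold
    if d is None:
        d = score_matrix(representatives, config)
    return [Cluster(members=[representatives[i] for i in idx])
            for idx in _flat_clusters(d, thr, "average")]


def two_stage_cluster(groups: list[list[MFS]],
                      intra_threshold: float | None = None,
                      inter_threshold: float | None = None,
                      config: Config = DEFAULT_CONFIG) -> ClusterSet:
    """Run the full pipeline: intra-group complete-linkage clustering
    with representatives, then average-linkage clustering of all
    representatives."""
    intra: list[Cluster] = []
    for g in groups:
        intra.extend(cluster_intra(g, intra_threshold, config))
    reps = [c.representative for c in intra]
    inter = cluster_inter(reps, inter_threshold, config)
    return ClusterSet(
        intra_clusters=intra, inter_clusters=inter,
        intra_threshold=(config.intra_threshold if intra_threshold is None
                         else intra_threshold),
        inter_threshold=(config.inter_threshold if inter_threshold is None
                         else inter_threshold),
    )
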