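"""Desk-scale statistical analyses over extracted MFSs.

Three analyses are provided:

* nuclearity/fragment statistics -- mean count of ligand-bearing
  sequence fragments and of amino-acid ligands per (metal, nuclearity)
  class, after filtering adventitious sites by per-metal minimum donor
  counts;
* sub-pattern alignment and positional enrichment -- fragments sharing
  a ligand sub-pattern (e.g. HX(2)C) are put in register on the anchor
  ligands and per-position residue frequencies are compared to a
  background;
* MFS-vs-chain sequence identity -- within clusters of structurally
  similar sites, the identity of the structure-based MFS alignment is
  compared with the identity of the full-chain alignment.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config, DEFAULT_CONFIG
from .metals2 import superpose
from .site_extraction import MFS, Fragment, passes_min_donors
from .clustering import Cluster, chain_identity, primary_chain


# --------------------------------------------------------------------------
# nuclearity / fragment statistics
# --------------------------------------------------------------------------

def ligand_bearing_fragments(mfs: MFS) -> list[Fragment]:
    """Fragments containing at least one amino-acid ligand of the metal."""
    aa_lig_keys = {r.key for r in mfs.site.endogenous_ligands
                   if r.kind == "amino_acid"}
    return [f for f in mfs.fragments
            if any(r.key in aa_lig_keys for r in f.residues)]


def aa_ligand_count(mfs: MFS) -> int:
    return sum(1 for r in mfs.site.endogenous_ligands
               if r.kind == "amino_acid")


def nuclearity_fragment_stats(sites: list[MFS],
                              config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """Mean ligand-bearing fragment count and amino-acid ligand count
    per (metal, nuclearity), over sites passing the per-metal minimum
    donor filter.  Heterometallic sites are pooled under 'mixed'."""
    rows = []
    for m in sites:
        if not passes_min_donors(m.site, config, structure=m.source):
            continue
        elems = set(m.site.elements)
        metal = elems.pop() if len(elems) == 1 else "mixed"
        rows.append({
            "metal": metal,
            "nuclearity": m.site.nuclearity,
            "n_fragments": len(ligand_bearing_fragments(m)),
            "n_aa_ligands": aa_ligand_count(m),
        })
    if not rows:
        return pd.DataFrame(columns=["metal", "nuclearity", "n_sites",
                                     "mean_fragments", "mean_aa_ligands"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["metal", "nuclearity"])
        .agg(n_sites=("n_fragments", "size"),
             mean_fragments=("n_fragments", "mean"),
             mean_aa_ligands=("n_aa_ligands", "mean"))
        .reset_index()
    )
    return out


# --------------------------------------------------------------------------
# sub-pattern alignment
# --------------------------------------------------------------------------

_SUBPATTERN_RE = re.compile(r"([A-Z])(?:X\((\d+)\))?")


def parse_subpattern(subpattern: str) -> tuple[tuple[int, str], ...]:
    """'HX(2)C' -> ((0, 'H'), (3, 'C')): offsets of the anchor residues
    relative to the first anchor."""
    out = []
    pos = 0
    matched = 0
    for m in _SUBPATTERN_RE.finditer(subpattern):
        out.append((pos, m.group(1)))
        gap = int(m.group(2)) if m.group(2) is not None else 0
        pos += gap + 1
        matched += len(m.group(0))
    if matched != len(subpattern) or not out:
        raise ValueError(f"cannot parse sub-pattern {subpattern!r}")
    return tuple(out)


@dataclass
class SubpatternAlignment:
    subpattern: str
    anchors: tuple[tuple[int, str], ...]
    entries: list[tuple[Fragment, int]] = field(default_factory=list)
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def column(self, rel_pos: int) -> list[str]:
        """Residue letters observed at a position relative to the first
        anchor (fragments lacking that position are skipped)."""
        out = []
        for frag, anchor in self.entries:
            for r in frag.residues:
                if r.seq_pos - anchor == rel_pos:
                    out.append(r.one_letter)
                    break
        return out

    def positions(self) -> list[int]:
        rels = set()
        for frag, anchor in self.entries:
            for r in frag.residues:
                rels.add(r.seq_pos - anchor)
        return sorted(rels)


def _find_anchor(frag: Fragment, anchors: tuple[tuple[int, str], ...]) -> int | None:
    """Lowest ligand seq position at which the whole sub-pattern matches
    the fragment's ligands."""
    by_pos = {r.seq_pos: r.one_letter for r in frag.residues}
    lig = set(frag.ligand_seq_positions)
    for start in sorted(lig):
        ok = all(
            (start + off) in lig and by_pos.get(start + off) == letter
            for off, letter in anchors
        )
        if ok:
            return start
    return None


def align_subpattern_fragments(fragments: list[Fragment],
                               subpattern: str) -> SubpatternAlignment:
    """Register fragments on a common ligand sub-pattern; fragments whose
    ligands do not realize the pattern are excluded (counted)."""
    anchors = parse_subpattern(subpattern)
    aln = SubpatternAlignment(subpattern=subpattern, anchors=anchors)
    for frag in fragments:
        anchor = _find_anchor(frag, anchors)
        if anchor is None:
            aln.n_excluded += 1
        else:
            aln.entries.append((frag, anchor))
    return aln


def positional_enrichment(alignment: SubpatternAlignment,
                          background: dict[str, float]) -> pd.DataFrame:
    """Observed/background frequency ratio per (relative position,
    residue type).  Frequencies at each position are computed over the
    fragments contributing a residue there and sum to one."""
    if len(alignment) == 0:
        raise ValueError("empty sub-pattern alignment")
    rows = []
    residues = sorted(background)
    for pos in alignment.positions():
        col = alignment.column(pos)
        if not col:
            continue
        n = len(col)
        for aa in sorted(set(col) | set(residues)):
            obs = col.count(aa) / n
            bg = background.get(aa, 0.0)
            if obs > 0 and bg <= 0:
                raise ValueError(
                    f"residue {aa!r} observed at position {pos} has zero "
                    "background frequency")
            rows.append({"position": pos, "residue": aa, "n": n,
                         "observed": obs, "background": bg,
                         "ratio": (obs / bg) if bg > 0 else 0.0})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# MFS vs chain sequence identity
# --------------------------------------------------------------------------

def mfs_pair_identity(a: MFS, b: MFS,
                      config: Config = DEFAULT_CONFIG) -> float:
    """Percent identity over the matched residue pairs of the
    structure-based MFS superposition (symmetrized over direction)."""
    vals = []
    for q, t in ((a, b), (b, a)):
        res = superpose(q, t, config)
        pairs = res.correspondence.residue_pairs
        if not pairs:
            vals.append(0.0)
            continue
        same = sum(1 for rp in pairs
                   if rp.query.one_letter == rp.target.one_letter)
        vals.append(100.0 * same / len(pairs))
    return float(np.mean(vals))


def chain_pair_identity(a: MFS, b: MFS) -> float:
    sa = a.source.chain_sequence(primary_chain(a))
    sb = b.source.chain_sequence(primary_chain(b))
    return chain_identity(sa, sb)


def identity_comparison(clusters: list[Cluster],
                        config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per cluster (>= 2 members): mean pairwise MFS structure-based
    identity (x) and mean pairwise whole-chain identity (y), both in
    percent and over the same member pairs."""
    rows = []
    for k, cl in enumerate(clusters):
        members = cl.members
        if len(members) < 2:
            continue
        xs, ys = [], []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                xs.append(mfs_pair_identity(members[i], members[j], config))
                ys.append(chain_pair_identity(members[i], members[j]))
        rows.append({
            "cluster": k,
            "n_members": len(members),
            "mfs_identity": float(np.mean(xs)),
            "chain_identity": float(np.mean(ys)),
        })
    return pd.DataFrame(rows)


def compare_identity(df: pd.DataFrame, n_permutations: int = 10000,
                     seed: int = 0, alpha: float = 0.01) -> dict:
    """Paired-difference summary of MFS-level vs chain-level identity:
    mean difference, paired t-test and a sign-flip permutation test."""
    from scipy import stats

    x = df["mfs_identity"].to_numpy(dtype=float)
    y = df["chain_identity"].to_numpy(dtype=float)
    diff = x - y
    out = {"n_clusters": int(len(diff)),
           "mean_difference": float(np.mean(diff)) if len(diff) else float("nan"),
           "alpha": alpha}
    if len(diff) >= 2 and np.std(diff) > 0:
        t = stats.ttest_rel(x, y)
        out["t_statistic"] = float(t.statistic)
        out["t_pvalue"] = float(t.pvalue)
        rng = np.random.default_rng(seed)
        obs = abs(np.mean(diff))
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(diff)))
        perm = np.abs((signs * diff).mean(axis=1))
        out["permutation_pvalue"] = float((1 + np.sum(perm >= obs))
                                          / (1 + n_permutations))
        out["significant"] = bool(min(out["t_pvalue"],
                                      out["permutation_pvalue"]) < alpha)
    return out
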