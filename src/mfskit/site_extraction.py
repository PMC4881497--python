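"""Metal-site extraction: donors, polynuclear assembly, MFS construction.

The pipeline mirrors the MetalPDB construction of minimal functional
sites (MFSs):

1. find the coordination donors of every metal ion (covalent-radius
   based cutoff, since crystal structures carry no explicit bonds);
2. merge metal ions that share a ligand residue or sit closer than 5 A
   into one polynuclear site (transitively);
3. collect the 5 A environment of all ligand residues;
4. decompose the site into sequence fragments and derive its
   metal-binding pattern (MBP) string.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import Config, DEFAULT_CONFIG
from .structure_model import (
    Atom,
    Residue,
    Structure,
    covalent_radius,
    is_metal,
    list_metal_atoms,
)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class MetalSite:
    metals: list[Atom]
    donor_atoms: list[Atom]
    endogenous_ligands: list[Residue]
    exogenous_ligands: list[Residue]
    site_id: str = ""

    @property
    def nuclearity(self) -> int:
        return len(self.metals)

    @property
    def ligands(self) -> list[Residue]:
        return self.endogenous_ligands + self.exogenous_ligands

    @property
    def center(self) -> np.ndarray:
        return np.mean([m.coords for m in self.metals], axis=0)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sorted(m.element for m in self.metals))


@dataclass
class Fragment:
    chain_id: str
    residues: list[Residue]
    n_ligands: int
    ligand_seq_positions: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def span(self) -> tuple[int, int]:
        return (self.residues[0].seq_pos, self.residues[-1].seq_pos)


@dataclass
class MFS:
    site: MetalSite
    environment: list[Residue]
    fragments: list[Fragment] = field(default_factory=list)
    mbp: str = ""
    source: Structure | None = field(default=None, repr=False)

    @property
    def center(self) -> np.ndarray:
        return self.site.center

    @property
    def residues(self) -> list[Residue]:
        """All MFS residues (ligands + environment) in chain/sequence order."""
        allr = self.site.ligands + self.environment
        return sorted(allr, key=lambda r: (r.chain_id, r.seq_pos, r.icode))

    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    @property
    def mfs_id(self) -> str:
        return self.site.site_id


# --------------------------------------------------------------------------
# donor detection
# --------------------------------------------------------------------------

def donor_cutoff(metal_element: str, donor_element: str,
                 config: Config = DEFAULT_CONFIG) -> float:
    """Metal-donor coordination cutoff: sum of covalent radii plus the
    configured pad, capped at ``donor_cap``."""
    raw = covalent_radius(metal_element) + covalent_radius(donor_element) \
        + config.donor_pad
    return min(raw, config.donor_cap)


def detect_donors(structure: Structure, metal: Atom,
                  config: Config = DEFAULT_CONFIG) -> list[Atom]:
    """Non-hydrogen donor-element atoms within the coordination cutoff
    of *metal*.  Metal atoms themselves never count as donors."""
    donors = []
    for res in structure.residues:
        for a in res.atoms:
            if a.is_hydrogen or a is metal:
                continue
            if a.element not in config.donor_elements:
                continue
            if metal.distance(a) <= donor_cutoff(metal.element, a.element,
                                                 config):
                donors.append(a)
    return donors


# --------------------------------------------------------------------------
# polynuclear assembly
# --------------------------------------------------------------------------

def assemble_sites(structure: Structure,
                   config: Config = DEFAULT_CONFIG) -> list[MetalSite]:
    """Group the metal ions of *structure* into sites.

    Two ions belong to the same site if they share a ligand residue or
    lie closer than the merge cutoff (strict ``<``); grouping is the
    transitive closure of this relation (connected components).
    """
    metals = list_metal_atoms(structure, config)
    if not metals:
        return []
    donors_per_metal = {id(m): detect_donors(structure, m, config)
                        for m in metals}
    lig_keys = {id(m): {d.residue.key for d in donors_per_metal[id(m)]}
                for m in metals}

    g = nx.Graph()
    g.add_nodes_from(range(len(metals)))
    for i in range(len(metals)):
        for j in range(i + 1, len(metals)):
            if metals[i].distance(metals[j]) < config.merge_cutoff or \
                    lig_keys[id(metals[i])] & lig_keys[id(metals[j])]:
                g.add_edge(i, j)

    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])

    sites = []
    for n, comp in enumerate(comps):
        ms = [metals[i] for i in comp]
        donor_atoms: list[Atom] = []
        seen: set[int] = set()
        for i in comp:
            for d in donors_per_metal[id(metals[i])]:
                if id(d) not in seen:
                    seen.add(id(d))
                    donor_atoms.append(d)
        endo, exo, seen_res = [], [], set()
        for d in donor_atoms:
            r = d.residue
            if r.key in seen_res:
                continue
            seen_res.add(r.key)
            (endo if r.is_polymer else exo).append(r)
        elems = "".join(sorted({m.element for m in ms}))
        sites.append(MetalSite(
            metals=ms, donor_atoms=donor_atoms,
            endogenous_ligands=endo, exogenous_ligands=exo,
            site_id=f"{structure.id}:{n + 1}:{elems}",
        ))
    return sites


# --------------------------------------------------------------------------
# MFS construction
# --------------------------------------------------------------------------

def build_mfs(structure: Structure, site: MetalSite,
              config: Config = DEFAULT_CONFIG) -> MFS:
    """Environment = every residue (any kind) with at least one
    non-hydrogen atom strictly within the neighbor cutoff of any
    non-hydrogen atom of any ligand residue, excluding the ligands
    themselves and the metal-bearing hetero residues of the site."""
    ligand_keys = {r.key for r in site.ligands}
    metal_res_keys = {m.residue.key for m in site.metals}

    lig_coords = np.concatenate(
        [r.heavy_coords() for r in site.ligands]
    ) if site.ligands else np.empty((0, 3))
    env: list[Residue] = []
    if len(lig_coords):
        tree = cKDTree(lig_coords)
        for res in structure.residues:
            if res.key in ligand_keys or res.key in metal_res_keys:
                continue
            coords = res.heavy_coords()
            if len(coords) == 0:
                continue
            dist, _ = tree.query(coords, k=1)
            if np.min(dist) < config.neighbor_cutoff:
                env.append(res)

    mfs = MFS(site=site, environment=env, source=structure)
    mfs.fragments = split_fragments(mfs)
    mfs.mbp = compute_mbp(mfs)
    return mfs


def extract_mfs(structure: Structure,
                config: Config = DEFAULT_CONFIG) -> list[MFS]:
    """Convenience: assemble all sites of *structure* and build their MFSs."""
    return [build_mfs(structure, s, config)
            for s in assemble_sites(structure, config)]


# --------------------------------------------------------------------------
# fragments and MBP
# --------------------------------------------------------------------------

def split_fragments(mfs: MFS) -> list[Fragment]:
    """Maximal runs of sequence-consecutive polymer residues of the MFS,
    per chain."""
    ligand_keys = {r.key for r in mfs.site.ligands}
    by_chain: dict[str, list[Residue]] = {}
    for r in mfs.polymer_residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    fragments = []
    for chain_id in sorted(by_chain):
        rs = sorted(by_chain[chain_id], key=lambda r: (r.seq_pos, r.icode))
        run: list[Residue] = []
        for r in rs:
            if run and r.seq_pos - run[-1].seq_pos > 1:
                fragments.append(_make_fragment(chain_id, run, ligand_keys))
                run = []
            # duplicate seq_pos (insertion codes) stays within the run
            run.append(r)
        if run:
            fragments.append(_make_fragment(chain_id, run, ligand_keys))
    return fragments


def _make_fragment(chain_id: str, residues: list[Residue],
                   ligand_keys: set) -> Fragment:
    ligs = [r for r in residues if r.key in ligand_keys]
    return Fragment(chain_id=chain_id, residues=list(residues),
                    n_ligands=len(ligs),
                    ligand_seq_positions=tuple(r.seq_pos for r in ligs))


def compute_mbp(site_or_mfs) -> str:
    """Metal-binding pattern: one-letter codes of the amino-acid ligands
    in chain/sequence order, separated by ``X(n)`` spacers giving the
    number of intervening sequence positions; chains joined by ``/``."""
    site = site_or_mfs.site if isinstance(site_or_mfs, MFS) else site_or_mfs
    aa_ligs = sorted(
        (r for r in site.endogenous_ligands if r.kind == "amino_acid"),
        key=lambda r: (r.chain_id, r.seq_pos, r.icode),
    )
    if not aa_ligs:
        warnings.warn(f"site {site.site_id}: no endogenous amino-acid "
                      "ligand, empty MBP", stacklevel=2)
        return ""
    parts = []
    for i, r in enumerate(aa_ligs):
        if i == 0:
            parts.append(r.one_letter)
            continue
        prev = aa_ligs[i - 1]
        if r.chain_id != prev.chain_id:
            parts.append("/")
        else:
            gap = r.seq_pos - prev.seq_pos - 1
            if gap > 0:
                parts.append(f"X({gap})")
        parts.append(r.one_letter)
    return "".join(parts)


# --------------------------------------------------------------------------
# statistics filter + JSON report
# --------------------------------------------------------------------------

def passes_min_donors(site: MetalSite, config: Config = DEFAULT_CONFIG,
                      structure: Structure | None = None) -> bool:
    """Adventitious-site filter: every metal ion of the site must have at
    least the per-element minimum number of donors."""
    st = structure
    for m in site.metals:
        need = config.min_donors.get(m.element, config.default_min_donors)
        if st is not None:
            have = len(detect_donors(st, m, config))
        else:
            have = sum(
                1 for d in site.donor_atoms
                if m.distance(d) <= donor_cutoff(m.element, d.element, config)
            )
        if have < need:
            return False
    return True


def mfs_report(mfs: MFS) -> dict:
    """JSON-serializable description of one MFS."""
    site = mfs.site
    return {
        "site_id": site.site_id,
        "metals": [
            {"element": m.element, "residue": m.residue.label,
             "coords": [round(float(v), 3) for v in m.coords]}
            for m in site.metals
        ],
        "nuclearity": site.nuclearity,
        "center": [round(float(v), 3) for v in mfs.center],
        "donors": [
            {"atom": d.name, "element": d.element, "residue": d.residue.label,
             "endogenous": d.residue.is_polymer}
            for d in site.donor_atoms
        ],
        "endogenous_ligands": [r.label for r in site.endogenous_ligands],
        "exogenous_ligands": [r.label for r in site.exogenous_ligands],
        "environment": [r.label for r in mfs.environment],
        "fragments": [
            {"chain": f.chain_id, "span": list(f.span),
             "sequence": f.sequence, "n_ligands": f.n_ligands}
            for f in mfs.fragments
        ],
        "mbp": mfs.mbp,
    }


def mfs_to_structure(mfs: MFS) -> Structure:
    """Standalone Structure containing only the MFS residues and metals
    (for PDB export / library storage)."""
    keys = {r.key for r in mfs.residues}
    metal_keys = {m.residue.key for m in mfs.site.metals}
    src = mfs.source
    residues = []
    for r in src.residues:
        if r.key in keys or r.key in metal_keys:
            atoms = [Atom(a.name, a.element, a.coords.copy(), a.occupancy,
                          a.altloc, serial=a.serial) for a in r.atoms]
            residues.append(Residue(r.chain_id, r.seq_pos, r.icode, r.name,
                                    r.kind, atoms))
    out = Structure(id=f"{mfs.mfs_id}", residues=residues)
    out.meta = {"mfs_of": src.id, "site_id": mfs.mfs_id}
    return out
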