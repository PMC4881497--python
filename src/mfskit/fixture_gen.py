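"""Deterministic generator of synthetic metalloprotein structures.

Every downstream stage (extraction, superposition, search, clustering,
statistics) is exercised on structures produced here, with ground truth
recorded in ``Structure.meta``.  The generator aims for *geometric*
realism where it matters to the method -- coordination distances and
angles, CA/CB placement near the donors, sequence-fragment layout --
and only approximates the rest of the backbone (no Ramachandran
enforcement, no sterics).

Layout mini-language
--------------------
A site is described by a :class:`SiteSpec`.  Its ``layout`` is a list of
``(chain_id, start_seq, pattern)`` fragments where each pattern
character is one residue:

* ``L`` -- the next ligand from ``ligands`` (donor on the metal),
* ``.`` -- an alanine filler,
* any other upper-case letter -- a filler of that amino-acid type
  (useful for enrichment fixtures, e.g. a Trp two before a His ligand).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import logger
from .structure_model import Atom, Residue, Structure, one_letter_code

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AMINO_ACIDS = tuple(_ONE_TO_THREE)

_GEOMETRIES: dict[str, np.ndarray] = {
    "tetrahedral": np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0),
    "octahedral": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    ),
    "linear": np.array([[1, 0, 0], [-1, 0, 0]], dtype=float),
}

#: donor-to-CB and donor-to-CA radial offsets (Angstrom); ring donors
#: (His NE2/ND1) sit further from the backbone than thiolate/carboxylate.
_SIDECHAIN_REACH = {"default": (1.2, 2.4), "ring": (2.2, 3.4)}


@dataclass(frozen=True)
class SiteSpec:
    """Recipe for one synthetic mononuclear site."""

    metal: str = "Zn"
    donor_geometry: str = "tetrahedral"
    metal_donor_distance: float = 2.3
    ligands: tuple[tuple[str, str], ...] = (
        ("CYS", "SG"), ("CYS", "SG"), ("CYS", "SG"), ("CYS", "SG"),
    )
    layout: tuple[tuple[str, int, str], ...] = (("A", 1, "L..L."), ("A", 19, ".L..L"))
    custom_directions: tuple[tuple[float, float, float], ...] = ()
    tail_length: int = 0            # distant same-chain residues (> 12 A away)
    noise_sd: float = 0.0
    seed: int = 0
    name: str = "site"

    @property
    def n_donors(self) -> int:
        return len(self.ligands)

    def replace(self, **kw) -> "SiteSpec":
        return dataclasses.replace(self, **kw)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(u, ref))


def _slerp(u0: np.ndarray, u1: np.ndarray, t: float) -> np.ndarray:
    dot = float(np.clip(np.dot(u0, u1), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-8:
        return u0
    if np.sin(omega) < 1e-6:            # antipodal: arc through a fixed normal
        axis = _perp(u0)
        return Rotation.from_rotvec(axis * (t * omega)).apply(u0)
    return _unit(
        (np.sin((1 - t) * omega) * u0 + np.sin(t * omega) * u1) / np.sin(omega)
    )


def _directions(spec: SiteSpec) -> np.ndarray:
    if spec.donor_geometry == "custom":
        dirs = np.array(spec.custom_directions, dtype=float)
        if len(dirs) < spec.n_donors:
            raise ValueError("custom geometry needs one direction per donor")
        return np.array([_unit(d) for d in dirs[: spec.n_donors]])
    if spec.donor_geometry not in _GEOMETRIES:
        raise ValueError(f"unsupported geometry {spec.donor_geometry!r}")
    verts = _GEOMETRIES[spec.donor_geometry]
    if spec.n_donors > len(verts):
        raise ValueError(
            f"{spec.donor_geometry} geometry supports at most {len(verts)} donors"
        )
    return verts[: spec.n_donors]


def _backbone_atoms(ca: np.ndarray, outward: np.ndarray, tangent: np.ndarray,
                    with_cb: bool) -> list[Atom]:
    """Minimal N/CA/C/O(/CB) set around a CA position."""
    atoms = [
        Atom("N", "N", ca - 1.46 * tangent + 0.4 * outward),
        Atom("CA", "C", ca.copy()),
        Atom("C", "C", ca + 1.52 * tangent + 0.4 * outward),
        Atom("O", "O", ca + 1.52 * tangent + 0.4 * outward + 1.23 * _perp(tangent)),
    ]
    if with_cb:
        atoms.append(Atom("CB", "C", ca + 1.53 * outward))
    return atoms


def _ligand_residue(chain: str, seq: int, resname: str, donor_name: str,
                    direction: np.ndarray, distance: float,
                    tangent: np.ndarray) -> Residue:
    donor = distance * direction
    reach = _SIDECHAIN_REACH["ring" if resname == "HIS" else "default"]
    cb = donor + reach[0] * direction
    ca = donor + reach[1] * direction + 0.3 * tangent
    atoms = _backbone_atoms(ca, direction, tangent, with_cb=(resname != "GLY"))
    atoms.append(Atom(donor_name, _donor_element(donor_name), donor))
    return Residue(chain, seq, "", resname, "amino_acid", atoms)


def _donor_element(atom_name: str) -> str:
    lead = atom_name.strip()[0]
    return {"S": "S", "O": "O", "N": "N", "P": "P"}.get(lead, lead)


def _filler_residue(chain: str, seq: int, code: str, ca: np.ndarray,
                    outward: np.ndarray, tangent: np.ndarray) -> Residue:
    resname = _ONE_TO_THREE[code]
    atoms = _backbone_atoms(ca, outward, tangent, with_cb=(resname != "GLY"))
    return Residue(chain, seq, "", resname, "amino_acid", atoms)


def make_site(spec: SiteSpec) -> Structure:
    """Build one mononuclear site per *spec*.

    The metal sits at the origin; donors sit exactly on the ideal
    geometry vertices at ``metal_donor_distance`` before noise; filler
    residues are threaded between the ligand anchors; ``tail_length``
    extra residues extend away from the site (all > 12 A from any
    ligand atom) so that chain-vs-MFS sequence comparisons have a
    non-site context.  Identical spec (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    dirs = _directions(spec)
    n_slots = sum(p.count("L") for _, _, p in spec.layout)
    if n_slots != spec.n_donors:
        raise ValueError(
            f"layout has {n_slots} ligand slots but spec lists {spec.n_donors} ligands"
        )

    residues: list[Residue] = []
    ligand_res: list[Residue] = []
    lig_index = 0
    d = spec.metal_donor_distance
    ca_radius = d + _SIDECHAIN_REACH["default"][1]

    for chain, start, pattern in spec.layout:
        # anchor CA positions for ligand slots in this fragment
        slots = [i for i, c in enumerate(pattern) if c == "L"]
        frag_ligs = list(range(lig_index, lig_index + len(slots)))
        frag_dirs = {i: dirs[frag_ligs[k]] for k, i in enumerate(slots)}
        # fragment tangent: perpendicular to the first anchor direction
        t0 = _perp(frag_dirs[slots[0]] if slots else np.array([1.0, 0.0, 0.0]))
        for i, c in enumerate(pattern):
            seq = start + i
            if c == "L":
                resname, donor_name = spec.ligands[lig_index]
                res = _ligand_residue(chain, seq, resname, donor_name,
                                      dirs[lig_index], d, t0)
                residues.append(res)
                ligand_res.append(res)
                lig_index += 1
            else:
                code = "A" if c == "." else c
                if code not in _ONE_TO_THREE:
                    raise ValueError(f"unknown layout code {c!r}")
                ca, outward = _filler_ca(i, pattern, slots, frag_dirs, t0, ca_radius)
                residues.append(_filler_residue(chain, seq, code, ca, outward, t0))

    # distant tail on the chain of the first fragment
    if spec.tail_length:
        chain = spec.layout[0][0]
        last = max(r.seq_pos for r in residues if r.chain_id == chain)
        far_dir = _unit(np.array([1.0, 1.0, -1.0]))
        t_t = _perp(far_dir)
        for j in range(spec.tail_length):
            ca = (16.0 + 3.8 * j) * far_dir + 2.0 * np.sin(0.7 * j) * t_t
            residues.append(
                _filler_residue(chain, last + 1 + j, "A", ca, far_dir, t_t)
            )

    metal_res = Residue("M", 900, "", spec.metal.upper(), "other_hetero",
                        [Atom(spec.metal.upper(), spec.metal.capitalize(),
                              np.zeros(3))])
    residues.append(metal_res)

    if spec.noise_sd > 0:
        for r in residues:
            if r is metal_res:
                continue
            for a in r.atoms:
                a.coords = a.coords + rng.normal(0.0, spec.noise_sd, 3)

    st = Structure(id=spec.name, residues=residues)
    st.meta = {
        "generator": "make_site",
        "seed": spec.seed,
        "nuclearity": 1,
        "metal": spec.metal.capitalize(),
        "ligand_keys": [list(r.key) for r in ligand_res],
        "mfs_keys": _intended_members(st),
    }
    return st


def _filler_ca(i: int, pattern: str, slots: list[int],
               frag_dirs: dict[int, np.ndarray], tangent: np.ndarray,
               ca_radius: float) -> tuple[np.ndarray, np.ndarray]:
    """CA position for filler *i*: arc between flanking ligand anchors,
    or a 3.8 A/residue walk beyond the terminal anchor."""
    prev = max((s for s in slots if s < i), default=None)
    nxt = min((s for s in slots if s > i), default=None)
    if prev is not None and nxt is not None:
        t = (i - prev) / (nxt - prev)
        u = _slerp(frag_dirs[prev], frag_dirs[nxt], t)
        # bulge outward so long gaps loop away from the site
        gap = nxt - prev - 1
        chord = ca_radius * np.linalg.norm(frag_dirs[nxt] - frag_dirs[prev])
        need = 3.5 * (gap + 1)
        bulge = max(0.0, (need - chord)) * 0.6 * np.sin(np.pi * t)
        return (ca_radius + bulge) * u, u
    anchor = prev if prev is not None else nxt
    if anchor is None:          # fragment with no ligand: straight strand
        u = _unit(np.array([0.0, 1.0, 1.0]))
        return (ca_radius + 6.0 + 3.8 * i) * u, u
    delta = i - anchor
    u = frag_dirs[anchor]
    ca = ca_radius * u + 3.8 * delta * tangent + 0.6 * abs(delta) * u
    return ca, u


def _intended_members(st: Structure) -> list[list]:
    """Ground-truth MFS membership (ligands + residues with a heavy atom
    within 5 A of a ligand heavy atom) recorded by direct scan of the
    generated coordinates."""
    from .site_extraction import assemble_sites, build_mfs

    sites = assemble_sites(st)
    keys: set = set()
    for site in sites:
        mfs = build_mfs(st, site)
        for r in mfs.residues:
            keys.add(r.key)
    return sorted([list(k) for k in keys])


# --------------------------------------------------------------------------
# polynuclear fixtures
# --------------------------------------------------------------------------

def make_polynuclear(n_metals: int, bridge: str, spacing: float, seed: int = 0,
                     metal: str = "Zn") -> Structure:
    """Chain of *n_metals* ions along x, each with two Cys ligands.

    ``bridge``:

    * ``shared_ligand`` -- consecutive ions share a bidentate Asp
      (OD1 on one ion, OD2 on the next), regardless of spacing;
    * ``proximity`` -- consecutive ions closer than 5 A with disjoint
      ligands (spacing >= 5 is rejected);
    * ``none`` -- disjoint ligands, no constraint on spacing.
    """
    if n_metals < 2:
        raise ValueError("n_metals must be >= 2")
    if bridge not in ("shared_ligand", "proximity", "none"):
        raise ValueError(f"unknown bridge mode {bridge!r}")
    if bridge == "proximity" and spacing >= 5.0:
        raise ValueError("proximity bridging requires spacing < 5 A")

    residues: list[Residue] = []
    xhat = np.array([1.0, 0.0, 0.0])
    for i in range(n_metals):
        pos = i * spacing * xhat
        residues.append(
            Residue("M", 901 + i, "", metal.upper(), "other_hetero",
                    [Atom(metal.upper(), metal.capitalize(), pos)])
        )
        # two Cys per ion, perpendicular to the chain axis, rotated per ion
        phi = np.deg2rad(35.0 * i)
        for k, base in enumerate((np.array([0.0, 1.0, 1.0]),
                                  np.array([0.0, -1.0, -1.0]))):
            u = _unit(Rotation.from_rotvec(phi * xhat).apply(base))
            res = _ligand_residue("A", 10 * i + 1 + 3 * k, "CYS", "SG", u, 2.3,
                                  _perp(u))
            for a in res.atoms:
                a.coords = a.coords + pos
            residues.append(res)
    if bridge == "shared_ligand":
        for i in range(n_metals - 1):
            a_pos = i * spacing * xhat
            b_pos = (i + 1) * spacing * xhat
            up = np.array([0.0, 0.0, 1.0])
            od1 = a_pos + 2.0 * _unit(up + 0.3 * xhat)
            od2 = b_pos + 2.0 * _unit(up - 0.3 * xhat)
            mid = 0.5 * (od1 + od2)
            cg = mid + 1.2 * up
            cb = cg + 1.5 * up
            ca = cb + 1.53 * _unit(up + 0.2 * xhat)
            t = _perp(up)
            atoms = _backbone_atoms(ca, up, t, with_cb=False)
            atoms += [Atom("CB", "C", cb), Atom("CG", "C", cg),
                      Atom("OD1", "O", od1), Atom("OD2", "O", od2)]
            residues.append(Residue("B", 50 + i, "", "ASP", "amino_acid", atoms))

    st = Structure(id=f"poly_{metal.lower()}{n_metals}_{bridge}",
                   residues=residues)
    st.meta = {
        "generator": "make_polynuclear",
        "seed": seed,
        "nuclearity": n_metals if bridge != "none" else 1,
        "n_sites": 1 if bridge != "none" else n_metals,
        "metal": metal.capitalize(),
    }
    return st


def make_fes4_cluster(seed: int = 0) -> Structure:
    """Cubane-like Fe4S4 cluster with four Cys ligands, three of them
    close in sequence (ferredoxin-style) and one distant."""
    a = 2.3
    fe_pos = np.array([[0, 0, 0], [a, a, 0], [a, 0, a], [0, a, a]], dtype=float)
    s_pos = np.array([[a, 0, 0], [0, a, 0], [0, 0, a], [a, a, a]], dtype=float)
    center = fe_pos.mean(axis=0)
    residues: list[Residue] = []
    for i, p in enumerate(fe_pos):
        residues.append(Residue("M", 901 + i, "", "FE", "other_hetero",
                                [Atom("FE", "Fe", p)]))
    for i, p in enumerate(s_pos):
        residues.append(Residue("M", 911 + i, "", "S", "other_hetero",
                                [Atom("S", "S", p)]))
    seqs = (5, 8, 11, 40)
    cys_res = []
    for i, (p, seq) in enumerate(zip(fe_pos, seqs)):
        u = _unit(p - center)
        res = _ligand_residue("A", seq, "CYS", "SG", u, 2.3, _perp(u))
        for at in res.atoms:
            at.coords = at.coords + p
        residues.append(res)
        cys_res.append(res)
    # connecting residues so the three close Cys form a single fragment
    for k in range(2):
        ca0 = cys_res[k].atom("CA").coords
        ca1 = cys_res[k + 1].atom("CA").coords
        radius = 0.5 * (np.linalg.norm(ca0 - center) + np.linalg.norm(ca1 - center))
        for j, t in enumerate((1 / 3, 2 / 3)):
            out = _slerp(_unit(ca0 - center), _unit(ca1 - center), t)
            ca = center + radius * out
            residues.append(_filler_residue("A", seqs[k] + 1 + j, "A", ca,
                                            out, _perp(out)))
    st = Structure(id="fes4", residues=residues)
    st.meta = {"generator": "make_fes4_cluster", "seed": seed,
               "nuclearity": 4, "metal": "Fe"}
    return st


# --------------------------------------------------------------------------
# families of related sites
# --------------------------------------------------------------------------

def make_family(base: SiteSpec, n_members: int, mutation_rate: float = 0.0,
                coord_noise_sd: float = 0.0, rigid_motion: bool = True,
                seed: int = 0, protect: str = "ligands",
                family_label: str | None = None) -> list[Structure]:
    """Family of structures derived from *base* by point mutations of
    non-ligand residues, per-atom Gaussian noise and a random rigid
    motion.  ``protect='mfs'`` additionally shields every residue of the
    base MFS from mutation, leaving only the distant context mutable.
    """
    if not 0.0 <= mutation_rate < 1.0:
        raise ValueError("mutation_rate must be in [0, 1)")
    if protect not in ("ligands", "mfs"):
        raise ValueError("protect must be 'ligands' or 'mfs'")
    rng = np.random.default_rng(seed)
    base_st = make_site(base)
    label = family_label or base.name
    lig_keys = {tuple(k) for k in base_st.meta["ligand_keys"]}
    protected = set(lig_keys)
    if protect == "mfs":
        protected |= {tuple(k) for k in base_st.meta["mfs_keys"]}

    members = []
    for m in range(n_members):
        residues = []
        for r in base_st.residues:
            name = r.name
            if (r.kind == "amino_acid" and r.key not in protected
                    and rng.random() < mutation_rate):
                cur = one_letter_code(name)
                choices = [c for c in AMINO_ACIDS if c not in (cur, "G", "P")]
                name = _ONE_TO_THREE[choices[rng.integers(len(choices))]]
            atoms = [Atom(a.name, a.element, a.coords.copy(), a.occupancy,
                          a.altloc) for a in r.atoms]
            residues.append(Residue(r.chain_id, r.seq_pos, r.icode, name,
                                    r.kind, atoms))
        if coord_noise_sd > 0:
            for r in residues:
                for a in r.atoms:
                    a.coords = a.coords + rng.normal(0.0, coord_noise_sd, 3)
        if rigid_motion:
            rot = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(2**31 - 1))))
            shift = rng.uniform(-20.0, 20.0, 3)
            for r in residues:
                for a in r.atoms:
                    a.coords = rot.apply(a.coords) + shift
        st = Structure(id=f"{label}_m{m}", residues=residues)
        st.meta = {
            "generator": "make_family",
            "family": label,
            "member": m,
            "seed": seed,
            "nuclearity": 1,
            "base_ligand_keys": sorted(list(k) for k in lig_keys),
        }
        members.append(st)
    return members


# --------------------------------------------------------------------------
# sequence-only fragments for enrichment statistics
# --------------------------------------------------------------------------

def make_pattern_fragments(n: int, subpattern_positions: tuple[tuple[int, str], ...],
                           flank_left: int, flank_right: int,
                           background: dict[str, float], seed: int = 0,
                           enrich: dict[int, tuple[str, float]] | None = None):
    """Sequence-only fragments around a fixed ligand sub-pattern.

    *subpattern_positions* gives (offset, one-letter code) of the anchor
    ligands relative to the first anchor (e.g. ``((0,'H'),(3,'C'))`` for
    HX(2)C).  Non-anchor positions are drawn i.i.d. from *background*;
    *enrich* optionally forces residue *aa* at a relative position with
    the given probability.  Returns :class:`~mfskit.site_extraction.Fragment`
    objects with the anchors marked as ligands.
    """
    from .site_extraction import Fragment

    rng = np.random.default_rng(seed)
    aas = sorted(background)
    probs = np.array([background[a] for a in aas], dtype=float)
    probs = probs / probs.sum()
    anchor = dict(subpattern_positions)
    start_rel = -flank_left
    length = flank_left + (max(anchor) + 1) + flank_right
    frags = []
    for i in range(n):
        residues = []
        lig_pos = []
        for j in range(length):
            rel = start_rel + j
            seq = 100 + j
            if rel in anchor:
                code = anchor[rel]
                lig_pos.append(seq)
            elif enrich and rel in enrich and rng.random() < enrich[rel][1]:
                code = enrich[rel][0]
            else:
                code = aas[rng.choice(len(aas), p=probs)]
            residues.append(Residue("A", seq, "", _ONE_TO_THREE[code],
                                    "amino_acid", []))
        frags.append(Fragment(chain_id="A", residues=residues,
                              n_ligands=len(lig_pos),
                              ligand_seq_positions=tuple(lig_pos)))
    logger.debug("generated %d pattern fragments", len(frags))
    return frags


# --------------------------------------------------------------------------
# randomized specs for property panels
# --------------------------------------------------------------------------

_LIGAND_POOL = (
    ("CYS", "SG"), ("HIS", "NE2"), ("ASP", "OD1"), ("GLU", "OE1"),
    ("SER", "OG"), ("MET", "SD"), ("ASN", "OD1"), ("TYR", "OH"),
)
_GEOMETRY_CAPACITY = {"tetrahedral": 4, "octahedral": 6, "linear": 2}


def random_site_spec(seed: int, name: str | None = None) -> SiteSpec:
    """Draw a varied but valid mononuclear site recipe: random metal,
    coordination geometry (randomly oriented and angularly jittered),
    ligand set, filler sequence and fragment layout.  Used for property
    panels (extraction oracles, score calibration)."""
    rng = np.random.default_rng(seed)
    metal = ["Zn", "Fe", "Cu", "Ca", "Mg", "Mn", "Ni", "Co"][rng.integers(8)]
    geometry = ["tetrahedral", "octahedral", "linear"][rng.integers(3)]
    cap = _GEOMETRY_CAPACITY[geometry]
    n_donors = int(rng.integers(2, cap + 1))
    ligands = tuple(_LIGAND_POOL[rng.integers(len(_LIGAND_POOL))]
                    for _ in range(n_donors))
    # randomly orient the ideal vertex frame, permute vertex assignment
    # and add a few degrees of angular jitter per donor
    verts = _GEOMETRIES[geometry][rng.permutation(cap)[:n_donors]]
    frame = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2**31 - 1))))
    dirs = []
    for v in verts:
        axis = _perp(v)
        jitter = Rotation.from_rotvec(
            axis * np.deg2rad(rng.uniform(0.0, 10.0)))
        spin = Rotation.from_rotvec(v * rng.uniform(0.0, 2 * np.pi))
        dirs.append(tuple(frame.apply(spin.apply(jitter.apply(v)))))
    # distribute donors over 1-3 fragments with varied filler sequence
    n_frags = int(rng.integers(1, min(3, n_donors) + 1))
    counts = np.ones(n_frags, dtype=int)
    for _ in range(n_donors - n_frags):
        counts[rng.integers(n_frags)] += 1
    layout = []
    start = int(rng.integers(1, 6))
    for fc in counts:
        pattern = ""
        for k in range(fc):
            pattern += _random_fillers(rng, 0, 3) + "L"
        pattern += _random_fillers(rng, 1, 4)
        layout.append(("A", start, pattern))
        start += len(pattern) + int(rng.integers(4, 15))
    # coordination distance near the covalent-radius sum of the metal and
    # its closest donor element (chemically plausible, never marginal
    # against the detection cutoff)
    from .structure_model import covalent_radius

    r_donor = min(covalent_radius(_donor_element(dn)) for _, dn in ligands)
    distance = covalent_radius(metal) + r_donor + float(rng.uniform(-0.25, -0.05))
    return SiteSpec(metal=metal, donor_geometry="custom",
                    custom_directions=tuple(dirs),
                    metal_donor_distance=distance, ligands=ligands,
                    layout=tuple(layout), seed=int(rng.integers(2**31 - 1)),
                    name=name or f"rand{seed}")


_FILLER_CODES = tuple(a for a in AMINO_ACIDS if a != "L")  # 'L' marks ligands


def _random_fillers(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi))
    return "".join(_FILLER_CODES[rng.integers(len(_FILLER_CODES))]
                   for _ in range(n))


def unrelated_spec_pair(seed: int) -> tuple[SiteSpec, SiteSpec]:
    """Two random specs guaranteed to differ in coordination geometry or
    ligand composition, i.e. genuinely unrelated sites."""
    a = random_site_spec(3 * seed + 1, name=f"u{seed}a")
    offset = 0
    while True:
        b = random_site_spec(10_000_019 + 3 * seed + offset, name=f"u{seed}b")
        if (b.donor_geometry != a.donor_geometry
                or sorted(b.ligands) != sorted(a.ligands)):
            return a, b
        offset += 1
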