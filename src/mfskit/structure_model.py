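"""Coordinate model, PDB/mmCIF input, metal identification and writers.

The in-memory model is deliberately flat: a :class:`Structure` owns an
ordered list of :class:`Residue` objects, each owning :class:`Atom`
objects.  Only the first model of a multi-model file is kept, and
alternate locations are collapsed to the highest-occupancy conformer so
that all downstream distance logic sees a single-conformer structure.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .config import Config, DEFAULT_CONFIG, logger

# --------------------------------------------------------------------------
# element sets
# --------------------------------------------------------------------------

_ALKALI = {"Li", "Na", "K", "Rb", "Cs", "Fr"}
_ALKALINE_EARTH = {"Be", "Mg", "Ca", "Sr", "Ba", "Ra"}
_TRANSITION = {
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Rf", "Db", "Sg", "Bh", "Hs",
}
_POST_TRANSITION = {"Al", "Ga", "In", "Sn", "Tl", "Pb", "Bi", "Po"}
_LANTHANIDES = {
    "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
    "Ho", "Er", "Tm", "Yb", "Lu",
}
_ACTINIDES = {
    "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
    "Es", "Fm", "Md", "No", "Lr",
}

#: Periodic-table metals.  Metalloids (B, Si, Ge, As, Se, Sb, Te) are
#: excluded by default but can be added through ``Config.extra_metals``.
METAL_ELEMENTS: frozenset[str] = frozenset(
    _ALKALI | _ALKALINE_EARTH | _TRANSITION | _POST_TRANSITION
    | _LANTHANIDES | _ACTINIDES
)

_KNOWN_ELEMENTS: frozenset[str] = frozenset(
    gemmi.Element(z).name for z in range(1, 119)
)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hydrogen: bool = False
    serial: int = 0
    residue: "Residue | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        self.is_hydrogen = self.element in ("H", "D")

    def distance(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.coords - other.coords))


@dataclass
class Residue:
    chain_id: str
    seq_pos: int
    icode: str
    name: str
    kind: str                      # amino_acid | nucleotide | water | other_hetero
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        for a in self.atoms:
            a.residue = self

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_pos, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.seq_pos}{self.icode}".rstrip()

    @property
    def is_polymer(self) -> bool:
        return self.kind in ("amino_acid", "nucleotide")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return one_letter_code(self.name) if self.kind == "amino_acid" else "X"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()]).reshape(-1, 3)


@dataclass
class Structure:
    id: str
    model_no: int = 1
    residues: list[Residue] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter amino-acid sequence of a chain (polymer residues only)."""
        return "".join(
            r.one_letter for r in self.residues
            if r.chain_id == chain_id and r.kind == "amino_acid"
        )

    def get_residue(self, key: tuple[str, int, str]) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None


# --------------------------------------------------------------------------
# residue / element classification helpers
# --------------------------------------------------------------------------

def residue_kind(name: str) -> str:
    if name.upper() in _WATER_NAMES:
        return "water"
    info = gemmi.find_tabulated_residue(name.upper())
    if info is not None:
        if info.is_water():
            return "water"
        if info.is_amino_acid():
            return "amino_acid"
        if info.is_nucleic_acid():
            return "nucleotide"
    return "other_hetero"


def one_letter_code(name: str) -> str:
    """One-letter code of an amino acid; nonstandard residues map to their
    parent where tabulated (e.g. MSE -> M), otherwise 'X'."""
    info = gemmi.find_tabulated_residue(name.upper())
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def is_metal(element: str, config: Config = DEFAULT_CONFIG) -> bool:
    """True if *element* is a periodic-table metal under the configured set."""
    sym = element.capitalize()
    if sym not in _KNOWN_ELEMENTS:
        raise ValueError(f"unknown element symbol: {element!r}")
    if sym in config.excluded_metals:
        return False
    return sym in METAL_ELEMENTS or sym in config.extra_metals


def list_metal_atoms(
    structure: Structure, config: Config = DEFAULT_CONFIG
) -> list[Atom]:
    """All metal atoms of *structure* in file order (owning residue via
    ``atom.residue``)."""
    out = []
    for res in structure.residues:
        for a in res.atoms:
            if a.element in _KNOWN_ELEMENTS and is_metal(a.element, config):
                out.append(a)
    return out


def covalent_radius(element: str) -> float:
    return float(gemmi.Element(element).covalent_r)


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

def _collapse_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    altloc letter."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
        else:
            kept.append(min(group, key=lambda a: (-a.occ, a.altloc)))
    return kept


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the mfskit coordinate model.

    Only the first model is kept (a warning is emitted for multi-model
    files); alternate locations are collapsed to the highest-occupancy
    conformer; hydrogens are retained but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and fmt not in ("pdb", "mmcif"):
            raise
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) > 1:
        warnings.warn(
            f"{path.name}: {len(st)} models present, using model 1 only",
            stacklevel=2,
        )
    if len(st) == 0:
        raise ParseError(f"{path}: no coordinate model found")

    model = st[0]
    residues: list[Residue] = []
    serial = 0
    for chain in model:
        for gres in chain:
            atoms = []
            for ga in _collapse_altlocs(list(gres)):
                serial += 1
                altloc = ga.altloc if ga.altloc not in ("\x00", "") else ""
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=float(ga.occ),
                        altloc=altloc,
                        serial=serial,
                    )
                )
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_pos=gres.seqid.num,
                    icode=icode,
                    name=gres.name,
                    kind=residue_kind(gres.name),
                    atoms=atoms,
                )
            )
    sid = st.name if st.name else path.stem
    return Structure(id=sid, model_no=1, residues=residues)


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def _pdb_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: element right-justified in columns 13-14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def to_pdb_string(structure: Structure) -> str:
    """Serialize a Structure as fixed-width PDB text (single model)."""
    lines = []
    serial = 0
    for res in structure.residues:
        record = "ATOM  " if res.kind in ("amino_acid", "nucleotide") else "HETATM"
        for a in res.atoms:
            serial += 1
            x, y, z = a.coords
            lines.append(
                f"{record}{serial:5d} {_pdb_atom_name(a.name, a.element):4s}"
                f"{'':1s}{res.name:>3s} {res.chain_id[:1]:1s}"
                f"{res.seq_pos:4d}{(res.icode or ' '):1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(structure: Structure, path: str | Path) -> None:
    Path(path).write_text(to_pdb_string(structure))


def structure_report(structure: Structure) -> dict:
    """JSON-serializable inventory of a structure."""
    return {
        "id": structure.id,
        "model_no": structure.model_no,
        "n_residues": len(structure.residues),
        "n_atoms": sum(len(r.atoms) for r in structure.residues),
        "chains": {
            cid: len(rs) for cid, rs in structure.chains().items()
        },
        "metals": [
            {
                "element": a.element,
                "residue": a.residue.label,
                "coords": [round(float(v), 3) for v in a.coords],
            }
            for a in list_metal_atoms(structure)
        ],
    }


def write_report(structure: Structure, path: str | Path) -> None:
    Path(path).write_text(json.dumps(structure_report(structure), indent=2))


# --------------------------------------------------------------------------
# optional download helper (used only for validation against real entries)
# --------------------------------------------------------------------------

def fetch_pdb(pdb_id: str, dest_dir: str | Path) -> Path:
    """Download a PDB entry from RCSB into *dest_dir* and return the path.

    Requires network access; cached files are reused.
    """
    import urllib.request

    pdb_id = pdb_id.lower()
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    logger.info("fetching %s", url)
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())
    return dest
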