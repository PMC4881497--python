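"""Shared fixtures: small deterministic synthetic sites."""
from __future__ import annotations

import numpy as np
import pytest

from mfskit import SiteSpec, build_mfs, assemble_sites, make_site


#: per-coordinate sd giving 0.3 A RMS atomic displacement
NOISE_SD_03 = 0.3 / np.sqrt(3.0)

FIG1_SPEC = SiteSpec(
    metal="Zn",
    ligands=(("CYS", "SG"), ("CYS", "SG"), ("HIS", "NE2"), ("CYS", "SG")),
    layout=(("A", 1, "L..L.."), ("A", 19, "..L......L..")),
    seed=1,
    name="fig1",
)

ZNF_SPEC = SiteSpec(
    metal="Zn",
    ligands=(("CYS", "SG"), ("CYS", "SG"), ("HIS", "NE2"), ("HIS", "NE2")),
    layout=(("A", 3, "L..L"), ("A", 17, "..L..L")),
    seed=2,
    name="znf",
)


def first_mfs(structure):
    sites = assemble_sites(structure)
    assert sites, f"no metal site in {structure.id}"
    return build_mfs(structure, sites[0])


@pytest.fixture(scope="session")
def fig1_structure():
    return make_site(FIG1_SPEC)


@pytest.fixture(scope="session")
def fig1_mfs(fig1_structure):
    return first_mfs(fig1_structure)


@pytest.fixture(scope="session")
def znf_mfs():
    return first_mfs(make_site(ZNF_SPEC))


def brute_force_environment(structure, site, cutoff=5.0):
    """O(n^2) all-pairs oracle for MFS environment membership: residues
    (other than ligands and the site's metal residues) with at least one
    non-hydrogen atom strictly within *cutoff* of a non-hydrogen atom of
    a ligand residue."""
    ligand_keys = {r.key for r in site.ligands}
    metal_keys = {m.residue.key for m in site.metals}
    lig_atoms = [a for r in site.ligands for a in r.atoms if not a.is_hydrogen]
    members = set()
    for res in structure.residues:
        if res.key in ligand_keys or res.key in metal_keys:
            continue
        hit = False
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            for la in lig_atoms:
                if np.linalg.norm(a.coords - la.coords) < cutoff:
                    hit = True
                    break
            if hit:
                break
        if hit:
            members.add(res.key)
    return members
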