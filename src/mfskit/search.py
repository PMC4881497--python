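"""Library search: rank a collection of MFSs against a query site.

A :class:`SiteLibrary` is a flat list of extracted MFSs with provenance.
On disk it is a directory holding one PDB file per site (written by the
package's own writer, hence human-inspectable and diff-friendly) plus a
JSON index; loading re-extracts each site from its coordinate block,
which is lossless because an MFS excerpt re-extracts to itself.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .config import Config, DEFAULT_CONFIG, logger
from .metals2 import superpose
from .site_extraction import MFS, extract_mfs, mfs_to_structure
from .structure_model import ParseError, read_structure, write_pdb


@dataclass
class LibraryEntry:
    entry_id: str
    mfs: MFS

    @property
    def metals(self) -> tuple[str, ...]:
        return self.mfs.site.elements

    @property
    def nuclearity(self) -> int:
        return self.mfs.site.nuclearity


@dataclass
class SiteLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, mfs: MFS, entry_id: str | None = None) -> None:
        eid = entry_id or mfs.mfs_id
        if any(e.entry_id == eid for e in self.entries):
            raise ValueError(f"duplicate library entry id {eid!r}")
        self.entries.append(LibraryEntry(entry_id=eid, mfs=mfs))

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        index = []
        for i, e in enumerate(self.entries):
            fname = f"site_{i:04d}.pdb"
            write_pdb(mfs_to_structure(e.mfs), d / fname)
            index.append({
                "entry_id": e.entry_id, "file": fname,
                "metals": list(e.metals), "nuclearity": e.nuclearity,
                "mbp": e.mfs.mbp,
            })
        (d / "index.json").write_text(json.dumps({"entries": index}, indent=2))

    @classmethod
    def load(cls, directory: str | Path,
             config: Config = DEFAULT_CONFIG) -> "SiteLibrary":
        d = Path(directory)
        index = json.loads((d / "index.json").read_text())
        lib = cls()
        for rec in index["entries"]:
            st = read_structure(d / rec["file"], format="pdb")
            sites = extract_mfs(st, config)
            if not sites:
                logger.warning("library block %s yielded no site; skipped",
                               rec["file"])
                continue
            # an MFS excerpt contains exactly one site's residues
            mfs = max(sites, key=lambda m: m.site.nuclearity)
            lib.entries.append(LibraryEntry(entry_id=rec["entry_id"], mfs=mfs))
        return lib


@dataclass
class SearchHit:
    entry_id: str
    score: float
    rmsd: float
    rank: int = 0

    def to_dict(self) -> dict:
        return {"rank": self.rank, "entry_id": self.entry_id,
                "score": self.score, "rmsd": self.rmsd}


def build_library(paths: list[str | Path],
                  config: Config = DEFAULT_CONFIG) -> SiteLibrary:
    """Extract every MFS of every readable structure file into a library.
    Unreadable files are skipped with a logged warning."""
    lib = SiteLibrary()
    for p in paths:
        try:
            st = read_structure(p)
        except (ParseError, FileNotFoundError) as exc:
            logger.warning("skipping %s: %s", p, exc)
            continue
        for mfs in extract_mfs(st, config):
            lib.add(mfs)
    return lib


def search_library(query: MFS, lib: SiteLibrary,
                   threshold: float = float("inf"),
                   metals: tuple[str, ...] | None = None,
                   nuclearity: int | None = None,
                   config: Config = DEFAULT_CONFIG) -> list[SearchHit]:
    """Score *query* against every library entry (no metal-identity
    prefilter unless requested) and return hits with score <= threshold,
    sorted ascending, ties broken by entry id."""
    if len(lib) == 0:
        raise ValueError("empty library")
    hits = []
    for e in lib.entries:
        if metals is not None and e.metals != tuple(sorted(metals)):
            continue
        if nuclearity is not None and e.nuclearity != nuclearity:
            continue
        res = superpose(query, e.mfs, config)
        hits.append(SearchHit(entry_id=e.entry_id, score=res.score.total,
                              rmsd=res.rmsd))
    hits.sort(key=lambda h: (h.score, h.entry_id))
    out = [h for h in hits if h.score <= threshold]
    for i, h in enumerate(out):
        h.rank = i + 1
    return out
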