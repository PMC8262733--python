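"""Template libraries for heterodimer docking.

Two libraries are built from coordinate files:

* **DB-Het** — heterodimers: every pair of distinct-sequence chains in contact
  within a structure of resolution 4.0 Å or better, de-duplicated at the pair
  level (an entry is redundant when BOTH of its chains exceed the identity cap
  against the same kept entry, in either part order).
* **DB-Mo/Ho** — monomers and homo-oligomers at a 70% mutual-identity cap;
  monomer chains are decomposed into compact domains so that two domains of
  one protein, or two chains of a homo-oligomer, can template a heterodimer.

Each entry stores two "parts" of one source structure plus the residue sets
forming their mutual interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import structio
from .align import global_align
from .structio import AssemblyStructure, ChainStructure

__all__ = [
    "TemplateEntry", "TemplateLibrary",
    "extract_interface", "build_het_db", "build_moho_db", "split_domains",
    "save_library", "load_library",
]

#: CA/CB contact cutoff defining interface residues (Å)
INTERFACE_CUTOFF = 8.0
#: domain decomposition: minimum segment length and maximum inter-segment
#: contact density (contacts per residue pair) that still permits a cut
DOMAIN_MIN_LEN = 30
DOMAIN_DENSITY = 0.04
DOMAIN_CONTACT_CUTOFF = 8.0


@dataclass
class TemplateEntry:
    """Two parts of one source structure usable as a dimer template.

    ``part2`` is absent for monomer chains that do not decompose into two
    domains; such entries count toward redundancy control but cannot seed a
    dimer model.
    """

    source_id: str
    entry_kind: str                       # heterodimer | monomer | homo_oligomer
    part1: ChainStructure
    part2: Optional[ChainStructure]
    interface1: frozenset[int] = frozenset()
    interface2: frozenset[int] = frozenset()
    resolution: Optional[float] = None
    n_chains: int = 2

    def __post_init__(self) -> None:
        if self.entry_kind not in ("heterodimer", "monomer", "homo_oligomer"):
            raise ValueError(f"unknown entry kind {self.entry_kind!r}")
        if self.entry_kind == "heterodimer" and self.part2 is not None:
            if not self.interface1 or not self.interface2:
                raise ValueError("stored dimer entries need non-empty interfaces")

    @property
    def is_dimeric(self) -> bool:
        return self.part2 is not None


@dataclass
class TemplateLibrary:
    """A searchable list of template entries with its build parameters."""

    entries: list[TemplateEntry]
    kind: str                              # DB_Het | DB_MoHo
    build_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("DB_Het", "DB_MoHo"):
            raise ValueError(f"unknown library kind {self.kind!r}")
        if self.kind == "DB_Het":
            for e in self.entries:
                if e.entry_kind != "heterodimer":
                    raise ValueError("DB_Het entries must all be heterodimers")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def extract_interface(part1: ChainStructure, part2: ChainStructure,
                      contact_cutoff: float = INTERFACE_CUTOFF
                      ) -> tuple[frozenset[int], frozenset[int]]:
    """Residues of each part with any CA/CB atom within ``contact_cutoff`` of
    any CA/CB atom of the other part."""
    if len(part1) == 0 or len(part2) == 0:
        raise ValueError("empty part")
    if contact_cutoff <= 0:
        return frozenset(), frozenset()
    c1, i1 = part1.contact_atoms()
    c2, i2 = part2.contact_atoms()
    pairs = cKDTree(c1).query_ball_tree(cKDTree(c2), r=contact_cutoff * (1 - 1e-12))
    set1, set2 = set(), set()
    for a, neigh in enumerate(pairs):
        if neigh:
            set1.add(int(i1[a]))
            set2.update(int(i2[b]) for b in neigh)
    return frozenset(set1), frozenset(set2)


def _pair_identity(e_new: tuple[str, str], e_kept: tuple[str, str]) -> float:
    """Pair-level mutual identity: max over direct / swapped part pairing of
    the weaker of the two chain identities."""
    def ident(x: str, y: str) -> float:
        return global_align(x, y).seq_identity

    direct = min(ident(e_new[0], e_kept[0]), ident(e_new[1], e_kept[1]))
    swapped = min(ident(e_new[0], e_kept[1]), ident(e_new[1], e_kept[0]))
    return max(direct, swapped)


def build_het_db(structures: list[AssemblyStructure], resolution_max: float = 4.0,
                 redundancy_identity: float = 0.7,
                 contact_cutoff: float = INTERFACE_CUTOFF) -> TemplateLibrary:
    """Build DB-Het: contacting distinct-sequence chain pairs from structures
    of resolution better than ``resolution_max``, pair-level de-duplicated."""
    kept: list[TemplateEntry] = []
    kept_seqs: list[tuple[str, str]] = []
    for asm in structures:
        if asm.resolution is not None and asm.resolution > resolution_max:
            continue
        n = len(asm.chains)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                p1, p2 = asm.chains[i], asm.chains[j]
                if p1.sequence == p2.sequence:
                    continue
                if1, if2 = extract_interface(p1, p2, contact_cutoff)
                if not if1 or not if2:
                    continue
                seqs = (p1.sequence, p2.sequence)
                redundant = any(_pair_identity(seqs, ks) > redundancy_identity
                                for ks in kept_seqs)
                if redundant:
                    continue
                kept.append(TemplateEntry(
                    source_id=f"{asm.source_id}_{p1.chain_id}{p2.chain_id}",
                    entry_kind="heterodimer", part1=p1, part2=p2,
                    interface1=if1, interface2=if2,
                    resolution=asm.resolution, n_chains=2))
                kept_seqs.append(seqs)
    return TemplateLibrary(entries=kept, kind="DB_Het",
                           build_params={"resolution_max": resolution_max,
                                         "redundancy_identity": redundancy_identity,
                                         "contact_cutoff": contact_cutoff})


def build_moho_db(structures: list[AssemblyStructure], identity_cap: float = 0.7,
                  contact_cutoff: float = INTERFACE_CUTOFF) -> TemplateLibrary:
    """Build DB-Mo/Ho: monomer (domain-split) and homo-oligomer entries,
    greedily retained in input order under the mutual identity cap."""
    kept: list[TemplateEntry] = []
    kept_seqs: list[str] = []
    for asm in structures:
        seqs = {c.sequence for c in asm.chains}
        if len(asm.chains) == 1:
            kind = "monomer"
        elif len(seqs) == 1:
            kind = "homo_oligomer"
        else:
            continue  # hetero assemblies belong in DB-Het
        rep_seq = asm.chains[0].sequence
        if any(global_align(rep_seq, ks).seq_identity > identity_cap
               for ks in kept_seqs):
            continue
        kept_seqs.append(rep_seq)
        if kind == "monomer":
            kept.extend(_monomer_entries(asm, contact_cutoff))
        else:
            kept.extend(_homo_entries(asm, contact_cutoff))
    return TemplateLibrary(entries=kept, kind="DB_MoHo",
                           build_params={"identity_cap": identity_cap,
                                         "contact_cutoff": contact_cutoff})


def _monomer_entries(asm: AssemblyStructure, contact_cutoff: float) -> list[TemplateEntry]:
    chain = asm.chains[0]
    domains = split_domains(chain) if len(chain) >= 20 else [chain]
    if len(domains) < 2:
        return [TemplateEntry(source_id=asm.source_id, entry_kind="monomer",
                              part1=chain, part2=None,
                              resolution=asm.resolution, n_chains=1)]
    entries = []
    for i in range(len(domains)):
        for j in range(i + 1, len(domains)):
            if1, if2 = extract_interface(domains[i], domains[j], contact_cutoff)
            entries.append(TemplateEntry(
                source_id=f"{asm.source_id}_d{i}{j}",
                entry_kind="monomer", part1=domains[i], part2=domains[j],
                interface1=if1, interface2=if2,
                resolution=asm.resolution, n_chains=1))
    return entries


def _homo_entries(asm: AssemblyStructure, contact_cutoff: float) -> list[TemplateEntry]:
    """One entry per homo-oligomer, exposing the chain pair with the largest
    mutual interface as its two parts."""
    best = None
    n = len(asm.chains)
    for i in range(n):
        for j in range(i + 1, n):
            if1, if2 = extract_interface(asm.chains[i], asm.chains[j], contact_cutoff)
            size = len(if1) + len(if2)
            if best is None or size > best[0]:
                best = (size, i, j, if1, if2)
    assert best is not None
    _, i, j, if1, if2 = best
    return [TemplateEntry(source_id=f"{asm.source_id}_{asm.chains[i].chain_id}{asm.chains[j].chain_id}",
                          entry_kind="homo_oligomer",
                          part1=asm.chains[i], part2=asm.chains[j],
                          interface1=if1, interface2=if2,
                          resolution=asm.resolution, n_chains=n)]


def split_domains(chain: ChainStructure, min_len: int = DOMAIN_MIN_LEN,
                  density_cutoff: float = DOMAIN_DENSITY,
                  contact_cutoff: float = DOMAIN_CONTACT_CUTOFF) -> list[ChainStructure]:
    """Contiguous-segment domain decomposition by a CA–CA contact-density cut.

    Recursively cut at the sequence position minimizing inter-segment CA
    contacts (within ``contact_cutoff``) normalized by the product of segment
    lengths, while both segments stay >= ``min_len`` residues and the density
    at the cut is below ``density_cutoff``; otherwise the chain is returned
    whole.
    """
    if len(chain) < 20:
        raise ValueError("domain splitting needs chains of >= 20 residues")
    n = len(chain)
    d = np.linalg.norm(chain.ca[:, None, :] - chain.ca[None, :, :], axis=2)
    contact = d < contact_cutoff
    np.fill_diagonal(contact, False)

    segments: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        length = hi - lo
        if length < 2 * min_len:
            segments.append((lo, hi))
            return
        best_cut, best_density = None, np.inf
        for cut in range(lo + min_len, hi - min_len + 1):
            cross = int(contact[lo:cut, cut:hi].sum())
            density = cross / ((cut - lo) * (hi - cut))
            if density < best_density:
                best_density = density
                best_cut = cut
        if best_cut is not None and best_density < density_cutoff:
            recurse(lo, best_cut)
            recurse(best_cut, hi)
        else:
            segments.append((lo, hi))

    recurse(0, n)
    if len(segments) == 1:
        return [chain]
    return [chain.slice(lo, hi) for lo, hi in segments]


# --- persistence ------------------------------------------------------------

def save_library(lib: TemplateLibrary, out_dir) -> None:
    """Persist a library as one PDB per entry plus a JSON index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {"kind": lib.kind, "build_params": lib.build_params, "entries": []}
    for k, e in enumerate(lib.entries):
        fname = f"entry_{k:05d}.pdb"
        chains = [_relabel(e.part1, "A")]
        if e.part2 is not None:
            chains.append(_relabel(e.part2, "B"))
        asm = AssemblyStructure(chains=chains, resolution=e.resolution,
                                source_id=e.source_id)
        structio.write_structure(asm, out_dir / fname)
        index["entries"].append({
            "file": fname,
            "source_id": e.source_id,
            "entry_kind": e.entry_kind,
            "chain_ids": [e.part1.chain_id] + ([e.part2.chain_id] if e.part2 is not None else []),
            "sequences": [e.part1.sequence] + ([e.part2.sequence] if e.part2 is not None else []),
            "interface1": sorted(e.interface1),
            "interface2": sorted(e.interface2),
            "resolution": e.resolution,
            "n_chains": e.n_chains,
        })
    (out_dir / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))


def _relabel(chain: ChainStructure, label: str) -> ChainStructure:
    c = chain.slice(0, len(chain))
    c.chain_id = label
    return c


def load_library(lib_dir) -> TemplateLibrary:
    """Reload a persisted library; coordinates round to the PDB's 3 decimals."""
    lib_dir = Path(lib_dir)
    index = json.loads((lib_dir / "index.json").read_text())
    entries = []
    for rec in index["entries"]:
        asm = structio.read_structure(lib_dir / rec["file"], format="pdb",
                                      min_chain_len=1)
        part1 = asm.chains[0]
        part1.chain_id = rec["chain_ids"][0]
        part2 = None
        if len(rec["chain_ids"]) > 1:
            part2 = asm.chains[1]
            part2.chain_id = rec["chain_ids"][1]
        entries.append(TemplateEntry(
            source_id=rec["source_id"], entry_kind=rec["entry_kind"],
            part1=part1, part2=part2,
            interface1=frozenset(rec["interface1"]),
            interface2=frozenset(rec["interface2"]),
            resolution=rec["resolution"], n_chains=rec["n_chains"]))
    return TemplateLibrary(entries=entries, kind=index["kind"],
                           build_params=index["build_params"])
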