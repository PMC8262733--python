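"""Coordinate file I/O and the chain/residue data model.

Structures are reduced to a residue-level representation: one CA coordinate
per residue (the representative atom used throughout the pipeline) plus the
CB coordinate where present.  Heteroatoms, waters, alternate locations other
than the first, and models beyond the first are discarded at read time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "ChainStructure",
    "AssemblyStructure",
    "StructureError",
    "read_structure",
    "write_structure",
    "representative_coords",
    "MIN_CHAIN_LEN",
]

#: Chains shorter than this are treated as peptide ligands and dropped at read
#: time (overridable via ``min_chain_len``).
MIN_CHAIN_LEN = 10

# PDB fixed columns hold at most 4 digits for the residue sequence number.
_MAX_PDB_RESNUM = 9999
_MIN_PDB_RESNUM = -999


class StructureError(ValueError):
    """Raised for unparsable files, empty structures, and serialization limits."""


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


def three_to_one(res_name: str) -> str:
    """Map a 3-letter residue code to 1-letter; unknown residues become X."""
    code = _THREE_TO_ONE.get(res_name.upper())
    if code is not None:
        return code
    info = gemmi.find_tabulated_residue(res_name.upper())
    if info and info.is_amino_acid():
        one = info.one_letter_code.upper()
        if one.isalpha():
            return one
    return "X"


@dataclass
class ChainStructure:
    """Ordered residues of one protein chain with CA (and optional CB) coordinates.

    Residue order is file order; ``res_numbers`` preserves author numbering but
    all internal correspondences use 0-based positional indices.  Missing CB
    coordinates (glycine, truncated side chains) are NaN rows in ``cb``.
    """

    chain_id: str
    res_numbers: np.ndarray          # (N,) int
    res_names: list[str]             # 3-letter codes, length N
    ca: np.ndarray                   # (N, 3) float64, Å
    cb: np.ndarray                   # (N, 3) float64, NaN where absent
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.res_numbers = np.asarray(self.res_numbers, dtype=np.int64)
        self.ca = np.asarray(self.ca, dtype=np.float64).reshape(-1, 3)
        self.cb = np.asarray(self.cb, dtype=np.float64).reshape(-1, 3)
        n = len(self.res_names)
        if not (len(self.res_numbers) == len(self.ca) == len(self.cb) == n):
            raise ValueError("inconsistent per-residue array lengths")

    def __len__(self) -> int:
        return len(self.res_names)

    @property
    def sequence(self) -> str:
        return "".join(three_to_one(n) for n in self.res_names)

    def has_cb(self) -> np.ndarray:
        """Boolean mask of residues with a CB coordinate."""
        return ~np.isnan(self.cb).any(axis=1)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainStructure":
        """Return a copy with every coordinate mapped through x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_cb = np.full_like(self.cb, np.nan)
        mask = self.has_cb()
        new_cb[mask] = self.cb[mask] @ R.T + t
        return replace(self, ca=self.ca @ R.T + t, cb=new_cb,
                       res_numbers=self.res_numbers.copy(),
                       res_names=list(self.res_names), meta=dict(self.meta))

    def slice(self, start: int, stop: int) -> "ChainStructure":
        """Contiguous sub-chain by 0-based positional indices [start, stop)."""
        meta = dict(self.meta)
        meta["segment"] = (int(start) + int(self.meta.get("segment", (0, 0))[0]),
                           int(stop) + int(self.meta.get("segment", (0, 0))[0]))
        return ChainStructure(
            chain_id=self.chain_id,
            res_numbers=self.res_numbers[start:stop].copy(),
            res_names=list(self.res_names[start:stop]),
            ca=self.ca[start:stop].copy(),
            cb=self.cb[start:stop].copy(),
            meta=meta,
        )

    def contact_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All CA and CB coordinates with the residue index of each atom.

        Returns (coords (M,3), residue_index (M,)) for use in interface and
        contact computations.
        """
        mask = self.has_cb()
        coords = np.vstack([self.ca, self.cb[mask]])
        idx = np.concatenate([np.arange(len(self)), np.flatnonzero(mask)])
        return coords, idx


@dataclass
class AssemblyStructure:
    """A set of chains from one coordinate file."""

    chains: list[ChainStructure]
    resolution: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        labels = [c.chain_id for c in self.chains]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate chain labels in {self.source_id!r}")

    def __iter__(self) -> Iterator[ChainStructure]:
        return iter(self.chains)

    def __len__(self) -> int:
        return len(self.chains)

    def get_chain(self, chain_id: str) -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path, format: str = "auto", min_chain_len: int = MIN_CHAIN_LEN) -> AssemblyStructure:
    """Read a PDB or mmCIF file into an :class:`AssemblyStructure`.

    Only the first model is read; waters, heteroatoms and non-first altlocs are
    dropped; chains shorter than ``min_chain_len`` residues are discarded
    (peptide ligands).  Raises :class:`StructureError` on unparsable input or
    when no polymer chain survives.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    chains: list[ChainStructure] = []
    for chain in model:
        nums, names, ca_list, cb_list = [], [], [], []
        for res in chain:
            if res.is_water():
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            ca = _pick_atom(res, "CA")
            if ca is None:
                continue
            cb = _pick_atom(res, "CB")
            nums.append(res.seqid.num)
            names.append(res.name)
            ca_list.append([ca.pos.x, ca.pos.y, ca.pos.z])
            cb_list.append([cb.pos.x, cb.pos.y, cb.pos.z] if cb is not None
                           else [np.nan] * 3)
        if len(nums) >= min_chain_len:
            chains.append(ChainStructure(chain.name, np.array(nums, dtype=np.int64),
                                         names, np.array(ca_list), np.array(cb_list)))
    if not chains:
        raise StructureError(f"{path}: no polymer chains of >= {min_chain_len} residues")
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    return AssemblyStructure(chains=chains, resolution=resolution, source_id=path.stem)


def _pick_atom(res: gemmi.Residue, name: str):
    """First-altloc atom of the given name, or None."""
    first = None
    for atom in res:
        if atom.name != name:
            continue
        if atom.altloc in ("", "\0", "A"):
            return atom
        if first is None:
            first = atom
    return first


def write_structure(model: AssemblyStructure, path, remarks: Sequence[str] = ()) -> None:
    """Write an assembly as PDB v3.3 text (CA/CB pseudo-residues, TER-separated).

    Round-trips chain ids, residue numbers, names and coordinates to 3 decimal
    places.  Raises :class:`StructureError` for empty assemblies or residue
    numbers outside the fixed-column PDB range.
    """
    if len(model.chains) == 0:
        raise StructureError("cannot write an empty assembly")
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    if model.resolution is not None:
        st.resolution = float(model.resolution)
    gm = gemmi.Model("1")
    for chain in model.chains:
        if chain.res_numbers.max() > _MAX_PDB_RESNUM or chain.res_numbers.min() < _MIN_PDB_RESNUM:
            raise StructureError(
                f"chain {chain.chain_id}: residue number outside the PDB field range")
        gc = gemmi.Chain(chain.chain_id)
        cb_mask = chain.has_cb()
        for i in range(len(chain)):
            res = gemmi.Residue()
            res.name = chain.res_names[i]
            res.seqid = gemmi.SeqId(int(chain.res_numbers[i]), " ")
            ca = gemmi.Atom()
            ca.name = "CA"
            ca.element = gemmi.Element("C")
            ca.pos = gemmi.Position(*np.round(chain.ca[i], 3))
            ca.occ = 1.0
            res.add_atom(ca)
            if cb_mask[i]:
                cb = gemmi.Atom()
                cb.name = "CB"
                cb.element = gemmi.Element("C")
                cb.pos = gemmi.Position(*np.round(chain.cb[i], 3))
                cb.occ = 1.0
                res.add_atom(cb)
            gc.add_residue(res)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    text = ""
    for rem in remarks:
        text += f"REMARK 999 {rem}\n"
    text += doc
    Path(path).write_text(text)


def representative_coords(chain: ChainStructure, mode: str = "CA") -> np.ndarray:
    """One representative coordinate per residue, in residue order."""
    if mode != "CA":
        raise ValueError(f"unsupported representative-atom mode {mode!r}")
    if len(chain) == 0:
        raise ValueError("empty chain")
    return chain.ca.copy()


# --- JSON helpers used by the template-library persistence layer -----------

def chain_to_dict(chain: ChainStructure) -> dict:
    return {
        "chain_id": chain.chain_id,
        "res_numbers": chain.res_numbers.tolist(),
        "res_names": list(chain.res_names),
        "ca": np.round(chain.ca, 3).tolist(),
        "cb": [None if not ok else list(np.round(xyz, 3))
               for ok, xyz in zip(chain.has_cb(), chain.cb)],
        "meta": {k: v for k, v in chain.meta.items() if _json_ok(v)},
    }


def chain_from_dict(d: dict) -> ChainStructure:
    cb = np.array([[np.nan] * 3 if xyz is None else xyz for xyz in d["cb"]], float)
    return ChainStructure(d["chain_id"], np.array(d["res_numbers"], dtype=np.int64),
                          list(d["res_names"]), np.array(d["ca"], float), cb,
                          meta=dict(d.get("meta", {})))


def _json_ok(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
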