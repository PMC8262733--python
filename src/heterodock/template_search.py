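"""Template detection for a target heterodimer.

Two search paths mirror the two libraries:

* structure-based over DB-Het: each target subunit is structurally aligned to
  each part of each heterodimer entry (both part orderings); a hit needs
  TM-score > 0.4 for both subunits and interface TM-score >= 0.4.
* sequence-based over DB-Mo/Ho: library parts are ranked per subunit by
  global sequence alignment (top 200 kept per subunit, or externally supplied
  HHsearch ranks); the two subunits must map to DIFFERENT parts of the same
  protein (two domains of a monomer, or two chain copies of a homo-oligomer),
  verified structurally with the same TM thresholds.

The interface TM-score places each subunit onto its template part (the
model-building superposition), restricts the correspondences to the
template's interface residues, and scores the pooled pairs jointly.  It
discards templates whose interface regions do not match the target subunits
even when their global folds do, and is invariant to the arbitrary input
frames of the two subunits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .align import AlignmentResult, global_align, structural_align
from .structio import ChainStructure
from .superpose import DegenerateInputError, d0, kabsch
from .template_db import TemplateEntry, TemplateLibrary

__all__ = ["TemplateHit", "search_structure_templates", "search_sequence_templates",
           "interface_tm", "hits_to_tsv"]

#: subunit structural-similarity threshold (exclusive)
TM_SUBUNIT = 0.4
#: interface-similarity threshold (hits below are discarded)
TM_INTERFACE = 0.4
#: resource guard: hits beyond this count are truncated by template score
MAX_HITS = 2000
#: sequence-path rank depth per subunit
TOP_K = 200


@dataclass
class TemplateHit:
    """Both target subunits mapped onto the two parts of one template entry."""

    entry: TemplateEntry
    align1: AlignmentResult           # subunit A -> part1 (or part2 when swapped)
    align2: AlignmentResult           # subunit B -> the other part
    tm1: float
    tm2: float
    tm_interface: float
    swap: bool = False

    @property
    def template_score(self) -> float:
        from .assemble import template_score
        return template_score(self)

    def parts(self) -> tuple[ChainStructure, ChainStructure]:
        """The (part for subunit A, part for subunit B) in hit order."""
        assert self.entry.part2 is not None
        if self.swap:
            return self.entry.part2, self.entry.part1
        return self.entry.part1, self.entry.part2

    def interfaces(self) -> tuple[frozenset[int], frozenset[int]]:
        if self.swap:
            return self.entry.interface2, self.entry.interface1
        return self.entry.interface1, self.entry.interface2


def interface_tm(hit: TemplateHit, subunit_a: ChainStructure,
                 subunit_b: ChainStructure) -> float:
    """Interface TM-score of a hit, evaluated in the template frame.

    Each subunit is first placed onto its template part by the least-squares
    fit of its full alignment (exactly the model-building superposition, so
    the score is invariant to how the input subunits happen to be oriented).
    The correspondences are then restricted to the template parts' interface
    residues, pooled, and scored jointly under those placements, normalized
    by the number of pooled target residues.  The pooled score is low when a
    subunit's interface region does not match the template interface even
    though its global fold does — the situation the filter must catch.
    An empty pool scores 0 (the hit is then discarded).
    """
    part_a, part_b = hit.parts()
    if_a, if_b = hit.interfaces()

    sel_a = np.array([j in if_a for j in hit.align1.corr.b], dtype=bool)
    sel_b = np.array([j in if_b for j in hit.align2.corr.b], dtype=bool)
    n_pool = int(sel_a.sum() + sel_b.sum())
    if n_pool < 3:
        return 0.0
    try:
        tf_a, _ = kabsch(subunit_a.ca[hit.align1.corr.a], part_a.ca[hit.align1.corr.b])
        tf_b, _ = kabsch(subunit_b.ca[hit.align2.corr.a], part_b.ca[hit.align2.corr.b])
    except DegenerateInputError:
        return 0.0
    placed = np.vstack([tf_a.apply(subunit_a.ca[hit.align1.corr.a[sel_a]]),
                        tf_b.apply(subunit_b.ca[hit.align2.corr.a[sel_b]])])
    templ = np.vstack([part_a.ca[hit.align1.corr.b[sel_a]],
                       part_b.ca[hit.align2.corr.b[sel_b]]])
    dist2 = ((placed - templ) ** 2).sum(axis=1)
    d0v = d0(n_pool)
    return float(np.sum(1.0 / (1.0 + dist2 / d0v ** 2)) / n_pool)


def _sorted_hits(hits: list[TemplateHit], max_hits: int = MAX_HITS) -> list[TemplateHit]:
    hits.sort(key=lambda h: (-h.template_score, -h.tm_interface, h.entry.source_id,
                             h.swap))
    return hits[:max_hits]


def search_structure_templates(subunit_a: ChainStructure, subunit_b: ChainStructure,
                               lib: TemplateLibrary,
                               tm_subunit: float = TM_SUBUNIT,
                               tm_interface_min: float = TM_INTERFACE,
                               max_hits: int = MAX_HITS) -> list[TemplateHit]:
    """Structure-based template search over a DB-Het library.

    Both part orderings of every entry are tried; retained hits satisfy
    tm1 > ``tm_subunit``, tm2 > ``tm_subunit`` and interface TM >=
    ``tm_interface_min``, sorted by template score.
    """
    if len(subunit_a) < 10 or len(subunit_b) < 10:
        raise ValueError("subunits must have >= 10 residues")
    if lib.kind != "DB_Het":
        raise ValueError("structure-based search runs on a DB_Het library")
    hits: list[TemplateHit] = []
    for entry in lib:
        if not entry.is_dimeric:
            continue
        for swap in (False, True):
            part_a, part_b = (entry.part2, entry.part1) if swap else (entry.part1, entry.part2)
            r1 = structural_align(subunit_a, part_a)
            if r1.tm is None or r1.tm <= tm_subunit:
                continue
            r2 = structural_align(subunit_b, part_b)
            if r2.tm is None or r2.tm <= tm_subunit:
                continue
            hit = TemplateHit(entry=entry, align1=r1, align2=r2,
                              tm1=r1.tm, tm2=r2.tm, tm_interface=0.0, swap=swap)
            hit.tm_interface = interface_tm(hit, subunit_a, subunit_b)
            if hit.tm_interface < tm_interface_min:
                continue
            hits.append(hit)
    return _sorted_hits(hits, max_hits)


def search_sequence_templates(subunit_a: ChainStructure, subunit_b: ChainStructure,
                              lib: TemplateLibrary, top_k: int = TOP_K,
                              tm_subunit: float = TM_SUBUNIT,
                              tm_interface_min: float = TM_INTERFACE,
                              max_hits: int = MAX_HITS,
                              external_ranks: Optional[dict] = None) -> list[TemplateHit]:
    """Sequence-based template search over a DB-Mo/Ho library.

    Library parts are ranked per subunit by global-alignment score (or by
    ``external_ranks`` mapping part keys to ranks, e.g. from HHsearch output);
    the top ``top_k`` parts per subunit are considered.  A hit requires the
    two subunits to map to different parts of the same entry, structural
    verification TM > ``tm_subunit`` for both, and interface TM >=
    ``tm_interface_min``.
    """
    if len(subunit_a) < 10 or len(subunit_b) < 10:
        raise ValueError("subunits must have >= 10 residues")
    if lib.kind != "DB_MoHo":
        raise ValueError("sequence-based search runs on a DB_MoHo library")

    parts: list[tuple[TemplateEntry, int, ChainStructure]] = []
    for entry in lib:
        if not entry.is_dimeric:
            continue
        parts.append((entry, 0, entry.part1))
        parts.append((entry, 1, entry.part2))

    def top_parts(subunit: ChainStructure) -> set[int]:
        scored = []
        for k, (_, _, part) in enumerate(parts):
            if external_ranks is not None:
                key = _part_key(parts[k][0], parts[k][1])
                if key not in external_ranks:
                    continue
                scored.append((external_ranks[key], k))
            else:
                aln = global_align(subunit.sequence, part.sequence)
                scored.append((-aln.score, k))
        scored.sort()
        return {k for _, k in scored[:top_k]}

    top_a = top_parts(subunit_a)
    top_b = top_parts(subunit_b)

    hits: list[TemplateHit] = []
    for entry in lib:
        if not entry.is_dimeric:
            continue
        k1 = _part_index(parts, entry, 0)
        k2 = _part_index(parts, entry, 1)
        for swap in (False, True):
            ka, kb = (k2, k1) if swap else (k1, k2)
            if ka not in top_a or kb not in top_b:
                continue
            part_a, part_b = (entry.part2, entry.part1) if swap else (entry.part1, entry.part2)
            r1 = structural_align(subunit_a, part_a)
            if r1.tm is None or r1.tm <= tm_subunit:
                continue
            r2 = structural_align(subunit_b, part_b)
            if r2.tm is None or r2.tm <= tm_subunit:
                continue
            hit = TemplateHit(entry=entry, align1=r1, align2=r2,
                              tm1=r1.tm, tm2=r2.tm, tm_interface=0.0, swap=swap)
            hit.tm_interface = interface_tm(hit, subunit_a, subunit_b)
            if hit.tm_interface < tm_interface_min:
                continue
            hits.append(hit)
    return _sorted_hits(hits, max_hits)


def _part_key(entry: TemplateEntry, part_idx: int) -> str:
    return f"{entry.source_id}/{part_idx}"


def _part_index(parts, entry, part_idx) -> int:
    for k, (e, idx, _) in enumerate(parts):
        if e is entry and idx == part_idx:
            return k
    return -1


def hits_to_tsv(hits: list[TemplateHit], path=None) -> str:
    """Serialize a hit list as TSV (source_id, kind, swap, TM components, score)."""
    lines = ["source_id\tkind\tswap\ttm1\ttm2\ttm_interface\ttemplate_score"]
    for h in hits:
        lines.append(f"{h.entry.source_id}\t{h.entry.entry_kind}\t{int(h.swap)}\t"
                     f"{h.tm1:.4f}\t{h.tm2:.4f}\t{h.tm_interface:.4f}\t"
                     f"{h.template_score:.4f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
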