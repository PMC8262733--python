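"""Complex-model building, physical filtering, scoring and ranking.

A model is built from a template hit by rigid-body superposition of each
target subunit onto its template part, so each subunit keeps its internal
geometry exactly and only the relative placement is inherited from the
template.  Models are then filtered on steric clashes, inter-subunit contacts
and buried interface area, scored by a template score combining the hit's
subunit and interface TM-scores, de-duplicated at complex TM-score > 0.8, and
ranked with a cap of 50 delivered models.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import biotite.structure as bst
from scipy.spatial.distance import cdist

from . import structio
from .structio import AssemblyStructure, ChainStructure
from .superpose import kabsch
from .template_search import TemplateHit

__all__ = [
    "ComplexModel", "FilterThresholds",
    "build_model", "clash_count", "contact_count", "interface_area",
    "apply_filters", "template_score", "remove_redundancy", "rank_models",
    "write_ranked_models", "merge_ab_initio_poses",
]

#: template-score weights: score = w_subunit*(tm1 + tm2) + w_interface*tm_interface
W_SUBUNIT = 1.0
W_INTERFACE = 2.0

#: coarse residue-sphere SASA model: CA-centered spheres
SASA_RADIUS = 3.4
SASA_PROBE = 1.4
SASA_POINTS = 960

CLASH_DISTANCE = 3.0
CONTACT_DISTANCE = 8.0
TM_REDUNDANCY = 0.8
MAX_MODELS = 50


@dataclass
class FilterThresholds:
    """Physical plausibility thresholds applied to assembled models."""

    max_clash_fraction: float = 0.1
    min_contacts: int = 5
    min_interface_area: float = 300.0      # Å²
    clash_distance: float = CLASH_DISTANCE

    def __post_init__(self) -> None:
        if min(self.max_clash_fraction, self.min_contacts,
               self.min_interface_area, self.clash_distance) < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class ComplexModel:
    """An assembled two-chain model with provenance and measurements."""

    chain_a: ChainStructure
    chain_b: ChainStructure
    provenance: dict = field(default_factory=dict)
    hit: Optional[TemplateHit] = None
    clash_count: Optional[int] = None
    contact_count: Optional[int] = None
    interface_area: Optional[float] = None
    template_score: float = 0.0
    rank: Optional[int] = None

    @property
    def chains(self) -> list[ChainStructure]:
        return [self.chain_a, self.chain_b]

    def as_assembly(self, source_id: str = "model") -> AssemblyStructure:
        a = self.chain_a.slice(0, len(self.chain_a))
        b = self.chain_b.slice(0, len(self.chain_b))
        a.chain_id, b.chain_id = "A", "B"
        return AssemblyStructure(chains=[a, b], source_id=source_id)


def build_model(subunit_a: ChainStructure, subunit_b: ChainStructure,
                hit: TemplateHit) -> ComplexModel:
    """Superpose each subunit onto its template part and keep both rigid.

    Each subunit is transformed by the least-squares fit of its aligned CA
    residues onto the corresponding part residues, preserving its internal
    geometry exactly; the template's relative orientation of the two parts is
    thereby inherited by the model.
    """
    part_a, part_b = hit.parts()
    c1, c2 = hit.align1.corr, hit.align2.corr
    if len(c1) < 3 or len(c2) < 3:
        raise ValueError("degenerate alignment: need >= 3 aligned pairs per subunit")
    tf_a, _ = kabsch(subunit_a.ca[c1.a], part_a.ca[c1.b])
    tf_b, _ = kabsch(subunit_b.ca[c2.a], part_b.ca[c2.b])
    model = ComplexModel(
        chain_a=subunit_a.transformed(tf_a.rotation, tf_a.translation),
        chain_b=subunit_b.transformed(tf_b.rotation, tf_b.translation),
        provenance={"kind": "template", "template_type": hit.entry.entry_kind,
                    "source_id": hit.entry.source_id, "swap": hit.swap},
        hit=hit,
        template_score=template_score(hit))
    return model


def clash_count(model: ComplexModel, clash_distance: float = CLASH_DISTANCE) -> int:
    """Number of inter-chain CA–CA pairs closer than ``clash_distance``."""
    d = cdist(model.chain_a.ca, model.chain_b.ca)
    return int((d < clash_distance).sum())


def contact_count(model: ComplexModel, contact_distance: float = CONTACT_DISTANCE,
                  clash_distance: float = CLASH_DISTANCE) -> int:
    """Inter-chain CA–CA pairs within ``contact_distance``, excluding clashes."""
    d = cdist(model.chain_a.ca, model.chain_b.ca)
    return int(((d < contact_distance) & (d >= clash_distance)).sum())


def _sasa(coords: np.ndarray, probe: float) -> float:
    n = len(coords)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["ALA"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    vals = bst.sasa(arr, probe_radius=probe, point_number=SASA_POINTS,
                    vdw_radii=np.full(n, SASA_RADIUS), ignore_ions=False)
    return float(np.nansum(vals))


def interface_area(model: ComplexModel, probe: float = SASA_PROBE) -> float:
    """Buried solvent-accessible surface area, SASA(A) + SASA(B) − SASA(AB).

    Shrake–Rupley on a coarse residue-sphere representation: one sphere of
    radius 3.4 Å per residue at its CA, 960 sample points per sphere.
    """
    a = model.chain_a.ca
    b = model.chain_b.ca
    buried = _sasa(a, probe) + _sasa(b, probe) - _sasa(np.vstack([a, b]), probe)
    return max(0.0, buried)


def measure(model: ComplexModel, thresholds: FilterThresholds | None = None) -> ComplexModel:
    """Fill in clash/contact/interface measurements (idempotent)."""
    th = thresholds or FilterThresholds()
    if model.clash_count is None:
        model.clash_count = clash_count(model, th.clash_distance)
    if model.contact_count is None:
        model.contact_count = contact_count(model, clash_distance=th.clash_distance)
    if model.interface_area is None:
        model.interface_area = interface_area(model)
    return model


def apply_filters(models: list[ComplexModel],
                  thresholds: FilterThresholds | None = None) -> list[ComplexModel]:
    """Keep physically plausible models; input order is preserved."""
    th = thresholds or FilterThresholds()
    kept = []
    for m in models:
        measure(m, th)
        n_min = min(len(m.chain_a), len(m.chain_b))
        assert m.clash_count is not None and m.contact_count is not None \
            and m.interface_area is not None
        if (m.clash_count / n_min <= th.max_clash_fraction
                and m.contact_count >= th.min_contacts
                and m.interface_area >= th.min_interface_area):
            kept.append(m)
    return kept


def template_score(hit: TemplateHit, w_subunit: float = W_SUBUNIT,
                   w_interface: float = W_INTERFACE) -> float:
    """Ranking score combining subunit and interface TM-scores.

    The interface term is double-weighted by default because it carries the
    dimer-specific signal (relative subunit orientation); the subunit terms
    measure how reliably each monomer maps onto the template.
    """
    return w_subunit * (hit.tm1 + hit.tm2) + w_interface * hit.tm_interface


def remove_redundancy(models: list[ComplexModel],
                      tm_cutoff: float = TM_REDUNDANCY) -> list[ComplexModel]:
    """Greedy de-duplication: walk models in score order, accept a model iff
    its complex TM-score to every already-accepted model is <= ``tm_cutoff``."""
    from .evaluate import complex_tm
    accepted: list[ComplexModel] = []
    for m in models:
        dominated = False
        for kept in accepted:
            try:
                if complex_tm(m, kept) > tm_cutoff:
                    dominated = True
                    break
            except ValueError:
                continue  # different subunit lengths: cannot be redundant
        if not dominated:
            accepted.append(m)
    return accepted


def rank_models(models: list[ComplexModel], max_models: int = MAX_MODELS) -> list[ComplexModel]:
    """Sort by template score (desc), ties by interface TM then source id,
    truncate to ``max_models`` and assign 1-based ranks."""
    def key(m: ComplexModel):
        tmi = m.hit.tm_interface if m.hit is not None else -1.0
        sid = m.provenance.get("source_id", "")
        return (-m.template_score, -tmi, sid)

    ranked = sorted(models, key=key)[:max_models]
    for i, m in enumerate(ranked, start=1):
        m.rank = i
    return ranked


def write_ranked_models(models: list[ComplexModel], out_dir) -> Path:
    """Write model_NN.pdb files plus the ranked TSV table.

    The table mirrors a docking server's output: rank, template type
    (heterodimer, monomer, or homo-oligomer), template source id, and template
    score.  Returns the TSV path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "ranked_models.tsv"
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "template_type", "template_id", "template_score"])
        for m in models:
            assert m.rank is not None
            name = f"model_{m.rank:02d}.pdb"
            ttype = m.provenance.get("template_type", m.provenance.get("kind", "ab_initio"))
            remarks = [f"heterodock rank {m.rank}",
                       f"template {m.provenance.get('source_id', '-')} ({ttype})",
                       f"template_score {m.template_score:.4f}"]
            structio.write_structure(m.as_assembly(source_id=name[:-4]),
                                     out_dir / name, remarks=remarks)
            writer.writerow([m.rank, ttype, m.provenance.get("source_id", "-"),
                             f"{m.template_score:.4f}"])
    return tsv_path


def merge_ab_initio_poses(models: list[ComplexModel], poses_dir,
                          score_table=None) -> list[ComplexModel]:
    """Append externally docked poses below the template-based models.

    ``poses_dir`` holds two-chain PDB files; ``score_table`` (optional TSV:
    filename, score) orders them.  Poses carry provenance "ab_initio" and a
    template score of 0, so they always rank after template-based models.
    This is the pluggable top-up stage for targets with too few templates; no
    docking engine is bundled.
    """
    poses_dir = Path(poses_dir)
    scores: dict[str, float] = {}
    if score_table is not None:
        with open(score_table) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) >= 2:
                    try:
                        scores[row[0]] = float(row[1])
                    except ValueError:
                        continue
    poses = []
    for path in sorted(poses_dir.glob("*.pdb")):
        asm = structio.read_structure(path, format="pdb")
        if len(asm.chains) != 2:
            continue
        poses.append((scores.get(path.name, 0.0), path.name, asm))
    poses.sort(key=lambda p: (-p[0], p[1]))
    merged = list(models)
    for score, name, asm in poses:
        merged.append(ComplexModel(
            chain_a=asm.chains[0], chain_b=asm.chains[1],
            provenance={"kind": "ab_initio", "source_id": name,
                        "docking_score": score},
            template_score=0.0))
    return merged
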