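"""End-to-end prediction: search both libraries, assemble, filter, rank.

This is the library face of the command-line ``predict`` workflow so that
scripts and tests can drive the whole pipeline without a shell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .assemble import (ComplexModel, FilterThresholds, apply_filters,
                       build_model, rank_models, remove_redundancy)
from .config import PipelineConfig
from .structio import ChainStructure
from .template_db import TemplateLibrary
from .template_search import (TemplateHit, search_sequence_templates,
                              search_structure_templates)

__all__ = ["PredictionResult", "predict_complex"]

log = logging.getLogger("heterodock")


@dataclass
class PredictionResult:
    """Ranked models plus the search/filter bookkeeping of one run."""

    models: list[ComplexModel]
    hits: list[TemplateHit]
    status: str                       # "ok" | "no_templates_found"
    counts: dict = field(default_factory=dict)


def predict_complex(subunit_a: ChainStructure, subunit_b: ChainStructure,
                    het_lib: Optional[TemplateLibrary] = None,
                    moho_lib: Optional[TemplateLibrary] = None,
                    config: Optional[PipelineConfig] = None) -> PredictionResult:
    """Predict heterodimer models for two subunits from template libraries.

    Runs the structure-based search over ``het_lib`` and the sequence-based
    search over ``moho_lib`` (each optional), builds a model per hit by
    superposition, applies the physical filters, removes redundant binding
    modes at complex TM-score > ``tm_redundancy``, and ranks the survivors by
    template score up to ``max_models``.
    """
    cfg = config or PipelineConfig()
    for name, sub in (("A", subunit_a), ("B", subunit_b)):
        if len(sub) >= cfg.max_subunit_len:
            raise ValueError(
                f"subunit {name} has {len(sub)} residues; the pipeline accepts "
                f"subunits of < {cfg.max_subunit_len} residues")

    hits: list[TemplateHit] = []
    if het_lib is not None and len(het_lib) > 0:
        hits += search_structure_templates(
            subunit_a, subunit_b, het_lib, tm_subunit=cfg.tm_subunit,
            tm_interface_min=cfg.tm_interface, max_hits=cfg.max_hits)
    if moho_lib is not None and len(moho_lib) > 0:
        hits += search_sequence_templates(
            subunit_a, subunit_b, moho_lib, top_k=cfg.top_k,
            tm_subunit=cfg.tm_subunit, tm_interface_min=cfg.tm_interface,
            max_hits=cfg.max_hits)
    hits.sort(key=lambda h: (-h.template_score, -h.tm_interface,
                             h.entry.source_id, h.swap))
    hits = hits[:cfg.max_hits]
    log.info("template search: %d hits", len(hits))

    counts = {"hits": len(hits)}
    if not hits:
        return PredictionResult(models=[], hits=[], status="no_templates_found",
                                counts=counts)

    models = [build_model(subunit_a, subunit_b, h) for h in hits]
    counts["built"] = len(models)
    thresholds = FilterThresholds(
        max_clash_fraction=cfg.max_clash_fraction, min_contacts=cfg.min_contacts,
        min_interface_area=cfg.min_interface_area, clash_distance=cfg.clash_distance)
    models = apply_filters(models, thresholds)
    counts["after_filters"] = len(models)
    models.sort(key=lambda m: (-m.template_score,
                               -(m.hit.tm_interface if m.hit else 0.0),
                               m.provenance.get("source_id", "")))
    models = remove_redundancy(models, tm_cutoff=cfg.tm_redundancy)
    counts["after_redundancy"] = len(models)
    models = rank_models(models, max_models=cfg.max_models)
    counts["ranked"] = len(models)
    log.info("pipeline: %s", counts)
    status = "ok" if models else "no_templates_found"
    return PredictionResult(models=models, hits=hits, status=status, counts=counts)
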