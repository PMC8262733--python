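"""Model building, physical measurements, filtering, redundancy, ranking."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from heterodock import synth
from heterodock.assemble import (ComplexModel, FilterThresholds, apply_filters,
                                 build_model, clash_count, contact_count,
                                 interface_area, measure, rank_models,
                                 remove_redundancy, template_score)
from heterodock.evaluate import complex_tm, lrmsd
from heterodock.structio import ChainStructure
from heterodock.template_search import TemplateHit

from .conftest import random_rigid
from .oracles import rotation_rmsd, two_sphere_buried_area


def separated_model(gap_vector):
    a = synth.make_bundle(30, seed=71, chain_id="A")
    b = synth.make_bundle(30, seed=72, chain_id="B")
    b = b.transformed(np.eye(3), np.asarray(gap_vector, float) - b.ca.mean(axis=0)
                      + a.ca.mean(axis=0))
    return ComplexModel(chain_a=a, chain_b=b)


class TestBuildModel:
    def test_self_template_reproduces_native_geometry(self, target_dimer, prediction):
        hit = prediction.hits[0]
        model = build_model(target_dimer.chains[0], target_dimer.chains[1], hit)
        native_cross = cdist(target_dimer.chains[0].ca, target_dimer.chains[1].ca)
        model_cross = cdist(model.chain_a.ca, model.chain_b.ca)
        # plant is a 0.3 Å-noise copy of the native: cross distances match closely
        assert np.abs(native_cross - model_cross).max() < 2.0

    def test_subunit_internal_geometry_preserved_exactly(self, target_dimer, prediction):
        hit = prediction.hits[0]
        model = build_model(target_dimer.chains[0], target_dimer.chains[1], hit)
        for orig, built in ((target_dimer.chains[0], model.chain_a),
                            (target_dimer.chains[1], model.chain_b)):
            np.testing.assert_allclose(pdist(orig.ca), pdist(built.ca), atol=1e-9)

    def test_perturbed_template_orientation_propagates_analytically(self, target_dimer):
        """A template differing from the native by a known rigid motion of
        part2 yields a model whose ligand RMSD equals the closed form."""
        from heterodock.align import structural_align
        from heterodock.template_db import TemplateEntry, extract_interface

        native_a, native_b = target_dimer.chains
        angle = 10.0
        axis = np.array([0.0, 0.0, 1.0])
        c, s = np.cos(np.deg2rad(angle)), np.sin(np.deg2rad(angle))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        center = native_b.ca.mean(axis=0)
        part2 = native_b.transformed(R, center - R @ center)
        if1, if2 = extract_interface(native_a, part2)
        entry = TemplateEntry(source_id="pert", entry_kind="heterodimer",
                              part1=native_a, part2=part2,
                              interface1=if1 or frozenset({0}),
                              interface2=if2 or frozenset({0}), resolution=2.0)
        r1 = structural_align(native_a, entry.part1)
        r2 = structural_align(native_b, entry.part2)
        hit = TemplateHit(entry=entry, align1=r1, align2=r2, tm1=r1.tm,
                          tm2=r2.tm, tm_interface=1.0)
        model = build_model(native_a, native_b, hit)
        native = ComplexModel(chain_a=native_a, chain_b=native_b)
        expected = rotation_rmsd(native_b.ca, axis, angle)
        assert lrmsd(model, native) == pytest.approx(expected, abs=1e-3)

    def test_degenerate_alignment_rejected(self, target_dimer, prediction):
        from dataclasses import replace
        from heterodock.superpose import Correspondence
        hit = prediction.hits[0]
        short = replace(hit.align1, corr=Correspondence(hit.align1.corr.pairs[:2]))
        bad = TemplateHit(entry=hit.entry, align1=short, align2=hit.align2,
                          tm1=hit.tm1, tm2=hit.tm2, tm_interface=hit.tm_interface)
        with pytest.raises(ValueError):
            build_model(target_dimer.chains[0], target_dimer.chains[1], bad)


class TestCounts:
    def test_distant_chains_have_no_clashes_or_contacts(self):
        m = separated_model([50.0, 0, 0])
        assert clash_count(m) == 0
        assert contact_count(m) == 0

    def test_coincident_chains_clash_massively(self):
        a = synth.make_bundle(30, seed=73, chain_id="A")
        b = a.slice(0, len(a))
        b.chain_id = "B"
        m = ComplexModel(chain_a=a, chain_b=b)
        assert clash_count(m) >= min(len(a), len(b))

    def test_counts_match_brute_force_and_exclude_clashes(self, native_model):
        d = cdist(native_model.chain_a.ca, native_model.chain_b.ca)
        assert clash_count(native_model, 3.0) == int((d < 3.0).sum())
        assert contact_count(native_model, 8.0) == int(((d >= 3.0) & (d < 8.0)).sum())

    def test_constructed_clashes_counted_exactly(self):
        ca_a = np.column_stack([np.zeros(10), np.zeros(10),
                                10.0 * np.arange(10)])   # 10 Å spacing
        a = ChainStructure("A", np.arange(1, 11), ["ALA"] * 10, ca_a,
                           np.full_like(ca_a, np.nan))
        ca = ca_a + np.array([50.0, 0.0, 0.0])
        ca[:3] = ca_a[:3] + np.array([2.0, 0.0, 0.0])    # exactly 3 pairs < 3 Å
        b = ChainStructure("B", a.res_numbers.copy(), list(a.res_names), ca,
                           np.full_like(ca, np.nan))
        m = ComplexModel(chain_a=a, chain_b=b)
        d = cdist(a.ca, ca)
        assert int((d < 3.0).sum()) == 3
        assert clash_count(m, 3.0) == 3

    def test_contact_count_monotone_in_cutoff(self, native_model):
        assert contact_count(native_model, 10.0) >= contact_count(native_model, 8.0)


class TestInterfaceArea:
    def test_distant_chains_bury_nothing(self):
        m = separated_model([100.0, 0, 0])
        assert interface_area(m) == pytest.approx(0.0, abs=1.0)

    def test_buried_area_non_negative(self, native_model):
        assert interface_area(native_model) >= 0.0

    def test_two_sphere_fixture_matches_cap_formula(self):
        # single-residue chains: two 3.4 Å spheres (plus 1.4 Å probe) 4 Å apart
        a = ChainStructure("A", [1], ["ALA"], np.zeros((1, 3)),
                           np.full((1, 3), np.nan))
        b = ChainStructure("B", [1], ["ALA"], np.array([[4.0, 0.0, 0.0]]),
                           np.full((1, 3), np.nan))
        m = ComplexModel(chain_a=a, chain_b=b)
        expected = two_sphere_buried_area(radius=3.4 + 1.4, center_distance=4.0)
        assert interface_area(m) == pytest.approx(expected, rel=0.02)


class TestFiltersAndRanking:
    def make_scored(self, n, base_score=4.0):
        models = []
        for i in range(n):
            m = separated_model([30.0 + i, 0, 0])
            m.template_score = base_score - 0.01 * i
            m.provenance = {"source_id": f"s{i:02d}", "template_type": "heterodimer"}
            models.append(m)
        return models

    def test_zero_contact_model_removed(self):
        m = separated_model([60.0, 0, 0])
        kept = apply_filters([m], FilterThresholds(min_contacts=1,
                                                   min_interface_area=0.0))
        assert kept == []

    def test_permissive_thresholds_are_identity(self, native_model, prediction):
        models = [native_model] + list(prediction.models)
        th = FilterThresholds(max_clash_fraction=1.0, min_contacts=0,
                              min_interface_area=0.0)
        assert apply_filters(models, th) == models

    def test_loosening_a_threshold_never_shrinks_survivors(self, prediction, native_model):
        models = [native_model] + list(prediction.models)
        tight = FilterThresholds(max_clash_fraction=0.05, min_contacts=10,
                                 min_interface_area=400.0)
        loose = FilterThresholds(max_clash_fraction=0.5, min_contacts=10,
                                 min_interface_area=400.0)
        assert set(map(id, apply_filters(models, tight))) \
            <= set(map(id, apply_filters(models, loose)))

    def test_template_score_formula(self, prediction):
        hit = prediction.hits[0]
        assert template_score(hit) == pytest.approx(
            hit.tm1 + hit.tm2 + 2.0 * hit.tm_interface)
        perfect = TemplateHit(entry=hit.entry, align1=hit.align1,
                              align2=hit.align2, tm1=1.0, tm2=1.0,
                              tm_interface=1.0)
        boundary = TemplateHit(entry=hit.entry, align1=hit.align1,
                               align2=hit.align2, tm1=0.4, tm2=0.4,
                               tm_interface=0.4)
        assert template_score(perfect) == pytest.approx(4.0)
        assert template_score(boundary) == pytest.approx(1.6)

    def test_duplicate_models_collapse(self, native_model):
        a, b = native_model.chain_a, native_model.chain_b
        dup = ComplexModel(chain_a=a.slice(0, len(a)), chain_b=b.slice(0, len(b)))
        kept = remove_redundancy([native_model, dup], tm_cutoff=0.8)
        assert len(kept) == 1

    def test_opposite_binding_faces_both_survive(self):
        a = synth.make_bundle(30, seed=74, chain_id="A")
        b = synth.make_bundle(30, seed=75, chain_id="B")
        d0deg = synth.make_dimer(a, b, 4.5, relative_rotation=0.0)
        d180 = synth.make_dimer(a, b, 4.5, relative_rotation=180.0)
        m1 = ComplexModel(chain_a=d0deg.chains[0], chain_b=d0deg.chains[1])
        m2 = ComplexModel(chain_a=d180.chains[0], chain_b=d180.chains[1])
        assert complex_tm(m1, m2) <= 0.8
        assert len(remove_redundancy([m1, m2])) == 2

    def test_redundancy_postcondition_all_pairs(self, native_model):
        rng = np.random.default_rng(81)
        models = []
        for i in range(12):
            sigma = 0.2 if i % 3 else 6.0
            pert = synth.perturb(
                synth.make_dimer(native_model.chain_a, native_model.chain_b,
                                 4.5, relative_rotation=float(30 * i)),
                sigma, seed=i)
            m = ComplexModel(chain_a=pert.chains[0], chain_b=pert.chains[1])
            m.template_score = float(rng.uniform(1.6, 4.0))
            models.append(m)
        models.sort(key=lambda m: -m.template_score)
        kept = remove_redundancy(models, tm_cutoff=0.8)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert complex_tm(kept[i], kept[j]) <= 0.8

    def test_ranking_caps_sorts_and_is_permutation_stable(self):
        models = self.make_scored(60)
        ranked = rank_models(models, max_models=50)
        assert len(ranked) == 50
        assert [m.rank for m in ranked] == list(range(1, 51))
        scores = [m.template_score for m in ranked]
        assert scores == sorted(scores, reverse=True)
        rng = np.random.default_rng(5)
        shuffled = list(models)
        rng.shuffle(shuffled)
        reranked = rank_models(shuffled, max_models=50)
        assert [m.provenance["source_id"] for m in reranked] \
            == [m.provenance["source_id"] for m in ranked]

    def test_small_sets_rank_unchanged(self):
        models = self.make_scored(3)
        assert [m.provenance["source_id"] for m in rank_models(models)] \
            == ["s00", "s01", "s02"]
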