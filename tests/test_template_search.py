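"""Template search: thresholds, part pairing, interface TM-score."""

import numpy as np
import pytest

from heterodock import synth
from heterodock.align import structural_align
from heterodock.structio import AssemblyStructure, ChainStructure
from heterodock.template_db import (TemplateEntry, TemplateLibrary,
                                    extract_interface)
from heterodock.template_search import (TemplateHit, interface_tm,
                                        search_sequence_templates,
                                        search_structure_templates)

from .conftest import random_rigid


def entry_from_dimer(dimer, source_id="tmpl", kind="heterodimer"):
    if1, if2 = extract_interface(dimer.chains[0], dimer.chains[1])
    return TemplateEntry(source_id=source_id, entry_kind=kind,
                         part1=dimer.chains[0], part2=dimer.chains[1],
                         interface1=if1, interface2=if2, resolution=2.0)


@pytest.fixture(scope="module")
def target(target_dimer):
    return target_dimer


class TestStructureSearch:
    def test_self_template_ranks_first_with_perfect_scores(self, target, planted_lib):
        exact = TemplateLibrary(entries=[entry_from_dimer(target, "self")]
                                + [e for e in planted_lib.entries
                                   if e.source_id.startswith("D")],
                                kind="DB_Het")
        hits = search_structure_templates(target.chains[0], target.chains[1], exact)
        assert hits
        top = hits[0]
        assert top.entry.source_id == "self"
        assert top.tm1 == pytest.approx(1.0, abs=1e-6)
        assert top.tm2 == pytest.approx(1.0, abs=1e-6)
        assert top.tm_interface == pytest.approx(1.0, abs=1e-6)

    def test_decoy_only_library_yields_no_hits(self, target, planted_lib):
        decoys = TemplateLibrary(entries=[e for e in planted_lib.entries
                                          if e.source_id.startswith("D")],
                                 kind="DB_Het")
        assert decoys.entries
        hits = search_structure_templates(target.chains[0], target.chains[1], decoys)
        assert hits == []

    def test_single_subunit_match_is_not_retained(self, target, planted_lib):
        decoy_chain = next(e for e in planted_lib.entries
                           if e.source_id.startswith("D")).part2
        half = synth.make_dimer(target.chains[0].slice(0, len(target.chains[0])),
                                decoy_chain.slice(0, len(decoy_chain)), 4.5,
                                source_id="half")
        lib = TemplateLibrary(entries=[entry_from_dimer(half, "half")], kind="DB_Het")
        hits = search_structure_templates(target.chains[0], target.chains[1], lib)
        assert hits == []

    def test_every_retained_hit_satisfies_all_thresholds(self, prediction):
        assert prediction.hits
        for h in prediction.hits:
            assert h.tm1 > 0.4
            assert h.tm2 > 0.4
            assert h.tm_interface >= 0.4

    def test_invariant_under_rigid_transform_of_inputs(self, target, planted_lib):
        base = search_structure_templates(target.chains[0], target.chains[1],
                                          planted_lib)
        R, t = random_rigid(77)
        moved_a = target.chains[0].transformed(R, t)
        moved = search_structure_templates(moved_a, target.chains[1], planted_lib)
        assert [h.entry.source_id for h in moved] == [h.entry.source_id for h in base]
        for hm, hb in zip(moved, base):
            assert hm.tm1 == pytest.approx(hb.tm1, abs=1e-6)
            assert hm.tm_interface == pytest.approx(hb.tm_interface, abs=1e-6)

    def test_swapped_query_order_mirrors_swap_flag(self, target, planted_lib):
        ab = search_structure_templates(target.chains[0], target.chains[1],
                                        planted_lib)
        ba = search_structure_templates(target.chains[1], target.chains[0],
                                        planted_lib)
        key_ab = {(h.entry.source_id, h.swap) for h in ab}
        key_ba = {(h.entry.source_id, not h.swap) for h in ba}
        assert key_ab == key_ba


def monomer_entry_from_parts(p1, p2, source_id="mono"):
    if1, if2 = extract_interface(p1, p2)
    return TemplateEntry(source_id=source_id, entry_kind="monomer",
                         part1=p1, part2=p2, interface1=if1, interface2=if2,
                         resolution=2.0, n_chains=1)


class TestSequenceSearch:
    def test_two_domain_monomer_matching_both_subunits(self, target):
        entry = monomer_entry_from_parts(target.chains[0], target.chains[1])
        lib = TemplateLibrary(entries=[entry], kind="DB_MoHo")
        hits = search_sequence_templates(target.chains[0], target.chains[1], lib)
        assert len(hits) >= 1
        top = hits[0]
        assert top.tm1 == pytest.approx(1.0, abs=1e-6)
        assert top.tm2 == pytest.approx(1.0, abs=1e-6)

    def test_homodimer_uses_different_chain_copies(self):
        seq = synth.random_sequence(30, seed=51)
        mono = synth.make_bundle(30, seed=52, sequence=seq, chain_id="A")
        homo = synth.make_dimer(mono, mono.slice(0, len(mono)), 4.5,
                                relative_rotation=120.0, source_id="homo")
        entry = entry_from_dimer(homo, "homo", kind="homo_oligomer")
        lib = TemplateLibrary(entries=[entry], kind="DB_MoHo")
        # the two target subunits are the two placed copies of the same chain
        hits = search_sequence_templates(homo.chains[0], homo.chains[1], lib)
        assert hits
        assert hits[0].tm_interface == pytest.approx(1.0, abs=1e-6)

    def test_no_hit_when_only_one_part_qualifies(self, target):
        decoy = synth.make_strand(40, sequence=synth.random_sequence(40, seed=53),
                                  chain_id="B")
        entry = monomer_entry_from_parts(target.chains[0], decoy, "lopsided")
        lib = TemplateLibrary(entries=[entry], kind="DB_MoHo")
        hits = search_sequence_templates(target.chains[0], target.chains[1], lib,
                                         top_k=1)
        assert hits == []


class TestInterfaceTM:
    def make_hit(self, target, subunit_a, subunit_b):
        entry = entry_from_dimer(target, "t")
        r1 = structural_align(subunit_a, entry.part1)
        r2 = structural_align(subunit_b, entry.part2)
        return TemplateHit(entry=entry, align1=r1, align2=r2,
                           tm1=r1.tm, tm2=r2.tm, tm_interface=0.0)

    def test_self_template_scores_one(self, target):
        hit = self.make_hit(target, target.chains[0], target.chains[1])
        assert interface_tm(hit, target.chains[0], target.chains[1]) \
            == pytest.approx(1.0, abs=1e-6)

    def test_empty_interface_pool_scores_zero(self, target):
        entry = entry_from_dimer(target, "t")
        # correspondences that avoid every template interface residue
        outside1 = sorted(set(range(len(entry.part1))) - set(entry.interface1))
        outside2 = sorted(set(range(len(entry.part2))) - set(entry.interface2))
        if not outside1 or not outside2:
            pytest.skip("fixture interface covers the whole chain")
        from heterodock.align import AlignmentResult
        from heterodock.superpose import Correspondence
        a1 = AlignmentResult(Correspondence.from_columns(outside1, outside1),
                             1.0, "structure", tm=1.0)
        a2 = AlignmentResult(Correspondence.from_columns(outside2, outside2),
                             1.0, "structure", tm=1.0)
        hit = TemplateHit(entry=entry, align1=a1, align2=a2, tm1=1.0, tm2=1.0,
                          tm_interface=0.0)
        assert interface_tm(hit, target.chains[0], target.chains[1]) == 0.0

    def test_invariant_to_input_frame_of_each_subunit(self, target):
        base_hit = self.make_hit(target, target.chains[0], target.chains[1])
        base = interface_tm(base_hit, target.chains[0], target.chains[1])
        R, t = random_rigid(55)
        b_moved = target.chains[1].transformed(R, t)
        hit = self.make_hit(target, target.chains[0], b_moved)
        assert interface_tm(hit, target.chains[0], b_moved) \
            == pytest.approx(base, abs=1e-6)

    def test_damaged_interface_regions_fail_filter_despite_global_fit(self, target):
        # displace only the interface residues of both subunits: the global
        # fold (hence tm1/tm2) survives, the interface-region fit must not
        entry = entry_from_dimer(target, "t")
        rng = np.random.default_rng(61)

        def damage(chain, interface):
            ca = chain.ca.copy()
            idx = sorted(interface)
            ca[idx] += rng.normal(scale=4.0, size=(len(idx), 3))
            from heterodock.structio import ChainStructure
            return ChainStructure(chain.chain_id, chain.res_numbers.copy(),
                                  list(chain.res_names), ca, chain.cb.copy())

        bad_a = damage(target.chains[0], entry.interface1)
        bad_b = damage(target.chains[1], entry.interface2)
        hit = self.make_hit(target, bad_a, bad_b)
        assert hit.tm1 > 0.4 and hit.tm2 > 0.4
        score = interface_tm(hit, bad_a, bad_b)
        assert score < 0.4
        assert score < min(hit.tm1, hit.tm2)
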