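"""One-pot closure, preassembly split/route equivalence, enumeration."""

import random

import networkx as nx
import pytest

from ggyl.assembler import (
    AssemblyDesign,
    DesignError,
    OpenJunctionError,
    count_fragments,
    covered_slots,
    enumerate_designs,
    plan_preassembly,
    sample_designs,
    simulate_one_pot,
    simulate_preassembly_route,
)
from ggyl.registry import SlotId
from ggyl.seqcore import BSAI, find_recognition_sites


def design_1tu(term="TLip2_EL", vector="GGE029"):
    return AssemblyDesign(
        "1TU",
        {
            SlotId.InsUp: "ZetaUp",
            SlotId.Marker: "URA3",
            SlotId.Prom1: "pTEF_P1",
            SlotId.Gene1: "RedStarII_G1",
            SlotId.Term1: term,
            SlotId.InsDown: "ZetaDown",
        },
        vector,
    )


def design_2tu():
    return AssemblyDesign(
        "2TU",
        {
            SlotId.InsUp: "ZetaUp",
            SlotId.Marker: "URA3",
            SlotId.Prom1: "pTEF_P1",
            SlotId.Gene1: "RedStarII_G1",
            SlotId.Term1: "TLip2_T1",
            SlotId.Prom2: "pTEF_P2",
            SlotId.Gene2: "YFP_G2",
            SlotId.Term2: "TLip2_HL",
            SlotId.InsDown: "ZetaDown",
        },
        "GGE029",
    )


def random_3tu(toolkit, rng, vector="GGE029"):
    from ggyl.registry import slot_layout

    pairs = {s: (l, r) for s, l, r in slot_layout("3TU")}

    def pick(cat, slot):
        return rng.choice(
            [
                b.id
                for b in toolkit.bricks_in(cat)
                if slot in b.slots
                and (b.left_letter, b.right_letter) == pairs[slot]
            ]
        )
    return AssemblyDesign(
        "3TU",
        {
            SlotId.InsUp: pick("insertion_up", SlotId.InsUp),
            SlotId.Marker: pick("marker", SlotId.Marker),
            SlotId.Prom1: pick("promoter", SlotId.Prom1),
            SlotId.Gene1: pick("gene", SlotId.Gene1),
            SlotId.Term1: pick("terminator", SlotId.Term1),
            SlotId.Prom2: pick("promoter", SlotId.Prom2),
            SlotId.Gene2: pick("gene", SlotId.Gene2),
            SlotId.Term2: pick("terminator", SlotId.Term2),
            SlotId.Prom3: pick("promoter", SlotId.Prom3),
            SlotId.Gene3: pick("gene", SlotId.Gene3),
            SlotId.Term3: pick("terminator", SlotId.Term3),
            SlotId.InsDown: pick("insertion_down", SlotId.InsDown),
        },
        vector,
    )


def _full_terminator(toolkit, slot):
    for b in toolkit.bricks_in("terminator"):
        if slot in b.slots and "shortcut" not in b.annotations:
            return b.id
    raise LookupError


class TestFragmentCounts:
    def test_3tu_design_has_13_molecules(self, demo):
        assert count_fragments(demo.design, demo.toolkit) == 13

    def test_1tu_shortcut_design_has_7(self, toolkit):
        assert count_fragments(design_1tu(), toolkit) == 7

    def test_2tu_shortcut_design_has_10(self, toolkit):
        assert count_fragments(design_2tu(), toolkit) == 10

    def test_preassembled_vector_reduces_count(self, demo):
        d = AssemblyDesign(
            "3TU",
            {
                s: demo.design.assignments[s]
                for s in demo.design.assignments
                if s not in (SlotId.InsUp, SlotId.Marker, SlotId.InsDown)
            },
            "GGE114",
        )
        assert covered_slots(d, demo.toolkit) >= {
            SlotId.Backbone, SlotId.InsUp, SlotId.Marker, SlotId.InsDown
        }
        assert count_fragments(d, demo.toolkit) == 10


class TestOnePot:
    def test_full_3tu_yields_single_bsai_free_circle(self, demo):
        construct = simulate_one_pot(demo.design, demo.toolkit)
        assert construct.plasmid.is_circular
        assert find_recognition_sites(construct.plasmid, BSAI) == []
        letters = [l for l, _, _ in construct.junctions]
        assert sorted(letters) == list("ABCDEFGHIJKLM")

    def test_missing_gene2_reports_open_junction_G_H(self, demo, monkeypatch):
        import ggyl.assembler as asm

        a = dict(demo.design.assignments)
        del a[SlotId.Gene2]
        broken = AssemblyDesign("3TU", a, "GGE029")
        # design validation already refuses; the pot itself must also fail
        with pytest.raises(DesignError):
            simulate_one_pot(broken, demo.toolkit)
        monkeypatch.setattr(asm, "validate_design", lambda *args: None)
        with pytest.raises(OpenJunctionError) as exc:
            simulate_one_pot(broken, demo.toolkit)
        assert exc.value.letters == ["G", "H"]

    def test_rfp_dropout_never_in_product(self, demo):
        construct = simulate_one_pot(demo.design, demo.toolkit)
        dropout = demo.toolkit.brick("GGE029").stuffer
        assert dropout not in construct.plasmid.residues * 2

    def test_order_invariance_under_input_shuffle(self, demo):
        """The pot is a set: assignment-dict ordering never changes the
        canonical product."""
        rng = random.Random(5)
        base = simulate_one_pot(demo.design, demo.toolkit).canonical
        items = list(demo.design.assignments.items())
        for _ in range(3):
            rng.shuffle(items)
            shuffled = AssemblyDesign("3TU", dict(items), "GGE029")
            assert simulate_one_pot(shuffled, demo.toolkit).canonical == base

    def test_features_tile_insert_without_gaps(self, demo):
        construct = simulate_one_pot(demo.design, demo.toolkit)
        feats = sorted(construct.features, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            assert a.end == b.start
        assert feats[-1].end == len(construct.plasmid)

    def test_closure_unique_vs_brute_force_cycle_enumeration(self, demo):
        """Independent oracle: the digraph of stable fragments has exactly
        one Hamiltonian cycle (networkx simple_cycles)."""
        from ggyl.assembler import _stable
        from ggyl.seqcore import digest

        tk = demo.toolkit
        frags = []
        for brick_id in list(demo.design.assignments.values()) + ["GGE029"]:
            frags.extend(f for f in digest(tk.donor(brick_id), BSAI) if _stable(f))
        assert len(frags) == 13
        g = nx.DiGraph()
        g.add_nodes_from(range(len(frags)))
        for i, f in enumerate(frags):
            for j, h in enumerate(frags):
                if i != j and f.right_overhang == h.left_overhang:
                    g.add_edge(i, j)
        hamiltonian = [c for c in nx.simple_cycles(g) if len(c) == len(frags)]
        assert len(hamiltonian) == 1


class TestPreassembly:
    def test_groups_exactly_as_published(self, demo):
        plan = plan_preassembly(demo.design, demo.toolkit)
        assert [len(g) for g in plan.sub_reactions] == [4, 4, 4]
        slots = demo.design.assignments
        assert plan.sub_reactions[0] == tuple(
            slots[s] for s in (SlotId.InsUp, SlotId.Marker, SlotId.Prom1, SlotId.Gene1)
        )
        assert plan.sub_reactions[1] == tuple(
            slots[s] for s in (SlotId.Term1, SlotId.Prom2, SlotId.Gene2, SlotId.Term2)
        )
        assert plan.sub_reactions[2] == tuple(
            slots[s] for s in (SlotId.Prom3, SlotId.Gene3, SlotId.Term3, SlotId.InsDown)
        )
        assert plan.final_inputs[-1] == "GGE029"

    def test_non_3tu_design_unsupported(self, toolkit):
        with pytest.raises(DesignError):
            plan_preassembly(design_1tu(), toolkit)

    def test_route_equivalence_direct_vs_split(self, demo):
        direct = simulate_one_pot(demo.design, demo.toolkit)
        split = simulate_preassembly_route(demo.design, demo.toolkit)
        assert direct.canonical == split.canonical

    def test_route_equivalence_on_random_designs(self, demo):
        rng = random.Random(77)
        tk = demo.toolkit
        for _ in range(10):
            d = random_3tu(tk, rng)
            assert (
                simulate_one_pot(d, tk).canonical
                == simulate_preassembly_route(d, tk).canonical
            )


class TestEnumeration:
    def test_count_is_product_of_option_counts(self, toolkit):
        proms = {
            slot: [b.id for b in toolkit.bricks_in("promoter") if slot in b.slots]
            for slot in (SlotId.Prom1, SlotId.Prom2, SlotId.Prom3)
        }
        assert all(len(v) == 9 for v in proms.values())
        assert len({b for v in proms.values() for b in v}) == 27
        options = {
            SlotId.InsUp: ["ZetaUp"],
            SlotId.Marker: ["URA3"],
            SlotId.Gene1: ["RedStarII_G1"],
            SlotId.Term1: ["TLip2_T1"],
            SlotId.Gene2: ["YFP_G2"],
            SlotId.Term2: ["TLip2_T2"],
            SlotId.Gene3: ["mTurquoise_G3"],
            SlotId.Term3: ["TLip2_T3"],
            SlotId.InsDown: ["ZetaDown"],
            **proms,
        }
        it, count = enumerate_designs("3TU", options, "GGE029")
        assert count == 9 ** 3 == 729
        designs = list(it)
        assert len(designs) == 729
        assert len({tuple(sorted((k.value, v) for k, v in d.assignments.items()))
                    for d in designs}) == 729

    def test_single_option_grid_yields_identity(self, toolkit):
        d = design_1tu()
        options = {s: [b] for s, b in d.assignments.items()}
        it, count = enumerate_designs("1TU", options, "GGE029")
        assert count == 1
        only = next(it)
        assert only.assignments == dict(d.assignments)

    def test_random_grids_match_product_rule(self, rng):
        for _ in range(20):
            options = {
                slot: [f"b{i}" for i in range(rng.randint(1, 5))]
                for slot in list(SlotId)[: rng.randint(1, 6)]
            }
            _, count = enumerate_designs("3TU", options, "V")
            expect = 1
            for v in options.values():
                expect *= len(v)
            assert count == expect

    def test_empty_slot_rejected_and_sampling_deterministic(self):
        with pytest.raises(DesignError):
            enumerate_designs("3TU", {SlotId.Prom1: []}, "V")
        a = sample_designs("3TU", {SlotId.Prom1: ["x", "y", "z"]}, "V", 5, seed=3)
        b = sample_designs("3TU", {SlotId.Prom1: ["x", "y", "z"]}, "V", 5, seed=3)
        assert a == b
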