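"""NotI release, colony PCR, reaction recipes and screening arithmetic."""

import json
import random

import pytest

from ggyl.assembler import AssembledConstruct, Feature, simulate_one_pot
from ggyl.qc_protocol import (
    CannotLinearizeError,
    IntegrationRecord,
    colony_pcr,
    integration_rate,
    make_protocol,
    notI_release,
    pmol_to_mass,
)
from ggyl.seqcore import NucSequence, revcomp

from conftest import random_dna


class TestNotIRelease:
    def test_xylose_fixture_releases_cassette_in_2_fragments(self, demo):
        construct = simulate_one_pot(demo.design, demo.toolkit)
        report = notI_release(construct)
        assert len(report.notI_fragments) == 2
        assert report.cassette_found
        sizes = sorted(f.length for f in report.notI_fragments)
        assert sum(sizes) == len(construct.plasmid)
        cassette = next(f for f in report.notI_fragments if f.is_cassette)
        # the cassette spans marker + 3 TUs, i.e. most of the insert
        assert cassette.length > sizes[0]

    def test_no_noti_site_cannot_linearize(self):
        plasmid = NucSequence("ACGT" * 100, "circular", "p")
        construct = AssembledConstruct(plasmid, [], [])
        with pytest.raises(CannotLinearizeError):
            notI_release(construct)

    def test_fragment_sizes_sum_to_plasmid_length_on_random_fixtures(self, rng):
        """Conservation oracle over 50 random NotI-carrying circles."""
        for _ in range(50):
            pieces = []
            for _k in range(rng.randint(1, 4)):
                pieces.append("GCGGCCGC")
                pieces.append(random_dna(rng, rng.randint(50, 400)))
            seq = "".join(pieces)
            plasmid = NucSequence(seq, "circular", "r")
            report = notI_release(AssembledConstruct(plasmid, [], []))
            assert sum(f.length for f in report.notI_fragments) == len(seq)

    def test_cassette_split_warning_when_internal_site(self, demo, rng):
        construct = simulate_one_pot(demo.design, demo.toolkit)
        # corrupt: inject an extra NotI site inside the marker feature
        marker = next(f for f in construct.features if f.slot == "Marker")
        res = construct.plasmid.residues
        mid = (marker.start + marker.end) // 2
        corrupted = NucSequence(
            res[:mid] + "GCGGCCGC" + res[mid + 8 :], "circular", "x"
        )
        report = notI_release(
            AssembledConstruct(corrupted, construct.features, [])
        )
        assert len(report.notI_fragments) == 3


class TestColonyPCR:
    def test_flanking_primers_540_bp(self, rng):
        fwd = random_dna(rng, 20)
        insert = random_dna(rng, 500)
        rev = random_dna(rng, 20)
        template = NucSequence(
            random_dna(rng, 100) + fwd + insert + revcomp(rev) + random_dna(rng, 80)
        )
        products = colony_pcr(template, fwd, rev)
        assert [p.length for p in products] == [540]

    def test_absent_reverse_primer_no_product(self, rng):
        template = NucSequence(random_dna(rng, 300))
        fwd = template.residues[10:30]
        products = colony_pcr(template, fwd, "ACGTACGTACGTACGTT")
        assert products == []

    def test_circular_template_spanning_origin(self, rng):
        fwd = random_dna(rng, 18)
        rev = random_dna(rng, 18)
        # amplicon wraps: fwd near the end, reverse site near the start
        template = NucSequence(
            revcomp(rev) + random_dna(rng, 60) + fwd + random_dna(rng, 30),
            "circular",
        )
        products = colony_pcr(template, fwd, rev)
        assert len(products) == 1
        n = len(template)
        assert products[0].length == (17 - products[0].forward_start) % n + 1

    def test_multi_site_primer_warns_and_lists_products(self, rng):
        site = random_dna(rng, 16)
        rev = random_dna(rng, 16)
        template = NucSequence(
            site + random_dna(rng, 50) + site + random_dna(rng, 50) + revcomp(rev)
        )
        with pytest.warns(UserWarning, match="multiple"):
            products = colony_pcr(template, site, rev)
        assert len(products) == 2

    def test_lengths_match_brute_force_oracle(self, rng):
        """Planted primer sites across 100 random templates; lengths checked
        against direct coordinate arithmetic."""
        for _ in range(100):
            fwd = random_dna(rng, rng.randint(16, 24))
            rev = random_dna(rng, rng.randint(16, 24))
            pre = random_dna(rng, rng.randint(10, 200))
            mid = random_dna(rng, rng.randint(0, 400))
            post = random_dna(rng, rng.randint(10, 200))
            template_str = pre + fwd + mid + revcomp(rev) + post
            template = NucSequence(template_str)
            products = colony_pcr(template, fwd, rev)
            expected = len(fwd) + len(mid) + len(rev)
            if [p.length for p in products] != [expected]:
                # random collision with extra matches: verify by rescanning
                starts = [
                    i
                    for i in range(len(template_str) - len(fwd) + 1)
                    if template_str[i : i + len(fwd)] == fwd
                ]
                assert len(starts) > 1 or len(products) != 1
            else:
                assert products[0].length == expected

    def test_short_primers_rejected(self):
        with pytest.raises(ValueError):
            colony_pcr(NucSequence("ACGT" * 50), "ACGTACGTAC", "ACGTACGTACGTACG")


class TestProtocols:
    def test_standard_one_pot_recipe(self):
        p = make_protocol("standard_one_pot", 13)
        assert p.per_fragment_pmol == 50
        assert p.bsai_units == 5 and p.ligase_units == 200
        assert p.buffer_ul == 2 and p.final_volume_ul == 20
        assert p.programme[0].cycles == 60
        assert p.programme[0].steps == ((37.0, 5.0), (16.0, 2.0))
        assert p.programme[1].steps == ((55.0, 5.0), (80.0, 5.0))

    def test_preassembly_recipe(self):
        p = make_protocol("preassembly", 4)
        assert p.programme[0].cycles == 30
        assert p.programme[0].steps == ((37.0, 3.0), (16.0, 2.0))
        assert p.final_volume_ul == 10 and p.buffer_ul == 1

    def test_multigene_final_recipe(self):
        p = make_protocol("multigene_final", 4)
        assert p.programme[0].cycles == 50
        assert p.programme[0].steps == ((37.0, 5.0), (16.0, 5.0))
        assert p.final_volume_ul == 40
        assert p.bsai_units == 20 and p.ligase_units == 400 and p.buffer_ul == 4

    def test_unknown_stage_and_tiny_pot_rejected(self):
        with pytest.raises(ValueError):
            make_protocol("midiprep", 5)
        with pytest.raises(ValueError):
            make_protocol("standard_one_pot", 1)

    def test_serialization_round_trips_bit_exact(self):
        p = make_protocol("standard_one_pot", 13)
        d1 = json.dumps(p.to_dict(), sort_keys=True)
        d2 = json.dumps(make_protocol("standard_one_pot", 13).to_dict(), sort_keys=True)
        assert d1 == d2
        assert "60" in p.render()


class TestArithmetic:
    def test_pmol_zero_and_unit_cases(self):
        assert pmol_to_mass(0, 1000) == 0
        assert pmol_to_mass(1, 1, 650) == pytest.approx(0.65)

    def test_50_pmol_of_2kb_matches_hand_calculation(self):
        # 50e-12 mol * 2000 bp * 650 g/mol/bp = 6.5e-5 g = 65000 ng
        assert pmol_to_mass(50, 2000) == pytest.approx(65_000)

    @pytest.mark.parametrize(
        "pos,scr,policy,expect",
        [
            (5, 37, "round", 14),     # LIP2 screen: 13.51 -> 14
            (5, 37, "truncate", 13),
            (11, 24, "round", 46),    # GSY1 screen: 45.83 -> 46
            (11, 24, "truncate", 45), # the printed 45% corresponds to truncation
            (0, 10, "round", 0),
            (10, 10, "round", 100),
        ],
    )
    def test_integration_rate_policies(self, pos, scr, policy, expect):
        assert integration_rate(pos, scr, policy) == expect

    def test_policy_must_be_explicit_in_records(self):
        rec = IntegrationRecord.compute("LIP2", 5, 37, "round")
        assert rec.percent == 14 and rec.policy == "round"
        rec_t = IntegrationRecord.compute("GSY1", 11, 24, "truncate")
        assert rec_t.percent == 45 and rec_t.policy == "truncate"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            integration_rate(1, 0)
        with pytest.raises(ValueError):
            integration_rate(5, 3)
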