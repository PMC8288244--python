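"""Exocyclic-bond decomposition: cut eligibility, acceptance rules, enumeration."""

import pytest

from rgroupnet.compound_io import make_record
from rgroupnet.fragmentation import (
    Decomposition,
    FragmentationConfig,
    Rejection,
    decompose,
    eligible_cut_bonds,
    enumerate_decompositions,
)
from rgroupnet.synthetic import generate_library, random_library_spec

from conftest import naive_enumerate


def heavy_cuts(record):
    return [c for c in eligible_cut_bonds(record) if c.kind == "bond"]


def hydrogen_cuts(record):
    return [c for c in eligible_cut_bonds(record) if c.kind == "hydrogen"]


class TestEligibleCuts:
    @pytest.mark.parametrize(
        "smiles,n_heavy,n_hydrogen",
        [
            ("c1ccccc1", 0, 6),        # all bonds aromatic; every CH is a virtual site
            ("Cc1ccccc1", 1, 6),       # only the methyl-ring bond is cuttable
            ("CCc1ccccc1", 2, 7),      # chain C-C and C-ring
            ("C1CCCCC1", 0, 6),        # saturated ring: ring bonds never cut
            ("C=Cc1ccccc1", 1, 7),     # the double bond itself is not cuttable
        ],
    )
    def test_cut_counts(self, smiles, n_heavy, n_hydrogen):
        rec = make_record("x", smiles)
        assert len(heavy_cuts(rec)) == n_heavy
        assert len(hydrogen_cuts(rec)) == n_hydrogen


class TestDecompose:
    def test_ethylbenzene_ring_cut(self):
        rec = make_record("e", "CCc1ccccc1")
        # the bond between the ring and CH2 is the one whose fragments are 6+2
        for cut in heavy_cuts(rec):
            outs = decompose(rec, [cut])
            accepted = [o for o in outs if isinstance(o, Decomposition)]
            if any(o.assignments[0].smiles == "*CC" for o in accepted):
                (dec,) = accepted
                assert dec.core.smiles == "[1*]c1ccccc1"
                assert dec.core.heavy_atoms == 6
                assert dec.assignments[0].heavy_atoms == 2
                return
        pytest.fail("no ring-CH2 decomposition found")

    def test_cutting_both_chain_bonds_is_rejected(self):
        # middle CH2 would be the only fragment touching both cuts but is
        # far too small to be a core
        rec = make_record("e", "CCc1ccccc1")
        outs = decompose(rec, heavy_cuts(rec))
        assert all(isinstance(o, Rejection) for o in outs)

    def test_half_rule_rejects_small_core_orientation(self):
        # 20 heavy atoms: 9-atom benzofuran + 11-atom chain; the ring-side
        # core (9 < 10) violates the half rule, the chain side passes
        rec = make_record("h", "CCCCCCCCCCCc1cc2ccccc2o1")
        for cut in heavy_cuts(rec):
            outs = decompose(rec, [cut])
            accepted = [o for o in outs if isinstance(o, Decomposition)]
            rejected = [o for o in outs if isinstance(o, Rejection)]
            if [d.core.heavy_atoms for d in accepted] == [11]:
                assert [r.rule for r in rejected] == ["half_rule"]
                break
        else:
            pytest.fail("attachment-bond cut not found")

    def test_rgroup_size_cap(self):
        # 14-carbon substituent on a large rigid scaffold: cutting at the
        # attachment yields an oversized R-group
        rec = make_record("s", "C" * 14 + "c1ccc2c(c1)oc1ccccc12")
        cfg = FragmentationConfig()
        seen_size_rejection = False
        for cut in heavy_cuts(rec):
            for o in decompose(rec, [cut], cfg):
                if isinstance(o, Decomposition):
                    assert all(r.heavy_atoms <= cfg.rgroup_max_heavy for r in o.assignments)
                elif o.rule == "rgroup_size":
                    seen_size_rejection = True
        assert seen_size_rejection

    def test_hydrogen_cut_outside_core_rejected(self):
        rec = make_record("t", "CCc1ccccc1")
        ring_cut = next(
            c for c in heavy_cuts(rec)
            if any(
                isinstance(o, Decomposition) and o.assignments[0].smiles == "*CC"
                for o in decompose(rec, [c])
            )
        )
        # hydrogen position on the terminal methyl: lands inside the R-group
        methyl_h = hydrogen_cuts(rec)[0]
        outs = decompose(rec, [ring_cut, methyl_h])
        assert any(
            isinstance(o, Rejection) and o.rule == "hydrogen_site_outside_core"
            for o in outs
        )

    def test_no_heavy_cut_is_rejected(self):
        rec = make_record("b", "c1ccccc1")
        outs = decompose(rec, hydrogen_cuts(rec)[:2])
        assert outs == [Rejection("b", "no_heavy_cut")]


class TestEnumerate:
    def test_benzene_yields_nothing(self):
        rec = make_record("b", "c1ccccc1")
        assert enumerate_decompositions(rec) == []
        cfg = FragmentationConfig(hydrogen_cuts=False)
        assert enumerate_decompositions(rec, cfg) == []

    def test_toluene_single_site_includes_methyl_and_hydrogen_rgroups(self):
        rec = make_record("t", "Cc1ccccc1")
        cfg = FragmentationConfig(max_sites=1)
        decs = enumerate_decompositions(rec, cfg)
        oracle = naive_enumerate(rec, cfg)
        assert [d.sort_key for d in decs] == [d.sort_key for d in oracle]
        rgroups = {d.assignments[0].smiles for d in decs}
        assert "*C" in rgroups  # benzene core + methyl

    def test_atom_conservation_and_rules_on_library(self, two_site_library):
        records, _ = two_site_library
        cfg = FragmentationConfig()
        for rec in records:
            for d in enumerate_decompositions(rec, cfg):
                total = d.core.heavy_atoms + sum(r.heavy_atoms for r in d.assignments)
                assert total == rec.heavy_atoms
                assert 2 * d.core.heavy_atoms >= rec.heavy_atoms
                assert all(r.heavy_atoms <= cfg.rgroup_max_heavy for r in d.assignments)
                assert d.core.n_sites == len(d.assignments) <= cfg.max_sites

    def test_matches_bruteforce_oracle_on_seeded_library(self):
        spec = random_library_spec(3)
        records, _ = generate_library(spec)
        for rec in records:
            mine = enumerate_decompositions(rec)
            oracle = naive_enumerate(rec)
            assert [d.sort_key for d in mine] == [d.sort_key for d in oracle], rec

    def test_enumeration_is_deterministic(self):
        rec = make_record("d", "CCOc1ccc2ncc(C)cc2c1")
        a = enumerate_decompositions(rec)
        b = enumerate_decompositions(rec)
        assert [d.sort_key for d in a] == [d.sort_key for d in b]

    def test_budget_exhaustion_skips_compound(self, caplog):
        rec = make_record("big", "C" * 30)
        cfg = FragmentationConfig(cut_budget=10)
        assert enumerate_decompositions(rec, cfg) == []
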