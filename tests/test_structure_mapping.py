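"""Variant-to-structure mapping rules: eligibility boundaries, neighbor
checks, preference ordering, PDB parsing and the AlphaFold fallback."""

import numpy as np
import pytest

from stabbench import (ChainRecord, StructureRecord, VariantKey,
                       chain_eligibility, map_variants, nonhuman_residue_check,
                       read_structure, select_structure)
from stabbench.structure_mapping import Candidate, align_chain, write_mapping_report
from stabbench.synthetic import FixtureChain, FixtureStructure, write_fixture_pdb

AA = "ACDEFGHIKLMNPQRSTVWY"


def human_sequence() -> str:
    rng = np.random.default_rng(42)
    return "".join(rng.choice(list(AA), size=80))


HUMAN = human_sequence()
CORE = HUMAN[10:70]  # 60-residue region covering human positions 11..70


def mutate(s: str, idxs) -> str:
    out = list(s)
    for i in idxs:
        out[i] = "P" if out[i] != "P" else "G"
    return "".join(out)


def chain(seq, cid="A", sid="X", first=1, human=False) -> ChainRecord:
    return ChainRecord(sid, cid, seq, list(range(first, first + len(seq))),
                       is_human_entry=human)


class TestChainEligibility:
    def test_933_percent_over_60_is_eligible(self):
        ok, region = chain_eligibility(chain(mutate(CORE, [12, 24, 36, 48])), HUMAN)
        assert region.n_aligned == 60 and region.n_identical == 56
        assert ok

    def test_exactly_90_percent_is_not_eligible(self):
        ok, region = chain_eligibility(
            chain(mutate(CORE, [9, 17, 25, 33, 41, 49])), HUMAN)
        assert region.identity == pytest.approx(0.90)
        assert not ok

    def test_full_identity_under_50_residues_is_not_eligible(self):
        ok, region = chain_eligibility(chain(HUMAN[10:55]), HUMAN)
        assert region.n_aligned == 45 and region.identity == 1.0
        assert not ok


class TestNonhumanResidueCheck:
    # mismatches at core indices 12/24/36/48 = human positions 23/35/47/59
    NONHUMAN = chain(mutate(CORE, [12, 24, 36, 48]))
    REGION = align_chain(NONHUMAN.sequence, HUMAN)

    def check(self, pos):
        wt = HUMAN[pos - 1]
        mut = "A" if wt != "A" else "C"
        return nonhuman_residue_check(
            self.NONHUMAN, VariantKey("GENE1", pos, wt, mut), HUMAN, self.REGION)

    def test_residue_and_neighbors_match(self):
        ok, _ = self.check(20)
        assert ok

    def test_mismatched_residue_rejected(self):
        ok, why = self.check(23)
        assert not ok and "residue differs" in why

    def test_mismatched_neighbor_rejected(self):
        for pos in (22, 24):  # both sides of the mismatch at 23
            ok, why = self.check(pos)
            assert not ok and "neighbor" in why

    def test_chain_terminus_requires_only_existing_neighbor(self):
        ok, _ = self.check(11)  # chain N-terminus: human pos 10 is unaligned
        assert ok

    def test_outside_aligned_region(self):
        ok, why = self.check(75)
        assert not ok and why == "outside aligned region"


def record(sid, resolution, assembly_size=1, method="xray") -> StructureRecord:
    ch = chain(CORE, sid=sid, human=True)
    return StructureRecord(sid, resolution, method,
                           [["A"] * assembly_size], [ch],
                           n_frames=3 if method == "nmr" else 1)


class TestSelectStructure:
    def cand(self, st):
        return Candidate(st, st.chains[0], 1)

    def test_best_resolution_first(self):
        order = select_structure([self.cand(record("HI", 2.5)),
                                  self.cand(record("LO", 1.8))])
        assert [c.structure.structure_id for c in order] == ["LO", "HI"]

    def test_largest_assembly_breaks_resolution_tie(self):
        order = select_structure([self.cand(record("SMALL", 2.0, 2)),
                                  self.cand(record("BIG", 2.0, 4))])
        assert order[0].structure.structure_id == "BIG"

    def test_lexicographic_id_is_final_tie_break(self):
        order = select_structure([self.cand(record("2XYZ", 2.0)),
                                  self.cand(record("1ABC", 2.0))])
        assert order[0].structure.structure_id == "1ABC"

    def test_unresolved_structures_sort_last(self):
        order = select_structure([self.cand(record("NMR", None, method="nmr")),
                                  self.cand(record("XR", 3.5))])
        assert order[0].structure.structure_id == "XR"


class TestReadStructure:
    def test_resolution_assembly_and_sequence(self, tmp_path):
        path = write_fixture_pdb(
            FixtureStructure("1FIX", [FixtureChain("A", CORE, first_resnum=5)],
                             resolution=1.8), tmp_path / "f.pdb")
        st = read_structure(path, human_chain_ids=["A"])
        assert st.resolution == pytest.approx(1.8)
        assert st.experimental_method == "xray"
        assert st.assemblies == [["A"]]
        assert st.chains[0].sequence == CORE
        assert st.chains[0].residue_numbers[0] == 5
        assert st.chains[0].is_human_entry

    def test_homodimer_assembly_size_two(self, tmp_path):
        path = write_fixture_pdb(
            FixtureStructure("2DIM", [FixtureChain("A", CORE)],
                             resolution=2.0, assemblies=[[("A", 2)]]),
            tmp_path / "d.pdb")
        st = read_structure(path)
        assert st.assemblies == [["A", "A"]]
        assert st.first_assembly_size == 2

    def test_altloc_collapses_to_single_residue(self, tmp_path):
        path = write_fixture_pdb(
            FixtureStructure("3ALT", [FixtureChain("A", CORE, altloc_positions=(2,))],
                             resolution=2.0), tmp_path / "a.pdb")
        st = read_structure(path)
        assert st.chains[0].sequence == CORE  # each position appears once
        assert len(st.chains[0].residue_numbers) == len(CORE)

    def test_nmr_keeps_first_frame_only(self, tmp_path):
        path = write_fixture_pdb(
            FixtureStructure("4NMR", [FixtureChain("A", CORE)],
                             resolution=None, n_models=3), tmp_path / "n.pdb")
        st = read_structure(path)
        assert st.experimental_method == "nmr"
        assert st.n_frames == 3
        assert st.resolution is None
        assert len(st.chains) == 1 and st.chains[0].sequence == CORE

    def test_unparsable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("")
        with pytest.raises(ValueError):
            read_structure(bad)


def fixture_structures() -> list[StructureRecord]:
    nonhuman_seq = mutate(CORE, [12, 24, 36, 48])  # mismatch at human pos 23 etc.
    return [
        StructureRecord("1ABC", 1.8, "xray", [["A"]],
                        [chain(CORE, sid="1ABC", first=5, human=True)]),
        StructureRecord("2BCD", 2.5, "xray", [["A"]],
                        [chain(CORE, sid="2BCD", human=True)]),
        StructureRecord("3NON", 1.0, "xray", [["A"]],
                        [chain(nonhuman_seq, sid="3NON", human=False)]),
        StructureRecord("4NMR", None, "nmr", [["A"]],
                        [chain(CORE, sid="4NMR", human=True)], n_frames=3),
        StructureRecord("5BIG", 2.5, "xray", [["A", "A"]],
                        [chain(CORE, sid="5BIG", human=True)]),
    ]


def variant(pos, wt=None, mut=None) -> VariantKey:
    wt = wt or (HUMAN[pos - 1] if pos <= len(HUMAN) else "L")
    mut = mut or ("A" if wt != "A" else "C")
    return VariantKey("GENE1", pos, wt, mut)


def brute_force_map(variants, structures, human):
    """Literal rule-by-rule enumeration used as the mapping oracle."""
    out = {}
    for v in variants:
        if v.position > len(human) or human[v.position - 1] != v.wt_aa:
            out[v] = ("unmapped", None)
            continue
        admissible = []
        for st in structures:
            for ch in st.chains:
                ok, region = chain_eligibility(ch, human)
                if not ok:
                    continue
                cidx = region.human_to_chain.get(v.position)
                if cidx is None or ch.sequence[cidx] != v.wt_aa:
                    continue
                if not ch.is_human_entry:
                    ok_nh, _ = nonhuman_residue_check(ch, v, human, region)
                    if not ok_nh:
                        continue
                admissible.append((st, ch, ch.residue_numbers[cidx]))
        if not admissible:
            out[v] = ("alphafold", v.position)
            continue
        admissible.sort(key=lambda t: (
            t[0].resolution if t[0].resolution is not None else float("inf"),
            -t[0].first_assembly_size, t[0].structure_id, t[1].chain_id))
        st, ch, resnum = admissible[0]
        out[v] = ("pdb", (st.structure_id, ch.chain_id, resnum))
    return out


class TestMapVariants:
    STRUCTURES = fixture_structures()
    SEQS = {"GENE1": HUMAN}

    def test_hand_written_expected_table(self):
        vs = [variant(20), variant(23), variant(24), variant(75), variant(90),
              variant(30, wt="W" if HUMAN[29] != "W" else "Y")]
        results = {r.variant: r for r in map_variants(vs, self.STRUCTURES, self.SEQS)}
        # pos 20: non-human 3NON admissible, best resolution 1.0 wins
        r = results[vs[0]]
        assert (r.target_kind, r.structure_id, r.residue_number) == ("pdb", "3NON", 10)
        # pos 23: 3NON residue differs -> human 1ABC at 1.8 A; resnum offset 5
        r = results[vs[1]]
        assert (r.target_kind, r.structure_id, r.residue_number) == ("pdb", "1ABC", 17)
        # pos 24: 3NON neighbor differs -> 1ABC
        r = results[vs[2]]
        assert (r.target_kind, r.structure_id, r.residue_number) == ("pdb", "1ABC", 18)
        # pos 75: outside every aligned region -> AlphaFold fallback
        r = results[vs[3]]
        assert (r.target_kind, r.uniprot_position) == ("alphafold", 75)
        # pos 90: beyond the human sequence
        r = results[vs[4]]
        assert r.target_kind == "unmapped"
        assert "position out of range" in r.provenance
        # wrong wild type
        r = results[vs[5]]
        assert r.target_kind == "unmapped"

    def test_assembly_size_breaks_resolution_tie(self):
        sts = [s for s in fixture_structures() if s.structure_id in ("2BCD", "5BIG")]
        (r,) = map_variants([variant(40)], sts, self.SEQS)
        assert r.structure_id == "5BIG"

    def test_matches_brute_force_oracle(self):
        vs = [variant(p) for p in range(11, 80, 3)] + [variant(85)]
        results = map_variants(vs, self.STRUCTURES, self.SEQS)
        oracle = brute_force_map(vs, self.STRUCTURES, self.SEQS["GENE1"])
        for r in results:
            kind, payload = oracle[r.variant]
            assert r.target_kind == kind
            if kind == "pdb":
                assert (r.structure_id, r.chain_id, r.residue_number) == payload
            elif kind == "alphafold":
                assert r.uniprot_position == payload

    def test_coverage_partition_and_order_invariance(self):
        vs = [variant(p) for p in range(11, 91, 7)]
        fwd = map_variants(vs, self.STRUCTURES, self.SEQS)
        rev = map_variants(vs, list(reversed(self.STRUCTURES)), self.SEQS)
        assert len(fwd) == len(vs)
        for a, b in zip(fwd, rev):
            assert a.target_kind == b.target_kind
            assert (a.structure_id, a.residue_number) == (b.structure_id, b.residue_number)
        kinds = {r.target_kind for r in fwd}
        assert kinds <= {"pdb", "alphafold", "unmapped"}
        for r in fwd:
            if r.target_kind == "unmapped":
                assert r.provenance

    def test_mapping_report_written(self, tmp_path):
        vs = [variant(20), variant(90)]
        results = map_variants(vs, self.STRUCTURES, self.SEQS)
        out = tmp_path / "report.tsv"
        write_mapping_report(results, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("gene\tposition")
        assert len(lines) == 3
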