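import numpy as np
import pytest

from scenabc import popdata
from scenabc.popdata import (
    AlignmentError,
    MicrosatGenotypes,
    MultilocusDataset,
    ParseError,
    PopulationMap,
    SequenceAlignment,
    assemble_dataset,
    read_alignment,
    read_genepop,
    read_population_map,
    write_alignment,
    write_genepop,
    write_population_map,
)


class TestFasta:
    def test_basic_read(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGT\n>s2\nACGA\n")
        aln = read_alignment(p)
        assert aln.n == 2
        assert aln.length == 4
        assert aln.ids == ["s1", "s2"]

    def test_round_trip(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGTNACG-T\n>s2\nACGAAACGTT\n")
        aln = read_alignment(p)
        q = tmp_path / "b.fa"
        write_alignment(aln, q, wrap=4)
        aln2 = read_alignment(q)
        assert aln2.ids == aln.ids
        assert (aln2.seqs == aln.seqs).all()

    def test_ragged_raises(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGTA\n>s2\nACGT\n")
        with pytest.raises(AlignmentError, match="ragged"):
            read_alignment(p)

    def test_illegal_symbol_names_record_and_position(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGT\n>s2\nACXT\n")
        with pytest.raises(ParseError, match=r"s2.*position 3.*X"):
            read_alignment(p)

    def test_record_order_preserved(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">z\nAC\n>a\nGT\n>m\nCC\n")
        assert read_alignment(p).ids == ["z", "a", "m"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            SequenceAlignment(["a", "a"], np.array([["A"], ["C"]]))


GENEPOP_TOY = """toy file
LocusA
Pop
ind1, 090100
ind2, 090090
Pop
ind3, 100100
ind4, 000000
"""


class TestGenepop:
    def test_toy_read(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text(GENEPOP_TOY)
        geno, pops = read_genepop(p)
        assert geno.loci == ["LocusA"]
        assert geno.ids == ["ind1", "ind2", "ind3", "ind4"]
        assert pops == {"ind1": "pop1", "ind2": "pop1",
                        "ind3": "pop2", "ind4": "pop2"}
        assert geno.calls[0, 0].tolist() == [90, 100]
        assert geno.calls[3, 0].tolist() == [-1, -1]

    def test_all_zero_missing(self, tmp_path, caplog):
        p = tmp_path / "g.gen"
        p.write_text("t\nL1\nPop\ni1, 0000\ni2, 0000\n")
        with caplog.at_level("WARNING"):
            geno, _ = read_genepop(p)
        assert (geno.calls == -1).all()
        assert any("missing" in r.message for r in caplog.records)

    def test_missing_pop_line(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text("t\nL1\ni1, 0909\n")
        with pytest.raises(ParseError, match="Pop"):
            read_genepop(p)

    def test_odd_allele_field(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text("t\nL1\nPop\ni1, 09010\n")
        with pytest.raises(ParseError):
            read_genepop(p)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text(GENEPOP_TOY)
        geno, pops = read_genepop(p)
        q = tmp_path / "h.gen"
        write_genepop(geno, pops, q)
        geno2, pops2 = read_genepop(q)
        assert geno2.ids == geno.ids
        assert (geno2.calls == geno.calls).all()
        assert pops2 == pops

    def test_two_digit_coding(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text("t\nL1\nPop\ni1, 0910\n")
        geno, _ = read_genepop(p)
        assert geno.calls[0, 0].tolist() == [9, 10]


class TestGenotypes:
    def test_half_missing_rejected(self):
        with pytest.raises(ValueError, match="exactly two"):
            MicrosatGenotypes(["a"], ["L"], np.array([[[5, -1]]]))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MicrosatGenotypes(["a"], ["L"], np.array([[[0, 5]]]))


class TestPopulationMap:
    def test_read_write_round_trip(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("individual\tpopulation\tgroup\n"
                     "i1\tp1\tG1\ni2\tp1\tG1\ni3\tp2\tG2\n")
        pmap = read_population_map(p)
        assert pmap.groups == ["G1", "G2"]
        q = tmp_path / "m2.tsv"
        write_population_map(pmap, q)
        pmap2 = read_population_map(q)
        assert pmap2.individual_to_population == pmap.individual_to_population
        assert pmap2.population_to_group == pmap.population_to_group

    def test_duplicate_individual(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("individual\tpopulation\tgroup\ni1\tp1\tG1\ni1\tp2\tG2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_population_map(p)

    def test_population_in_two_groups(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("individual\tpopulation\tgroup\ni1\tp1\tG1\ni2\tp1\tG2\n")
        with pytest.raises(ParseError, match="two groups"):
            read_population_map(p)

    def test_group_counts(self):
        pmap = PopulationMap({"a": "p1", "b": "p1", "c": "p2"},
                             {"p1": "G1", "p2": "G2"})
        assert pmap.group_counts(["a", "b", "c"]) == {"G1": 2, "G2": 1}


class TestAssemble:
    def _write_map(self, tmp_path, rows):
        p = tmp_path / "m.tsv"
        p.write_text("individual\tpopulation\tgroup\n"
                     + "".join(f"{i}\t{pp}\t{g}\n" for i, pp, g in rows))
        return p

    def test_ok(self, tmp_path):
        aln = SequenceAlignment(["i1", "i2"], np.array([["A"], ["C"]]))
        mp = self._write_map(tmp_path, [("i1", "p1", "G1"), ("i2", "p2", "G2")])
        ds = assemble_dataset(aln, None, mp)
        assert ds.groups == ["G1", "G2"]

    def test_unmapped_individual_named(self, tmp_path):
        aln = SequenceAlignment(["i1", "iX"], np.array([["A"], ["C"]]))
        mp = self._write_map(tmp_path, [("i1", "p1", "G1")])
        with pytest.raises(ValueError, match="iX"):
            assemble_dataset(aln, None, mp)

    def test_alignment_only_dataset(self, tmp_path):
        aln = SequenceAlignment(["i1", "i2"], np.array([["A"], ["C"]]))
        mp = self._write_map(tmp_path, [("i1", "p1", "G1"), ("i2", "p1", "G1")])
        ds = assemble_dataset(aln, None, mp)
        with pytest.raises(ValueError, match="microsatellite"):
            ds.require_genotypes()

    def test_no_marker_rejected(self):
        pmap = PopulationMap({"a": "p"}, {"p": "G"})
        with pytest.raises(ValueError, match="marker"):
            MultilocusDataset(popmap=pmap)
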