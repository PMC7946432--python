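"""Edit calling: thresholds, control comparison, replicate intersection, I/O."""

import numpy as np
import pandas as pd
import pytest

from editscope.editcall import (
    EditCallConfig,
    call_edits,
    intersect_replicates,
    pileup_from_alignments,
    read_bedgraph,
    write_bedgraph,
)
from editscope.refmodel import GeneModelIndex, GenomeSeq, TranscriptModel


def _row(pos, nA=0, nC=0, nG=0, nT=0, strand="+", ref=None, contig="chr1", sample="s"):
    if ref is None:
        ref = "A" if strand == "+" else "T"
    return dict(contig=contig, pos0=pos, ref=ref, strand=strand,
                nA=nA, nC=nC, nG=nG, nT=nT, sample_id=sample)


def _df(rows):
    return pd.DataFrame(rows)


STRICT = EditCallConfig(ctrl_max_alt_frac=0.0)


class TestCallEdits:
    def test_inclusive_threshold_boundary_called(self):
        exp = _df([_row(10, nA=34, nG=6)])  # cov 40, frac 0.15
        ctrl = _df([_row(10, nA=30)])
        res = call_edits(exp, ctrl, STRICT)
        assert len(res.sites) == 1
        assert res.sites.iloc[0]["edit_fraction"] == pytest.approx(0.15)

    def test_coverage_below_20_rejected(self):
        exp = _df([_row(10, nA=13, nG=6)])  # cov 19, frac 0.316
        ctrl = _df([_row(10, nA=30)])
        assert len(call_edits(exp, ctrl, STRICT).sites) == 0

    def test_fraction_below_15pct_rejected(self):
        exp = _df([_row(10, nA=90, nG=10)])  # frac 0.10
        ctrl = _df([_row(10, nA=30)])
        assert len(call_edits(exp, ctrl, STRICT).sites) == 0

    def test_minus_strand_uses_c_reads_on_genomic_t(self):
        exp = _df([_row(10, nT=16, nC=4, strand="-")])  # frac 0.2 of cov 20
        ctrl = _df([_row(10, nT=25, strand="-")])
        res = call_edits(exp, ctrl, STRICT)
        assert len(res.sites) == 1
        assert res.sites.iloc[0]["edit_fraction"] == pytest.approx(0.2)

    def test_missing_or_undercovered_control_excluded_and_tallied(self):
        exp = _df([_row(10, nA=30, nG=10), _row(20, nA=30, nG=10)])
        ctrl = _df([_row(20, nA=10)])  # pos 10 absent; pos 20 control cov 10 < 20
        res = call_edits(exp, ctrl, STRICT)
        assert len(res.sites) == 0
        assert res.n_no_control == 2 and res.n_exp_pass == 2

    def test_edited_control_excluded(self):
        exp = _df([_row(10, nA=30, nG=10)])
        ctrl = _df([_row(10, nA=25, nG=5)])
        res = call_edits(exp, ctrl, STRICT)
        assert len(res.sites) == 0 and res.n_control_edited == 1

    def test_matches_brute_force_oracle_on_random_table(self):
        rng = np.random.default_rng(17)
        n = 2000
        rows_e, rows_c = [], []
        for i in range(n):
            strand = "+" if rng.random() < 0.5 else "-"
            cov = int(rng.integers(0, 60))
            ed = int(rng.binomial(cov, rng.choice([0.0, 0.1, 0.15, 0.3])))
            ref_n = cov - ed
            kw = {"nA": ref_n, "nG": ed} if strand == "+" else {"nT": ref_n, "nC": ed}
            rows_e.append(_row(i, strand=strand, **kw))
            if rng.random() < 0.9:  # some sites lack control
                ccov = int(rng.integers(0, 60))
                ced = int(rng.binomial(ccov, rng.choice([0.0, 0.0, 0.05])))
                ckw = {"nA": ccov - ced, "nG": ced} if strand == "+" else {"nT": ccov - ced, "nC": ced}
                rows_c.append(_row(i, strand=strand, **ckw))
        exp, ctrl = _df(rows_e), _df(rows_c)
        cfg = EditCallConfig()
        got = call_edits(exp, ctrl, cfg).sites
        # independent row-by-row reference
        cidx = {(r["contig"], r["pos0"], r["strand"]): r for r in rows_c}
        expected = []
        for r in rows_e:
            cov = r["nA"] + r["nC"] + r["nG"] + r["nT"]
            ed = r["nG"] if r["strand"] == "+" else r["nC"]
            if cov < cfg.min_coverage or ed / cov < cfg.min_edit_frac:
                continue
            c = cidx.get((r["contig"], r["pos0"], r["strand"]))
            if c is None:
                continue
            ccov = c["nA"] + c["nC"] + c["nG"] + c["nT"]
            ced = c["nG"] if c["strand"] == "+" else c["nC"]
            if ccov < cfg.ctrl_min_coverage or ced / ccov > cfg.ctrl_max_alt_frac:
                continue
            expected.append((r["contig"], r["pos0"], r["strand"], cov, ed / cov))
        got_set = {(r.contig, r.pos0, r.strand, r.coverage, r.edit_fraction) for r in got.itertuples()}
        assert got_set == set(expected)

    def test_strand_mirror_equivalence(self):
        """A minus-strand dataset and its plus-strand mirror give equal fractions."""
        minus_e = _df([_row(i, nT=30, nC=10, strand="-") for i in range(5)])
        minus_c = _df([_row(i, nT=30, strand="-") for i in range(5)])
        plus_e = _df([_row(i, nA=30, nG=10, strand="+") for i in range(5)])
        plus_c = _df([_row(i, nA=30, strand="+") for i in range(5)])
        f1 = call_edits(minus_e, minus_c, STRICT).sites["edit_fraction"]
        f2 = call_edits(plus_e, plus_c, STRICT).sites["edit_fraction"]
        assert (f1.to_numpy() == f2.to_numpy()).all()


class TestIntersectReplicates:
    def _sites(self, positions):
        return pd.DataFrame(
            {
                "contig": "c", "pos0": list(positions), "strand": "+",
                "coverage": 30, "edit_fraction": 0.3, "sample_id": "r",
            }
        )

    def test_set_intersection_semantics(self):
        out = intersect_replicates([self._sites([1, 2, 3]), self._sites([2, 3, 4])])
        assert out["pos0"].tolist() == [2, 3]

    def test_disjoint_sets_yield_empty_success(self, caplog):
        with caplog.at_level("WARNING"):
            out = intersect_replicates([self._sites([1]), self._sites([2])])
        assert out.empty and "common" in caplog.text

    def test_three_replicates(self):
        out = intersect_replicates([self._sites([1, 2]), self._sites([1, 2]), self._sites([2])])
        assert out["pos0"].tolist() == [2]
        assert {"frac_rep1", "frac_rep2", "frac_rep3"} <= set(out.columns)

    def test_single_set_errors(self):
        with pytest.raises(ValueError, match="replication required"):
            intersect_replicates([self._sites([1])])

    def test_output_subset_of_each_input(self, called_edits, default_sim):
        cfg, genome, models, truth, pileups = default_sim
        from editscope.editcall import call_edits as ce

        reps = [ce(pileups[f"rep{i+1}"], pileups["control"], EditCallConfig()).sites for i in range(2)]
        common_keys = set(map(tuple, called_edits[["contig", "pos0", "strand"]].to_numpy()))
        for r in reps:
            assert common_keys <= set(map(tuple, r[["contig", "pos0", "strand"]].to_numpy()))


class TestBedgraph:
    def test_formatting_example(self, tmp_path):
        sites = pd.DataFrame({"contig": ["chr1"], "pos0": [999], "strand": ["+"],
                              "coverage": [40], "edit_fraction": [0.25], "sample_id": ["s"]})
        p = tmp_path / "e.bedgraph"
        write_bedgraph(sites, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("#")
        assert lines[1] == "chr1\t999\t1000\t25.00"

    def test_empty_set_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        write_bedgraph(pd.DataFrame(columns=["contig", "pos0", "edit_fraction"]), p)
        assert p.read_text().startswith("#")
        assert read_bedgraph(p).empty

    def test_round_trip_of_random_sites(self, tmp_path):
        rng = np.random.default_rng(3)
        n = 100
        sites = pd.DataFrame(
            {
                "contig": [f"c{i % 3}" for i in range(n)],
                "pos0": rng.integers(0, 10000, n),
                "edit_fraction": rng.integers(1500, 10000, n) / 10000.0,
            }
        )
        # quantize to the 2-decimal percent resolution the format carries
        sites["edit_fraction"] = (sites["edit_fraction"] * 10000).round() / 10000
        p = tmp_path / "rt.bedgraph"
        write_bedgraph(sites, p)
        back = read_bedgraph(p)
        got = sorted(zip(back["contig"], back["pos0"], back["edit_fraction"].round(4)))
        want = sorted(zip(sites["contig"], sites["pos0"], sites["edit_fraction"].round(4)))
        assert got == want

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t10\t11\t25.00\nchr1\tten\televen\tx\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bedgraph(p)


class TestPileupFromAlignments:
    @pytest.fixture
    def tiny_alignment(self, tmp_path):
        # one + gene (A at pos 5) and one - gene (T at pos 45) on a 60 nt contig
        seq = list("CCCCC" + "A" + "CCCC" * 5 + "CCCC")
        seq = "".join(seq).ljust(60, "C")
        seq = seq[:45] + "T" + seq[46:]
        genome = GenomeSeq({"c": seq})
        models = [
            TranscriptModel("tp", "gp", "c", "+", [(0, 30)]),
            TranscriptModel("tm", "gm", "c", "-", [(30, 60)]),
        ]
        index = GeneModelIndex(models)
        sam = tmp_path / "t.sam"
        reads = []
        for i in range(10):  # + gene reads: 8 match, 2 G at pos 5
            bases = list(seq[0:20])
            if i < 2:
                bases[5] = "G"
            reads.append(f"p{i}\t0\tc\t1\t60\t20M\t*\t0\t0\t{''.join(bases)}\t{'I' * 20}")
        for i in range(10):  # - gene reads: 4 C at pos 45
            bases = list(seq[40:60])
            if i < 4:
                bases[5] = "C"
            reads.append(f"m{i}\t0\tc\t41\t60\t20M\t*\t0\t0\t{''.join(bases)}\t{'I' * 20}")
        # one low-base-quality read that must not be counted
        reads.append(f"lq\t0\tc\t1\t60\t20M\t*\t0\t0\t{'G' * 20}\t{'#' * 20}")
        sam.write_text("@SQ\tSN:c\tLN:60\n" + "\n".join(reads) + "\n")
        import pysam

        bam = tmp_path / "t.bam"
        pysam.sort("-o", str(bam), str(sam))
        pysam.index(str(bam))
        return bam, genome, index

    def test_counts_and_strand_convention(self, tiny_alignment):
        bam, genome, index = tiny_alignment
        df = pileup_from_alignments(bam, genome, index).set_index("pos0")
        assert df.loc[5, "nA"] == 8 and df.loc[5, "nG"] == 2
        assert df.loc[45, "nT"] == 6 and df.loc[45, "nC"] == 4
        # low-quality-only bases contribute nothing: the lq read is all-G
        assert df.loc[5, ["nA", "nC", "nG", "nT"]].sum() == 10

    def test_simulated_sam_round_trips_through_pileup(self, tmp_path):
        """The synthetic SAM emitter and the alignment-pileup path agree on
        planted edit fractions at well-covered sites."""
        import pysam

        from editscope.synthetic_data import SimConfig, simulate_reference, write_sam

        cfg = SimConfig(seed=3, n_genes=6, n_target_genes=2, intron_prob=0.0)
        genome, models, truth = simulate_reference(cfg)
        sam, bam = tmp_path / "x.sam", tmp_path / "x.bam"
        write_sam(sam, genome, models, truth, depth=30, read_len=50)
        pysam.sort("-o", str(bam), str(sam))
        pysam.index(str(bam))
        df = pileup_from_alignments(bam, genome, GeneModelIndex(models)).set_index(["contig", "pos0"])
        checked = 0
        for e in truth.edits:
            r = df.loc[(e.contig, e.pos0)]
            cov = r[["nA", "nC", "nG", "nT"]].sum()
            if cov < 20:
                continue  # tiling depth drops at exon edges
            edited = r["nG"] if e.strand == "+" else r["nC"]
            assert abs(edited / cov - e.true_fraction) < 0.1
            checked += 1
        assert checked >= 4

    def test_unindexed_input_errors(self, tmp_path, tiny_alignment):
        _, genome, index = tiny_alignment
        import pysam

        sam = tmp_path / "u.bam"
        with pysam.AlignmentFile(sam, "wb", reference_names=["c"], reference_lengths=[60]):
            pass
        with pytest.raises(ValueError, match="index"):
            pileup_from_alignments(sam, genome, index)
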