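import numpy as np
import pytest

from bsalign3.align import AlignmentResult, EditScript
from bsalign3.genome import Genome, revcomp
from bsalign3.index import GenomicLocus
from bsalign3.methylation import (
    MethTable,
    call_methylation,
    cytosine_context,
    read_cgmap,
    write_cgmap,
)
from bsalign3.postprocess import emit_sam, recount_mismatches
from bsalign3.read_prep import BisRead

from conftest import make_random_genome


class TestCytosineContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 1, "+", ("CG", "CG")),
            ("ACAGT", 1, "+", ("CHG", "CA")),
            ("ACAAT", 1, "+", ("CHH", "CA")),
            ("ACGT", 2, "-", ("CG", "CG")),  # Watson G = Crick C; next Crick base = comp(Watson[1])
            ("ACNGT", 1, "+", ("NA", "CN")),
            ("TTC", 2, "+", ("NA", "CN")),  # runs off the chromosome end
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        g = Genome(["c"], {"c": seq})
        assert cytosine_context(g, "c", pos, strand) == expected

    def test_non_cytosine_rejected(self):
        g = Genome(["c"], {"c": "ACGT"})
        with pytest.raises(ValueError, match="cytosine"):
            cytosine_context(g, "c", 0, "+")

    def test_context_partition_and_cg_palindrome(self):
        """Every non-N cytosine gets exactly one context; '+' and '-' CG
        site counts are equal (CG dinucleotides are palindromic)."""
        genome = make_random_genome(2000, seed=3)
        seq = genome.chrom_seqs["chr1"]
        counts = {"+": {"CG": 0, "CHG": 0, "CHH": 0, "NA": 0},
                  "-": {"CG": 0, "CHG": 0, "CHH": 0, "NA": 0}}
        n_cyt = 0
        for pos, base in enumerate(seq):
            for strand, cbase in (("+", "C"), ("-", "G")):
                if base != cbase:
                    continue
                n_cyt += 1
                ctx, _ = cytosine_context(genome, "chr1", pos, strand)
                counts[strand][ctx] += 1
        assert sum(counts["+"].values()) + sum(counts["-"].values()) == n_cyt
        assert counts["+"]["CG"] == counts["-"]["CG"]


def _write_sam(tmp_path, genome, entries):
    """entries: list of (read_id, read_seq, pos, strand) on the first chromosome."""
    chrom = genome.chrom_names[0]
    records = []
    for rid, seq, pos, strand in entries:
        read = BisRead(rid, seq, "I" * len(seq))
        script = EditScript([("M", len(seq))])
        aln = AlignmentResult(
            status="unique",
            locus=GenomicLocus(chrom, pos, strand),
            edit_distance=0,
            script=script,
            aln_len=len(seq),
        )
        rep = recount_mismatches(aln, seq, genome, 10, rid)
        records.append((read, aln, rep))
    path = tmp_path / "calls.sam"
    emit_sam(records, genome, path)
    return path


class TestCallMethylation:
    def test_retained_c_is_methylated(self, tmp_path):
        g = Genome(["c"], {"c": "ACGT"})
        sam = _write_sam(tmp_path, g, [("r1", "ACGT", 0, "+")])
        table = call_methylation(sam, g)
        site = table.get("c", 1, "+")
        assert (site.meth_count, site.total_count) == (1, 1)
        assert site.context == "CG" and site.level == 1.0

    def test_converted_c_is_unmethylated(self, tmp_path):
        g = Genome(["c"], {"c": "ACGT"})
        sam = _write_sam(tmp_path, g, [("r1", "ATGT", 0, "+")])
        site = call_methylation(sam, g).get("c", 1, "+")
        assert (site.meth_count, site.total_count) == (0, 1) and site.level == 0.0

    def test_counts_accumulate_across_reads(self, tmp_path):
        g = Genome(["c"], {"c": "ACGT"})
        sam = _write_sam(tmp_path, g, [("r1", "ACGT", 0, "+"), ("r2", "ATGT", 0, "+")])
        site = call_methylation(sam, g).get("c", 1, "+")
        assert (site.meth_count, site.total_count) == (1, 2) and site.level == 0.5

    def test_crick_read_calls_crick_site(self, tmp_path):
        # Watson ACGT; Crick origin read revcomp = ACGT; Crick C at Watson pos 2
        g = Genome(["c"], {"c": "ACGT"})
        sam = _write_sam(tmp_path, g, [("r1", "ACGT", 0, "-")])
        site = call_methylation(sam, g).get("c", 2, "-")
        assert (site.meth_count, site.total_count) == (1, 1)
        assert site.context == "CG"

    def test_uncovered_sites_absent(self, tmp_path):
        g = Genome(["c"], {"c": "ACGTAACGTT"})
        sam = _write_sam(tmp_path, g, [("r1", "ACGT", 0, "+")])
        table = call_methylation(sam, g)
        assert table.get("c", 7, "+") is None
        assert len(table) >= 1

    def test_total_counts_match_bruteforce_pileup(self, tmp_path):
        """Conservation: table totals equal a brute-force pileup oracle."""
        genome = make_random_genome(500, seed=8)
        rng = np.random.default_rng(9)
        entries = []
        for i in range(60):
            pos = int(rng.integers(0, 470))
            strand = "+" if rng.random() < 0.5 else "-"
            seg = genome.chrom_seqs["chr1"][pos : pos + 30]
            seq = seg if strand == "+" else revcomp(seg)
            # convert a random half of the origin-strand Cs
            seq = "".join(
                "T" if b == "C" and rng.random() < 0.5 else b for b in seq
            )
            entries.append((f"r{i}", seq, pos, strand))
        g = Genome(["c"], {"c": genome.chrom_seqs["chr1"]})
        sam = _write_sam(tmp_path, g, entries)
        table = call_methylation(sam, g)

        expected = 0
        for rid, seq, pos, strand in entries:
            ref = g.chrom_seqs["c"][pos : pos + 30]
            ref_origin = ref if strand == "+" else revcomp(ref)
            for rb, gb in zip(seq, ref_origin):
                if gb == "C" and rb in "CT":
                    expected += 1
        assert int(table.df.total.sum()) == expected


class TestCGmapIO:
    def test_row_format(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 1, "strand": "+", "context": "CG",
                 "dinucleotide": "CG", "meth": 1, "total": 2},
                {"chrom": "chr1", "pos": 5, "strand": "-", "context": "CHH",
                 "dinucleotide": "CA", "meth": 0, "total": 3},
                {"chrom": "chr1", "pos": 9, "strand": "+", "context": "NA",
                 "dinucleotide": "CN", "meth": 1, "total": 1},
            ]
        )
        table = MethTable(df, {"chr1": 20})
        path = tmp_path / "x.CGmap"
        write_cgmap(table, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "chr1\tC\t2\tCG\tCG\t0.50\t1\t2"
        assert lines[1].split("\t")[1] == "G"  # '-' strand site
        assert len(lines) == 2  # NA-context site dropped

    def test_empty_table_gives_empty_file(self, tmp_path):
        import pandas as pd

        table = MethTable(pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "dinucleotide", "meth", "total"]))
        path = tmp_path / "empty.CGmap"
        write_cgmap(table, path)
        assert path.read_text() == ""

    def test_roundtrip(self, tmp_path):
        g = Genome(["c"], {"c": "ACGTACGT"})
        sam = _write_sam(tmp_path, g, [("r1", "ACGTATGT", 0, "+")])
        table = call_methylation(sam, g)
        path = tmp_path / "rt.CGmap"
        write_cgmap(table, path)
        back = read_cgmap(path, g.chrom_lengths)
        cols = ["chrom", "pos", "strand", "context", "dinucleotide", "meth", "total"]
        a = table.df[table.df.context != "NA"][cols].reset_index(drop=True)
        b = back.df[cols].astype(a.dtypes.to_dict()).reset_index(drop=True)
        assert a.equals(b)
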