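import numpy as np
import pytest

from bsalign3.genome import revcomp
from bsalign3.index import bisulfite_convert
from bsalign3.simulate import (
    random_genome,
    read_truth,
    simulate_methylome,
    simulate_reads,
    write_truth,
)


@pytest.fixture(scope="module")
def genome():
    return random_genome({"chr1": 100_000}, seed=31)


class TestMethylome:
    def test_extreme_probabilities(self, genome):
        none = simulate_methylome(genome, 0, 0, 0, seed=1)
        full = simulate_methylome(genome, 1, 1, 1, seed=1)
        codes = genome.codes("chr1")
        c_pos = codes == 1
        g_pos = codes == 2
        assert not none.plus["chr1"].any() and not none.minus["chr1"].any()
        # with p=1 every classifiable cytosine is methylated
        for ctx in ("CG", "CHG", "CHH"):
            assert full.fraction_methylated(genome, ctx) == 1.0
        # states only defined on cytosines
        assert not full.plus["chr1"][~c_pos].any()
        assert full.minus["chr1"][g_pos].sum() > 0

    def test_cg_fraction_within_binomial_error(self, genome):
        meth = simulate_methylome(genome, 0.5, 0.2, 0.1, seed=2)
        frac = meth.fraction_methylated(genome, "CG")
        n_cg = 2 * genome.chrom_seqs["chr1"].count("CG")
        se = np.sqrt(0.25 / n_cg)
        assert abs(frac - 0.5) <= 3 * se

    def test_clear_chrom_for_spike_in(self, genome):
        meth = simulate_methylome(genome, 0.9, 0.9, 0.9, seed=3)
        meth.clear_chrom("chr1")
        assert not meth.plus["chr1"].any()


class TestSimulateReads:
    def test_noise_free_reads_equal_converted_origin(self, genome):
        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        recs, truth = simulate_reads(
            genome, meth, 50, 80, sub_rate=0, indel_rate=0, conversion_rate=1.0,
            directional=True, seed=5,
        )
        for rid, seq, _ in recs:
            t = truth[rid]
            seg = genome.chrom_seqs[t.chrom][t.pos : t.pos + 80]
            origin = seg if t.strand == "+" else revcomp(seg)
            assert seq == bisulfite_convert(origin, "C2T")
            assert t.n_subs == 0 and t.n_indels == 0

    def test_no_conversion_keeps_original_cytosines(self, genome):
        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        recs, truth = simulate_reads(
            genome, meth, 30, 80, sub_rate=0, indel_rate=0, conversion_rate=0.0,
            directional=True, seed=6,
        )
        for rid, seq, _ in recs:
            t = truth[rid]
            seg = genome.chrom_seqs[t.chrom][t.pos : t.pos + 80]
            assert seq == (seg if t.strand == "+" else revcomp(seg))

    def test_indel_count_matches_binomial_expectation(self, genome):
        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        n, L, rate = 2000, 100, 0.025
        _, truth = simulate_reads(
            genome, meth, n, L, sub_rate=0, indel_rate=rate, conversion_rate=1.0,
            directional=True, seed=7,
        )
        mean_indels = np.mean([t.n_indels for t in truth.values()])
        se = np.sqrt(L * rate * (1 - rate) / n)
        assert abs(mean_indels - L * rate) <= 3 * se

    def test_seed_determinism_byte_identical(self, genome, tmp_path):
        meth = simulate_methylome(genome, 0.5, 0.2, 0.05, seed=4)
        paths = []
        for tag in ("a", "b"):
            fq = tmp_path / f"{tag}.fq"
            tr = tmp_path / f"{tag}.tsv"
            simulate_reads(genome, meth, 200, 100, 0.01, 0.01, 0.99, True, 99,
                           fastq_path=fq, truth_path=tr)
            paths.append((fq, tr))
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()

    def test_invalid_parameters_rejected(self, genome):
        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        with pytest.raises(ValueError):
            simulate_reads(genome, meth, 0, 50)
        with pytest.raises(ValueError):
            simulate_reads(genome, meth, 10, 50, sub_rate=1.5)

    def test_truth_roundtrip(self, genome, tmp_path):
        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        _, truth = simulate_reads(genome, meth, 20, 60, seed=8)
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        assert read_truth(path) == truth


class TestEvaluateMapping:
    def _sam_for(self, tmp_path, genome, truth, mutate=None):
        import pysam

        from bsalign3.postprocess import sam_header

        header = sam_header(genome)
        path = tmp_path / "eval.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for rid, t in truth.items():
                rec = pysam.AlignedSegment(header)
                rec.query_name = rid
                rec.query_sequence = "A" * 10
                chrom, pos, strand, unmapped = t.chrom, t.pos, t.strand, False
                if mutate:
                    chrom, pos, strand, unmapped = mutate(t)
                if unmapped:
                    rec.flag = 4
                else:
                    rec.flag = 16 if strand == "-" else 0
                    rec.reference_id = header.get_tid(chrom)
                    rec.reference_start = pos
                    rec.cigarstring = "10M"
                out.write(rec)
        return path

    def test_all_exact_is_fully_correct(self, genome, tmp_path):
        from bsalign3.simulate import evaluate_mapping, simulate_methylome

        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        _, truth = simulate_reads(genome, meth, 25, 60, seed=9)
        sam = self._sam_for(tmp_path, genome, truth)
        rep = evaluate_mapping(sam, truth, 5)
        assert rep.n_reads == rep.n_mapped == rep.n_correct == 25
        assert rep.pct_correct == 1.0 and rep.mapability == 1.0

    def test_all_unmapped(self, genome, tmp_path):
        from bsalign3.simulate import evaluate_mapping

        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        _, truth = simulate_reads(genome, meth, 10, 60, seed=10)
        sam = self._sam_for(tmp_path, genome, truth,
                            mutate=lambda t: (t.chrom, t.pos, t.strand, True))
        rep = evaluate_mapping(sam, truth, 5)
        assert rep.mapability == 0 and rep.pct_correct == 0

    def test_wrong_strand_is_mapped_but_incorrect(self, genome, tmp_path):
        from bsalign3.simulate import evaluate_mapping

        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        _, truth = simulate_reads(genome, meth, 10, 60, seed=11)
        flip = {"+": "-", "-": "+"}
        sam = self._sam_for(tmp_path, genome, truth,
                            mutate=lambda t: (t.chrom, t.pos, flip[t.strand], False))
        rep = evaluate_mapping(sam, truth, 5)
        assert rep.n_mapped == 10 and rep.n_correct == 0

    def test_contaminated_sam_rejected(self, genome, tmp_path):
        from bsalign3.simulate import evaluate_mapping

        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        _, truth = simulate_reads(genome, meth, 5, 60, seed=12)
        sam = self._sam_for(tmp_path, genome, truth)
        (leftover,) = [k for k in list(truth) if k.endswith("0000000")]
        del truth[leftover]
        with pytest.raises(ValueError, match="absent from truth"):
            evaluate_mapping(sam, truth, 5)

    def test_position_tolerance(self, genome, tmp_path):
        from bsalign3.simulate import evaluate_mapping

        meth = simulate_methylome(genome, 0, 0, 0, seed=4)
        _, truth = simulate_reads(genome, meth, 10, 60, seed=13)
        sam = self._sam_for(tmp_path, genome, truth,
                            mutate=lambda t: (t.chrom, t.pos + 5, t.strand, False))
        assert evaluate_mapping(sam, truth, 5).n_correct == 10
        assert evaluate_mapping(sam, truth, 4).n_correct == 0
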