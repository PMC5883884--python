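import numpy as np
import pandas as pd
import pytest

from bsalign3.methylation import MethTable
from bsalign3.qc import (
    conversion_efficiency,
    genome_windows,
    metaplot,
    mismatch_by_position,
    read_features,
)


def table_from_rows(rows, chrom_lengths):
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "dinucleotide", "meth", "total"]
    )
    return MethTable(df, chrom_lengths)


class TestMismatchByPosition:
    def _sam(self, tmp_path, genome, entries):
        from test_methylation import _write_sam

        return _write_sam(tmp_path, genome, entries)

    def test_perfect_reads_give_zero_rates(self, tmp_path, small_genome):
        seq = small_genome.chrom_seqs["chr1"]
        entries = [(f"r{i}", seq[i * 40 : i * 40 + 30], i * 40, "+") for i in range(10)]
        sam = self._sam(tmp_path, small_genome, entries)
        profile = mismatch_by_position(sam, small_genome)
        assert profile.coverage.size == 30
        assert (profile.coverage == 10).all()
        assert (profile.mismatches == 0).all()

    def test_single_substitution_counted_at_its_cycle(self, tmp_path, small_genome):
        seq = small_genome.chrom_seqs["chr1"]
        entries = [(f"r{i}", seq[i * 40 : i * 40 + 20], i * 40, "+") for i in range(10)]
        bad = list(seq[480:500])
        bad[2] = {"A": "G", "G": "A", "C": "A", "T": "G"}[bad[2]]
        entries.append(("bad", "".join(bad), 480, "+"))
        profile = mismatch_by_position(self._sam(tmp_path, small_genome, entries), small_genome)
        rates = profile.rates
        assert rates[2] == pytest.approx(1 / 11)
        assert rates[[0, 1]].sum() == 0 and rates[3:].sum() == 0

    def test_conversion_only_differences_are_not_mismatches(self, tmp_path, small_genome):
        seq = small_genome.chrom_seqs["chr1"]
        entries = [("conv", seq[100:140].replace("C", "T"), 100, "+")]
        from bsalign3.genome import revcomp

        entries.append(("convm", revcomp(seq[200:240]).replace("C", "T"), 200, "-"))
        profile = mismatch_by_position(self._sam(tmp_path, small_genome, entries), small_genome)
        assert profile.mismatches.sum() == 0
        assert (profile.coverage[:40] == 2).all()


class TestConversionEfficiency:
    def test_arithmetic(self):
        rows = [("lambda", 10 * i, "+", "CHH", "CA", m, t)
                for i, (m, t) in enumerate([(2, 40), (3, 60)])]
        table = table_from_rows(rows, {"lambda": 1000})
        stats = conversion_efficiency(table, "lambda")
        assert stats.converted == 95 and stats.unconverted == 5
        assert stats.efficiency == pytest.approx(0.95)

    def test_perfect_conversion(self):
        table = table_from_rows([("lambda", 5, "+", "CG", "CG", 0, 50)], {"lambda": 100})
        assert conversion_efficiency(table, "lambda").efficiency == 1.0

    def test_no_coverage_is_an_error(self):
        table = table_from_rows([("chr1", 5, "+", "CG", "CG", 1, 2)], {"chr1": 100})
        with pytest.raises(ValueError, match="no spike-in coverage"):
            conversion_efficiency(table, "lambda")

    def test_ch_only_restricts_contexts(self):
        rows = [("lambda", 1, "+", "CG", "CG", 10, 10),
                ("lambda", 5, "+", "CHH", "CA", 0, 10)]
        table = table_from_rows(rows, {"lambda": 100})
        assert conversion_efficiency(table, "lambda", ch_only=True).efficiency == 1.0
        assert conversion_efficiency(table, "lambda").efficiency == pytest.approx(0.5)


class TestGenomeWindows:
    def test_single_site_window_level(self):
        table = table_from_rows([("c", 3, "+", "CG", "CG", 1, 2)], {"c": 100})
        win = genome_windows(table, 10)["c"]
        assert win.loc[0, "CG"] == pytest.approx(0.5)
        assert np.isnan(win.loc[10, "CG"])

    def test_empty_chromosome_all_missing(self):
        table = table_from_rows([("c", 3, "+", "CG", "CG", 1, 2)], {"c": 50, "empty": 30})
        win = genome_windows(table, 10)["empty"]
        assert win.isna().all().all()

    def test_count_weighted_not_mean_of_levels(self):
        rows = [("c", 1, "+", "CG", "CG", 1, 1), ("c", 3, "+", "CG", "CG", 0, 1)]
        win = genome_windows(table_from_rows(rows, {"c": 10}), 10)["c"]
        assert win.loc[0, "CG"] == pytest.approx(0.5)

    def test_chromosome_sized_window_reproduces_pooled_level(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(50):
            t = int(rng.integers(1, 6))
            rows.append(("c", 2 * i, "+", "CG", "CG", int(rng.integers(0, t + 1)), t))
        table = table_from_rows(rows, {"c": 200})
        win = genome_windows(table, 200)["c"]
        assert win.loc[0, "CG"] == pytest.approx(table.pooled_level("CG"))


class TestMetaplot:
    def _uniform_table(self, level_num=1, level_den=2):
        rows = [("c", p, "+", "CG", "CG", level_num, level_den) for p in range(0, 5000, 7)]
        return table_from_rows(rows, {"c": 5000})

    def test_single_methylated_site_in_body(self):
        table = table_from_rows([("c", 550, "+", "CG", "CG", 3, 3)], {"c": 2000})
        prof = metaplot(table, [("c", 500, 600, "+")], body_bins=5, flank_bp=100, flank_bins=2)
        body = prof.levels["CG"][2:7]
        assert body[2] == 1.0  # site at body fraction 0.5
        assert np.isnan(np.delete(prof.levels["CG"], 4)).all()

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty feature set"):
            metaplot(self._uniform_table(), [])

    def test_strand_mirroring_reverses_profiles(self):
        table = table_from_rows(
            [("c", p, "+", "CG", "CG", (p // 7) % 2, 1) for p in range(0, 5000, 7)],
            {"c": 5000},
        )
        feats = [("c", 1000, 2200, "+"), ("c", 2500, 3100, "+")]
        flipped = [(c, s, e, "-") for c, s, e, _ in feats]
        a = metaplot(table, feats, 10, 200, 4)
        b = metaplot(table, flipped, 10, 200, 4)
        np.testing.assert_array_equal(a.levels["CG"], b.levels["CG"][::-1])

    def test_out_of_bounds_feature_skipped(self):
        prof = metaplot(
            self._uniform_table(),
            [("c", 1000, 2000, "+"), ("c", 4000, 9000, "+")],
            10, 200, 4,
        )
        assert prof.counts["CG"].sum() > 0

    def test_efficiency_complement_of_windows(self):
        """conversion_efficiency == 1 - chromosome-wide level on the spike."""
        rng = np.random.default_rng(11)
        rows = []
        for i in range(40):
            t = int(rng.integers(1, 8))
            ctx = ("CG", "CHG", "CHH")[i % 3]
            rows.append(("lambda", 5 * i, "+", ctx, "CG", int(rng.integers(0, t + 1)), t))
        table = table_from_rows(rows, {"lambda": 300})
        eff = conversion_efficiency(table, "lambda").efficiency
        level = table.df.meth.sum() / table.df.total.sum()
        assert eff == pytest.approx(1 - level)


class TestReadFeatures:
    def test_bed6_and_gff3_agree(self, tmp_path):
        bed = tmp_path / "f.bed"
        bed.write_text("chr1\t100\t200\tgeneA\t0\t+\nchr1\t400\t500\tgeneB\t0\t-\n")
        gff = tmp_path / "f.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
            "chr1\tsrc\tgene\t401\t500\t.\t-\t.\tID=geneB\n"
        )
        assert read_features(bed) == read_features(gff) == [
            ("chr1", 100, 200, "+"),
            ("chr1", 400, 500, "-"),
        ]
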