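from itertools import combinations

import numpy as np
import pytest

from cifi.contacts import (
    ContactPair,
    MonomerAlignment,
    _Candidate,
    cis_fraction,
    dedup_pairs,
    expand_all,
    expand_pairs,
    ingest_alignments,
    pair_stats,
    parse_segment_name,
    read_pairs,
    sort_pairs,
    write_pairs,
)


def mono(read_id="r", ordinal=0, chrom="chr1", start=0, end=None, strand="+", mapq=60):
    return MonomerAlignment(
        read_id, ordinal, chrom, start, start + 100 if end is None else end, strand, mapq
    )


class TestParseSegmentName:
    def test_basic(self):
        assert parse_segment_name("r1:0:0:100") == ("r1", 0, 0, 100)

    def test_colons_in_read_id(self):
        assert parse_segment_name("m64:12/4:3:10:20") == ("m64:12/4", 3, 10, 20)

    def test_malformed(self):
        with pytest.raises(ValueError, match="does not match"):
            parse_segment_name("r1_0_0")
        with pytest.raises(ValueError):
            parse_segment_name("r1:a:b:c")


class TestIngest:
    def test_primary_beats_secondary(self):
        cands = [
            (("r", 0), _Candidate("chr1", 0, 50, "+", 0, primary=False)),
            (("r", 0), _Candidate("chr2", 0, 50, "+", 60, primary=True)),
        ]
        monomers, _ = ingest_alignments(cands, mapq_min=0)
        assert monomers[0].chrom == "chr2"

    def test_primary_wins_even_at_lower_mapq(self):
        cands = [
            (("r", 0), _Candidate("chr1", 0, 50, "+", 60, primary=False)),
            (("r", 0), _Candidate("chr2", 0, 50, "+", 10, primary=True)),
        ]
        monomers, _ = ingest_alignments(cands, mapq_min=0)
        assert monomers[0].chrom == "chr2"

    def test_subthreshold_dropped_and_counted(self):
        cands = [(("r", 0), _Candidate("chr1", 0, 50, "+", 0, primary=True))]
        monomers, stats = ingest_alignments(cands, mapq_min=1)
        assert monomers == []
        assert stats["segments_below_mapq"] == 1

    def test_tie_break_deterministic(self):
        # equal mapq and primary: longest span wins, then smallest (chrom, start)
        cands = [
            (("r", 0), _Candidate("chr1", 0, 40, "+", 30, primary=True)),
            (("r", 0), _Candidate("chr1", 100, 160, "+", 30, primary=True)),
        ]
        monomers, _ = ingest_alignments(cands, mapq_min=0)
        assert monomers[0].start == 100  # span 60 beats span 40

    def test_oracle_tsv_roundtrip(self, small_sim, tmp_path, small_monomers):
        _, readset = small_sim
        path = tmp_path / "oracle.tsv"
        readset.write_oracle_tsv(path)
        monomers, stats = ingest_alignments(path, mapq_min=0)
        assert stats["monomers_selected"] == len(readset.truth)
        got = {(m.read_id, m.ordinal): (m.chrom, m.start, m.end, m.strand) for m in monomers}
        want = {
            (m.read_id, m.ordinal): (m.chrom, m.start, m.end, m.strand)
            for m in small_monomers
        }
        assert got == want

    def test_bad_tsv_header(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="columns"):
            ingest_alignments(p)

    def test_unknown_chrom_errors(self):
        cands = [(("r", 0), _Candidate("chrX", 0, 50, "+", 60, primary=True))]
        with pytest.raises(ValueError, match="unknown reference"):
            ingest_alignments(cands, known_chroms=["chr1"])

    def test_bam_ingest(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1000}]}
        path = tmp_path / "segs.sam"
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for name, pos, mapq, flag in [
                ("r1:0:0:50", 10, 60, 0),
                ("r1:0:0:50", 500, 0, 256),  # secondary, never selected
                ("r1:1:50:90", 200, 60, 16),
            ]:
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = "A" * 40
                a.flag = flag
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = mapq
                a.cigarstring = "40M"
                out.write(a)
        monomers, stats = ingest_alignments(path, mapq_min=1)
        assert stats["monomers_selected"] == 2
        assert monomers[0].start == 10
        assert monomers[1].strand == "-"


class TestExpandPairs:
    def test_seventeen_monomers_gives_136(self):
        monomers = [mono(ordinal=i, start=i * 1000) for i in range(17)]
        assert len(expand_pairs(monomers)) == 136

    def test_two_monomers_one_pair(self):
        assert len(expand_pairs([mono(ordinal=0), mono(ordinal=1, start=500)])) == 1

    def test_four_monomers_six_pairs(self):
        monomers = [mono(ordinal=i, start=i * 10) for i in range(4)]
        assert len(expand_pairs(monomers)) == 6

    @pytest.mark.parametrize("n", range(0, 51, 7))
    def test_count_formula_vs_bruteforce(self, n):
        monomers = [mono(ordinal=i, start=i * 5) for i in range(n)]
        pairs = expand_pairs(monomers)
        assert len(pairs) == n * (n - 1) // 2
        assert len(pairs) == len(list(combinations(range(n), 2)))

    def test_mate_normalization(self):
        a = mono(ordinal=0, chrom="chr2", start=500)
        b = mono(ordinal=1, chrom="chr1", start=100)
        (p,) = expand_pairs([a, b], chrom_order=["chr1", "chr2"])
        assert (p.chrom1, p.pos1) == ("chr1", 100)
        assert (p.ordinal1, p.ordinal2) == (0, 1)

    def test_symmetry_under_input_order(self):
        a = mono(ordinal=0, chrom="chr1", start=900, strand="-")
        b = mono(ordinal=1, chrom="chr1", start=100)
        (p1,) = expand_pairs([a, b])
        (p2,) = expand_pairs([b, a])
        assert (p1.chrom1, p1.pos1, p1.strand1, p1.chrom2, p1.pos2, p1.strand2) == (
            p2.chrom1, p2.pos1, p2.strand1, p2.chrom2, p2.pos2, p2.strand2,
        )

    def test_pair_type(self):
        (p,) = expand_pairs([mono(ordinal=0), mono(ordinal=1, chrom="chr1", start=5)])
        assert p.pair_type == "cis"
        (q,) = expand_pairs(
            [mono(ordinal=0), mono(ordinal=1, chrom="chr2")], ["chr1", "chr2"]
        )
        assert q.pair_type == "trans"

    def test_mixed_reads_rejected(self):
        with pytest.raises(ValueError):
            expand_pairs([mono(read_id="a"), mono(read_id="b", ordinal=1)])

    def test_pair_count_conservation(self, small_sim, small_monomers):
        _, readset = small_sim
        order = list(small_sim[0].chrom_sizes)
        pairs = expand_all(small_monomers, order)
        sizes = readset.truth.groupby("read_id").size()
        expected = int((sizes * (sizes - 1) // 2).sum())
        assert len(pairs) == expected


class TestDedup:
    def _pair(self, read_id, pos1=100, pos2=500, strand2="+"):
        return ContactPair(read_id, "chr1", pos1, "+", "chr1", pos2, strand2, 0, 1)

    def test_identical_pairs_second_flagged(self):
        pairs = dedup_pairs([self._pair("a"), self._pair("b")])
        assert [p.duplicate for p in pairs] == [False, True]

    def test_strand_difference_not_flagged(self):
        pairs = dedup_pairs([self._pair("a"), self._pair("b", strand2="-")])
        assert [p.duplicate for p in pairs] == [False, False]

    def test_same_read_never_flagged(self):
        pairs = dedup_pairs([self._pair("a"), self._pair("a")])
        assert [p.duplicate for p in pairs] == [False, False]

    def test_unsorted_errors(self):
        with pytest.raises(ValueError, match="sorted"):
            dedup_pairs([self._pair("a", pos1=500, pos2=600), self._pair("b")])

    def test_injected_duplication_rate_recovered(self, small_sim):
        from cifi.simulate import inject_duplicates
        from tests.conftest import monomers_from_truth

        genome, readset = small_sim
        dup = inject_duplicates(readset, 0.05)
        order = list(genome.chrom_sizes)
        pairs = sort_pairs(expand_all(monomers_from_truth(dup.truth), order), order)
        pairs = dedup_pairs(pairs, order)
        flagged = sum(p.duplicate for p in pairs) / len(pairs)
        n_dup_reads = len(dup.reads) - len(readset.reads)
        injected = n_dup_reads / len(dup.reads)
        assert abs(flagged - injected) < 0.01


class TestPairsIO:
    def test_coordinate_shift(self, tmp_path):
        p = ContactPair("r", "chrA", 11, "+", "chrA", 51, "-", 0, 1)
        path = tmp_path / "x.pairs"
        write_pairs([p], {"chrA": 1000}, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == ["r\tchrA\t12\tchrA\t52\t+\t-"]

    def test_empty_header_only(self, tmp_path):
        path = tmp_path / "x.pairs"
        write_pairs([], {"chrA": 1000}, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "## pairs format v1.0"
        assert all(l.startswith("#") for l in lines)

    def test_unknown_chrom_errors(self, tmp_path):
        p = ContactPair("r", "chrZ", 1, "+", "chrZ", 2, "+", 0, 1)
        with pytest.raises(ValueError, match="unknown chromosome"):
            write_pairs([p], {"chrA": 1000}, tmp_path / "x.pairs")

    def test_roundtrip(self, small_sim, small_monomers, tmp_path):
        genome, _ = small_sim
        order = list(genome.chrom_sizes)
        pairs = sort_pairs(expand_all(small_monomers, order), order)
        path = tmp_path / "rt.pairs.gz"
        write_pairs(pairs, genome.chrom_sizes, path)
        back, sizes = read_pairs(path)
        assert sizes == genome.chrom_sizes
        orig = [(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2) for p in pairs]
        got = [(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2) for p in back]
        assert orig == got


class TestCisFraction:
    def _cis(self, read_id):
        return ContactPair(read_id, "chr1", 10, "+", "chr1", 20, "+", 0, 1, "cis")

    def _trans(self, read_id):
        return ContactPair(read_id, "chr1", 10, "+", "chr2", 20, "+", 0, 1, "trans")

    def test_all_cis(self):
        assert cis_fraction([self._cis("a"), self._cis("b")]) == 1.0

    def test_three_one(self):
        pairs = [self._cis(c) for c in "abc"] + [self._trans("d")]
        assert cis_fraction(pairs) == 0.75

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cis_fraction([])

    def test_trans_fraction_recovered(self):
        # Closed-form oracle: a read is anchor + (n-1) independent partners,
        # each trans w.p. f_t (uniform over the K-1 other chromosomes). So
        #   P(anchor-partner pair cis)   = 1 - f_t
        #   P(partner-partner pair cis)  = (1-f_t)^2 + f_t^2 / (K-1)
        # and the expected cis fraction is the pair-count-weighted mixture.
        from cifi.simulate import SimConfig, simulate_genome, simulate_reads
        from tests.conftest import monomers_from_truth

        f_t, K = 0.25, 3
        cfg = SimConfig(
            seed=5, chrom_lengths=(300_000, 300_000, 300_000), n_reads=1500,
            segments_median=2, trans_fraction=f_t, min_cis_dist=500,
        )
        genome = simulate_genome(cfg)
        readset = simulate_reads(genome, cfg)
        order = list(genome.chrom_sizes)
        pairs = expand_all(monomers_from_truth(readset.truth), order)

        p_ap = 1 - f_t
        p_pp = (1 - f_t) ** 2 + f_t**2 / (K - 1)
        sizes = readset.truth.groupby("read_id").size()
        n_ap = int((sizes - 1).sum())
        n_pp = int(((sizes - 1) * (sizes - 2) // 2).sum())
        assert n_ap + n_pp == len(pairs)
        expected = (n_ap * p_ap + n_pp * p_pp) / (n_ap + n_pp)

        frac = cis_fraction(pairs)
        sigma = np.sqrt(expected * (1 - expected) / len(pairs))
        assert abs(frac - expected) < 3 * sigma + 0.02

    def test_pair_stats_counters(self):
        pairs = dedup_pairs([self._cis("a"), self._cis("b")]) + [self._trans("c")]
        stats = pair_stats(pairs)
        assert stats["pairs_total"] == 3
        assert stats["pairs_duplicate"] == 1
        assert stats["pairs_nodup"] == 2


def test_end_to_end_distance_matches_truth(small_sim, small_monomers):
    """Cis pair distances equal fragment-start distances from the truth table."""
    genome, readset = small_sim
    order = list(genome.chrom_sizes)
    pairs = expand_all(small_monomers, order)
    truth = readset.truth.set_index(["read_id", "ordinal"])
    ok = total = 0
    for p in pairs:
        if p.pair_type != "cis":
            continue
        total += 1
        a = truth.loc[(p.read_id, p.ordinal1)]
        b = truth.loc[(p.read_id, p.ordinal2)]
        if a.chrom == b.chrom and abs(int(a.start) - int(b.start)) == p.distance:
            ok += 1
    assert total > 0
    assert ok / total >= 0.99
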