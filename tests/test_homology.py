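"""Aligner behaviour, tabular-alignment ingestion, and window statistics
against a per-base brute-force oracle."""

import numpy as np
import pytest

from parscope.homology import (
    AlignerParams,
    AlignmentBlock,
    align,
    bin_intervals,
    read_tabular_alignments,
    revcomp,
    window_stats,
)
from parscope.seqio import GenomicInterval, SequenceRecord
from parscope.simulate import mutate_sequence

from conftest import random_seq


class TestBinIntervals:
    @pytest.mark.parametrize(
        "length,window,n,last",
        [
            (3_500_000, 1_000_000, 4, (3_000_000, 3_500_000)),
            (1_000_000, 1_000_000, 1, (0, 1_000_000)),
            # chromosome-scale length whose last bin is a remainder
            (15_624_455, 1_000_000, 16, (15_000_000, 15_624_455)),
        ],
    )
    def test_partition(self, length, window, n, last):
        windows = bin_intervals(length, window)
        assert len(windows) == n
        assert (windows[-1].start, windows[-1].end) == last
        # consecutive, disjoint, covering
        assert windows[0].start == 0
        for a, b in zip(windows, windows[1:]):
            assert a.end == b.start

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bin_intervals(0, 100)


class TestAlign:
    def test_identical_sequences_single_full_identity_block(self, rng):
        seq = random_seq(rng, 10_000)
        rec = SequenceRecord("q", seq)
        blocks = align(rec, SequenceRecord("t", seq))
        assert len(blocks) == 1
        b = blocks[0]
        assert b.strand == "+"
        assert (b.query.start, b.query.end) == (0, 10_000)
        assert (b.target.start, b.target.end) == (0, 10_000)
        assert b.identity == 1.0

    def test_reverse_complement_yields_minus_block(self, rng):
        seq = random_seq(rng, 10_000)
        blocks = align(
            SequenceRecord("q", revcomp(seq)), SequenceRecord("t", seq)
        )
        assert len(blocks) == 1
        b = blocks[0]
        assert b.strand == "-"
        assert (b.query.start, b.query.end) == (0, 10_000)
        assert b.identity == 1.0

    def test_no_homology_gives_empty_list(self, rng):
        q = SequenceRecord("q", random_seq(rng, 3_000))
        t = SequenceRecord("t", random_seq(rng, 3_000))
        assert align(q, t) == []

    def test_identity_tracks_mutation_transcript(self, rng):
        # column-weighted identity of the block set must match the realized
        # identity of the mutation transcript within 0.01
        seq = random_seq(rng, 50_000)
        mut, realized = mutate_sequence(seq, 0.05, 0.0, 17)
        blocks = align(SequenceRecord("q", seq), SequenceRecord("t", mut))
        cols = sum(b.aln_columns for b in blocks)
        weighted = sum(b.aln_columns * b.identity for b in blocks) / cols
        assert abs(weighted - realized) <= 0.01
        assert abs(realized - 0.95) < 0.01

    def test_mirror_symmetry_under_query_reverse_complement(self, rng):
        # build a query with a forward and an inverted homologous segment
        core = random_seq(rng, 6_000)
        target = SequenceRecord("t", core)
        qseq = core[:3_000] + revcomp(core[3_600:5_600])
        q = SequenceRecord("q", qseq)
        fwd = align(q, target)
        mirrored = align(SequenceRecord("q", revcomp(qseq)), target)
        n = len(qseq)

        def norm(blocks, flip):
            out = set()
            for b in blocks:
                if flip:
                    qiv = (n - b.query.end, n - b.query.start)
                    strand = "-" if b.strand == "+" else "+"
                else:
                    qiv = (b.query.start, b.query.end)
                    strand = b.strand
                out.add((qiv, (b.target.start, b.target.end), strand, b.matches, b.aln_columns))
            return out

        assert norm(fwd, False) == norm(mirrored, True)

    def test_n_runs_are_not_seeded(self, rng):
        seq = random_seq(rng, 2_000)
        gapped = seq[:900] + "N" * 200 + seq[1100:]
        blocks = align(SequenceRecord("q", gapped), SequenceRecord("t", gapped))
        assert all(b.identity >= 0.99 for b in blocks)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AlignerParams(k=4)
        with pytest.raises(ValueError):
            AlignerParams(k=15, min_block=10)


class TestTabularIngestion:
    BLAST6 = "q\tt\t95.00\t100\t5\t0\t1\t100\t200\t101\t1e-10\t180\n"

    def test_blast6_coordinate_conventions(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text(self.BLAST6)
        (b,) = read_tabular_alignments(path, "blast6")
        assert (b.query.start, b.query.end) == (0, 100)
        # subject start > end encodes the minus strand
        assert (b.target.start, b.target.end) == (100, 200)
        assert b.strand == "-"
        assert b.matches == 95 and b.aln_columns == 100

    def test_paf_passthrough(self, tmp_path):
        line = "q\t1000\t10\t110\t+\tt\t2000\t20\t120\t90\t100\t60\n"
        path = tmp_path / "a.paf"
        path.write_text(line)
        (b,) = read_tabular_alignments(path, "paf")
        assert (b.query.start, b.query.end) == (10, 110)
        assert (b.target.start, b.target.end) == (20, 120)
        assert b.strand == "+" and b.matches == 90 and b.aln_columns == 100

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("")
        assert read_tabular_alignments(path, "blast6") == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(self.BLAST6 + "not\tenough\tcolumns\n")
        with pytest.raises(ValueError, match=":2:"):
            read_tabular_alignments(path, "blast6")

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError):
            read_tabular_alignments(tmp_path / "x", "sam")


def _block(qs, qe, identity, chrom="q"):
    cols = qe - qs
    return AlignmentBlock(
        query=GenomicInterval(chrom, qs, qe),
        target=GenomicInterval("t", 0, cols),
        strand="+",
        matches=round(identity * cols),
        aln_columns=cols,
    )


def window_stats_oracle(blocks, windows):
    """Per-base brute force: mark covered bases; average identity base-wise."""
    out = []
    for w in windows:
        acc = np.zeros(w.span)
        cnt = np.zeros(w.span)
        for b in blocks:
            s = max(b.query.start, w.start) - w.start
            e = min(b.query.end, w.end) - w.start
            if e > s:
                acc[s:e] += b.identity
                cnt[s:e] += 1
        coverage = float((cnt > 0).sum()) / w.span
        identity = float(acc.sum() / cnt.sum()) if cnt.sum() else None
        out.append((coverage, identity))
    return out


class TestWindowStats:
    def test_no_blocks_flagged_no_data(self):
        (s,) = window_stats([], [GenomicInterval("q", 0, 1_000_000)])
        assert s.coverage == 0.0 and s.identity is None and s.block_count == 0

    def test_single_half_window_block(self):
        (s,) = window_stats(
            [_block(0, 500_000, 0.99)], [GenomicInterval("q", 0, 1_000_000)]
        )
        assert s.coverage == 0.5 and s.identity == pytest.approx(0.99)

    def test_overlapping_blocks_column_weighted(self):
        blocks = [_block(0, 600_000, 0.90), _block(400_000, 1_000_000, 0.80)]
        (s,) = window_stats(blocks, [GenomicInterval("q", 0, 1_000_000)])
        assert s.coverage == 1.0
        assert s.identity == pytest.approx(0.85)

    def test_block_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            window_stats(
                [_block(0, 2_000, 0.9)],
                [GenomicInterval("q", 0, 1_000)],
                sequence_length=1_000,
            )

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(50):
            length = int(rng.integers(1_000, 50_000))
            wsize = int(rng.integers(200, length))
            windows = bin_intervals(length, wsize, "q")
            blocks = []
            for _ in range(int(rng.integers(0, 12))):
                qs = int(rng.integers(0, length - 1))
                qe = int(rng.integers(qs + 1, min(qs + 5_000, length) + 1))
                blocks.append(_block(qs, qe, float(rng.uniform(0.1, 1.0))))
            stats = window_stats(blocks, windows)
            oracle = window_stats_oracle(blocks, windows)
            for s, (cov, ident) in zip(stats, oracle):
                assert s.coverage == pytest.approx(cov, abs=0)
                if ident is None:
                    assert s.identity is None
                else:
                    assert s.identity == pytest.approx(ident, abs=1e-9)

    def test_coverage_invariant_under_block_split(self, rng):
        windows = bin_intervals(10_000, 3_000, "q")
        whole = [_block(1_000, 9_000, 0.9)]
        mid = 5_000
        split = [_block(1_000, mid, 0.9), _block(mid, 9_000, 0.9)]
        for a, b in zip(window_stats(whole, windows), window_stats(split, windows)):
            assert a.coverage == b.coverage
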