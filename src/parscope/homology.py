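"""X-vs-Y homology: an internal seed–chain–extend aligner and window statistics.

The aligner finds exact k-mer seed matches (k-mers containing N are never
seeded), merges co-diagonal seeds into segments, chains nearby segments across
small diagonal shifts, and polishes each chain with a unit-cost global
edit-distance alignment (edlib) of the chained substrings to obtain match and
column counts. Blocks shorter than ``min_block`` are discarded. It is a
deliberately simple, fully documented stand-in for a BLASTN-style local
aligner; externally produced alignments (BLAST tabular outfmt 6 or PAF) can be
ingested with :func:`read_tabular_alignments` and drive the identical
downstream pipeline.

Per-window coverage is the fraction of window bases covered by the union of
clipped block query-intervals; per-window identity is the alignment-column-
weighted mean identity of clipped blocks (overlapping blocks double-count in
the identity weighting, by design — see docs/methods.md).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .seqio import GenomicInterval, SequenceRecord

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
_ENC[ord("N")] = 4
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTN", "TGCAN")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN string to uint8 codes (A=0 .. T=3, N=4)."""
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return arr


def decode(codes: np.ndarray) -> str:
    return bytes(_DEC[codes]).decode()


def edit_alignment_counts(query: str, target: str) -> tuple[int, int]:
    """(matches, alignment columns) of an optimal unit-cost global alignment."""
    res = edlib.align(query, target, mode="NW", task="path")
    matches = 0
    columns = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def global_identity(a: str, b: str) -> float:
    """Identity (matches / columns) of an optimal global alignment of a and b."""
    m, c = edit_alignment_counts(a, b)
    return m / c


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment: the atomic evidence unit for windowed statistics."""

    query: GenomicInterval
    target: GenomicInterval
    strand: str
    matches: int
    aln_columns: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.matches <= self.aln_columns):
            raise ValueError("matches must lie in [0, aln_columns]")
        if self.aln_columns < self.query.span or self.aln_columns < self.target.span:
            raise ValueError("alignment columns fewer than aligned span")

    @property
    def identity(self) -> float:
        return self.matches / self.aln_columns


@dataclass
class WindowStat:
    """Coverage/identity summary of one window; identity is None when no block
    intersects the window (the no-data flag)."""

    window: GenomicInterval
    coverage: float
    identity: Optional[float]
    block_count: int


@dataclass
class AlignerParams:
    """Parameters of the seed–chain–extend aligner.

    k: seed length; min_block: shortest reported block; max_gap: largest
    query/target gap bridged within a chain; diag_band: largest diagonal shift
    bridged within a chain (bounds the indel imbalance); max_seed_occ: seeds
    occurring more often than this in the target are skipped (repeat guard).
    """

    k: int = 15
    min_block: int = 100
    max_gap: int = 500
    diag_band: int = 100
    max_seed_occ: int = 16

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if self.min_block < self.k:
            raise ValueError("min_block must be >= k")


def bin_intervals(length: int, window: int, chrom: str = "") -> list[GenomicInterval]:
    """Partition [0, length) into consecutive windows of the given size.

    All windows have the requested size except possibly the last.
    """
    if length <= 0 or window <= 0:
        raise ValueError("length and window must be positive")
    return [
        GenomicInterval(chrom, s, min(s + window, length))
        for s in range(0, length, window)
    ]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for all k-mer start positions; valid is False where the
    window contains an N."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = (codes << 2) | (arr[j : j + n] & 3).astype(np.int64)
    is_n = (arr == 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


class TargetIndex:
    """Sorted k-mer index of a target sequence, reusable across queries."""

    def __init__(self, record: SequenceRecord, k: int = 15):
        self.record = record
        self.k = k
        arr = encode(record.sequence)
        codes, valid = _kmer_codes(arr, k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def lookup(self, query_codes: np.ndarray, query_valid: np.ndarray, max_occ: int):
        """All (query_pos, target_pos) seed matches, repeat-filtered."""
        lo = np.searchsorted(self._codes, query_codes, "left")
        hi = np.searchsorted(self._codes, query_codes, "right")
        cnt = hi - lo
        cnt[~query_valid] = 0
        single = cnt == 1
        multi = (cnt > 1) & (cnt <= max_occ)
        qpos = [np.nonzero(single)[0]]
        tpos = [self._pos[lo[single]]]
        qm = np.nonzero(multi)[0]
        if len(qm):
            reps = cnt[qm]
            offs = np.concatenate([np.arange(r) for r in reps])
            qpos.append(np.repeat(qm, reps))
            tpos.append(self._pos[np.repeat(lo[qm], reps) + offs])
        return np.concatenate(qpos), np.concatenate(tpos)


def _merge_diagonal_runs(qpos, tpos, k, max_gap):
    """Merge seed hits into co-diagonal segments (qs, qe, ts, te)."""
    diag = qpos - tpos
    order = np.lexsort((qpos, diag))
    d, q, t = diag[order], qpos[order], tpos[order]
    brk = np.nonzero((np.diff(d) != 0) | (np.diff(q) > max_gap))[0] + 1
    starts = np.concatenate([[0], brk])
    ends = np.concatenate([brk, [len(q)]])
    return np.column_stack(
        [q[starts], q[ends - 1] + k, t[starts], t[ends - 1] + k]
    )


def _chain_segments(segs: np.ndarray, max_gap: int, diag_band: int, k: int):
    """Greedy sweep chaining of segments into (qs, qe, ts, te) chains."""
    if len(segs) == 0:
        return []
    segs = segs[np.lexsort((segs[:, 2], segs[:, 0]))]
    chains: list[list[int]] = []  # [qs, qe, ts, te]
    active: list[list[int]] = []
    for qs, qe, ts, te in segs:
        active = [c for c in active if c[1] >= qs - max_gap]
        attached = False
        for c in active:
            if (
                abs((qs - ts) - (c[0] - c[2])) <= diag_band
                and qs >= c[1] - k
                and ts >= c[3] - k
                and ts - c[3] <= max_gap
            ):
                c[1] = max(c[1], qe)
                c[3] = max(c[3], te)
                attached = True
                break
        if not attached:
            c = [qs, qe, ts, te]
            chains.append(c)
            active.append(c)
    return chains


def _polish_chain(qseq: str, tseq: str, qs, qe, ts, te):
    matches, columns = edit_alignment_counts(qseq[qs:qe], tseq[ts:te])
    return matches, columns


def align(
    query: SequenceRecord,
    target: SequenceRecord,
    params: AlignerParams | None = None,
    index: TargetIndex | None = None,
    query_offset: int = 0,
) -> list[AlignmentBlock]:
    """Align query against target on both strands.

    ``index`` may be supplied to reuse a prebuilt target k-mer index (it must
    have been built with the same k). ``query_offset`` shifts reported query
    coordinates — used when aligning a slice of a longer sequence.

    No homology yields an empty list, never an error.
    """
    params = params or AlignerParams()
    if index is None:
        index = TargetIndex(target, params.k)
    elif index.k != params.k:
        raise ValueError("target index built with a different seed length")
    blocks: list[AlignmentBlock] = []
    qlen = len(query.sequence)
    for strand in "+-":
        qseq = query.sequence if strand == "+" else revcomp(query.sequence)
        arr = encode(qseq)
        codes, valid = _kmer_codes(arr, params.k)
        if len(codes) == 0:
            continue
        qpos, tpos = index.lookup(codes, valid, params.max_seed_occ)
        if len(qpos) == 0:
            continue
        segs = _merge_diagonal_runs(qpos, tpos, params.k, params.max_gap)
        for qs, qe, ts, te in _chain_segments(
            segs, params.max_gap, params.diag_band, params.k
        ):
            if qe - qs < params.min_block and te - ts < params.min_block:
                continue
            matches, columns = _polish_chain(
                qseq, index.record.sequence, qs, qe, ts, te
            )
            if strand == "+":
                q_iv = GenomicInterval(query.id, query_offset + qs, query_offset + qe)
            else:
                q_iv = GenomicInterval(
                    query.id, query_offset + qlen - qe, query_offset + qlen - qs
                )
            blocks.append(
                AlignmentBlock(
                    query=q_iv,
                    target=GenomicInterval(target.id, int(ts), int(te)),
                    strand=strand,
                    matches=int(matches),
                    aln_columns=int(columns),
                )
            )
    blocks.sort(key=lambda b: (b.query.start, b.query.end, b.target.start, b.strand))
    return blocks


# --- standard-format alignment ingestion ------------------------------------


def read_tabular_alignments(path: str | Path, dialect: str) -> list[AlignmentBlock]:
    """Read alignments from BLAST tabular (outfmt 6) or PAF into blocks.

    blast6: qstart/qend 1-based inclusive; sstart > send encodes the minus
    strand; matches are recovered as round(pident/100 x length).
    PAF: coordinates already 0-based half-open; column 5 is the strand,
    column 10 the number of matching bases, column 11 the alignment length.
    """
    if dialect not in ("blast6", "paf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "blast6":
                    if len(fields) < 12:
                        raise ValueError("expected 12 columns")
                    qid, sid = fields[0], fields[1]
                    pident = float(fields[2])
                    length = int(fields[3])
                    qstart, qend = int(fields[6]), int(fields[7])
                    sstart, send = int(fields[8]), int(fields[9])
                    q_iv = GenomicInterval(qid, qstart - 1, qend)
                    if sstart <= send:
                        t_iv = GenomicInterval(sid, sstart - 1, send)
                        strand = "+"
                    else:
                        t_iv = GenomicInterval(sid, send - 1, sstart)
                        strand = "-"
                    matches = round(pident / 100.0 * length)
                    blocks.append(
                        AlignmentBlock(q_iv, t_iv, strand, matches, length)
                    )
                else:
                    if len(fields) < 12:
                        raise ValueError("expected >= 12 columns")
                    qid = fields[0]
                    qstart, qend = int(fields[2]), int(fields[3])
                    strand = fields[4]
                    tid = fields[5]
                    tstart, tend = int(fields[7]), int(fields[8])
                    matches, alnlen = int(fields[9]), int(fields[10])
                    blocks.append(
                        AlignmentBlock(
                            GenomicInterval(qid, qstart, qend),
                            GenomicInterval(tid, tstart, tend),
                            strand,
                            matches,
                            alnlen,
                        )
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {dialect} line: {exc}")
    return blocks


# --- windowed statistics -----------------------------------------------------


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def window_stats(
    blocks: Sequence[AlignmentBlock],
    windows: Sequence[GenomicInterval],
    sequence_length: int | None = None,
) -> list[WindowStat]:
    """Per-window coverage and identity from alignment blocks.

    Coverage: union of clipped block query-intervals over the window length.
    Identity: sum(clipped columns x block identity) / sum(clipped columns),
    where a block's clipped columns are its alignment columns scaled by the
    clipped fraction of its query span. Windows intersected by no block carry
    identity None (no-data).
    """
    if sequence_length is not None:
        for b in blocks:
            if b.query.end > sequence_length:
                raise ValueError(
                    f"block {b.query} extends past sequence length {sequence_length}"
                )
    stats = []
    for w in windows:
        clipped: list[tuple[int, int]] = []
        wsum = 0.0
        isum = 0.0
        count = 0
        for b in blocks:
            ov = b.query.overlap(w)
            if ov == 0:
                continue
            count += 1
            s = max(b.query.start, w.start)
            clipped.append((s, s + ov))
            cols = b.aln_columns * (ov / b.query.span)
            wsum += cols
            isum += cols * b.identity
        coverage = _union_length(clipped) / w.span
        identity = (isum / wsum) if count else None
        stats.append(WindowStat(window=w, coverage=coverage, identity=identity, block_count=count))
    return stats


def window_stats_table(stats: Sequence[WindowStat]):
    """WindowStat list as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "window_start": [s.window.start for s in stats],
            "window_end": [s.window.end for s in stats],
            "coverage": [s.coverage for s in stats],
            "identity": [s.identity if s.identity is not None else float("nan") for s in stats],
            "block_count": [s.block_count for s in stats],
        }
    )
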