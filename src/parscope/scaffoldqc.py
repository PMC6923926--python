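"""Y-scaffold validation: candidate flagging, bin alignment-fraction
filtering, marker-map concordance, and dual-map inversion resolution.

The rules mirror standard assembly-validation practice for a repeat-dense Y:
scaffolds shorter than 50 kb carrying fewer than three known Y genes are
flagged for inspection; flagged scaffolds are partitioned into 50-kb bins and
aligned against trusted reference sequence, and those with less than 90% of
their bases aligned are removed (a scaffold at exactly 90% is retained).
Marker-map concordance is the minimum number of markers whose removal makes
assembly order a monotone function of map rank (n minus the longest monotone
subsequence), plus Kendall's tau; a contig inversion is proposed only when
every provided map independently supports it — when maps conflict, the
assembly layout is retained.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .homology import AlignerParams, TargetIndex, align
from .seqio import SequenceRecord


@dataclass
class QcThresholds:
    min_scaffold_len: int = 50_000
    min_gene_hits: int = 3
    qc_bin: int = 50_000
    min_aligned_fraction: float = 0.90
    min_block_identity: float = 0.80  # identity floor for a base to count as aligned

    def __post_init__(self) -> None:
        if min(self.min_scaffold_len, self.min_gene_hits, self.qc_bin) <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.min_aligned_fraction <= 1.0):
            raise ValueError("min_aligned_fraction must be in (0, 1]")


@dataclass
class ScaffoldLayout:
    """Ordered contigs of an assembly: (contig_id, length, orientation)."""

    contigs: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        for cid, length, orient in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {cid!r} has non-positive length")
            if orient not in "+-":
                raise ValueError(f"contig {cid!r} has invalid orientation {orient!r}")

    @property
    def offsets(self) -> list[int]:
        offs, pos = [], 0
        for _, length, _ in self.contigs:
            offs.append(pos)
            pos += length
        return offs

    @property
    def total_length(self) -> int:
        return sum(length for _, length, _ in self.contigs)

    def contig_of(self, position: int) -> int:
        """Index of the contig containing an assembly position."""
        if not (0 <= position < self.total_length):
            raise ValueError(f"position {position} outside the assembly")
        for i, off in enumerate(self.offsets):
            if off <= position < off + self.contigs[i][1]:
                return i
        raise AssertionError("unreachable")


@dataclass
class MarkerMap:
    """An ordered marker map scored against an assembly.

    markers: (marker_id, map_rank, assembly_position), ordered by map_rank.
    """

    map_name: str
    markers: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        ranks = [r for _, r, _ in self.markers]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError(f"map {self.map_name!r}: map_rank not strictly increasing")
        ids = [m for m, _, _ in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError(f"map {self.map_name!r}: duplicate marker ids")

    @classmethod
    def from_frame(
        cls, name: str, frame: pd.DataFrame, position_col: str = "assembly_position"
    ) -> "MarkerMap":
        return cls(
            name,
            [
                (str(m), int(r), int(p))
                for m, r, p in zip(
                    frame["marker_id"], frame["map_rank"], frame[position_col]
                )
            ],
        )

    @property
    def positions(self) -> list[int]:
        return [p for _, _, p in self.markers]


def flag_candidate_scaffolds(
    scaffolds: Sequence[SequenceRecord],
    gene_hit_counts: dict[str, int],
    thresholds: QcThresholds | None = None,
) -> list[str]:
    """Ids of scaffolds shorter than the length cutoff AND with fewer known
    Y-gene hits than the count cutoff ("fewer than three" is strict)."""
    thresholds = thresholds or QcThresholds()
    ids = {s.id for s in scaffolds}
    unknown = set(gene_hit_counts) - ids
    if unknown:
        raise ValueError(f"gene-hit counts for unknown scaffolds: {sorted(unknown)}")
    flagged = []
    for s in scaffolds:
        hits = gene_hit_counts.get(s.id, 0)
        if len(s) < thresholds.min_scaffold_len and hits < thresholds.min_gene_hits:
            flagged.append(s.id)
    return flagged


def scaffold_aligned_fraction(
    scaffold: SequenceRecord,
    references: Sequence[SequenceRecord],
    thresholds: QcThresholds | None = None,
    params: AlignerParams | None = None,
) -> float:
    """Fraction of scaffold bases covered by alignments to any reference.

    The scaffold is partitioned into qc_bin bins, each bin aligned against
    every reference; bases covered by blocks with identity >= the block
    identity floor count as aligned. The scaffold-level fraction is the
    union of covered bases over the scaffold length.
    """
    thresholds = thresholds or QcThresholds()
    params = params or AlignerParams()
    if not references:
        raise ValueError("reference set must be non-empty")
    indexes = [TargetIndex(r, params.k) for r in references]
    n = len(scaffold)
    covered = np.zeros(n, dtype=bool)
    for s in range(0, n, thresholds.qc_bin):
        e = min(s + thresholds.qc_bin, n)
        bin_rec = SequenceRecord(scaffold.id, scaffold.sequence[s:e])
        for ref, idx in zip(references, indexes):
            for b in align(bin_rec, ref, params, idx, query_offset=s):
                if b.identity >= thresholds.min_block_identity:
                    covered[b.query.start : b.query.end] = True
    return float(covered.sum()) / n


def filter_scaffolds(
    scaffolds: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    thresholds: QcThresholds | None = None,
    params: AlignerParams | None = None,
) -> tuple[list[str], list[str], dict[str, float]]:
    """(kept ids, removed ids, aligned fractions). Removal is strict:
    a scaffold at exactly the fraction threshold is retained."""
    thresholds = thresholds or QcThresholds()
    kept, removed, fractions = [], [], {}
    for s in scaffolds:
        frac = scaffold_aligned_fraction(s, references, thresholds, params)
        fractions[s.id] = frac
        (removed if frac < thresholds.min_aligned_fraction else kept).append(s.id)
    return kept, removed, fractions


# --- marker concordance ------------------------------------------------------


def _longest_increasing(seq: Sequence[int]) -> int:
    """Length of the longest strictly increasing subsequence, O(n log n)."""
    tails: list[int] = []
    for v in seq:
        i = bisect_left(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


def marker_concordance(
    layout: Optional[ScaffoldLayout], marker_map: MarkerMap
) -> tuple[int, float]:
    """(discordant marker count, Kendall rank correlation) of a map vs an
    assembly.

    The discordant count is the minimum number of markers whose removal
    leaves assembly positions monotone in map rank (n minus the longest
    monotone subsequence); the monotone direction is chosen per map as the
    one minimising discordance, since map orientation is arbitrary.
    """
    positions = marker_map.positions
    if len(positions) < 2:
        raise ValueError("marker concordance requires at least 2 markers")
    if layout is not None:
        total = layout.total_length
        for mid, _, p in marker_map.markers:
            if not (0 <= p < total):
                raise ValueError(
                    f"marker {mid!r} at {p} outside the assembly (unknown contig)"
                )
    best = max(
        _longest_increasing(positions),
        _longest_increasing([-p for p in positions]),
    )
    discordant = len(positions) - best
    tau = kendalltau(range(len(positions)), positions).statistic
    return discordant, float(tau)


# --- inversion resolution ----------------------------------------------------


def _flip_positions(layout: ScaffoldLayout, contig_idx: int, positions):
    """Marker positions after in-silico inversion of one contig."""
    off = layout.offsets[contig_idx]
    length = layout.contigs[contig_idx][1]
    out = []
    for p in positions:
        if off <= p < off + length:
            out.append(off + (off + length - 1 - p))
        else:
            out.append(p)
    return out


def _discordance(positions) -> int:
    best = max(
        _longest_increasing(positions), _longest_increasing([-p for p in positions])
    )
    return len(positions) - best


def detect_inversions(
    layout: ScaffoldLayout, maps: Sequence[MarkerMap]
) -> list[str]:
    """Contig flips unanimously supported by every marker map.

    A flip is proposed only if reversing the contig's marker order strictly
    decreases the discordant count of EVERY map, and applying the full flip
    set leaves no map worse than baseline. When maps disagree, nothing is
    proposed and the assembly layout is retained (the arrangement backed by
    the assembly evidence wins over conflicting maps).
    """
    if not maps:
        raise ValueError("at least one marker map is required")
    for m in maps:
        marker_concordance(layout, m)  # validates positions against the layout
    base = {m.map_name: _discordance(m.positions) for m in maps}
    proposals: list[int] = []
    for ci in range(len(layout.contigs)):
        if all(
            _discordance(_flip_positions(layout, ci, m.positions)) < base[m.map_name]
            for m in maps
        ):
            proposals.append(ci)
    if proposals:
        # joint sanity: applying every proposed flip must not hurt any map
        for m in maps:
            pos = m.positions
            for ci in proposals:
                pos = _flip_positions(layout, ci, pos)
            if _discordance(pos) > base[m.map_name]:
                return []
    return [layout.contigs[ci][0] for ci in proposals]


def qc_report(
    layout: ScaffoldLayout, maps: Sequence[MarkerMap]
) -> pd.DataFrame:
    """Per-map concordance summary as a DataFrame (TSV-ready)."""
    rows = []
    for m in maps:
        d, tau = marker_concordance(layout, m)
        rows.append(
            {
                "map_name": m.map_name,
                "n_markers": len(m.markers),
                "discordant_count": d,
                "kendall_tau": tau,
            }
        )
    return pd.DataFrame(rows)
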