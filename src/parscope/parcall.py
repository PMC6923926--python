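"""Pseudoautosomal boundary calling by the first-failing-bin rule.

The X is partitioned into windows (1 Mb at chromosome scale) and aligned
against the Y; the first window from the proximal end with coverage below 80%
AND identity below 80% marks the pseudoautosomal boundary (PAB). The
conjunction is strict: a window must fail both criteria, and strict
inequality is used — a window at exactly the threshold passes. A window with
no alignment at all (no-data identity) counts as failing the identity
criterion: absence of alignment is the strongest evidence of non-homology.

The coarse call is then refined by re-binning a small interval around the
failing window at successively finer window sizes, re-aligning locally and
re-applying the identical rule, down to the finest scheduled size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .homology import (
    AlignerParams,
    TargetIndex,
    WindowStat,
    align,
    bin_intervals,
    window_stats,
)
from .seqio import GenomicInterval, SequenceRecord


@dataclass
class Thresholds:
    """The 80/80 rule thresholds and the window/refinement schedule."""

    coverage_min: float = 0.80
    identity_min: float = 0.80
    window: int = 1_000_000
    refine_schedule: tuple[int, ...] = (100_000, 10_000, 1_000)

    def __post_init__(self) -> None:
        for name in ("coverage_min", "identity_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        sizes = (self.window, *self.refine_schedule)
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("refine_schedule must be strictly decreasing from window")


@dataclass
class PabCall:
    """A called pseudoautosomal boundary.

    boundary is the first base NOT in the PAR (0-based); the PAR is
    [0, boundary). boundary_found is False when no window fails the rule
    (X and Y homologous throughout — the whole sequence is flagged as PAR).
    """

    boundary: int
    resolution: int
    profile: list[list[WindowStat]]
    boundary_found: bool
    chrom: str = "X"

    @property
    def par(self) -> Optional[GenomicInterval]:
        if self.boundary == 0:
            return None  # empty PAR
        return GenomicInterval(self.chrom, 0, self.boundary)


def _fails(stat: WindowStat, thresholds: Thresholds) -> bool:
    cov_fail = stat.coverage < thresholds.coverage_min
    id_fail = stat.identity is None or stat.identity < thresholds.identity_min
    return cov_fail and id_fail


def _passes_both(stat: WindowStat, thresholds: Thresholds) -> bool:
    return (
        stat.coverage >= thresholds.coverage_min
        and stat.identity is not None
        and stat.identity >= thresholds.identity_min
    )


def call_pab_coarse(
    stats: Sequence[WindowStat], thresholds: Thresholds | None = None
) -> Optional[int]:
    """Index of the first window failing both criteria; None if none fails.

    stats must be ordered by window start from the proximal end.
    """
    thresholds = thresholds or Thresholds()
    if not stats:
        raise ValueError("empty window-statistics list")
    for i, stat in enumerate(stats):
        if _fails(stat, thresholds):
            return i
    return None


def _first_fail_and_anchor(
    stats: Sequence[WindowStat], thresholds: Thresholds
) -> tuple[Optional[int], Optional[int]]:
    """(first failing index, nearest preceding index passing BOTH criteria)."""
    fail = None
    for i, stat in enumerate(stats):
        if _fails(stat, thresholds):
            fail = i
            break
    if fail is None:
        return None, None
    anchor = None
    for j in range(fail - 1, -1, -1):
        if _passes_both(stats[j], thresholds):
            anchor = j
            break
    return fail, anchor


def refine_pab(
    x: SequenceRecord,
    y: SequenceRecord,
    coarse_index: int,
    thresholds: Thresholds | None = None,
    params: AlignerParams | None = None,
    index: TargetIndex | None = None,
    coarse_stats: Sequence[WindowStat] | None = None,
) -> PabCall:
    """Refine a coarse boundary call down the window-size schedule.

    Each level re-bins the interval between the nearest window passing both
    criteria and the end of the failing window, re-aligns that X interval
    against the full Y, and re-applies the identical rule. The final boundary
    is the start of the first failing window at the finest size. The window
    profile of every level is retained.

    The proximal anchor is the nearest preceding window passing BOTH
    criteria (not merely the window before the failing one): windows that
    fail only coverage — e.g. a sparse high-identity gene relic in otherwise
    non-homologous sequence — are neither passing nor failing under the
    conjunction rule and must not truncate the refinement interval.
    """
    thresholds = thresholds or Thresholds()
    params = params or AlignerParams()
    if index is None:
        index = TargetIndex(y, params.k)
    if coarse_stats is None:
        blocks = align(x, y, params, index)
        windows = bin_intervals(len(x), thresholds.window, x.id)
        coarse_stats = window_stats(blocks, windows, sequence_length=len(x))
    if not (0 <= coarse_index < len(coarse_stats)):
        raise ValueError("coarse_index outside the window-statistics list")

    profile: list[list[WindowStat]] = [list(coarse_stats)]
    _, anchor = _first_fail_and_anchor(
        list(coarse_stats[: coarse_index + 1]), thresholds
    )
    region_start = coarse_stats[anchor].window.start if anchor is not None else 0
    region_end = coarse_stats[coarse_index].window.end
    boundary = coarse_stats[coarse_index].window.start
    resolution = thresholds.window

    for w in thresholds.refine_schedule:
        if w >= region_end - region_start:
            raise ValueError(
                f"refinement window {w} not finer than the region "
                f"[{region_start}, {region_end})"
            )
        windows = [
            GenomicInterval(x.id, s, min(s + w, region_end))
            for s in range(region_start, region_end, w)
        ]
        sub_x = SequenceRecord(x.id, x.sequence[region_start:region_end])
        blocks = align(sub_x, y, params, index, query_offset=region_start)
        stats_w = window_stats(blocks, windows, sequence_length=len(x))
        fail, anchor = _first_fail_and_anchor(stats_w, thresholds)
        profile.append(stats_w)
        resolution = w
        if fail is None:
            # homology extends through the whole region at this resolution
            boundary = region_end
            break
        boundary = stats_w[fail].window.start
        region_start = stats_w[anchor].window.start if anchor is not None else region_start
        region_end = stats_w[fail].window.end

    return PabCall(
        boundary=boundary,
        resolution=resolution,
        profile=profile,
        boundary_found=True,
        chrom=x.id,
    )


def call_pab(
    x: SequenceRecord,
    y: SequenceRecord,
    thresholds: Thresholds | None = None,
    params: AlignerParams | None = None,
    index: TargetIndex | None = None,
) -> PabCall:
    """Coarse 80/80 scan plus refinement; the one-call entry point.

    When no window fails (X and Y homologous throughout) the sentinel call is
    returned: boundary at the sequence end, boundary_found False, whole
    sequence flagged as PAR.
    """
    thresholds = thresholds or Thresholds()
    params = params or AlignerParams()
    if index is None:
        index = TargetIndex(y, params.k)
    blocks = align(x, y, params, index)
    windows = bin_intervals(len(x), thresholds.window, x.id)
    stats = window_stats(blocks, windows, sequence_length=len(x))
    coarse = call_pab_coarse(stats, thresholds)
    if coarse is None:
        return PabCall(
            boundary=len(x),
            resolution=thresholds.window,
            profile=[stats],
            boundary_found=False,
            chrom=x.id,
        )
    return refine_pab(x, y, coarse, thresholds, params, index, coarse_stats=stats)


# --- PAR gene report ---------------------------------------------------------


@dataclass
class ParReport:
    """Gene content of a called PAR.

    par_genes: ids of genes fully inside the PAR, in positional order.
    spanning_genes: genes straddling the boundary (excluded from the count).
    nearest_gene / distance: the gene whose distal end lies closest proximal
    to the boundary, and boundary - gene end in bases.
    """

    par_genes: list[str]
    spanning_genes: list[str]
    nearest_gene: Optional[str]
    distance: Optional[int]


def par_report(call: PabCall, genes: Sequence) -> ParReport:
    """Summarise gene content of the called PAR (genes on the same sequence)."""
    boundary = call.boundary
    inside = []
    spanning = []
    for g in sorted(genes, key=lambda g: (g.interval.start, g.id)):
        if g.interval.end <= boundary:
            inside.append(g)
        elif g.interval.start < boundary:
            spanning.append(g.id)
    nearest = max(inside, key=lambda g: g.interval.end, default=None)
    return ParReport(
        par_genes=[g.id for g in inside],
        spanning_genes=spanning,
        nearest_gene=nearest.id if nearest else None,
        distance=(boundary - nearest.interval.end) if nearest else None,
    )
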