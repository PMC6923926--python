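"""Seeded generator of X/Y sequence pairs with full ground truth.

The generator emulates the structure of a mammalian sex-chromosome pair at
one-tenth chromosome scale: a proximal pseudoautosomal region (PAR) shared by
X and Y at ~99% identity ending at a sharp boundary; X-degenerate segments on
the Y carrying single-copy gametologs at 60-96% identity to their X partners;
ampliconic segments carrying multi-copy gene families (by default a 3-copy and
a 4-copy family, mirroring the ruminant OBP and BDA20 expansions, with
within-family identity in the observed 74-91% band); independently generated
background sequence beyond the boundary (whose windowed identity against the X
is background-level, ~15%); N-gap runs standing in for assembly gaps; RH-style
marker maps; and assembly corruptions (contig fragmentation, inversion, drop)
with the true layout recorded for scaffold-QC scoring.

Every stochastic choice flows from a single seed through numpy's PCG64
generator, so a fixed configuration yields byte-identical outputs on any
platform. Realized identities are recorded from the applied edit transcripts,
never re-estimated by alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gametolog import GeneModel, RegionLabel
from .homology import decode, encode
from .seqio import GenomicInterval, SequenceRecord, write_fasta, write_gff3, write_marker_tsv


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.PCG64(seed))


# --- mutation with an explicit edit transcript -------------------------------


@dataclass
class MutationTranscript:
    """Record of the edits applied to a sequence.

    sub/dele/ins are per-original-position masks (ins marks a single-base
    insertion after that position; indel events are single-base). The identity
    of the mutated sequence to its source is computed from this transcript:
    matched columns / alignment columns, where columns = length + insertions.
    """

    sub: np.ndarray
    dele: np.ndarray
    ins: np.ndarray

    def __post_init__(self):
        n = len(self.sub)
        self._match_cum = np.concatenate(
            [[0], np.cumsum(~self.sub & ~self.dele)]
        )
        self._del_cum = np.concatenate([[0], np.cumsum(self.dele)])
        self._ins_cum = np.concatenate([[0], np.cumsum(self.ins)])

    @property
    def realized_identity(self) -> float:
        n = len(self.sub)
        return self._match_cum[n] / (n + self._ins_cum[n])

    def identity_over(self, start: int, end: int) -> float:
        """Identity of the transcript restricted to source columns [start, end)."""
        cols = (end - start) + (self._ins_cum[end] - self._ins_cum[start])
        return (self._match_cum[end] - self._match_cum[start]) / cols

    def map_position(self, pos: int) -> int:
        """Map a source coordinate to the mutated sequence's coordinate."""
        return pos - int(self._del_cum[pos]) + int(self._ins_cum[pos])

    def map_interval(self, iv: GenomicInterval, chrom: str) -> GenomicInterval:
        return GenomicInterval(chrom, self.map_position(iv.start), self.map_position(iv.end))


def _mutate_codes(
    codes: np.ndarray, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, MutationTranscript]:
    n = len(codes)
    mutable = codes != 4  # N positions are never edited
    sub = (rng.random(n) < sub_rate) & mutable
    out = codes.copy()
    k = int(sub.sum())
    if k:
        # substitutions drawn uniformly among the 3 alternative bases
        out[sub] = (out[sub] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
    if indel_rate > 0:
        dele = (rng.random(n) < indel_rate / 2) & mutable
        ins = (rng.random(n) < indel_rate / 2) & mutable
    else:
        dele = np.zeros(n, dtype=bool)
        ins = np.zeros(n, dtype=bool)
    transcript = MutationTranscript(sub=sub, dele=dele, ins=ins)
    kept = out[~dele]
    ins_pos = np.nonzero(ins)[0]
    if len(ins_pos):
        kept_cum = np.cumsum(~dele)
        insert_at = kept_cum[ins_pos]  # insert after the (possibly kept) base
        values = rng.integers(0, 4, len(ins_pos), dtype=np.uint8)
        kept = np.insert(kept, insert_at, values)
    return kept, transcript


def mutate_sequence(
    seq: str, sub_rate: float, indel_rate: float, seed: int | np.random.Generator
) -> tuple[str, float]:
    """Mutate a sequence; return (mutated sequence, realized identity).

    Realized identity is matched columns over alignment columns of the edit
    transcript, not an alignment re-estimate. N positions are never mutated.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    out, transcript = _mutate_codes(encode(seq), sub_rate, indel_rate, _rng(seed))
    return decode(out), transcript.realized_identity


# --- configuration -----------------------------------------------------------


@dataclass
class XdegSegment:
    """An X-degenerate segment: single-copy gametologs in a span of this length.

    divergence is a (low, high) range; each gene's divergence from its X
    partner is drawn uniformly from it (identity 1 - d).
    """

    length: int = 150_000
    divergence: tuple[float, float] = (0.06, 0.38)
    n_genes: int = 11


@dataclass
class AmpliconFamily:
    """A multi-copy Y gene family laid out in tandem with short spacers.

    within_family_divergence is the target range of PAIRWISE divergence
    between copies; each copy is mutated from a common ancestral unit at half
    a value drawn from this range, so pairwise identity between copies lands
    in ~[1 - high, 1 - low].
    """

    copy_count: int = 3
    unit_length: int = 3_000
    within_family_divergence: tuple[float, float] = (0.09, 0.26)
    name: str = ""


@dataclass
class SimulationConfig:
    """Study-scale defaults: X = 2 Mb with a 684 kb PAR (one-tenth of the
    cattle chromosome geometry), 1% PAR divergence, an 11/2/2 gametolog
    layout mirroring X-d1/X-d2a/X-d2b, and 3- and 4-copy ampliconic families."""

    x_length: int = 2_000_000
    par_length: int = 684_000
    par_sub_rate: float = 0.01
    par_indel_rate: float = 0.0
    xdeg_segments: list[XdegSegment] = field(
        default_factory=lambda: [
            XdegSegment(150_000, (0.06, 0.38), 11),
            XdegSegment(60_000, (0.06, 0.38), 2),
            XdegSegment(60_000, (0.06, 0.38), 2),
        ]
    )
    ampliconic_families: list[AmpliconFamily] = field(
        default_factory=lambda: [
            AmpliconFamily(3, 3_000, (0.09, 0.26), "OBP"),
            AmpliconFamily(4, 3_000, (0.09, 0.26), "BDA20"),
        ]
    )
    background_identity: float = 0.15  # expected windowed identity of the
    # independently generated background; documentation-level, not a dial
    gene_density: float = 15.0  # PAR genes per Mb
    gene_length: int = 2_000
    n_y_specific_genes: int = 2
    n_gap_runs: list[tuple[int, int]] = field(
        default_factory=lambda: [(200_000, 5_000), (452_000, 3_000)]
    )
    marker_count: int = 30
    marker_maps: int = 2
    corruption_ops: list[tuple] = field(
        default_factory=lambda: [
            ("fragment", "Y", (500_000, 900_000, 1_300_000)),
            ("invert", "Y.3"),
        ]
    )
    xdeg_x_buffer: int = 100_000  # gap between the PAB and the first X-side
    # gametolog locus (their X homologues are dispersed well distal of the PAR)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.par_length < self.x_length):
            raise ValueError("require 0 < par_length < x_length")
        for name in ("par_sub_rate", "par_indel_rate", "background_identity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for seg in self.xdeg_segments:
            lo, hi = seg.divergence
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("xdeg divergence range must satisfy 0 <= lo <= hi <= 1")
            if seg.length < seg.n_genes * self.gene_length:
                raise ValueError("xdeg segment too short for its genes")
        for fam in self.ampliconic_families:
            lo, hi = fam.within_family_divergence
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("family divergence range must satisfy 0 <= lo <= hi <= 1")
        for pos, length in self.n_gap_runs:
            if not (0 <= pos and pos + length <= self.par_length):
                raise ValueError("default gap runs must lie within the PAR span")


# --- ground truth ------------------------------------------------------------


@dataclass
class ContigPlacement:
    """One contig of a (possibly corrupted) assembly layout, in assembly order."""

    contig_id: str
    source_start: int  # interval on the original, uncorrupted sequence
    source_end: int
    orientation: str  # '+' or '-'


@dataclass
class LayoutTruth:
    """True layout of a corrupted contig set against the original sequence."""

    contigs: list[ContigPlacement]
    applied_ops: list[tuple]

    def offsets(self) -> list[int]:
        offs, pos = [], 0
        for c in self.contigs:
            offs.append(pos)
            pos += c.source_end - c.source_start
        return offs

    def project(self, pos: int) -> Optional[int]:
        """Map an original coordinate into the corrupted assembly (None if
        the position was dropped)."""
        for c, off in zip(self.contigs, self.offsets()):
            if c.source_start <= pos < c.source_end:
                if c.orientation == "+":
                    return off + (pos - c.source_start)
                return off + (c.source_end - 1 - pos)
        return None

    def undo(self, contigs: Sequence[SequenceRecord]) -> str:
        """Reassemble the original sequence from the corrupted contig set
        (dropped intervals excepted)."""
        from .homology import revcomp

        by_id = {r.id: r for r in contigs}
        parts = sorted(self.contigs, key=lambda c: c.source_start)
        out = []
        for c in parts:
            seq = by_id[c.contig_id].sequence
            out.append(seq if c.orientation == "+" else revcomp(seq))
        return "".join(out)


@dataclass
class SimulationTruth:
    """Ground truth against which every pipeline stage is scored."""

    pab_position: int  # first base NOT in the PAR, X coordinates
    pab_position_y: int  # same boundary in Y coordinates
    par_realized_identity: float  # X-Y PAR identity from the edit transcript
    region_map: list[RegionLabel]
    par_pairs: list[tuple[str, str, float]]  # (x_gene, y_gene, realized identity)
    gametolog_pairs: list[tuple[str, str, float]]
    family_assignments: dict[str, str]  # gene id -> family id
    family_copy_numbers: dict[str, int]
    family_identity_ranges: dict[str, tuple[float, float]]
    y_specific_genes: list[str]
    marker_tables: list[pd.DataFrame]
    gap_runs: list[tuple[int, int]]
    layout: Optional[LayoutTruth]
    applied_corruptions: list[tuple]

    def to_json_dict(self) -> dict:
        return {
            "pab_position": self.pab_position,
            "pab_position_y": self.pab_position_y,
            "par_realized_identity": self.par_realized_identity,
            "region_map": [
                {
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "klass": r.klass,
                    "name": r.name,
                }
                for r in self.region_map
            ],
            "par_pairs": [list(p) for p in self.par_pairs],
            "gametolog_pairs": [list(p) for p in self.gametolog_pairs],
            "family_assignments": self.family_assignments,
            "family_copy_numbers": self.family_copy_numbers,
            "family_identity_ranges": {
                k: list(v) for k, v in self.family_identity_ranges.items()
            },
            "y_specific_genes": self.y_specific_genes,
            "marker_tables": [t.to_dict(orient="list") for t in self.marker_tables],
            "gap_runs": [list(g) for g in self.gap_runs],
            "layout": None
            if self.layout is None
            else {
                "contigs": [asdict(c) for c in self.layout.contigs],
                "applied_ops": [list(op) for op in self.layout.applied_ops],
            },
            "applied_corruptions": [list(op) for op in self.applied_corruptions],
        }


@dataclass
class SimulationResult:
    x: SequenceRecord
    y: SequenceRecord
    x_genes: list[GeneModel]
    y_genes: list[GeneModel]
    marker_tables: list[pd.DataFrame]
    corrupted_contigs: list[SequenceRecord]
    truth: SimulationTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.x], outdir / "X.fa")
        write_fasta([self.y], outdir / "Y.fa")
        write_gff3(self.x_genes, outdir / "X_genes.gff3")
        write_gff3(self.y_genes, outdir / "Y_genes.gff3")
        for i, table in enumerate(self.marker_tables, 1):
            write_marker_tsv(table, outdir / f"markers_RH{i}.tsv")
        if self.corrupted_contigs:
            write_fasta(self.corrupted_contigs, outdir / "Y_contigs.fa")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                self.truth.to_json_dict(),
                fh,
                indent=1,
                sort_keys=True,
                default=lambda o: o.item() if hasattr(o, "item") else str(o),
            )
            fh.write("\n")


# --- assembly corruption -----------------------------------------------------


def corrupt_assembly(
    contigs: Sequence[SequenceRecord], ops: Sequence[tuple], seed: int = 0
) -> tuple[list[SequenceRecord], LayoutTruth]:
    """Apply fragmentation / inversion / drop operations to a contig set.

    Supported ops (applied in order):
      ("fragment", contig_id, (pos, ...)) — split at positions within the
        contig; pieces are named ``<id>.1``, ``<id>.2``, ...
      ("invert", contig_id) — reverse-complement the contig in place.
      ("drop", contig_id) — remove the contig.

    At most one op may target a given contig (overlapping corruptions are an
    error). Returns the corrupted contig set in assembly order plus the true
    layout for QC-stage scoring. The seed is accepted for interface symmetry
    with the other generators; the operations themselves are deterministic.
    """
    from .homology import revcomp

    layout: list[tuple[SequenceRecord, ContigPlacement]] = []
    pos = 0
    for rec in contigs:
        layout.append(
            (rec, ContigPlacement(rec.id, pos, pos + len(rec), "+"))
        )
        pos += len(rec)

    touched: set[str] = set()
    for op in ops:
        kind, cid = op[0], op[1]
        idx = next((i for i, (r, _) in enumerate(layout) if r.id == cid), None)
        if idx is None:
            raise ValueError(f"corruption op {op!r}: no contig named {cid!r}")
        if cid in touched:
            raise ValueError(f"overlapping corruption ops on contig {cid!r}")
        touched.add(cid)
        rec, place = layout[idx]
        if kind == "fragment":
            cuts = sorted(set(op[2]))
            if any(not (0 < c < len(rec)) for c in cuts):
                raise ValueError(f"fragment positions outside contig {cid!r}")
            bounds = [0] + cuts + [len(rec)]
            pieces = []
            for i in range(len(bounds) - 1):
                s, e = bounds[i], bounds[i + 1]
                pid = f"{cid}.{i + 1}"
                pieces.append(
                    (
                        SequenceRecord(pid, rec.sequence[s:e]),
                        ContigPlacement(
                            pid, place.source_start + s, place.source_start + e, "+"
                        ),
                    )
                )
                touched.add(pid)
            layout[idx : idx + 1] = pieces
            touched.discard(cid)
            for p, _ in pieces:
                touched.discard(p.id)
        elif kind == "invert":
            layout[idx] = (
                SequenceRecord(rec.id, revcomp(rec.sequence)),
                ContigPlacement(
                    place.contig_id,
                    place.source_start,
                    place.source_end,
                    "-" if place.orientation == "+" else "+",
                ),
            )
        elif kind == "drop":
            del layout[idx]
        else:
            raise ValueError(f"unknown corruption op {kind!r}")

    truth = LayoutTruth(contigs=[p for _, p in layout], applied_ops=list(ops))
    return [r for r, _ in layout], truth


# --- the generator -----------------------------------------------------------


def _place_intervals(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    n: int,
    length: int,
    forbidden: Sequence[tuple[int, int]] = (),
    max_tries: int = 10_000,
) -> list[int]:
    """n non-overlapping interval starts in [lo, hi - length], avoiding the
    forbidden intervals, by seeded rejection sampling; returned sorted."""
    if n == 0:
        return []
    if hi - lo < n * length:
        raise ValueError("region too short to place genes")
    starts: list[int] = []
    tries = 0
    while len(starts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place gene intervals; region too crowded")
        s = int(rng.integers(lo, hi - length + 1))
        e = s + length
        if any(s < fe and fs < e for fs, fe in forbidden):
            continue
        if any(s < ps + length and ps < e for ps in starts):
            continue
        starts.append(s)
    return sorted(starts)


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split total into `parts` non-negative integers (seeded, sums exactly)."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.integers(0, total + 1, parts - 1))
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def simulate_sex_chromosome_pair(config: SimulationConfig) -> SimulationResult:
    """Generate an (X, Y) pair with annotations, marker maps, corrupted contig
    set, and full ground truth. Deterministic given config (incl. seed)."""
    config.validate()
    rng = _rng(config.seed)
    glen = config.gene_length

    # X chromosome: uniform random sequence
    x_codes = rng.integers(0, 4, config.x_length, dtype=np.uint8)

    # PAR genes on X, avoiding the configured N-gap intervals
    n_par_genes = int(round(config.par_length / 1e6 * config.gene_density))
    forbidden = [(p, p + l) for p, l in config.n_gap_runs]
    par_starts = _place_intervals(
        rng, 0, config.par_length - 2_000, n_par_genes, glen, forbidden
    )

    # Y PAR: mutated copy of the X PAR
    ypar_codes, par_transcript = _mutate_codes(
        x_codes[: config.par_length], config.par_sub_rate, config.par_indel_rate, rng
    )

    x_genes: list[GeneModel] = []
    y_genes: list[GeneModel] = []
    par_pairs: list[tuple[str, str, float]] = []
    for i, s in enumerate(par_starts, 1):
        xid, yid = f"PAR{i:02d}_X", f"PAR{i:02d}_Y"
        x_iv = GenomicInterval("X", s, s + glen)
        y_iv = par_transcript.map_interval(x_iv, "Y")
        x_genes.append(GeneModel(xid, x_iv, ""))
        y_genes.append(GeneModel(yid, y_iv, ""))
        par_pairs.append((xid, yid, float(par_transcript.identity_over(s, s + glen))))

    # X-side gametolog loci, dispersed distal of the PAR
    n_gam = sum(seg.n_genes for seg in config.xdeg_segments)
    gam_starts = _place_intervals(
        rng,
        config.par_length + config.xdeg_x_buffer,
        config.x_length,
        n_gam,
        glen,
    )

    # Y distal architecture: interleave X-degenerate segments and ampliconic
    # families (X-d1, amp, X-d2a, amp, X-d2b, ...), then background fill.
    y_parts: list[np.ndarray] = [ypar_codes]
    y_pos = len(ypar_codes)
    gametolog_pairs: list[tuple[str, str, float]] = []
    family_assignments: dict[str, str] = {}
    family_identity_ranges: dict[str, tuple[float, float]] = {}
    region_map: list[RegionLabel] = [
        RegionLabel(GenomicInterval("Y", 0, y_pos), "PAR", "PAR")
    ]

    seg_names = ["XD1", "XD2A", "XD2B", "XD2C", "XD2D"]
    region_names = ["X-d1", "X-d2a", "X-d2b", "X-d2c", "X-d2d"]
    gam_iter = iter(gam_starts)

    def emit_xdeg(seg: XdegSegment, seg_idx: int):
        nonlocal y_pos
        spacers = _split_lengths(rng, seg.length - seg.n_genes * glen, seg.n_genes + 1)
        first_gene_start = None
        last_gene_end = None
        for j in range(seg.n_genes):
            sp = spacers[j]
            if sp:
                y_parts.append(rng.integers(0, 4, sp, dtype=np.uint8))
                y_pos += sp
            xs = next(gam_iter)
            xid = f"{seg_names[seg_idx]}_{j + 1:02d}_X"
            yid = f"{seg_names[seg_idx]}_{j + 1:02d}_Y"
            x_iv = GenomicInterval("X", xs, xs + glen)
            x_genes.append(GeneModel(xid, x_iv, ""))
            d = float(rng.uniform(*seg.divergence))
            mutated, transcript = _mutate_codes(
                x_codes[xs : xs + glen], d, 0.0, rng
            )
            y_parts.append(mutated)
            y_iv = GenomicInterval("Y", y_pos, y_pos + len(mutated))
            y_genes.append(GeneModel(yid, y_iv, ""))
            gametolog_pairs.append((xid, yid, float(transcript.realized_identity)))
            if first_gene_start is None:
                first_gene_start = y_iv.start
            last_gene_end = y_iv.end
            y_pos += len(mutated)
        sp = spacers[-1]
        if sp:
            y_parts.append(rng.integers(0, 4, sp, dtype=np.uint8))
            y_pos += sp
        region_map.append(
            RegionLabel(
                GenomicInterval("Y", first_gene_start, last_gene_end),
                "X-degenerate",
                region_names[seg_idx],
            )
        )

    def emit_family(fam: AmpliconFamily, fam_idx: int):
        nonlocal y_pos
        name = fam.name or f"FAM{fam_idx + 1}"
        unit = rng.integers(0, 4, fam.unit_length, dtype=np.uint8)
        lo, hi = fam.within_family_divergence
        copies = []
        for c in range(fam.copy_count):
            d = float(rng.uniform(lo, hi)) / 2.0
            mutated, _ = _mutate_codes(unit, d, 0.0, rng)
            copies.append(mutated)
        first = None
        last = None
        for c, codes in enumerate(copies, 1):
            gid = f"{name}_{c}"
            y_iv = GenomicInterval("Y", y_pos, y_pos + len(codes))
            y_genes.append(GeneModel(gid, y_iv, "", family_id=name))
            family_assignments[gid] = name
            if first is None:
                first = y_iv.start
            last = y_iv.end
            y_parts.append(codes)
            y_pos += len(codes)
            if c < len(copies):
                y_parts.append(rng.integers(0, 4, 500, dtype=np.uint8))
                y_pos += 500
        # realized pairwise identity between copies (substitution-only, so the
        # Hamming fraction IS the transcript identity)
        idents = [
            float(np.mean(copies[i] == copies[j]))
            for i in range(len(copies))
            for j in range(i + 1, len(copies))
        ]
        family_identity_ranges[name] = (min(idents), max(idents))
        region_map.append(
            RegionLabel(GenomicInterval("Y", first, last), "ampliconic", "ampliconic")
        )

    n_blocks = max(len(config.xdeg_segments), len(config.ampliconic_families))
    for i in range(n_blocks):
        if i < len(config.xdeg_segments):
            emit_xdeg(config.xdeg_segments[i], i)
        if i < len(config.ampliconic_families):
            emit_family(config.ampliconic_families[i], i)

    # background fill with Y-specific genes
    remaining = config.x_length - y_pos
    y_specific: list[str] = []
    if remaining > 0:
        bg = rng.integers(0, 4, remaining, dtype=np.uint8)
        if config.n_y_specific_genes:
            ys_starts = _place_intervals(
                rng, 0, remaining, config.n_y_specific_genes, glen
            )
            for i, s in enumerate(ys_starts, 1):
                gid = f"YSP_{i}"
                y_genes.append(GeneModel(gid, GenomicInterval("Y", y_pos + s, y_pos + s + glen), ""))
                y_specific.append(gid)
        y_parts.append(bg)
        y_pos += remaining

    y_codes = np.concatenate(y_parts)

    # assembly N-gap runs (overwrite, preserving coordinates)
    for pos, length in config.n_gap_runs:
        if pos + length > len(y_codes):
            raise ValueError("N-gap run outside the Y sequence")
        for g in y_genes:
            if g.interval.start < pos + length and pos < g.interval.end:
                raise ValueError("N-gap run overlaps a simulated gene")
        y_codes[pos : pos + length] = 4

    x_rec = SequenceRecord("X", decode(x_codes))
    y_rec = SequenceRecord("Y", decode(y_codes))
    for g in x_genes:
        g.sequence = x_rec.sequence[g.interval.start : g.interval.end]
    for g in y_genes:
        g.sequence = y_rec.sequence[g.interval.start : g.interval.end]
    x_genes.sort(key=lambda g: g.interval.start)
    y_genes.sort(key=lambda g: g.interval.start)

    # RH-style marker maps: independent marker sets, ranks in true order
    marker_tables = []
    for m in range(1, config.marker_maps + 1):
        positions = np.sort(
            rng.choice(len(y_codes), size=config.marker_count, replace=False)
        )
        marker_tables.append(
            pd.DataFrame(
                {
                    "marker_id": [f"RH{m}_m{i:03d}" for i in range(1, len(positions) + 1)],
                    "map_rank": np.arange(1, len(positions) + 1),
                    "map_units": np.round(positions / 20_000.0, 2),
                    "true_position": positions.astype(int),
                }
            )
        )

    # corrupted assembly for the QC stage
    corrupted: list[SequenceRecord] = []
    layout: Optional[LayoutTruth] = None
    if config.corruption_ops:
        corrupted, layout = corrupt_assembly(
            [y_rec], config.corruption_ops, seed=int(rng.integers(0, 2**31))
        )

    truth = SimulationTruth(
        pab_position=config.par_length,
        pab_position_y=len(ypar_codes),
        par_realized_identity=float(par_transcript.realized_identity),
        region_map=region_map,
        par_pairs=par_pairs,
        gametolog_pairs=gametolog_pairs,
        family_assignments=family_assignments,
        family_copy_numbers={
            f.name or f"FAM{i + 1}": f.copy_count
            for i, f in enumerate(config.ampliconic_families)
        },
        family_identity_ranges=family_identity_ranges,
        y_specific_genes=y_specific,
        marker_tables=marker_tables,
        gap_runs=list(config.n_gap_runs),
        layout=layout,
        applied_corruptions=list(config.corruption_ops),
    )
    return SimulationResult(
        x=x_rec,
        y=y_rec,
        x_genes=x_genes,
        y_genes=y_genes,
        marker_tables=marker_tables,
        corrupted_contigs=corrupted,
        truth=truth,
    )
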