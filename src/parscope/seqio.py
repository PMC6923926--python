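"""Sequence and annotation I/O with one internal coordinate convention.

All coordinates inside the package are 0-based, half-open. Conversion to and
from 1-based inclusive conventions (GFF3, BLAST tabular) happens only at the
format border, in this module and in :mod:`parscope.homology`.

Gaps are runs of literal ``N`` — the assembly-gap convention of deposited
chromosome sequences. Soft-masking (lowercase) carries no meaning here; input
is upper-cased on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_INVALID_RE = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.sequence = self.sequence.upper()
        m = _INVALID_RE.search(self.sequence)
        if m:
            raise FormatError(
                f"record {self.id!r}: invalid character {m.group()!r} at "
                f"position {m.start()} (only A, C, G, T, N are supported; "
                "IUPAC ambiguity codes are not)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GapRun:
    """A maximal run of N within a sequence."""

    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.span


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated, upper-cased records.

    Duplicate ids and non-ACGTN characters are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 80
) -> None:
    """Write records as FASTA with fixed line width (deterministic output)."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def count_gap_runs(record: SequenceRecord, min_len: int = 1) -> list[GapRun]:
    """Maximal N-runs of length >= min_len, sorted by start position."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    runs = []
    for m in re.finditer(r"N+", record.sequence):
        if m.end() - m.start() >= min_len:
            runs.append(GapRun(GenomicInterval(record.id, m.start(), m.end())))
    return runs


# --- GFF3 -------------------------------------------------------------------
#
# GFF3 is 1-based inclusive; genes are stored internally as [start-1, end).
# Only single-exon gene features are modelled (see docs/methods.md).


def read_gff3(path: str | Path):
    """Read gene features from GFF3 into GeneModel objects (without sequence).

    Returns a list of :class:`parscope.gametolog.GeneModel` with empty
    sequences; attach sequences from the corresponding FASTA with
    :func:`attach_gene_sequences`.
    """
    from gffutils.iterators import DataIterator

    from .gametolog import GeneModel

    genes = []
    for feat in DataIterator(str(path)):
        if feat.featuretype not in ("gene", "pseudogene"):
            continue
        if feat.end < feat.start:
            raise FormatError(
                f"{path}: feature end < start ({feat.start}..{feat.end})"
            )
        gene_id = feat.attributes.get("ID", [feat.id or ""])[0]
        if not gene_id:
            raise FormatError(f"{path}: gene feature without ID attribute")
        interval = GenomicInterval(
            feat.seqid, feat.start - 1, feat.end, feat.strand if feat.strand in "+-" else "."
        )
        family = feat.attributes.get("family", [None])[0]
        genes.append(GeneModel(id=gene_id, interval=interval, sequence="", family_id=family))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.id))
    return genes


def write_gff3(genes, path: str | Path, source: str = "parscope") -> None:
    """Write GeneModel objects as GFF3 gene features (1-based inclusive)."""
    genes = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            if g.family_id:
                attrs += f";family={g.family_id}"
            strand = g.interval.strand if g.interval.strand in "+-" else "."
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        source,
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def attach_gene_sequences(genes, records: Sequence[SequenceRecord]):
    """Fill gene sequences from their source records (in place; returns genes)."""
    by_id = {r.id: r for r in records}
    for g in genes:
        rec = by_id.get(g.interval.chrom)
        if rec is None:
            raise FormatError(f"gene {g.id!r}: no sequence named {g.interval.chrom!r}")
        if g.interval.end > len(rec):
            raise FormatError(f"gene {g.id!r} extends past end of {rec.id!r}")
        g.sequence = rec.sequence[g.interval.start : g.interval.end]
    return genes


# --- marker maps and BED ----------------------------------------------------

MARKER_COLUMNS = ["marker_id", "map_rank", "map_units", "true_position"]


def read_marker_tsv(path: str | Path) -> pd.DataFrame:
    """Read a marker-map TSV (marker_id, map_rank, map_units, position columns).

    map_rank must be strictly increasing — a marker map is an ordered list.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "map_rank"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    ranks = df["map_rank"].to_numpy()
    if len(ranks) and not (ranks[1:] > ranks[:-1]).all():
        raise FormatError(f"{path}: map_rank is not strictly increasing")
    if df["marker_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate marker ids")
    return df


def write_marker_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(labels, path: str | Path) -> None:
    """Write labelled intervals as BED (0-based half-open, name in column 4)."""
    rows = []
    for lab in labels:
        iv = lab.interval if hasattr(lab, "interval") else lab
        name = getattr(lab, "name", None) or getattr(lab, "klass", ".")
        rows.append((iv.chrom, iv.start, iv.end, name))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
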