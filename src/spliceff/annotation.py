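"""Gene annotation handling: GTF exon parsing and intron inference.

All coordinates are 0-based half-open internally.  GTF input (1-based
closed) and BED output (0-based half-open) are converted at the package
boundary, so every downstream position comparison (boundary-base coverage
in particular) is free of off-by-one ambiguity.

Introns are inferred per transcript as the gaps between consecutive exons
and then deduplicated *within a gene* by (chrom, start, end, strand).  Two
genes that happen to share coordinates keep separate intron models, because
gene-level efficiency aggregation needs gene ownership.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Gaps shorter than this are treated as annotation artifacts, not introns.
MIN_INTRON_LENGTH = 4


class GtfParseError(ValueError):
    """Raised for malformed GTF input (message names the offending line)."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _merge_overlapping(intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge strictly overlapping intervals; bookended intervals stay apart."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of exons on one chromosome/strand.

    ``exons`` is a tuple of 0-based half-open intervals sorted by start and
    pairwise non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon start {s} >= end {e}"
                )
            if s < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class IntronModel:
    """An intron, the unit at which retention is measured.

    ``start`` is the 0-based first intronic base and ``end`` is exclusive
    (``end - 1`` is the last intronic base).  The donor boundary base is the
    first intronic base at the transcript-5' end of the intron and the
    acceptor boundary base is the last intronic base at the 3' end; on the
    minus strand the two are reflected in genomic coordinates.
    """

    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.intron_id}")
        if self.end - self.start < MIN_INTRON_LENGTH:
            raise ValueError(
                f"intron {self.intron_id}: length {self.end - self.start} < "
                f"{MIN_INTRON_LENGTH}"
            )

    @property
    def donor_boundary_base(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor_boundary_base(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def make_intron_id(gene_id: str, chrom: str, start: int, end: int, strand: str) -> str:
    return f"{gene_id}:{chrom}:{start}-{end}:{strand}"


def parse_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file and build transcript models.

    Only ``exon`` features are consulted; each must carry ``gene_id`` and
    ``transcript_id`` attributes.  Exons overlapping within one transcript
    are merged; exons are never merged across transcripts.

    Raises
    ------
    GtfParseError
        For a missing required attribute or an exon with start > end; the
        message names the 1-based line number.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # transcript -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if start1 > end1:
                raise GtfParseError(f"line {lineno}: exon start {start1} > end {end1}")
            attr_map = dict(_ATTR_RE.findall(attrs))
            for required in ("gene_id", "transcript_id"):
                if required not in attr_map:
                    raise GtfParseError(f"line {lineno}: missing attribute {required}")
            tid = attr_map["transcript_id"]
            # GTF is 1-based closed -> 0-based half-open
            interval = (start1 - 1, end1)
            if tid in meta:
                gene, c, s = meta[tid]
                if (attr_map["gene_id"], chrom, strand) != (gene, c, s):
                    raise GtfParseError(
                        f"line {lineno}: transcript {tid} changes gene/chrom/strand"
                    )
            else:
                meta[tid] = (attr_map["gene_id"], chrom, strand)
            exons.setdefault(tid, []).append(interval)
    transcripts = []
    for tid, ivs in exons.items():
        gene, chrom, strand = meta[tid]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=_merge_overlapping(ivs),
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.span, t.transcript_id))
    return transcripts


def transcript_intron_intervals(transcript: TranscriptModel) -> list[tuple[int, int]]:
    """Gaps between consecutive exons of one transcript (may be length 0)."""
    out = []
    for (_, prev_end), (next_start, _) in zip(transcript.exons, transcript.exons[1:]):
        out.append((prev_end, next_start))
    return out


def infer_introns(
    transcripts: Iterable[TranscriptModel],
    min_length: int = MIN_INTRON_LENGTH,
) -> list[IntronModel]:
    """Infer the deduplicated per-gene intron set from transcript models.

    Zero-length gaps (bookended exons) and gaps shorter than ``min_length``
    are skipped with a warning.  Introns shared by several transcripts of
    one gene yield a single :class:`IntronModel`; the same coordinates under
    two different genes yield two.
    """
    seen: set[tuple[str, str, int, int, str]] = set()
    introns: list[IntronModel] = []
    n_skipped = 0
    for t in transcripts:
        for start, end in transcript_intron_intervals(t):
            if end - start < max(min_length, 1):
                n_skipped += 1
                logger.warning(
                    "skipping gap %s:%d-%d in %s (length %d < %d)",
                    t.chrom, start, end, t.transcript_id, end - start, min_length,
                )
                continue
            key = (t.gene_id, t.chrom, start, end, t.strand)
            if key in seen:
                continue
            seen.add(key)
            introns.append(
                IntronModel(
                    intron_id=make_intron_id(t.gene_id, t.chrom, start, end, t.strand),
                    gene_id=t.gene_id,
                    chrom=t.chrom,
                    strand=t.strand,
                    start=start,
                    end=end,
                )
            )
    if n_skipped:
        logger.info("skipped %d sub-minimal exon gaps", n_skipped)
    introns.sort(key=lambda i: (i.chrom, i.start, i.end, i.gene_id))
    return introns


def write_introns_bed(introns: Iterable[IntronModel], path: str | Path) -> None:
    """Write the intron set as BED6 (name = intron_id, score = 0)."""
    with open(path, "w") as fh:
        for i in introns:
            fh.write(f"{i.chrom}\t{i.start}\t{i.end}\t{i.intron_id}\t0\t{i.strand}\n")


def read_introns_bed(path: str | Path) -> list[IntronModel]:
    """Read a BED6 intron file written by :func:`write_introns_bed`."""
    introns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected BED6")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            gene_id = name.split(":", 1)[0]
            introns.append(
                IntronModel(
                    intron_id=name,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=int(start_s),
                    end=int(end_s),
                )
            )
    return introns
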