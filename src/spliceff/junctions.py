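"""Junction-read extraction and boundary-base coverage from alignments.

These are the two raw quantities of the splicing-efficiency statistic:

* junction reads ("transreads"): reads whose CIGAR carries one or more N
  (skipped-region) operations; each N interval is one exon-exon gap and
  evidence of a completed splicing event;
* boundary coverage: the number of reads placing an aligned base on the
  first intronic base at each end of an intron.  In error-free data these
  bases are covered only by retention reads, so the two counts separate
  spliced from unspliced transcripts cleanly.

A read with k N operations contributes to k junctions.  Secondary,
supplementary, duplicate and unmapped records are excluded everywhere.
For paired data, fragments are counted once: overlapping mates are
deduplicated by read name at each junction and each boundary base.

The minimum anchor (aligned bases required on each side of a gap) defaults
to 1 — the weakest possible, since any junction alignment has at least one
aligned base per side.  Larger anchors (Regtools uses 8) guard against
spurious spliced alignments in real data, but they censor junction
evidence relative to boundary coverage and bias the efficiency and PSI
estimators; see the methods note.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .annotation import IntronModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR = 1

_REF_COVERING = {0, 2, 7, 8}  # M, D, =, X consume reference and cover it (N does not)
_QUERY_ALIGNED = {0, 7, 8}  # M, =, X


@dataclass(frozen=True)
class JunctionCount:
    """One distinct N-gap with its supporting read count."""

    chrom: str
    gap_start: int
    gap_end: int
    count: int
    matched_intron_id: str | None = None

    @property
    def novel(self) -> bool:
        return self.matched_intron_id is None


@dataclass(frozen=True)
class SiteQuant:
    """Raw evidence at one splice site of one intron.

    ``transread_count`` is the number of junction reads whose gap equals
    the intron exactly; ``boundary_coverage`` counts reads with an aligned
    reference base on the site's boundary position (reads whose N-gap
    spans the position do not contribute; deletions do).
    """

    intron_id: str
    site: str  # "donor" or "acceptor"
    transread_count: int
    boundary_coverage: int

    def __post_init__(self) -> None:
        if self.site not in ("donor", "acceptor"):
            raise ValueError(f"invalid site {self.site!r}")
        if self.transread_count < 0 or self.boundary_coverage < 0:
            raise ValueError("negative counts")


def _open_alignments(alignments) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments, False
    return pysam.AlignmentFile(str(alignments)), True


def _iter_filtered(
    af: pysam.AlignmentFile, min_mapq: int
) -> Iterator[pysam.AlignedSegment]:
    n_skipped = 0
    for read in af:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapping_quality < min_mapq
        ):
            continue
        if read.cigartuples is None:
            n_skipped += 1
            logger.error("read %s has no CIGAR; skipped", read.query_name)
            continue
        yield read
    if n_skipped:
        logger.info("skipped %d records without CIGAR", n_skipped)


def cigar_gaps(
    cigartuples: Sequence[tuple[int, int]], pos: int
) -> list[tuple[int, int, int, int]]:
    """N-gap intervals of one alignment with flanking anchor sizes.

    Returns ``(gap_start, gap_end, left_anchor, right_anchor)`` per N
    operation, where anchors count query-aligned (M/=/X) bases between the
    gap and the nearest neighbouring gap or read end.
    """
    gaps: list[list[int]] = []
    ref = pos
    aligned_since_gap = 0
    for op, length in cigartuples:
        if op == 3:  # N
            if gaps:
                gaps[-1][3] = aligned_since_gap
            gaps.append([ref, ref + length, aligned_since_gap, 0])
            aligned_since_gap = 0
            ref += length
        else:
            if op in _QUERY_ALIGNED:
                aligned_since_gap += length
            if op in _REF_COVERING:
                ref += length
    if gaps:
        gaps[-1][3] = aligned_since_gap
    return [tuple(g) for g in gaps]  # type: ignore[return-value]


def covered_intervals(
    cigartuples: Sequence[tuple[int, int]], pos: int
) -> list[tuple[int, int]]:
    """Maximal reference intervals covered by M/=/X/D (N splits, D joins)."""
    out: list[list[int]] = []
    ref = pos
    for op, length in cigartuples:
        if op in _REF_COVERING:
            if out and out[-1][1] == ref:
                out[-1][1] = ref + length
            else:
                out.append([ref, ref + length])
            ref += length
        elif op == 3:
            ref += length
    return [(s, e) for s, e in out]


def extract_junctions(
    alignments,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_mapq: int = 0,
) -> list[JunctionCount]:
    """Count distinct N-gaps over a SAM/BAM stream.

    A read contributes one count per N operation whose flanking anchors
    are both >= ``min_anchor`` aligned bases.  Paired fragments count once
    per gap (mate dedup by read name).
    """
    af, close = _open_alignments(alignments)
    counts: dict[tuple[str, int, int], int] = {}
    seen_pairs: dict[tuple[str, int, int], set[str]] = {}
    try:
        for read in _iter_filtered(af, min_mapq):
            chrom = read.reference_name
            for gs, ge, left, right in cigar_gaps(
                read.cigartuples, read.reference_start
            ):
                if left < min_anchor or right < min_anchor:
                    continue
                key = (chrom, gs, ge)
                if read.is_paired:
                    names = seen_pairs.setdefault(key, set())
                    if read.query_name in names:
                        continue
                    names.add(read.query_name)
                counts[key] = counts.get(key, 0) + 1
    finally:
        if close:
            af.close()
    return [
        JunctionCount(chrom=c, gap_start=s, gap_end=e, count=n)
        for (c, s, e), n in sorted(counts.items())
    ]


def boundary_coverage(
    alignments,
    introns: Iterable[IntronModel],
    min_mapq: int = 0,
) -> dict[tuple[str, str], int]:
    """Read coverage at the donor and acceptor boundary bases of introns.

    Returns ``{(intron_id, site): coverage}`` with site in
    {"donor", "acceptor"}.  A read covers a position if an M/=/X/D segment
    of its alignment spans it; N-gaps do not cover.  Introns on contigs
    absent from the alignment header get coverage 0 with a warning.
    """
    introns = list(introns)
    af, close = _open_alignments(alignments)
    try:
        refs = set(af.references or ())
        slots: dict[tuple[str, str], int] = {}
        by_chrom: dict[str, list[tuple[int, tuple[str, str]]]] = {}
        for intron in introns:
            for site, base in (
                ("donor", intron.donor_boundary_base),
                ("acceptor", intron.acceptor_boundary_base),
            ):
                key = (intron.intron_id, site)
                slots[key] = 0
                if intron.chrom not in refs:
                    continue
                by_chrom.setdefault(intron.chrom, []).append((base, key))
        for intron in introns:
            if intron.chrom not in refs:
                logger.warning(
                    "intron %s on contig %s absent from alignment header",
                    intron.intron_id, intron.chrom,
                )
        pos_arrays = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            pos_arrays[chrom] = (
                np.array([p for p, _ in pairs], dtype=int),
                [k for _, k in pairs],
            )
        seen_pairs: dict[tuple[str, str], set[str]] = {}
        for read in _iter_filtered(af, min_mapq):
            entry = pos_arrays.get(read.reference_name)
            if entry is None:
                continue
            positions, keys = entry
            for s, e in covered_intervals(read.cigartuples, read.reference_start):
                i = int(np.searchsorted(positions, s, side="left"))
                while i < len(positions) and positions[i] < e:
                    key = keys[i]
                    if read.is_paired:
                        names = seen_pairs.setdefault(key, set())
                        if read.query_name in names:
                            i += 1
                            continue
                        names.add(read.query_name)
                    slots[key] += 1
                    i += 1
    finally:
        if close:
            af.close()
    return slots


def match_junctions_to_introns(
    junctions: Iterable[JunctionCount],
    introns: Iterable[IntronModel],
) -> list[JunctionCount]:
    """Assign junctions to introns by exact interval equality.

    A junction matches an intron iff its gap equals the intron interval at
    both ends; unmatched junctions are retained with
    ``matched_intron_id=None`` (novel).  When several genes share an
    intron interval, the lexicographically first intron_id is recorded.
    """
    lookup: dict[tuple[str, int, int], str] = {}
    for intron in sorted(introns, key=lambda i: i.intron_id):
        lookup.setdefault((intron.chrom, intron.start, intron.end), intron.intron_id)
    return [
        replace(j, matched_intron_id=lookup.get((j.chrom, j.gap_start, j.gap_end)))
        for j in junctions
    ]


def quantify_sample(
    alignments,
    introns: Iterable[IntronModel],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_mapq: int = 0,
) -> tuple[list[SiteQuant], list[JunctionCount]]:
    """Full per-sample quantification: SiteQuants plus the junction list.

    The junction list has ``matched_intron_id`` set; the SiteQuant list
    carries one donor and one acceptor record per intron (transread counts
    at the two sites of one intron are equal by construction — both equal
    the exact-gap junction count).
    """
    introns = list(introns)
    junctions = match_junctions_to_introns(
        extract_junctions(alignments, min_anchor=min_anchor, min_mapq=min_mapq),
        introns,
    )
    coverage = boundary_coverage(alignments, introns, min_mapq=min_mapq)
    by_interval: dict[tuple[str, int, int], int] = {
        (j.chrom, j.gap_start, j.gap_end): j.count for j in junctions
    }
    quants = []
    for intron in introns:
        tr = by_interval.get((intron.chrom, intron.start, intron.end), 0)
        for site in ("donor", "acceptor"):
            quants.append(
                SiteQuant(
                    intron_id=intron.intron_id,
                    site=site,
                    transread_count=tr,
                    boundary_coverage=coverage[(intron.intron_id, site)],
                )
            )
    return quants, junctions


def write_junctions_tsv(junctions: Iterable[JunctionCount], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tgap_start\tgap_end\tcount\tmatched_intron_id\tnovel\n")
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.gap_start}\t{j.gap_end}\t{j.count}\t"
                f"{j.matched_intron_id or '.'}\t{int(j.novel)}\n"
            )
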