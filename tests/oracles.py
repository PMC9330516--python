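"""Independent brute-force oracles used to check the package.

Everything here re-derives quantities from raw SAM text (or raw
sequences) with the most naive possible algorithm and no imports from the
package's quantification code paths.
"""
from __future__ import annotations

import re
from collections import Counter

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_sam_text(path):
    """Yield (qname, flag, rname, pos0, mapq, cigar_ops) per alignment line.

    cigar_ops is a list of (length, op_char).
    """
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            ops = [(int(n), c) for n, c in _CIGAR_RE.findall(f[5])]
            yield f[0], int(f[1]), f[2], int(f[3]) - 1, int(f[4]), ops


def read_gaps(pos0, ops, min_anchor):
    """Every N interval of one read whose flanking M/=/X anchors qualify."""
    gaps = []
    # positions of N ops with anchors counted by scanning left/right
    segments = []  # (kind, ref_start, ref_end, aligned_len)
    ref = pos0
    for length, op in ops:
        if op in "M=X":
            segments.append(("M", ref, ref + length, length))
            ref += length
        elif op == "D":
            segments.append(("D", ref, ref + length, 0))
            ref += length
        elif op == "N":
            segments.append(("N", ref, ref + length, 0))
            ref += length
        # I, S, H, P consume no reference
    for i, (kind, s, e, _) in enumerate(segments):
        if kind != "N":
            continue
        left = 0
        for j in range(i - 1, -1, -1):
            if segments[j][0] == "N":
                break
            left += segments[j][3]
        right = 0
        for j in range(i + 1, len(segments)):
            if segments[j][0] == "N":
                break
            right += segments[j][3]
        if left >= min_anchor and right >= min_anchor:
            gaps.append((s, e))
    return gaps


def read_covered_positions(pos0, ops):
    """Set of reference positions covered by M/=/X/D of one read."""
    covered = set()
    ref = pos0
    for length, op in ops:
        if op in "M=XD":
            covered.update(range(ref, ref + length))
            ref += length
        elif op == "N":
            ref += length
    return covered


def _use_read(flag, mapq, min_mapq):
    # unmapped 0x4, secondary 0x100, dup 0x400, supplementary 0x800
    return not (flag & (0x4 | 0x100 | 0x400 | 0x800)) and mapq >= min_mapq


def junction_counts_oracle(path, min_anchor=1, min_mapq=0):
    """Brute-force transread counts: {(rname, gap_start, gap_end): count}."""
    counts = Counter()
    for _q, flag, rname, pos0, mapq, ops in parse_sam_text(path):
        if not _use_read(flag, mapq, min_mapq):
            continue
        for gap in read_gaps(pos0, ops, min_anchor):
            counts[(rname, *gap)] += 1
    return dict(counts)


def coverage_oracle(path, positions, min_mapq=0):
    """Naive pileup at selected positions: {(rname, pos): depth}.

    ``positions`` is an iterable of (rname, pos) pairs.
    """
    wanted = set(positions)
    depth = {p: 0 for p in wanted}
    for _q, flag, rname, pos0, mapq, ops in parse_sam_text(path):
        if not _use_read(flag, mapq, min_mapq):
            continue
        for p in read_covered_positions(pos0, ops):
            if (rname, p) in wanted:
                depth[(rname, p)] += 1
    return depth


def iupac_scan_oracle(sequence, pattern, table):
    """Sliding-window degenerate match offsets (both args RNA upper-case)."""
    m = len(pattern)
    out = []
    for i in range(len(sequence) - m + 1):
        if all(sequence[i + j] in table[pattern[j]] for j in range(m)):
            out.append(i)
    return out


def pwm_scan_oracle(sequence, logodds, threshold_abs):
    """Window offsets with summed log-odds >= absolute threshold."""
    m = len(logodds)
    index = {"A": 0, "C": 1, "G": 2, "U": 3}
    out = []
    for i in range(len(sequence) - m + 1):
        window = sequence[i : i + m]
        if any(b not in index for b in window):
            continue
        score = sum(logodds[j][index[window[j]]] for j in range(m))
        if score >= threshold_abs - 1e-12:
            out.append(i)
    return out


def dinucleotide_counts(sequence):
    return Counter(zip(sequence, sequence[1:]))
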