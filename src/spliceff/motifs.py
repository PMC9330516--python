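"""Intron sequence retrieval and RNA-binding-motif scanning.

Motifs are user input — an IUPAC degenerate string or a position-weight
matrix over ACGU — because consensus binding sequences of RNA-binding
proteins are figure-level knowledge, not something this package should
invent.  Scanning is sense-strand only by default (an RBP binds the
pre-mRNA, not its reverse complement).

PWM scanning scores each window by log-odds against a uniform 0.25
background and reports windows whose *relative* score

    (score - min_score) / (max_score - min_score)

reaches ``score_threshold``: threshold 1.0 keeps only maximal-score
windows (for an indicator PWM this reduces exactly to the IUPAC scan) and
threshold 0.0 keeps every window.

Enrichment against background is assessed with dinucleotide-preserving
shuffles (Altschul-Erikson): local composition inflates naive
mononucleotide nulls, so shuffles preserve the exact dinucleotide counts.
The empirical p uses the add-one estimator and is therefore always in
(0, 1].
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from numpy.random import Generator, default_rng

from .annotation import IntronModel

_ALPHABET = "ACGU"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT_DNA = str.maketrans("ACGTNacgtn", "TGCANtgcan")
#: Pseudo-probability added to PWM columns before taking logs, so that an
#: indicator column keeps a finite (hugely negative) mismatch score and
#: relative scores stay well defined.
_PWM_EPS = 1e-6

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


class MotifError(ValueError):
    """Invalid motif specification."""


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MotifSpec:
    """A motif as an IUPAC string or a PWM (rows = positions over ACGU)."""

    motif_id: str
    iupac: str | None = None
    pwm: tuple[tuple[float, ...], ...] | None = None
    score_threshold: float = 0.8

    def __post_init__(self) -> None:
        if (self.iupac is None) == (self.pwm is None):
            raise MotifError("exactly one of iupac or pwm must be given")
        if self.iupac is not None:
            normalized = _normalize_rna(self.iupac)
            object.__setattr__(self, "iupac", normalized)
            bad = set(normalized) - set(IUPAC)
            if bad:
                raise MotifError(f"invalid IUPAC symbols: {sorted(bad)}")
            if not normalized:
                raise MotifError("empty motif")
        else:
            mat = np.asarray(self.pwm, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] == 0:
                raise MotifError("pwm must be a non-empty (length x 4) matrix")
            if np.any(mat < 0):
                raise MotifError("pwm probabilities must be non-negative")
            if np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
                raise MotifError("pwm columns must sum to 1 within 1e-9")
            object.__setattr__(self, "pwm", tuple(tuple(row) for row in mat))
        if not 0.0 <= self.score_threshold <= 1.0:
            raise MotifError("score_threshold must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.iupac) if self.iupac is not None else len(self.pwm)

    @property
    def mode(self) -> str:
        return "iupac" if self.iupac is not None else "pwm"


def load_motif(path: str | Path) -> MotifSpec:
    """Read a motif JSON file ({motif_id, iupac} or {motif_id, pwm, ...})."""
    with open(path) as fh:
        data = json.load(fh)
    return MotifSpec(
        motif_id=data.get("motif_id", Path(path).stem),
        iupac=data.get("iupac"),
        pwm=tuple(map(tuple, data["pwm"])) if "pwm" in data else None,
        score_threshold=float(data.get("score_threshold", 0.8)),
    )


@dataclass(frozen=True)
class MotifHit:
    """One motif match inside an intron's sense-strand sequence."""

    intron_id: str
    offset: int  # 0-based within the sense-strand intron sequence
    matched_seq: str
    score: float


def extract_intron_sequence(fasta, intron: IntronModel) -> str:
    """RNA-sense sequence of an intron from a genome FASTA.

    Fetches [start, end) on the genome, reverse-complements for minus-
    strand introns, and reports in RNA alphabet (T -> U).
    """
    close = False
    if not isinstance(fasta, pysam.FastaFile):
        fasta = pysam.FastaFile(str(fasta))
        close = True
    try:
        if intron.chrom not in fasta.references:
            raise ValueError(f"contig {intron.chrom!r} absent from FASTA")
        if intron.end > fasta.get_reference_length(intron.chrom):
            raise ValueError(
                f"intron {intron.chrom}:{intron.start}-{intron.end} exceeds contig"
            )
        seq = fasta.fetch(intron.chrom, intron.start, intron.end).upper()
    finally:
        if close:
            fasta.close()
    if intron.strand == "-":
        seq = seq.translate(_COMPLEMENT_DNA)[::-1]
    return seq.replace("T", "U")


def scan_iupac(sequence: str, motif: MotifSpec, intron_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) degenerate matches, ascending offset."""
    if motif.mode != "iupac":
        raise MotifError("scan_iupac requires an IUPAC motif")
    seq = _normalize_rna(sequence)
    m = len(motif)
    sets = [set(IUPAC[sym]) for sym in motif.iupac]
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if all(base in allowed for base, allowed in zip(window, sets)):
            hits.append(MotifHit(intron_id, i, window, 1.0))
    return hits


def _pwm_logodds(motif: MotifSpec) -> np.ndarray:
    mat = np.asarray(motif.pwm, dtype=float)
    mat = (mat + _PWM_EPS) / (1.0 + 4 * _PWM_EPS)
    return np.log2(mat / 0.25)


def scan_pwm(sequence: str, motif: MotifSpec, intron_id: str = "") -> list[MotifHit]:
    """Log-odds PWM scan with a relative-score threshold."""
    if motif.mode != "pwm":
        raise MotifError("scan_pwm requires a PWM motif")
    seq = _normalize_rna(sequence)
    m = len(motif)
    if len(seq) < m:
        return []
    logodds = _pwm_logodds(motif)
    max_score = float(logodds.max(axis=1).sum())
    min_score = float(logodds.min(axis=1).sum())
    span = max_score - min_score
    idx = np.array([_INDEX.get(b, -1) for b in seq])
    hits = []
    for i in range(len(seq) - m + 1):
        window_idx = idx[i : i + m]
        if np.any(window_idx < 0):  # ambiguous base: never a hit
            continue
        score = float(logodds[np.arange(m), window_idx].sum())
        rel = 1.0 if span == 0 else (score - min_score) / span
        if rel >= motif.score_threshold - 1e-12:
            hits.append(MotifHit(intron_id, i, seq[i : i + m], score))
    return hits


def scan_motif(sequence: str, motif: MotifSpec, intron_id: str = "") -> list[MotifHit]:
    """Dispatch to the IUPAC or PWM scanner according to the motif mode."""
    if motif.mode == "iupac":
        return scan_iupac(sequence, motif, intron_id)
    return scan_pwm(sequence, motif, intron_id)


def dinucleotide_shuffle(sequence: str, rng: Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul-Erikson shuffle: build the multigraph whose edges are the
    observed dinucleotides, pick a random set of "last exit" edges forming
    a tree into the terminal vertex (guaranteeing an Eulerian walk exists),
    shuffle the remaining edges per vertex and read off the walk.  First
    and last characters are preserved.
    """
    seq = sequence
    n = len(seq)
    if n < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        # every vertex must reach the terminal by following last edges
        ok = True
        for v in vertices:
            cur, steps = v, 0
            while cur != last and steps <= len(vertices) + 1:
                cur = last_edge.get(cur, last)
                steps += 1
            if cur != last:
                ok = False
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[i] for i in perm]
        if v in last_edge:
            ordered.append(last_edge[v])
        shuffled[v] = ordered
    out = [seq[0]]
    cursors = {v: 0 for v in shuffled}
    cur = seq[0]
    for _ in range(n - 1):
        nxt = shuffled[cur][cursors[cur]]
        cursors[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass(frozen=True)
class EnrichmentResult:
    observed_hits: int
    p_value: float
    n_shuffles: int
    shuffle_mean: float


def motif_enrichment(
    sequences: Mapping[str, str],
    motif: MotifSpec,
    n_shuffles: int = 500,
    seed: int = 0,
) -> EnrichmentResult:
    """Empirical enrichment p of a motif over an intron sequence set.

    The total hit count over all sequences is compared with the counts in
    ``n_shuffles`` dinucleotide-preserving shuffles of each sequence;
    p = (1 + #{shuffles >= observed}) / (1 + n_shuffles).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    normalized = {k: _normalize_rna(v) for k, v in sequences.items()}
    observed = sum(len(scan_motif(s, motif, k)) for k, s in normalized.items())
    rng = default_rng(seed)
    ge = 0
    total = 0.0
    for _ in range(n_shuffles):
        count = sum(
            len(scan_motif(dinucleotide_shuffle(s, rng), motif))
            for s in normalized.values()
        )
        total += count
        if count >= observed:
            ge += 1
    return EnrichmentResult(
        observed_hits=observed,
        p_value=(1 + ge) / (1 + n_shuffles),
        n_shuffles=n_shuffles,
        shuffle_mean=total / n_shuffles,
    )


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("intron_id\toffset\tmatched_seq\tscore\n")
        for h in hits:
            fh.write(f"{h.intron_id}\t{h.offset}\t{h.matched_seq}\t{h.score:.6g}\n")
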