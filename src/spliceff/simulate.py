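"""Synthetic RNA-seq with known per-intron retention fractions.

The generator emits a toy genome (FASTA), its exon annotation (GTF),
coordinate-sorted error-free alignments (SAM, one file per sample) and a
ground-truth table, so the whole quantification pipeline is testable
without any external download.

Generative model
----------------
Each gene carries ``introns_per_gene`` introns separating equal-length
exons.  Per condition and replicate, a fixed pool of ``molecules_per_gene``
pre-mRNA molecules is drawn for every gene; each molecule independently
retains each intron with probability ``psi`` (the per-replicate effective
value after logit-scale dispersion noise).  Sequencing fragments start
uniformly over every valid position of every molecule, so a molecule
contributes reads in proportion to its length, exactly as uniform
fragmentation of a transcript pool would.  Reads are emitted directly as
primary, MAPQ-60, error-free alignments: a read crossing a spliced
junction carries an N-gap CIGAR spanning exactly the intron, a read from a
retained molecule aligns contiguously (M) through the intron.

Two conditions x 3 replicates, retention increasing in the "knockdown"
condition, depth in the 50-200x range, uniform fragment starts and no
sequencing error are the default study conditions.

A count-level companion (:func:`simulate_intron_counts`) draws boundary
coverage and junction counts directly from the same Poisson rates; it is
used for large repeat studies (test power and size) where emitting and
re-parsing millions of SAM records would add nothing but runtime.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from scipy.special import expit, logit

from .annotation import make_intron_id

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``depth`` is the mean read coverage per transcript base (a value of 100
    means each expressed base is covered by ~100 reads).  ``psi_map`` maps
    each condition name to its retention fraction(s): a scalar applied to
    every intron, a per-gene sequence, or an (n_genes, introns_per_gene)
    array.  ``dispersion`` adds replicate-level noise: psi is perturbed on
    the logit scale with this standard deviation and per-gene depth is
    scaled by a mean-1 gamma variate with this coefficient of variation.
    ``depth_multipliers`` optionally scales per-gene expression per
    condition (the hook for simulating differential expression).
    """

    n_genes: int = 20
    introns_per_gene: int = 2
    exon_len: int = 200
    intron_len: int = 150
    read_len: int = 150
    depth: float = 100.0
    psi_map: Mapping[str, object] = field(
        default_factory=lambda: {"control": 0.1, "knockdown": 0.3}
    )
    replicates: int = 3
    dispersion: float = 0.1
    seed: int = 0
    molecules_per_gene: int = 300
    depth_multipliers: Mapping[str, Sequence[float]] | None = None
    spacer_len: int = 300
    chrom: str = "simchr"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.introns_per_gene < 1:
            raise SimConfigError("need at least one gene and one intron per gene")
        if self.read_len >= self.exon_len:
            raise SimConfigError("read_len must be smaller than exon_len")
        if self.depth <= 0:
            raise SimConfigError("depth must be positive")
        if self.replicates < 1:
            raise SimConfigError("need at least one replicate")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be non-negative")
        if self.molecules_per_gene < 1:
            raise SimConfigError("molecules_per_gene must be positive")
        if not self.psi_map:
            raise SimConfigError("psi_map must name at least one condition")
        for cond in self.psi_map:
            arr = self.psi_array(cond)
            if np.any(arr < 0) or np.any(arr > 1):
                raise SimConfigError(f"psi outside [0,1] for condition {cond!r}")

    @property
    def conditions(self) -> list[str]:
        return list(self.psi_map)

    def psi_array(self, condition: str) -> np.ndarray:
        """Per-intron retention fractions, shape (n_genes, introns_per_gene)."""
        raw = np.asarray(self.psi_map[condition], dtype=float)
        if raw.ndim == 0:
            raw = np.full((self.n_genes, self.introns_per_gene), float(raw))
        elif raw.ndim == 1:
            if raw.shape[0] != self.n_genes:
                raise SimConfigError(
                    f"per-gene psi for {condition!r} must have length n_genes"
                )
            raw = np.repeat(raw[:, None], self.introns_per_gene, axis=1)
        elif raw.shape != (self.n_genes, self.introns_per_gene):
            raise SimConfigError(
                f"psi array for {condition!r} must be (n_genes, introns_per_gene)"
            )
        return raw

    def multiplier_array(self, condition: str) -> np.ndarray:
        if self.depth_multipliers is None or condition not in self.depth_multipliers:
            return np.ones(self.n_genes)
        arr = np.asarray(self.depth_multipliers[condition], dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.n_genes, float(arr))
        if arr.shape != (self.n_genes,):
            raise SimConfigError("depth multiplier must be scalar or per-gene")
        if np.any(arr < 0):
            raise SimConfigError("depth multipliers must be non-negative")
        return arr

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]


@dataclass(frozen=True)
class SimTruth:
    """Realized ground truth for one intron in one sample.

    ``true_psi`` is the realized fraction of the molecule pool retaining
    the intron.  ``n_spliced_reads`` counts emitted junction-spanning
    reads; ``n_retained_reads`` counts emitted reads overlapping any base
    of the intron body; ``n_cov_donor``/``n_cov_acceptor`` count reads
    placing an aligned base on the two boundary bases.  The fraction
    mean(n_cov_donor, n_cov_acceptor) / (mean + n_spliced_reads) converges
    to true_psi as depth grows.
    """

    intron_id: str
    gene_id: str
    condition: str
    replicate: int
    nominal_psi: float
    true_psi: float
    n_spliced_reads: int
    n_retained_reads: int
    n_cov_donor: int
    n_cov_acceptor: int


@dataclass
class SimResult:
    """Paths and in-memory tables produced by :func:`simulate_dataset`."""

    fasta_path: Path
    gtf_path: Path
    sam_paths: dict[str, Path]  # sample name -> SAM
    truth_path: Path
    counts_path: Path
    truth: pd.DataFrame
    counts: pd.DataFrame
    sample_conditions: dict[str, str]


# ---------------------------------------------------------------------------
# Gene layout and genome


def _gene_span(config: SimConfig) -> int:
    k = config.introns_per_gene
    return (k + 1) * config.exon_len + k * config.intron_len


def gene_structures(config: SimConfig) -> list[dict]:
    """Deterministic gene layout: alternating strands along one chromosome."""
    genes = []
    pos = config.spacer_len
    span = _gene_span(config)
    for g in range(config.n_genes):
        exons = []
        cursor = pos
        for _ in range(config.introns_per_gene + 1):
            exons.append((cursor, cursor + config.exon_len))
            cursor += config.exon_len + config.intron_len
        introns = [
            (e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])
        ]
        genes.append(
            {
                "gene_id": f"G{g + 1:03d}",
                "transcript_id": f"G{g + 1:03d}.T1",
                "strand": "+" if g % 2 == 0 else "-",
                "exons": exons,
                "introns": introns,
                "start": pos,
                "end": pos + span,
            }
        )
        pos += span + config.spacer_len
    return genes


def _genome_length(config: SimConfig) -> int:
    return config.spacer_len + config.n_genes * (_gene_span(config) + config.spacer_len)


def _build_genome(config: SimConfig) -> str:
    rng = default_rng([config.seed, 101])
    n = _genome_length(config)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def write_fasta(sequence: str, chrom: str, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def write_gtf(genes: Sequence[dict], chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for s, e in gene["exons"]:
                attrs = (
                    f'gene_id "{gene["gene_id"]}"; '
                    f'transcript_id "{gene["transcript_id"]}";'
                )
                fh.write(
                    f"{chrom}\tspliceff_sim\texon\t{s + 1}\t{e}\t.\t"
                    f"{gene['strand']}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Replicate perturbation


def perturb_replicates(config: SimConfig) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    """Per-replicate effective psi and depth factors.

    psi is perturbed on the logit scale with standard deviation
    ``dispersion`` (values of exactly 0 or 1 are left untouched); per-gene
    depth is scaled by a mean-1 gamma variate with coefficient of variation
    ``dispersion``.  With ``dispersion == 0`` all replicates are identical.

    Returns a mapping ``(condition, replicate) -> {"psi": (n_genes, k)
    array, "depth_factor": (n_genes,) array}`` with replicates numbered
    from 1.
    """
    rng = default_rng([config.seed, 202])
    d = config.dispersion
    out: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for cond in config.conditions:
        base = config.psi_array(cond)
        for rep in range(1, config.replicates + 1):
            z = rng.standard_normal(base.shape)
            interior = (base > 0) & (base < 1)
            psi = base.copy()
            if d > 0:
                psi[interior] = expit(logit(base[interior]) + d * z[interior])
                shape = 1.0 / d**2
                depth_factor = rng.gamma(shape, scale=1.0 / shape, size=config.n_genes)
            else:
                depth_factor = np.ones(config.n_genes)
            out[(cond, rep)] = {"psi": psi, "depth_factor": depth_factor}
    return out


# ---------------------------------------------------------------------------
# Read emission


def _pattern_layout(gene: dict, bits: tuple[int, ...], genome: str, read_len: int) -> dict:
    """Template layout for one retention pattern of one gene.

    Returns merged genomic blocks, the template sequence, per-intron
    template offsets (junction offsets for spliced introns, [start, end)
    spans for retained ones) and the template length.
    """
    blocks: list[list[int]] = []
    for idx, (s, e) in enumerate(gene["exons"]):
        if blocks and blocks[-1][1] == s:
            blocks[-1][1] = e
        else:
            blocks.append([s, e])
        if idx < len(gene["introns"]) and bits[idx]:
            i_s, i_e = gene["introns"][idx]
            # retained intron is contiguous with the exon just added
            blocks[-1][1] = i_e
    # template offsets
    junction_offsets: dict[int, int] = {}
    retained_spans: dict[int, tuple[int, int]] = {}
    offset = gene["exons"][0][1] - gene["exons"][0][0]
    for idx, (i_s, i_e) in enumerate(gene["introns"]):
        if bits[idx]:
            retained_spans[idx] = (offset, offset + (i_e - i_s))
            offset += i_e - i_s
        else:
            junction_offsets[idx] = offset
        ex_s, ex_e = gene["exons"][idx + 1]
        offset += ex_e - ex_s
    template = "".join(genome[s:e] for s, e in blocks)
    return {
        "blocks": [(s, e) for s, e in blocks],
        "template": template,
        "length": len(template),
        "junction_offsets": junction_offsets,
        "retained_spans": retained_spans,
        "cumlen": np.cumsum([e - s for s, e in blocks]),
    }


def _read_alignment(layout: dict, start: int, read_len: int) -> tuple[int, str]:
    """Map a template start to (genomic 0-based pos, CIGAR)."""
    cumlen = layout["cumlen"]
    blocks = layout["blocks"]
    bi = int(np.searchsorted(cumlen, start, side="right"))
    within = start - (cumlen[bi - 1] if bi else 0)
    pos = blocks[bi][0] + within
    remaining = read_len
    parts: list[str] = []
    cur = pos
    while remaining > 0:
        bs, be = blocks[bi]
        take = min(remaining, be - cur)
        parts.append(f"{take}M")
        remaining -= take
        cur += take
        if remaining > 0:
            bi += 1
            gap = blocks[bi][0] - cur
            parts.append(f"{gap}N")
            cur = blocks[bi][0]
    return pos, "".join(parts)


def _count_in_window(starts: np.ndarray, lo: int, hi: int) -> int:
    """Number of start positions in the closed window [lo, hi]."""
    return int(np.count_nonzero((starts >= lo) & (starts <= hi)))


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate genome, annotation, alignments and truth for one study.

    Writes ``genome.fa``, ``annotation.gtf``, one ``<condition>_rep<k>.sam``
    per sample, ``truth.tsv`` and ``counts.tsv`` into ``out_dir``.  The
    same config (including seed) produces byte-identical output.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = _build_genome(config)
    genes = gene_structures(config)
    fasta_path = out / "genome.fa"
    gtf_path = out / "annotation.gtf"
    write_fasta(genome, config.chrom, fasta_path)
    write_gtf(genes, config.chrom, gtf_path)

    perturbed = perturb_replicates(config)
    rng = default_rng([config.seed, 303])
    L = config.read_len
    k = config.introns_per_gene
    patterns = [tuple((j >> i) & 1 for i in range(k)) for j in range(2**k)]
    qual = "I" * L

    # per-gene pattern layouts are pattern-dependent but replicate-independent
    layouts = [
        {bits: _pattern_layout(gene, bits, genome, L) for bits in patterns}
        for gene in genes
    ]

    truth_rows: list[SimTruth] = []
    counts: dict[str, dict[str, int]] = {}
    sam_paths: dict[str, Path] = {}
    sample_conditions: dict[str, str] = {}
    header = f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{config.chrom}\tLN:{len(genome)}\n"

    for cond in config.conditions:
        nominal = config.psi_array(cond)
        mult = config.multiplier_array(cond)
        for rep in range(1, config.replicates + 1):
            sample = f"{cond}_rep{rep}"
            sample_conditions[sample] = cond
            params = perturbed[(cond, rep)]
            positions: list[int] = []
            cigars: list[str] = []
            seqs: list[str] = []
            counts[sample] = {}
            for g, gene in enumerate(genes):
                psi_g = params["psi"][g]
                M = config.molecules_per_gene
                prior = np.array(
                    [
                        math.prod(
                            psi_g[i] if bits[i] else 1.0 - psi_g[i] for i in range(k)
                        )
                        for bits in patterns
                    ]
                )
                prior = prior / prior.sum()
                m = rng.multinomial(M, prior)
                c = (
                    config.depth
                    * mult[g]
                    * params["depth_factor"][g]
                    / (M * L)
                )
                spliced = np.zeros(k, dtype=int)
                retained_body = np.zeros(k, dtype=int)
                cov_start = np.zeros(k, dtype=int)
                cov_end = np.zeros(k, dtype=int)
                n_gene_reads = 0
                for j, bits in enumerate(patterns):
                    layout = layouts[g][bits]
                    lt = layout["length"]
                    lam = m[j] * c * (lt - L + 1)
                    n_reads = int(rng.poisson(lam)) if lam > 0 else 0
                    if n_reads == 0:
                        continue
                    starts = rng.integers(0, lt - L + 1, size=n_reads)
                    n_gene_reads += n_reads
                    template = layout["template"]
                    for s in np.sort(starts):
                        pos, cigar = _read_alignment(layout, int(s), L)
                        positions.append(pos)
                        cigars.append(cigar)
                        seqs.append(template[int(s) : int(s) + L])
                    for i in range(k):
                        if bits[i]:
                            a, b = layout["retained_spans"][i]
                            retained_body[i] += _count_in_window(starts, a - L + 1, b - 1)
                            cov_start[i] += _count_in_window(starts, a - L + 1, a)
                            cov_end[i] += _count_in_window(starts, b - L, b - 1)
                        else:
                            t = layout["junction_offsets"][i]
                            spliced[i] += _count_in_window(starts, t - L + 1, t - 1)
                counts[sample][gene["gene_id"]] = n_gene_reads
                m_ret = np.array(
                    [sum(m[j] for j, bits in enumerate(patterns) if bits[i]) for i in range(k)]
                )
                for i, (i_s, i_e) in enumerate(gene["introns"]):
                    # genomic start side is the donor on '+', acceptor on '-'
                    if gene["strand"] == "+":
                        cov_donor, cov_acceptor = cov_start[i], cov_end[i]
                    else:
                        cov_donor, cov_acceptor = cov_end[i], cov_start[i]
                    truth_rows.append(
                        SimTruth(
                            intron_id=make_intron_id(
                                gene["gene_id"], config.chrom, i_s, i_e, gene["strand"]
                            ),
                            gene_id=gene["gene_id"],
                            condition=cond,
                            replicate=rep,
                            nominal_psi=float(nominal[g, i]),
                            true_psi=float(m_ret[i] / M),
                            n_spliced_reads=int(spliced[i]),
                            n_retained_reads=int(retained_body[i]),
                            n_cov_donor=int(cov_donor),
                            n_cov_acceptor=int(cov_acceptor),
                        )
                    )
            # sort by coordinate (stable on emission order for ties)
            order = np.argsort(np.asarray(positions, dtype=int), kind="stable")
            sam_path = out / f"{sample}.sam"
            with open(sam_path, "w") as fh:
                fh.write(header)
                for serial, idx in enumerate(order):
                    fh.write(
                        f"sim.{sample}.{serial}\t0\t{config.chrom}\t"
                        f"{positions[idx] + 1}\t60\t{cigars[idx]}\t*\t0\t0\t"
                        f"{seqs[idx]}\t{qual}\n"
                    )
            sam_paths[sample] = sam_path

    truth_df = pd.DataFrame([t.__dict__ for t in truth_rows])
    truth_path = out / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False, float_format="%.6g")
    counts_df = pd.DataFrame(counts)
    counts_df.index.name = "gene_id"
    counts_path = out / "counts.tsv"
    counts_df.to_csv(counts_path, sep="\t")
    return SimResult(
        fasta_path=fasta_path,
        gtf_path=gtf_path,
        sam_paths=sam_paths,
        truth_path=truth_path,
        counts_path=counts_path,
        truth=truth_df,
        counts=counts_df,
        sample_conditions=sample_conditions,
    )


def knockdown_study_config(
    n_targets: int = 8,
    n_genes: int = 100,
    seed: int = 13,
    base_psi: float = 0.1,
    target_psi: float = 0.5,
    target_expression_factor: float = 0.25,
    depth: float = 80.0,
    exon_len: int = 120,
    intron_len: int = 90,
    read_len: int = 75,
    dispersion: float = 0.15,
) -> tuple[SimConfig, list[str]]:
    """A knockdown study with engineered retained-intron target genes.

    The first ``n_targets`` genes are the regulator's targets: in the
    knockdown condition their expression drops by
    ``target_expression_factor`` (4-fold down by default) and their intron
    retention rises from ``base_psi`` to ``target_psi``; all other genes
    are unchanged.  Returns the config and the target gene ids.
    """
    psi_kd = np.full(n_genes, base_psi)
    psi_kd[:n_targets] = target_psi
    mult_kd = np.ones(n_genes)
    mult_kd[:n_targets] = target_expression_factor
    config = SimConfig(
        n_genes=n_genes,
        introns_per_gene=2,
        exon_len=exon_len,
        intron_len=intron_len,
        read_len=read_len,
        depth=depth,
        psi_map={"control": base_psi, "knockdown": psi_kd},
        depth_multipliers={"knockdown": mult_kd},
        replicates=3,
        dispersion=dispersion,
        seed=seed,
    )
    targets = [f"G{g + 1:03d}" for g in range(n_targets)]
    return config, targets


# ---------------------------------------------------------------------------
# Count-level companion simulator


def simulate_intron_counts(
    n_introns: int,
    psi_map: Mapping[str, float | np.ndarray],
    depth: float,
    read_len: int,
    replicates: int,
    dispersion: float,
    seed: int,
) -> pd.DataFrame:
    """Draw per-intron boundary/junction counts directly from model rates.

    For an intron with retention fraction psi at coverage ``depth``, the
    expected boundary-base coverage is ``depth * psi`` at each of the two
    boundary bases and the expected junction-read count is
    ``depth * (1 - psi) * (read_len - 1) / read_len`` (a junction read
    needs at least one aligned base on each side of the gap).  Counts are
    Poisson; replicate noise follows :func:`perturb_replicates` (logit-
    scale psi perturbation, gamma depth factor).  Used for large repeat
    studies of the differential tests.

    Returns a tidy frame with columns intron_id, condition, replicate,
    cov_donor, cov_acceptor, transreads, true_psi.
    """
    rng = default_rng(seed)
    w = (read_len - 1) / read_len
    rows = []
    for cond, psi_raw in psi_map.items():
        psi_base = np.broadcast_to(np.asarray(psi_raw, dtype=float), (n_introns,)).copy()
        if np.any((psi_base < 0) | (psi_base > 1)):
            raise SimConfigError(f"psi outside [0,1] for condition {cond!r}")
        for rep in range(1, replicates + 1):
            psi = psi_base.copy()
            if dispersion > 0:
                interior = (psi > 0) & (psi < 1)
                psi[interior] = expit(
                    logit(psi[interior]) + dispersion * rng.standard_normal(interior.sum())
                )
                shape = 1.0 / dispersion**2
                dfac = rng.gamma(shape, scale=1.0 / shape, size=n_introns)
            else:
                dfac = np.ones(n_introns)
            lam_cov = depth * dfac * psi
            lam_tr = depth * dfac * (1.0 - psi) * w
            cov_d = rng.poisson(lam_cov)
            cov_a = rng.poisson(lam_cov)
            tr = rng.poisson(lam_tr)
            for i in range(n_introns):
                rows.append(
                    {
                        "intron_id": f"I{i + 1:04d}",
                        "condition": cond,
                        "replicate": rep,
                        "cov_donor": int(cov_d[i]),
                        "cov_acceptor": int(cov_a[i]),
                        "transreads": int(tr[i]),
                        "true_psi": float(psi[i]),
                    }
                )
    return pd.DataFrame(rows)
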