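"""Splicing-efficiency and intron-retention PSI statistics.

The per-site statistic is

    efficiency = transread count / boundary-base coverage,

the ratio of junction-spanning reads to read coverage at the first
intronic base of the site.  It is a spliced:unspliced odds and therefore
unbounded above; at infinite depth it converges to (1 - psi) / psi for an
intron retained in a fraction psi of transcripts.  The bounded companion
is the intron-retention PSI,

    psi_ir = mean(cov_donor, cov_acceptor)
             / (mean(cov_donor, cov_acceptor) + transreads),

which converges to psi.  Both are always reported side by side.

Aggregation to intron and gene level uses pooled ratios (sum of
numerators over sum of denominators), i.e. coverage weighting, which is
variance-stabilising compared with a mean of ratios.  A zero denominator
makes the statistic undefined: it is reported as NaN, never silently 0.
An optional pseudocount c is added to both numerator and denominator when
requested.  Introns whose total evidence (transreads + mean boundary
coverage) falls below ``min_evidence`` are flagged low-confidence and
excluded from differential testing by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .junctions import SiteQuant

#: Introns with transreads + mean boundary coverage below this are flagged.
DEFAULT_MIN_EVIDENCE = 10.0

_SITES = ("donor", "acceptor", "intron", "gene")


@dataclass(frozen=True)
class EfficiencyRecord:
    """Splicing efficiency at one unit (site, intron or gene)."""

    unit_id: str
    site: str
    efficiency: float  # NaN when undefined
    transread_count: int
    boundary_coverage: int
    condition: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.site not in _SITES:
            raise ValueError(f"invalid site {self.site!r}")
        if self.transread_count < 0 or self.boundary_coverage < 0:
            raise ValueError("negative counts")

    @property
    def defined(self) -> bool:
        return not math.isnan(self.efficiency)


@dataclass(frozen=True)
class IRPsiRecord:
    """Intron-retention PSI of one intron."""

    intron_id: str
    psi_ir: float  # NaN when undefined
    retained_support: float  # mean of the two boundary coverages
    spliced_support: int  # transread count
    condition: str | None = None
    replicate: int | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.psi_ir)


def _ratio(numer: float, denom: float, pseudocount: float = 0.0) -> float:
    numer += pseudocount
    denom += pseudocount
    if denom <= 0:
        return math.nan
    return numer / denom


def site_efficiency(
    q: SiteQuant,
    condition: str | None = None,
    replicate: int | None = None,
    pseudocount: float = 0.0,
) -> EfficiencyRecord:
    """Per-site efficiency: transreads / boundary coverage (NaN if cov 0)."""
    return EfficiencyRecord(
        unit_id=q.intron_id,
        site=q.site,
        efficiency=_ratio(q.transread_count, q.boundary_coverage, pseudocount),
        transread_count=q.transread_count,
        boundary_coverage=q.boundary_coverage,
        condition=condition,
        replicate=replicate,
    )


def intron_efficiency(
    donor: EfficiencyRecord, acceptor: EfficiencyRecord, pseudocount: float = 0.0
) -> EfficiencyRecord:
    """Pooled intron-level efficiency from the donor and acceptor records.

    (transreads_d + transreads_a) / (cov_d + cov_a): undefined only when
    both coverages are zero, so one empty site is absorbed by pooling.
    """
    if donor.unit_id != acceptor.unit_id:
        raise ValueError(
            f"mismatched intron ids: {donor.unit_id!r} vs {acceptor.unit_id!r}"
        )
    if (donor.condition, donor.replicate) != (acceptor.condition, acceptor.replicate):
        raise ValueError("donor/acceptor records from different samples")
    tr = donor.transread_count + acceptor.transread_count
    cov = donor.boundary_coverage + acceptor.boundary_coverage
    return EfficiencyRecord(
        unit_id=donor.unit_id,
        site="intron",
        efficiency=_ratio(tr, cov, pseudocount),
        transread_count=tr,
        boundary_coverage=cov,
        condition=donor.condition,
        replicate=donor.replicate,
    )


def gene_efficiency(
    gene_id: str,
    records: Sequence[EfficiencyRecord],
    pseudocount: float = 0.0,
) -> EfficiencyRecord:
    """Coverage-weighted pooled efficiency across a gene's introns.

    Sum of transreads over sum of coverages across the per-intron
    records; undefined iff every intron is undefined (total coverage 0).
    """
    if not records:
        raise ValueError(f"gene {gene_id}: no intron records")
    tr = sum(r.transread_count for r in records)
    cov = sum(r.boundary_coverage for r in records)
    first = records[0]
    return EfficiencyRecord(
        unit_id=gene_id,
        site="gene",
        efficiency=_ratio(tr, cov, pseudocount),
        transread_count=tr,
        boundary_coverage=cov,
        condition=first.condition,
        replicate=first.replicate,
    )


def intron_retention_psi(
    q_donor: SiteQuant,
    q_acceptor: SiteQuant,
    condition: str | None = None,
    replicate: int | None = None,
) -> IRPsiRecord:
    """PSI of intron retention from the two boundary SiteQuants.

    psi_ir = mean(cov_d, cov_a) / (mean(cov_d, cov_a) + transreads),
    in [0, 1]; undefined (NaN) when the denominator is zero.  The
    transread counts of the two sites are equal by construction; their
    shared value is used.
    """
    if q_donor.intron_id != q_acceptor.intron_id:
        raise ValueError("mismatched intron ids")
    retained = (q_donor.boundary_coverage + q_acceptor.boundary_coverage) / 2.0
    spliced = q_donor.transread_count
    denom = retained + spliced
    return IRPsiRecord(
        intron_id=q_donor.intron_id,
        psi_ir=math.nan if denom <= 0 else retained / denom,
        retained_support=retained,
        spliced_support=spliced,
        condition=condition,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# Table builders (tidy frames, one row per unit x condition x replicate)


def site_table(
    quants: Iterable[SiteQuant],
    condition: str,
    replicate: int,
    gene_of: dict[str, str] | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-site efficiency table for one sample."""
    rows = []
    for q in quants:
        rec = site_efficiency(q, condition, replicate, pseudocount)
        rows.append(
            {
                "intron_id": q.intron_id,
                "gene_id": (gene_of or {}).get(q.intron_id, q.intron_id.split(":")[0]),
                "site": q.site,
                "transread_count": q.transread_count,
                "boundary_coverage": q.boundary_coverage,
                "efficiency": rec.efficiency,
                "condition": condition,
                "replicate": replicate,
            }
        )
    return pd.DataFrame(rows)


def intron_table(
    site_df: pd.DataFrame,
    pseudocount: float = 0.0,
    min_evidence: float = DEFAULT_MIN_EVIDENCE,
) -> pd.DataFrame:
    """Per-intron efficiency and PSI from a (multi-sample) site table."""
    rows = []
    group_cols = ["intron_id", "gene_id", "condition", "replicate"]
    for (intron_id, gene_id, cond, rep), grp in site_df.groupby(group_cols, sort=True):
        pivot = grp.set_index("site")
        cov_d = int(pivot.loc["donor", "boundary_coverage"])
        cov_a = int(pivot.loc["acceptor", "boundary_coverage"])
        tr = int(pivot.loc["donor", "transread_count"])
        retained = (cov_d + cov_a) / 2.0
        eff = _ratio(2 * tr, cov_d + cov_a, pseudocount)
        denom = retained + tr
        rows.append(
            {
                "intron_id": intron_id,
                "gene_id": gene_id,
                "condition": cond,
                "replicate": rep,
                "transreads": tr,
                "cov_donor": cov_d,
                "cov_acceptor": cov_a,
                "efficiency": eff,
                "psi_ir": math.nan if denom <= 0 else retained / denom,
                "retained_support": retained,
                "spliced_support": tr,
                "low_confidence": bool(tr + retained < min_evidence),
            }
        )
    return pd.DataFrame(rows)


def gene_table(intron_df: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Pooled per-gene efficiency from the intron table.

    Low-confidence introns are excluded from the pool; a gene with no
    confident introns is reported with NaN efficiency and n_introns 0.
    """
    rows = []
    for (gene_id, cond, rep), grp in intron_df.groupby(
        ["gene_id", "condition", "replicate"], sort=True
    ):
        ok = grp[~grp["low_confidence"]]
        tr = int((2 * ok["transreads"]).sum())
        cov = int((ok["cov_donor"] + ok["cov_acceptor"]).sum())
        rows.append(
            {
                "gene_id": gene_id,
                "condition": cond,
                "replicate": rep,
                "transreads": tr,
                "boundary_coverage": cov,
                "efficiency": _ratio(tr, cov, pseudocount),
                "n_introns": int(len(ok)),
            }
        )
    return pd.DataFrame(rows)


def condition_means(
    df: pd.DataFrame, unit_col: str, value_col: str = "efficiency"
) -> pd.DataFrame:
    """Replicate means of a statistic, one row per unit, one column per condition.

    NaN (undefined) replicate values are dropped before averaging; a unit
    undefined in every replicate of a condition stays NaN there.
    """
    return (
        df.pivot_table(
            index=unit_col, columns="condition", values=value_col, aggfunc="mean"
        )
        .rename_axis(columns=None)
    )
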