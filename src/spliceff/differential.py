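"""Between-condition tests: global splicing-efficiency shift, expression
change, candidate selection and PSI-expression correlation.

The global shift between two conditions is tested with a Wilcoxon
signed-rank test on per-intron efficiencies paired by intron: efficiency
ratios are heavy-tailed, and pairing removes intron-level nuisance
(length, coverage, GC).  The expression stage is a deliberately simple
stand-in for a dedicated count-based DE engine: library-size-normalised
means, log2 fold change with a 0.5 pseudocount, Welch's t-test on log2
counts, Benjamini-Hochberg adjustment across genes.  Users with real data
can import an external DE table (gene_id, log2fc, p_value) instead.

Candidate retained-intron genes are selected by intersection: expression
down (log2fc < -fc_cut and p < p_cut) in BOTH datasets AND gene-level
splicing efficiency decreased (delta < 0, from confident introns) in
both, sorted by combined rank.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FC_CUT = 1.0  # |log2 FC| threshold
DEFAULT_P_CUT = 0.05
MIN_PAIRS = 20


@dataclass(frozen=True)
class GlobalShiftResult:
    statistic: float
    p_value: float
    median_delta: float
    n_pairs: int


def global_shift_test(
    eff_a: Sequence[float] | pd.Series,
    eff_b: Sequence[float] | pd.Series,
) -> GlobalShiftResult:
    """Paired Wilcoxon signed-rank test on per-intron efficiency vectors.

    ``eff_a`` and ``eff_b`` must be paired on intron identity (same order
    or shared index).  Undefined (NaN) entries are dropped pairwise; fewer
    than 20 surviving pairs is refused as underpowered.  All-zero
    differences return p = 1 by convention.
    """
    a = np.asarray(eff_a, dtype=float)
    b = np.asarray(eff_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("efficiency vectors must be paired (equal length)")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < MIN_PAIRS:
        raise ValueError(
            f"only {a.size} defined pairs (< {MIN_PAIRS}); test refused as underpowered"
        )
    diff = b - a
    median_delta = float(np.median(diff))
    if np.all(diff == 0):
        return GlobalShiftResult(0.0, 1.0, 0.0, int(a.size))
    res = stats.wilcoxon(
        b, a, zero_method="wilcox", correction=True, alternative="two-sided",
        method="approx",
    )
    return GlobalShiftResult(
        float(res.statistic), float(res.pvalue), median_delta, int(a.size)
    )


def expression_change(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch p-value between count tables.

    ``counts_a``/``counts_b`` are gene x replicate frames (>= 2 replicate
    columns each).  Columns are library-size normalised to the grand mean
    library; log2fc compares normalised means (B vs A) with a pseudocount;
    the Welch t-test runs on log2(normalised + pseudocount).  Genes absent
    from one table are treated as zero counts and flagged.  q_value is the
    BH adjustment across genes.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    genes = counts_a.index.union(counts_b.index)
    a = counts_a.reindex(genes).fillna(0.0)
    b = counts_b.reindex(genes).fillna(0.0)
    missing = (~genes.isin(counts_a.index)) | (~genes.isin(counts_b.index))
    lib = pd.concat([a.sum(axis=0), b.sum(axis=0)])
    target = lib.mean()
    a_norm = a / a.sum(axis=0) * target
    b_norm = b / b.sum(axis=0) * target
    mean_a = a_norm.mean(axis=1)
    mean_b = b_norm.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    la = np.log2(a_norm + pseudocount)
    lb = np.log2(b_norm + pseudocount)
    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "t_statistic": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "missing_in_one_table": missing,
        }
    ).set_index("gene_id")
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def gene_efficiency_delta(
    gene_df: pd.DataFrame, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Per-gene efficiency change (replicate means, B - A) from a gene table."""
    pivot = gene_df.pivot_table(
        index="gene_id", columns="condition", values="efficiency", aggfunc="mean"
    )
    for cond in (condition_a, condition_b):
        if cond not in pivot.columns:
            raise ValueError(f"condition {cond!r} absent from gene table")
    out = pd.DataFrame(
        {
            "mean_eff_a": pivot[condition_a],
            "mean_eff_b": pivot[condition_b],
        }
    )
    out["delta"] = out["mean_eff_b"] - out["mean_eff_a"]
    n_introns = gene_df.pivot_table(
        index="gene_id", columns="condition", values="n_introns", aggfunc="min"
    ).min(axis=1)
    out["n_confident_introns"] = n_introns.reindex(out.index).fillna(0).astype(int)
    return out


def select_candidates(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    eff1: pd.DataFrame,
    eff2: pd.DataFrame,
    fc_cut: float = DEFAULT_FC_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> pd.DataFrame:
    """Intersection rule over two datasets.

    A gene is selected iff log2fc < -fc_cut and p_value < p_cut in both DE
    tables AND delta < 0 with at least one confident intron in both
    efficiency-delta tables.  The result is sorted by combined rank (sum
    of the four per-table ranks: log2fc ascending, delta ascending); an
    empty intersection returns an empty frame.
    """
    genes = de1.index.union(de2.index).union(eff1.index).union(eff2.index)
    d1 = de1.reindex(genes)
    d2 = de2.reindex(genes)
    e1 = eff1.reindex(genes)
    e2 = eff2.reindex(genes)
    down = (
        (d1["log2fc"] < -fc_cut)
        & (d1["p_value"] < p_cut)
        & (d2["log2fc"] < -fc_cut)
        & (d2["p_value"] < p_cut)
    )
    eff_down = (
        (e1["delta"] < 0)
        & (e1["n_confident_introns"] > 0)
        & (e2["delta"] < 0)
        & (e2["n_confident_introns"] > 0)
    )
    selected = (down & eff_down).fillna(False)
    result = pd.DataFrame(
        {
            "log2fc_1": d1["log2fc"],
            "log2fc_2": d2["log2fc"],
            "p_value_1": d1["p_value"],
            "p_value_2": d2["p_value"],
            "eff_delta_1": e1["delta"],
            "eff_delta_2": e2["delta"],
        },
        index=genes,
    )[selected]
    if result.empty:
        result["combined_rank"] = pd.Series(dtype=float)
        return result
    rank = (
        result["log2fc_1"].rank()
        + result["log2fc_2"].rank()
        + result["eff_delta_1"].rank()
        + result["eff_delta_2"].rank()
    )
    result["combined_rank"] = rank
    return result.sort_values(["combined_rank", "log2fc_1"]).rename_axis("gene_id")


@dataclass(frozen=True)
class CorrelationResult:
    r: float  # NaN when undefined (zero variance)
    p_value: float
    n: int


def psi_expression_correlation(
    psi: Sequence[float] | pd.Series,
    expression: Sequence[float] | pd.Series,
) -> CorrelationResult:
    """Pearson correlation of per-sample PSI with regulator expression.

    Pairs with a missing value in either vector are dropped; fewer than 10
    surviving pairs is an error; zero variance in either vector gives an
    undefined (NaN) r, flagged rather than raised.
    """
    x = np.asarray(psi, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise ValueError(f"only {x.size} paired samples (< 10)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, int(x.size))
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size))
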