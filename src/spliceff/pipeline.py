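"""Pipeline orchestration: configuration, stage execution, manifest.

``run_pipeline`` ties the stages together in the order the analysis runs:
annotation -> per-sample quantification -> efficiency/PSI tables ->
differential testing (-> candidate selection when two datasets are given,
-> motif scan when a motif and genome are given).  All outputs are TSV
plus a JSON run manifest recording the package and library versions, the
seed, the thresholds and a SHA-256 checksum of every input, so any silent
input change is detectable and identical config + inputs reproduce
byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import scipy
import yaml

from . import __version__
from .annotation import infer_introns, parse_gtf, write_introns_bed
from .differential import (
    DEFAULT_FC_CUT,
    DEFAULT_P_CUT,
    expression_change,
    gene_efficiency_delta,
    global_shift_test,
    select_candidates,
)
from .efficiency import (
    DEFAULT_MIN_EVIDENCE,
    condition_means,
    gene_table,
    intron_table,
    site_table,
)
from .junctions import DEFAULT_MIN_ANCHOR, quantify_sample, write_junctions_tsv
from .motifs import extract_intron_sequence, load_motif, motif_enrichment, scan_motif, write_hits_tsv

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Invalid run configuration (raised before any compute)."""


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class SampleSpec:
    path: Path
    condition: str
    replicate: int


@dataclass
class Thresholds:
    min_anchor: int = DEFAULT_MIN_ANCHOR
    min_evidence: float = DEFAULT_MIN_EVIDENCE
    fc_cut: float = DEFAULT_FC_CUT
    p_cut: float = DEFAULT_P_CUT
    pseudocount: float = 0.0
    min_mapq: int = 0

    def validate(self) -> None:
        if self.min_anchor < 1:
            raise ConfigError("min_anchor must be >= 1")
        if self.min_evidence < 0 or self.fc_cut <= 0 or not (0 < self.p_cut <= 1):
            raise ConfigError("thresholds must be positive (p_cut in (0, 1])")
        if self.pseudocount < 0 or self.min_mapq < 0:
            raise ConfigError("pseudocount and min_mapq must be non-negative")


@dataclass
class DatasetSpec:
    name: str
    samples: dict[str, SampleSpec]
    counts: Path | None = None


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    gtf: Path
    datasets: list[DatasetSpec]
    contrast: tuple[str, str]  # (reference condition, test condition)
    fasta: Path | None = None
    motif: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ConfigError("config must be a YAML mapping")
        base = Path(path).parent

        def _resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        try:
            datasets = []
            for name, ds in raw["datasets"].items():
                samples = {}
                for sname, spec in ds["samples"].items():
                    if "condition" not in spec:
                        raise ConfigError(f"sample {sname!r} has no condition")
                    samples[sname] = SampleSpec(
                        path=_resolve(spec["path"]),
                        condition=str(spec["condition"]),
                        replicate=int(spec.get("replicate", 1)),
                    )
                datasets.append(
                    DatasetSpec(
                        name=str(name),
                        samples=samples,
                        counts=_resolve(ds["counts"]) if ds.get("counts") else None,
                    )
                )
            contrast = raw["contrast"]
            if not isinstance(contrast, (list, tuple)) or len(contrast) != 2:
                raise ConfigError("contrast must list exactly two conditions")
            config = cls(
                gtf=_resolve(raw["gtf"]),
                datasets=datasets,
                contrast=(str(contrast[0]), str(contrast[1])),
                fasta=_resolve(raw["fasta"]) if raw.get("fasta") else None,
                motif=_resolve(raw["motif"]) if raw.get("motif") else None,
                thresholds=Thresholds(**raw.get("thresholds", {})),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        config.validate()
        return config

    def validate(self) -> None:
        self.thresholds.validate()
        if not self.datasets:
            raise ConfigError("at least one dataset required")
        if len(self.datasets) > 2:
            raise ConfigError("at most two datasets supported")
        for p in [self.gtf, self.fasta, self.motif]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input not found: {p}")
        ref, test = self.contrast
        if ref == test:
            raise ConfigError("contrast conditions must differ")
        for ds in self.datasets:
            if not ds.samples:
                raise ConfigError(f"dataset {ds.name!r} has no samples")
            for sname, s in ds.samples.items():
                if not s.path.exists():
                    raise ConfigError(f"alignment not found for {sname!r}: {s.path}")
            for cond in self.contrast:
                n = sum(1 for s in ds.samples.values() if s.condition == cond)
                if n < 2:
                    raise ConfigError(
                        f"dataset {ds.name!r}: condition {cond!r} has {n} replicates (< 2)"
                    )
            if ds.counts is not None and not ds.counts.exists():
                raise ConfigError(f"counts table not found: {ds.counts}")
        if (self.motif is None) != (self.fasta is None) and self.motif is not None:
            raise ConfigError("motif scanning requires a fasta")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    global_shift: dict[str, dict]
    candidates: pd.DataFrame | None


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Execute all configured stages; see the module docstring."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "spliceff_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "pysam": pysam.__version__,
        },
        "seed": config.seed,
        "thresholds": config.thresholds.__dict__,
        "contrast": list(config.contrast),
        "inputs": {},
        "stages": [],
        "incomplete": True,
    }
    input_paths = [config.gtf] + [
        s.path for ds in config.datasets for s in ds.samples.values()
    ]
    input_paths += [p for p in (config.fasta, config.motif) if p]
    input_paths += [ds.counts for ds in config.datasets if ds.counts]
    for p in input_paths:
        manifest["inputs"][str(p)] = _sha256(Path(p))

    def _stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        _stage("annotation")
        transcripts = parse_gtf(config.gtf)
        introns = infer_introns(transcripts)
        if not introns:
            raise PipelineError("annotation: no introns inferred")
        write_introns_bed(introns, out / "introns.bed")
        gene_of = {i.intron_id: i.gene_id for i in introns}

        ref_cond, test_cond = config.contrast
        th = config.thresholds
        global_results: dict[str, dict] = {}
        gene_deltas: dict[str, pd.DataFrame] = {}
        de_tables: dict[str, pd.DataFrame] = {}
        for ds in config.datasets:
            _stage(f"quantify[{ds.name}]")
            site_frames = []
            for sname in sorted(ds.samples):
                spec = ds.samples[sname]
                quants, junctions = quantify_sample(
                    spec.path, introns, min_anchor=th.min_anchor, min_mapq=th.min_mapq
                )
                write_junctions_tsv(junctions, out / f"{ds.name}.{sname}.junctions.tsv")
                site_frames.append(
                    site_table(
                        quants, spec.condition, spec.replicate,
                        gene_of=gene_of, pseudocount=th.pseudocount,
                    )
                )
            site_df = pd.concat(site_frames, ignore_index=True)
            _write(site_df, out / f"{ds.name}.sites.tsv")

            _stage(f"efficiency[{ds.name}]")
            intron_df = intron_table(
                site_df, pseudocount=th.pseudocount, min_evidence=th.min_evidence
            )
            _write(intron_df, out / f"{ds.name}.introns.tsv")
            gene_df = gene_table(intron_df, pseudocount=th.pseudocount)
            _write(gene_df, out / f"{ds.name}.genes.tsv")

            _stage(f"differential[{ds.name}]")
            confident = intron_df[~intron_df["low_confidence"]]
            eff_means = condition_means(confident, "intron_id")
            if ref_cond not in eff_means.columns or test_cond not in eff_means.columns:
                raise PipelineError(
                    f"differential[{ds.name}]: contrast condition missing from data"
                )
            shift = global_shift_test(eff_means[ref_cond], eff_means[test_cond])
            global_results[ds.name] = {
                "statistic": shift.statistic,
                "p_value": shift.p_value,
                "median_delta": shift.median_delta,
                "n_pairs": shift.n_pairs,
            }
            gene_deltas[ds.name] = gene_efficiency_delta(gene_df, ref_cond, test_cond)
            _write(gene_deltas[ds.name], out / f"{ds.name}.gene_delta.tsv", index=True)
            if ds.counts is not None:
                counts = pd.read_csv(ds.counts, sep="\t", index_col=0)
                cols_a = [
                    s for s, spec in ds.samples.items() if spec.condition == ref_cond
                ]
                cols_b = [
                    s for s, spec in ds.samples.items() if spec.condition == test_cond
                ]
                missing = [c for c in cols_a + cols_b if c not in counts.columns]
                if missing:
                    raise PipelineError(
                        f"differential[{ds.name}]: counts table lacks columns {missing}"
                    )
                de = expression_change(counts[cols_a], counts[cols_b])
                de_tables[ds.name] = de
                _write(de, out / f"{ds.name}.expression.tsv", index=True)

        candidates = None
        if len(config.datasets) == 2:
            _stage("select_candidates")
            names = [ds.name for ds in config.datasets]
            if all(n in de_tables for n in names):
                candidates = select_candidates(
                    de_tables[names[0]], de_tables[names[1]],
                    gene_deltas[names[0]], gene_deltas[names[1]],
                    fc_cut=th.fc_cut, p_cut=th.p_cut,
                )
                _write(candidates, out / "candidates.tsv", index=True)
            else:
                logger.warning("candidate selection skipped: counts missing")

        motif_summary = None
        if config.motif is not None and config.fasta is not None:
            _stage("motif_scan")
            motif = load_motif(config.motif)
            with pysam.FastaFile(str(config.fasta)) as fasta:
                sequences = {
                    i.intron_id: extract_intron_sequence(fasta, i) for i in introns
                }
            hits = [
                h
                for iid, seq in sorted(sequences.items())
                for h in scan_motif(seq, motif, iid)
            ]
            write_hits_tsv(hits, out / "motif_hits.tsv")
            enrich = motif_enrichment(sequences, motif, seed=config.seed)
            motif_summary = {
                "motif_id": motif.motif_id,
                "observed_hits": enrich.observed_hits,
                "p_value": enrich.p_value,
                "n_shuffles": enrich.n_shuffles,
                "shuffle_mean": enrich.shuffle_mean,
            }
    except (PipelineError, ConfigError):
        _finalize(manifest, out)
        raise
    except Exception as exc:  # annotate unexpected failures with the stage
        _finalize(manifest, out)
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise PipelineError(f"{stage}: {exc}") from exc

    manifest["incomplete"] = False
    summary = {
        "global_shift": global_results,
        "candidates": list(candidates.index) if candidates is not None else None,
        "motif": motif_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _finalize(manifest, out)
    return PipelineResult(
        out_dir=out,
        manifest=manifest,
        global_shift=global_results,
        candidates=candidates,
    )


def _finalize(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
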