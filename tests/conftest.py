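"""Shared fixtures: small simulated studies reused across test modules."""
from __future__ import annotations

import re

import pytest

from spliceff import SimConfig, infer_introns, parse_gtf, simulate_dataset


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """Small two-condition study with retention increasing under knockdown."""
    config = SimConfig(
        n_genes=4,
        introns_per_gene=2,
        depth=100.0,
        psi_map={"control": 0.1, "knockdown": 0.4},
        replicates=3,
        dispersion=0.1,
        seed=7,
    )
    out = tmp_path_factory.mktemp("tiny_study")
    return config, simulate_dataset(config, out)


@pytest.fixture(scope="session")
def tiny_introns(tiny_study):
    _config, result = tiny_study
    return infer_introns(parse_gtf(result.gtf_path))


def write_sam(path, records, chrom="chr1", length=100000):
    """Write a minimal SAM file from (qname, flag, pos0, cigar) tuples."""
    with open(path, "w") as fh:
        fh.write(f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{chrom}\tLN:{length}\n")
        for qname, flag, pos0, cigar, *rest in records:
            mapq = rest[0] if rest else 60
            seqlen = sum(int(n) for n, _op in re.findall(r"(\d+)([MIS=X])", cigar))
            fh.write(
                f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t"
                f"{'A' * seqlen}\t{'I' * seqlen}\n"
            )
    return path
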