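"""Junction extraction and boundary coverage vs independent oracles."""
import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from spliceff import (
    IntronModel,
    boundary_coverage,
    extract_junctions,
    match_junctions_to_introns,
    quantify_sample,
)
from spliceff.junctions import JunctionCount, cigar_gaps, covered_intervals

from .conftest import write_sam
from .oracles import coverage_oracle, junction_counts_oracle, read_gaps


def _intron(start, end, strand="+", gene="G1", chrom="chr1"):
    return IntronModel(
        intron_id=f"{gene}:{chrom}:{start}-{end}:{strand}",
        gene_id=gene, chrom=chrom, strand=strand, start=start, end=end,
    )


def _ops(cigar):
    import re
    code = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
    return [(code[op], int(n)) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]


class TestCigarWalk:
    def test_single_gap_arithmetic(self):
        gaps = cigar_gaps(_ops("50M100N50M"), 100)
        assert gaps == [(150, 250, 50, 50)]

    def test_multi_gap_walk(self):
        start = 1000
        gaps = cigar_gaps(_ops("30M50N40M60N30M"), start)
        assert [(g[0], g[1]) for g in gaps] == [
            (start + 30, start + 80),
            (start + 120, start + 180),
        ]
        assert [(g[2], g[3]) for g in gaps] == [(30, 40), (40, 30)]

    def test_insertions_clips_do_not_advance_reference(self):
        gaps = cigar_gaps(_ops("5S20M2I10M100N30M"), 0)
        assert [(g[0], g[1]) for g in gaps] == [(30, 130)]
        assert gaps[0][2] == 30  # anchors count aligned M bases only, not S/I

    def test_deletion_covers_but_gap_does_not(self):
        intervals = covered_intervals(_ops("10M5D10M100N10M"), 0)
        assert intervals == [(0, 25), (125, 135)]


def test_junction_counts_on_handmade_reads(tmp_path):
    sam = write_sam(
        tmp_path / "t.sam",
        [
            ("r1", 0, 100, "50M100N50M"),
            ("r2", 0, 100, "50M100N50M"),
            ("r3", 0, 120, "30M100N70M"),
            ("r4", 0, 100, "3M147N97M"),  # left anchor 3
            ("r5", 256, 100, "50M100N50M"),  # secondary: excluded
            ("r6", 0, 500, "100M"),  # no gap
        ],
    )
    juncs = extract_junctions(sam, min_anchor=8)
    assert [(j.gap_start, j.gap_end, j.count) for j in juncs] == [(150, 250, 3)]
    juncs1 = extract_junctions(sam, min_anchor=1)
    assert {(j.gap_start, j.gap_end): j.count for j in juncs1} == {
        (150, 250, ): 3, (103, 250): 1,
    }


def test_boundary_coverage_counting_rules(tmp_path):
    intron = _intron(100, 250)
    sam = write_sam(
        tmp_path / "cov.sam",
        [
            ("r1", 0, 50, "100M"),          # M across donor base 100
            ("r2", 0, 50, "50M150N50M"),    # gap spans both boundaries: no cover
            ("r3", 0, 95, "5M10D85M"),      # deletion covers 100
            ("r4", 0, 240, "20M"),          # M across acceptor base 249
            ("r5", 0, 250, "20M"),          # starts after acceptor base
        ],
    )
    cov = boundary_coverage(sam, [intron])
    assert cov[(intron.intron_id, "donor")] == 2  # r1 + r3
    assert cov[(intron.intron_id, "acceptor")] == 1  # r4


def test_paired_fragments_counted_once(tmp_path):
    intron = _intron(100, 250)
    sam = write_sam(
        tmp_path / "pair.sam",
        [
            ("frag1", 99, 50, "50M150N30M"),   # mate 1: junction, no boundary
            ("frag1", 147, 60, "40M150N40M"),  # mate 2: same junction
            ("frag2", 99, 80, "40M"),          # mate 1 covers donor base
            ("frag2", 147, 90, "30M"),         # mate 2 covers donor base again
        ],
    )
    juncs = extract_junctions(sam)
    assert [(j.gap_start, j.gap_end, j.count) for j in juncs] == [(100, 250, 1)]
    cov = boundary_coverage(sam, [intron])
    assert cov[(intron.intron_id, "donor")] == 1


def test_intron_on_missing_contig_gets_zero_coverage(tmp_path, caplog):
    sam = write_sam(tmp_path / "m.sam", [("r1", 0, 50, "100M")], chrom="chr1")
    other = _intron(100, 250, chrom="chrX")
    cov = boundary_coverage(sam, [other])
    assert cov[(other.intron_id, "donor")] == 0
    assert "absent" in caplog.text


class TestMatching:
    def test_exact_match_and_one_off_novel(self):
        introns = [_intron(100, 200)]
        juncs = [
            JunctionCount("chr1", 100, 200, 5),
            JunctionCount("chr1", 100, 201, 2),
        ]
        matched = match_junctions_to_introns(juncs, introns)
        assert matched[0].matched_intron_id == introns[0].intron_id
        assert matched[1].matched_intron_id is None and matched[1].novel

    def test_simulated_junctions_all_annotated(self, tiny_study, tiny_introns):
        _config, result = tiny_study
        for sam in result.sam_paths.values():
            matched = match_junctions_to_introns(
                extract_junctions(sam), tiny_introns
            )
            assert matched and all(not j.novel for j in matched)


@pytest.mark.parametrize("min_anchor", [1, 8])
def test_simulated_reads_match_bruteforce_oracles(tiny_study, tiny_introns, min_anchor):
    """Transread counts and boundary coverage equal per-read re-scan oracles."""
    _config, result = tiny_study
    sam = result.sam_paths["knockdown_rep2"]
    juncs = extract_junctions(sam, min_anchor=min_anchor)
    oracle = junction_counts_oracle(sam, min_anchor=min_anchor)
    assert {(j.chrom, j.gap_start, j.gap_end): j.count for j in juncs} == oracle

    cov = boundary_coverage(sam, tiny_introns)
    wanted = {}
    for i in tiny_introns:
        wanted[(i.intron_id, "donor")] = (i.chrom, i.donor_boundary_base)
        wanted[(i.intron_id, "acceptor")] = (i.chrom, i.acceptor_boundary_base)
    pile = coverage_oracle(sam, set(wanted.values()))
    assert all(cov[k] == pile[pos] for k, pos in wanted.items())


def test_transread_conservation_against_truth(tiny_study, tiny_introns):
    """In error-free data the exact-gap junction count equals the simulator's
    per-intron spliced-read count and boundary coverage equals its coverage."""
    _config, result = tiny_study
    truth = result.truth
    for sample, sam in result.sam_paths.items():
        cond, rep = sample.rsplit("_rep", 1)
        sub = truth[(truth.condition == cond) & (truth.replicate == int(rep))]
        quants, _ = quantify_sample(sam, tiny_introns)
        by_key = {(q.intron_id, q.site): q for q in quants}
        for row in sub.itertuples():
            donor = by_key[(row.intron_id, "donor")]
            acceptor = by_key[(row.intron_id, "acceptor")]
            assert donor.transread_count == acceptor.transread_count == row.n_spliced_reads
            assert donor.boundary_coverage == row.n_cov_donor
            assert acceptor.boundary_coverage == row.n_cov_acceptor


# ---------------------------------------------------------------------------
# Property test: random CIGARs vs the brute-force gap oracle


@st.composite
def random_cigars(draw):
    """Alternating aligned/other segments forming a plausible CIGAR."""
    parts = [f"{draw(st.integers(1, 80))}M"]
    for _ in range(draw(st.integers(0, 5))):
        op = draw(st.sampled_from(["N", "D", "I"]))
        parts.append(f"{draw(st.integers(1, 200))}{op}")
        parts.append(f"{draw(st.integers(1, 80))}M")
    if draw(st.booleans()):
        parts.insert(0, f"{draw(st.integers(1, 10))}S")
    if draw(st.booleans()):
        parts.append(f"{draw(st.integers(1, 10))}S")
    return "".join(parts)


@settings(max_examples=120, derandomize=True)
@given(cigar=random_cigars(), pos=st.integers(0, 5000), anchor=st.integers(1, 12))
def test_gap_extraction_equals_oracle_on_random_cigars(cigar, pos, anchor):
    ops = _ops(cigar)
    ours = [
        (s, e)
        for s, e, left, right in cigar_gaps(ops, pos)
        if left >= anchor and right >= anchor
    ]
    oracle = read_gaps(pos, [(l, "MIDNSHP=X"[op]) for op, l in ops], anchor)
    assert ours == oracle
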