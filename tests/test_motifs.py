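"""Motif scanning: IUPAC/PWM oracles, shuffling, enrichment, strand logic."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.random import default_rng

from spliceff import (
    IntronModel,
    MotifSpec,
    dinucleotide_shuffle,
    extract_intron_sequence,
    load_motif,
    motif_enrichment,
    scan_iupac,
    scan_pwm,
)
from spliceff.motifs import IUPAC, MotifError, _pwm_logodds
from spliceff.simulate import write_fasta

from .oracles import dinucleotide_counts, iupac_scan_oracle, pwm_scan_oracle


def _intron(start, end, strand="+", chrom="chr1"):
    return IntronModel(
        intron_id=f"G1:{chrom}:{start}-{end}:{strand}",
        gene_id="G1", chrom=chrom, strand=strand, start=start, end=end,
    )


def _indicator_pwm(seq):
    rows = []
    for b in seq:
        row = [0.0, 0.0, 0.0, 0.0]
        row["ACGU".index(b)] = 1.0
        rows.append(tuple(row))
    return tuple(rows)


class TestMotifSpec:
    def test_requires_exactly_one_mode(self):
        with pytest.raises(MotifError):
            MotifSpec(motif_id="m")
        with pytest.raises(MotifError):
            MotifSpec(motif_id="m", iupac="ACG", pwm=_indicator_pwm("ACG"))

    def test_invalid_symbols_and_bad_pwm_rejected(self):
        with pytest.raises(MotifError, match="IUPAC"):
            MotifSpec(motif_id="m", iupac="ACZ")
        with pytest.raises(MotifError, match="sum"):
            MotifSpec(motif_id="m", pwm=((0.5, 0.5, 0.1, 0.0),))

    def test_dna_alphabet_normalized_to_rna(self):
        assert MotifSpec(motif_id="m", iupac="acgt").iupac == "ACGU"

    def test_json_round_trip(self, tmp_path):
        p = tmp_path / "m.json"
        p.write_text('{"motif_id": "demo", "iupac": "UGUA"}\n')
        motif = load_motif(p)
        assert motif.motif_id == "demo" and motif.iupac == "UGUA"


class TestExtractIntronSequence:
    GENOME = "AAACCCGGG"

    def _fasta(self, tmp_path):
        path = tmp_path / "g.fa"
        write_fasta(self.GENOME, "chr1", path)
        return path

    def test_plus_strand_slice(self, tmp_path):
        seq = extract_intron_sequence(self._fasta(tmp_path), _intron(3, 7))
        assert seq == "CCCG"

    def test_minus_strand_reverse_complement(self, tmp_path):
        seq = extract_intron_sequence(self._fasta(tmp_path), _intron(3, 7, "-"))
        assert seq == "CGGG"

    def test_round_trip_reembeds_genome_slice(self, tmp_path):
        comp = str.maketrans("ACGU", "UGCA")
        for strand in "+-":
            seq = extract_intron_sequence(self._fasta(tmp_path), _intron(2, 8, strand))
            back = seq if strand == "+" else seq.translate(comp)[::-1]
            assert back.replace("U", "T") == self.GENOME[2:8]

    def test_out_of_bounds_interval_raises(self, tmp_path):
        with pytest.raises(ValueError, match="exceeds"):
            extract_intron_sequence(self._fasta(tmp_path), _intron(3, 50))


class TestIupacScan:
    def test_overlapping_exact_matches(self):
        hits = scan_iupac("ACGUACGU", MotifSpec(motif_id="m", iupac="ACG"))
        assert [h.offset for h in hits] == [0, 4]

    def test_degenerate_symbol(self):
        hits = scan_iupac("ACGGCGU", MotifSpec(motif_id="m", iupac="RCG"))
        assert [h.offset for h in hits] == [0, 3]

    def test_random_sequence_matches_sliding_window_oracle(self):
        rng = default_rng(23)
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=10000)])
        motif = MotifSpec(motif_id="m", iupac="ACGU")
        hits = scan_iupac(seq, motif)
        assert [h.offset for h in hits] == iupac_scan_oracle(seq, "ACGU", IUPAC)


class TestPwmScan:
    def test_indicator_pwm_at_threshold_one_equals_iupac(self):
        seq = "ACGUACGGACG"
        pwm = MotifSpec(motif_id="m", pwm=_indicator_pwm("ACG"), score_threshold=1.0)
        iupac = MotifSpec(motif_id="m", iupac="ACG")
        assert [h.offset for h in scan_pwm(seq, pwm)] == [
            h.offset for h in scan_iupac(seq, iupac)
        ]

    def test_threshold_zero_reports_every_window(self):
        seq = "ACGUACGU"
        pwm = MotifSpec(motif_id="m", pwm=_indicator_pwm("ACG"), score_threshold=0.0)
        assert len(scan_pwm(seq, pwm)) == len(seq) - 3 + 1

    def test_random_pwm_matches_exhaustive_oracle(self):
        rng = default_rng(29)
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=3000)])
        raw = rng.dirichlet(np.ones(4), size=6)
        motif = MotifSpec(
            motif_id="m", pwm=tuple(map(tuple, raw)), score_threshold=0.7
        )
        logodds = _pwm_logodds(motif)
        lo, hi = logodds.min(axis=1).sum(), logodds.max(axis=1).sum()
        threshold_abs = lo + 0.7 * (hi - lo)
        ours = [h.offset for h in scan_pwm(seq, motif)]
        assert ours == pwm_scan_oracle(seq, logodds.tolist(), threshold_abs)


@settings(max_examples=60, derandomize=True)
@given(
    seq=st.text(alphabet="ACGU", min_size=6, max_size=60),
    pattern=st.text(alphabet="ACGURYSWKMN", min_size=1, max_size=5),
)
def test_iupac_scan_equals_indicator_pwm_everywhere(seq, pattern):
    """Degenerate-symbol PWM at threshold 1.0 is the IUPAC scan, always."""
    rows = []
    for sym in pattern:
        allowed = IUPAC[sym]
        rows.append(tuple(1.0 / len(allowed) if b in allowed else 0.0 for b in "ACGU"))
    pwm = MotifSpec(motif_id="m", pwm=tuple(rows), score_threshold=1.0)
    iupac = MotifSpec(motif_id="m", iupac=pattern)
    assert [h.offset for h in scan_pwm(seq, pwm)] == [
        h.offset for h in scan_iupac(seq, iupac)
    ]


def test_strand_consistency_of_hits(tmp_path):
    """Scanning the reverse-complement genome with flipped strand/coords
    yields identical sense-strand hits."""
    rng = default_rng(31)
    genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=400)])
    rc = genome.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    fwd, rev = tmp_path / "fwd.fa", tmp_path / "rev.fa"
    write_fasta(genome, "chr1", fwd)
    write_fasta(rc, "chr1", rev)
    motif = MotifSpec(motif_id="m", iupac="RCGU")
    start, end = 100, 300
    seq_fwd = extract_intron_sequence(fwd, _intron(start, end, "+"))
    seq_rev = extract_intron_sequence(
        rev, _intron(len(genome) - end, len(genome) - start, "-")
    )
    assert seq_fwd == seq_rev
    assert [h.offset for h in scan_iupac(seq_fwd, motif)] == [
        h.offset for h in scan_iupac(seq_rev, motif)
    ]


class TestDinucleotideShuffle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_preserves_dinucleotide_counts_and_endpoints(self, seed):
        rng = default_rng(seed)
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=300)])
        shuf = dinucleotide_shuffle(seq, rng)
        assert len(shuf) == len(seq)
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
        assert dinucleotide_counts(shuf) == dinucleotide_counts(seq)

    def test_actually_permutes(self):
        rng = default_rng(5)
        seq = "".join(np.array(list("ACGU"))[default_rng(6).integers(0, 4, size=200)])
        assert any(dinucleotide_shuffle(seq, rng) != seq for _ in range(5))


class TestEnrichment:
    def test_absent_motif_gives_p_one(self):
        seqs = {"i1": "ACACACACAC" * 10}
        res = motif_enrichment(seqs, MotifSpec(motif_id="m", iupac="GGGG"), 200, seed=1)
        assert res.p_value == 1.0 and res.observed_hits == 0

    def test_planted_motif_strongly_enriched(self):
        rng = default_rng(31)
        bg = "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=400)])
        planted = list(bg)
        motif_seq = "UGUAUGUA"
        for k in range(20):
            pos = 10 + 19 * k
            planted[pos : pos + len(motif_seq)] = motif_seq
        seqs = {"i1": "".join(planted), "i2": bg}
        res = motif_enrichment(
            seqs, MotifSpec(motif_id="m", iupac="UGUAUGUA"), 500, seed=31
        )
        assert res.observed_hits >= 20
        assert res.p_value <= 0.01

    def test_p_always_in_unit_interval(self):
        seqs = {"i1": "ACGUACGUACGUACGUACGU"}
        res = motif_enrichment(seqs, MotifSpec(motif_id="m", iupac="N"), 100, seed=2)
        assert 0 < res.p_value <= 1.0

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError, match="100"):
            motif_enrichment({"i": "ACGU"}, MotifSpec(motif_id="m", iupac="A"), 10)
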