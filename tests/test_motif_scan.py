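"""Window extraction, overlap-counting motif scan, QRE calls, enrichment."""

import numpy as np
import pytest

from bpcompete.io_formats import GenomeSequence, IntronAnnotation, reverse_complement
from bpcompete.motif_scan import (
    CUSTOM_BP_MOTIFS,
    MotifPattern,
    WindowSpec,
    WindowSkipped,
    dual_motif_enrichment,
    extract_3ss_window,
    find_qre,
    has_dual_core,
    positional_motif_map,
    scan_motif,
)
from conftest import random_dna, random_window_set


def brute_force_scan(seq: str, pattern: str) -> list[int]:
    """Position-by-position oracle, independent of the regex scanner."""
    sets = MotifPattern.compile(pattern).sets
    return [
        i
        for i in range(len(seq) - len(sets) + 1)
        if all(seq[i + j] in allowed for j, allowed in enumerate(sets))
    ]


def oracle_window(genome: GenomeSequence, intron: IntronAnnotation,
                  up_start: int, up_end: int) -> str:
    """Independent slicing oracle working directly in genomic coordinates."""
    ilen = intron.end - intron.start
    up_start = min(up_start, ilen)
    if intron.strand == "+":
        return genome.sequence[intron.end - up_start : intron.end - up_end]
    return reverse_complement(
        genome.sequence[intron.start + up_end : intron.start + up_start]
    )


class TestWindowExtraction:
    def test_plus_strand_matches_slicing_oracle(self, plus_intron):
        genome, intron = plus_intron
        win = extract_3ss_window(genome, intron, WindowSpec(80, 0))
        assert win == oracle_window(genome, intron, 80, 0)
        assert len(win) == 80

    def test_minus_strand_is_reverse_complement_of_slice(self, plus_intron):
        genome, intron = plus_intron
        minus = IntronAnnotation(
            intron.intron_id, intron.gene_id, intron.chrom,
            intron.start, intron.end, "-",
        )
        win = extract_3ss_window(genome, minus, WindowSpec(80, 0))
        assert win == oracle_window(genome, minus, 80, 0)

    def test_random_introns_both_strands(self, rng):
        for _ in range(100):
            seq = random_dna(rng, 500)
            genome = GenomeSequence("c", seq)
            start = int(rng.integers(0, 200))
            end = start + int(rng.integers(90, 300))
            strand = "+" if rng.random() < 0.5 else "-"
            intron = IntronAnnotation("i", "g", "c", start, end, strand)
            up_start = int(rng.integers(30, 90))
            up_end = int(rng.integers(0, 25))
            win = extract_3ss_window(genome, intron, WindowSpec(up_start, up_end))
            assert win == oracle_window(genome, intron, up_start, up_end)

    def test_truncate_policy_on_short_intron(self):
        genome = GenomeSequence("c", "A" * 100)
        intron = IntronAnnotation("i", "g", "c", 30, 60, "+")  # 30-nt intron
        win = extract_3ss_window(genome, intron, WindowSpec(80, 0))
        assert len(win) == 30

    def test_skip_policy_on_short_intron(self):
        genome = GenomeSequence("c", "A" * 100)
        intron = IntronAnnotation("i", "g", "c", 30, 60, "+")
        with pytest.raises(WindowSkipped):
            extract_3ss_window(genome, intron, WindowSpec(80, 0, "skip"))

    def test_window_never_crosses_into_exon(self):
        # intron bracketed by distinctive exon sequence: window stays inside
        intron_seq = "T" * 50
        genome = GenomeSequence("c", "G" * 20 + intron_seq + "G" * 20)
        intron = IntronAnnotation("i", "g", "c", 20, 70, "+")
        win = extract_3ss_window(genome, intron, WindowSpec(80, 0))
        assert set(win) == {"T"}


class TestScanMotif:
    def test_tandem_embedded_example_two_overlapping_hits(self):
        hits = scan_motif("TACTAACTAAC", "ACTAA")
        assert [h.offset for h in hits] == [1, 5]

    def test_rna_input_accepted(self):
        hits = scan_motif("UACUAACUAAC", "ACUAA")
        assert [h.offset for h in hits] == [1, 5]

    def test_absent_pattern(self):
        assert scan_motif("GGGGGGGG", "ACTAA") == []

    def test_n_never_matches(self):
        assert scan_motif("ACTNA", "ACTNA") == []
        assert scan_motif("ACTAA", "ACTNA") != []

    def test_equals_brute_force_on_random_sequences(self, rng):
        for _ in range(100):
            seq = random_dna(rng, 80)
            for pattern in CUSTOM_BP_MOTIFS:
                got = [h.offset for h in scan_motif(seq, pattern)]
                assert got == brute_force_scan(seq, pattern)

    def test_strand_consistency_mirrored_offsets(self, rng):
        pattern = MotifPattern.compile("ACTAA[CT]")
        for _ in range(30):
            seq = random_dna(rng, 120)
            fwd = [h.offset for h in scan_motif(seq, pattern)]
            rc_hits = [
                h.offset
                for h in scan_motif(reverse_complement(seq), pattern.reverse_complement())
            ]
            mirrored = sorted(len(seq) - len(pattern) - o for o in rc_hits)
            assert fwd == mirrored

    def test_pattern_validation(self):
        with pytest.raises(ValueError, match="shorter than 3"):
            MotifPattern.compile("AC")
        with pytest.raises(ValueError, match="unclosed"):
            MotifPattern.compile("ACT[AG")
        with pytest.raises(ValueError, match="bad symbol"):
            MotifPattern.compile("ACT*A")


class TestQre:
    def test_core_plus_downstream_halfsite(self):
        # ACTAA core, 10-nt gap, then TAAC half-site
        seq = "G" + "ACTAA" + "G" * 10 + "TAAC" + "GG"
        calls = find_qre(seq)
        assert len(calls) == 1
        assert calls[0].gap == 10
        assert calls[0].orientation == "3prime"

    def test_no_halfsite_within_gap(self):
        seq = "G" + "ACTAA" + "G" * 30 + "TAAC"
        assert find_qre(seq, max_gap=20) == []

    def test_halfsite_embedded_in_core_excluded(self):
        # ACTAAC contains TAAC; no independent half-site nearby
        seq = "GGG" + "ACTAAC" + "GGGGGG"
        assert find_qre(seq, core="ACTAAC") == []


class TestDualCore:
    def test_tandem_embedded_counts_as_dual(self):
        flag, count = has_dual_core("TACTAACTAAC")
        assert flag and count == 2

    def test_single_core_not_dual(self):
        flag, count = has_dual_core("GGACTAAGG")
        assert not flag and count == 1


class TestDualMotifEnrichment:
    def test_equal_proportions_give_null(self, rng):
        windows = random_window_set(rng, 50, 0.3)
        table, res = dual_motif_enrichment(windows, list(windows))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_table_equals_brute_force_counts(self, rng):
        reg = random_window_set(rng, 40, 0.4)
        ctl = random_window_set(rng, 100, 0.06)
        table, _ = dual_motif_enrichment(reg, ctl)
        n_reg_dual = sum(
            len(brute_force_scan(w, "ACTAA")) >= 2 for w in reg
        )
        n_ctl_dual = sum(
            len(brute_force_scan(w, "ACTAA")) >= 2 for w in ctl
        )
        assert table[0, 0] == n_reg_dual and table[0, 1] == 40 - n_reg_dual
        assert table[1, 0] == n_ctl_dual and table[1, 1] == 100 - n_ctl_dual

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dual_motif_enrichment([], ["ACGT" * 20])


class TestPositionalMap:
    def test_fg_equal_bg_gives_flat_pvalues(self, rng):
        windows = random_window_set(rng, 30, 0.3)
        df = positional_motif_map(windows, [], list(windows), "ACTAA",
                                  window_len=30, step=5)
        assert (df["p_up"] > 0.9).all()

    def test_planted_offset_is_p_minimum(self, rng):
        bg = random_window_set(rng, 60, 0.0)
        fg = []
        for w in random_window_set(rng, 60, 0.0):
            fg.append(w[:35] + "ACTAA" + w[40:])  # planted at offset 35
        df = positional_motif_map(fg, [], bg, "ACTAA", window_len=10, step=1)
        best = df.loc[df["p_up"].idxmin(), "position"]
        assert 30 <= best <= 36  # window containing the planted motif

    def test_fractions_equal_brute_force(self, rng):
        fg = random_window_set(rng, 20, 0.5)
        bg = random_window_set(rng, 20, 0.1)
        df = positional_motif_map(fg, [], bg, "ACTAA", window_len=20, step=10)
        for row in df.itertuples(index=False):
            lo, hi = row.position, row.position + 20 - 5
            frac = np.mean(
                [any(lo <= o <= hi for o in brute_force_scan(w, "ACTAA")) for w in fg]
            )
            assert row.frac_up == pytest.approx(frac)

    def test_empty_foreground_error(self, rng):
        with pytest.raises(ValueError):
            positional_motif_map([], [], random_window_set(rng, 5, 0.0), "ACTAA")
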