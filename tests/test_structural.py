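"""The direct-repeat finder, structural filters and the candidate adapter."""

import numpy as np
import pytest

from ltrnet.structural_candidates import (
    CandidateElement,
    StructuralParams,
    apply_structural_filters,
    check_motif,
    check_tsd,
    find_candidates,
    load_candidates_tsv,
)
from ltrnet.genome_io import GenomeSequence
from ltrnet.synthetic_data import gen_window


def _random_dna(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def _window_with_implant(rng, ltr_len=500, internal_len=3000, pos=5000, pad=12000,
                         tsd="GATCA"):
    """Background with LTR+internal+LTR implanted at ``pos``, TSD on both
    flanks; returns (window, element_start, element_end)."""
    ltr = "TG" + _random_dna(ltr_len - 4, rng) + "CA"
    elem = ltr + _random_dna(internal_len, rng) + ltr
    bg_l = _random_dna(pos - len(tsd), rng) + tsd
    bg_r = tsd + _random_dna(pad, rng)
    return bg_l + elem + bg_r, len(bg_l), len(bg_l) + len(elem)


class TestFindCandidates:
    def test_single_implant_recovered_with_tight_boundaries(self):
        rng = np.random.default_rng(0)
        win, s, e = _window_with_implant(rng)
        cands = find_candidates(win)
        assert len(cands) == 1
        c = cands[0]
        assert abs(c.start - s) <= 10 and abs(c.end - e) <= 10
        assert c.tg_ca_ok

    def test_background_only_window_is_empty(self):
        rng = np.random.default_rng(1)
        assert find_candidates(_random_dna(20_000, rng)) == []

    def test_length_filter_excludes_short_elements(self):
        rng = np.random.default_rng(2)
        win, _, _ = _window_with_implant(rng, ltr_len=300, internal_len=300)
        assert find_candidates(win, StructuralParams(min_len=2000)) == []

    def test_genome_offset_applied(self):
        rng = np.random.default_rng(3)
        win, s, e = _window_with_implant(rng)
        c = find_candidates(win, genome_offset=100_000, source_id="chr9")[0]
        assert c.source_id == "chr9"
        assert abs(c.start - (100_000 + s)) <= 10

    def test_recovery_rate_on_generated_windows(self):
        """Seeded property: implanted intact elements are recovered with
        both boundaries within +/-20 bp at a >=95% rate."""
        rng = np.random.default_rng(42)
        params = StructuralParams()
        hits = 0
        n = 30
        for _ in range(n):
            seq, truth = gen_window(True, 50_000, seed=int(rng.integers(2**31)))
            cands = apply_structural_filters(find_candidates(seq), seq, params)
            hits += any(
                abs(c.start - truth.start) <= 20 and abs(c.end - truth.end) <= 20
                for c in cands
            )
        assert hits >= 0.95 * n

    def test_candidate_sequence_extractable_from_genome(self):
        rng = np.random.default_rng(5)
        win, s, e = _window_with_implant(rng)
        g = GenomeSequence("chr1", win)
        c = find_candidates(win, source_id="chr1")[0]
        assert g.seq[c.start : c.end] == win[c.start : c.end]
        assert c.ltr5[1] <= c.ltr3[0]  # 5' LTR precedes 3' LTR


class TestMotifAndTsd:
    def _candidate(self, seq, s, e, ltr_len):
        return CandidateElement("c", s, e, (s, s + ltr_len), (e - ltr_len, e))

    def test_motif_true_for_tg_ca_ltrs(self):
        rng = np.random.default_rng(0)
        win, s, e = _window_with_implant(rng, ltr_len=200)
        assert check_motif(self._candidate(win, s, e, 200), win)

    def test_motif_false_otherwise(self):
        seq = "AG" + "A" * 96 + "CA"
        c = self._candidate(seq, 0, 100, 50)
        assert not check_motif(c, seq)

    def test_motif_check_can_be_disabled(self):
        """With require_tg_ca off, a candidate without the motif survives."""
        rng = np.random.default_rng(11)
        ltr = "AG" + _random_dna(396, rng) + "TT"  # no TG...CA termini
        elem = ltr + _random_dna(2500, rng) + ltr
        tsd = "CGTAT"
        win = _random_dna(4000 - 5, rng) + tsd + elem + tsd + _random_dna(4000, rng)
        params = StructuralParams(require_tg_ca=False, require_tsd=False)
        cands = apply_structural_filters(find_candidates(win, params), win, params)
        assert len(cands) == 1 and not cands[0].tg_ca_ok
        strict = StructuralParams(require_tg_ca=True)
        assert apply_structural_filters(find_candidates(win, strict), win, strict) == []

    def test_tsd_found_and_reported(self):
        rng = np.random.default_rng(1)
        win, s, e = _window_with_implant(rng, tsd="GATCA")
        c = self._candidate(win, s, e, 500)
        assert check_tsd(c, win) == "GATCA"

    def test_tsd_absent_at_sequence_edge(self):
        seq = "TG" + "A" * 5000 + "CA"
        c = self._candidate(seq, 0, len(seq), 100)
        assert check_tsd(c, seq) is None

    def test_tsd_absent_for_random_flanks(self):
        rng = np.random.default_rng(9)
        absent = 0
        for _ in range(20):
            seq = _random_dna(3000, rng)
            c = self._candidate(seq, 1000, 2000, 100)
            absent += check_tsd(c, seq) is None
        assert absent >= 18  # 4^-4 chance per offset makes hits rare


class TestCandidateTsv:
    def _genome(self):
        return [GenomeSequence("chr1", "A" * 10_000)]

    def test_coordinates_converted(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("chr1\t1001\t6000\t1001\t1300\t5701\t6000\n")
        (c,) = load_candidates_tsv(p, self._genome())
        assert (c.start, c.end) == (1000, 6000)
        assert c.ltr5 == (1000, 1300) and c.ltr3 == (5700, 6000)

    def test_header_row_skipped(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "source_id\tstart\tend\tltr5_start\tltr5_end\tltr3_start\tltr3_end\n"
            "chr1\t1\t5000\t1\t200\t4801\t5000\n"
        )
        assert len(load_candidates_tsv(p, self._genome())) == 1

    @pytest.mark.parametrize(
        "row,msg",
        [
            ("chr1\t6000\t1001\t1\t2\t3\t4", "line 1"),
            ("chrX\t1\t100\t1\t10\t90\t100", "chrX"),
            ("chr1\t1\t99999\t1\t10\t90\t99999", "outside"),
            ("chr1\tx\t100\t1\t10\t90\t100", "non-integer"),
            ("chr1\t1\t100", "7 columns"),
        ],
    )
    def test_malformed_rows_rejected(self, tmp_path, row, msg):
        p = tmp_path / "c.tsv"
        p.write_text(row + "\n")
        with pytest.raises(ValueError, match=msg):
            load_candidates_tsv(p, self._genome())
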