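"""Generators: determinism, coordinate consistency and class structure."""

import numpy as np
import pytest
from scipy import stats

from ltrnet.kmer_conv import build_filter_bank, count_kmers_fast
from ltrnet.synthetic_data import (
    LENGTH_TOLERANCE,
    default_lineage_models,
    gen_element,
    gen_filter_set,
    gen_genome,
    gen_lineage_set,
    gen_training_windows,
    gen_window,
)


class TestLineageModels:
    def test_thirteen_distinct_models(self):
        models = default_lineage_models()
        assert len(models) == 13
        assert len({m.name for m in models}) == 13
        for m in models:
            assert np.allclose(m.trans.sum(axis=1), 1.0)
            lo, hi = m.element_len_range
            assert 2000 <= lo < hi <= 28_000

    def test_six_mer_profiles_separate_lineages(self):
        """Inter-lineage 6-mer profile distance exceeds intra-lineage
        distance — the property that makes classifier training possible."""
        bank = build_filter_bank()
        models = default_lineage_models()
        rng = np.random.default_rng(4)
        profiles = []
        for m in models:
            reps = []
            for _ in range(3):
                e = gen_element(m, rng)
                v = count_kmers_fast(e.seq, bank).counts[bank.offsets[6]:].astype(float)
                reps.append(v / v.sum())
            profiles.append(reps)
        intra, inter = [], []
        for i, reps in enumerate(profiles):
            intra.append(np.linalg.norm(reps[0] - reps[1]))
            for j in range(i + 1, len(profiles)):
                inter.append(np.linalg.norm(reps[0] - profiles[j][0]))
        assert np.mean(inter) > 2 * np.mean(intra)


class TestGenElement:
    def test_termini_and_ltr_identity(self):
        models = default_lineage_models()
        rng = np.random.default_rng(0)
        for m in models:
            e = gen_element(m, rng)
            assert e.seq.startswith("TG") and e.seq.endswith("CA")
            a = e.seq[e.ltr5[0] : e.ltr5[1]]
            b = e.seq[e.ltr3[0] : e.ltr3[1]]
            ident = np.mean([x == y for x, y in zip(a, b)])
            assert ident >= 0.96  # 2% divergence in expectation
            lo, hi = m.element_len_range
            assert lo <= len(e.seq) <= hi

    def test_seeded_determinism(self):
        m = default_lineage_models()[3]
        assert gen_element(m, seed=5).seq == gen_element(m, seed=5).seq
        assert gen_element(m, seed=5).seq != gen_element(m, seed=6).seq


class TestGenWindow:
    def test_truth_coordinates_and_tsd(self):
        seq, truth = gen_window(True, window_size=20_000, seed=8)
        assert len(seq) == 20_000
        elem = seq[truth.start : truth.end]
        assert elem.startswith("TG") and elem.endswith("CA")
        L = len(truth.tsd)
        assert 4 <= L <= 6
        assert seq[truth.start - L : truth.start] == truth.tsd
        assert seq[truth.end : truth.end + L] == truth.tsd

    def test_background_window_has_no_truth(self):
        seq, truth = gen_window(False, window_size=5000, seed=1)
        assert len(seq) == 5000 and truth is None

    def test_oversized_elements_rejected(self):
        with pytest.raises(ValueError, match="longer than window"):
            gen_window(True, window_size=1000, seed=0)

    def test_balanced_labels(self):
        seqs, labels, truths = gen_training_windows(5, 7, window_size=5000, seed=2)
        assert len(seqs) == 12
        assert labels.sum() == 5
        for lab, t in zip(labels, truths):
            assert (t is not None) == bool(lab)
            if t is not None:
                assert 0 <= t.start < t.end <= 5000


class TestGenFilterSet:
    def test_class_counts_and_labels(self):
        seqs, labels, truths = gen_filter_set(30, 40, seed=3)
        assert len(seqs) == 70
        assert (labels == 0).sum() == 30 and (labels == 1).sum() == 40
        for lab, t in zip(labels, truths):
            assert t.intact == (lab == 0)
            assert (t.defect == "none") == t.intact

    def test_length_violations_break_the_envelope(self):
        models = {m.name: m for m in default_lineage_models()}
        _, labels, truths = gen_filter_set(5, 200, seed=9)
        checked = 0
        for t in truths:
            if t.defect != "length_violation":
                continue
            lo, hi = models[t.lineage].length_envelope(LENGTH_TOLERANCE)
            assert t.end - t.start < lo or t.end - t.start > hi
            checked += 1
        assert checked > 20

    def test_intact_elements_respect_the_envelope(self):
        models = {m.name: m for m in default_lineage_models()}
        seqs, labels, truths = gen_filter_set(50, 5, seed=10)
        for lab, t in zip(labels, truths):
            if lab == 0:
                lo, hi = models[t.lineage].length_envelope(LENGTH_TOLERANCE)
                assert lo <= t.end - t.start <= hi

    def test_defect_types_roughly_uniform(self):
        _, _, truths = gen_filter_set(1, 3000, seed=12)
        kinds = [t.defect for t in truths if not t.intact]
        _, counts = np.unique(kinds, return_counts=True)
        assert len(counts) == 3
        assert stats.chisquare(counts).pvalue > 0.01

    def test_degenerate_requests_rejected(self):
        with pytest.raises(ValueError):
            gen_filter_set(0, 5)


class TestGenGenome:
    def test_truth_is_coordinate_consistent(self):
        genome, truths = gen_genome(length=200_000, n_implants=4, seed=6)
        g = genome[0]
        assert g.length == 200_000
        assert len(truths) == 4
        for t in truths:
            elem = g.seq[t.start : t.end]
            assert elem.startswith("TG") and elem.endswith("CA")
            L = len(t.tsd)
            assert g.seq[t.start - L : t.start] == t.tsd == g.seq[t.end : t.end + L]
            assert g.seq[t.ltr5[0] : t.ltr5[0] + 2] == "TG"
            assert g.seq[t.ltr3[1] - 2 : t.ltr3[1]] == "CA"

    def test_implants_are_spaced(self):
        _, truths = gen_genome(length=300_000, n_implants=6, seed=7)
        spans = sorted((t.start, t.end) for t in truths)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert s1 - e0 >= 1000

    def test_straddling_implant_crosses_window_boundary(self):
        _, truths = gen_genome(length=500_000, n_implants=10, seed=1, straddle=True)
        strad = [t for t in truths if t.straddles]
        assert len(strad) == 1
        t = strad[0]
        assert t.straddles % 50_000 == 0
        assert t.start < t.straddles < t.end

    def test_seeded_byte_determinism(self):
        a, _ = gen_genome(length=150_000, n_implants=3, seed=5)
        b, _ = gen_genome(length=150_000, n_implants=3, seed=5)
        assert a[0].seq == b[0].seq

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            gen_genome(length=50_000, n_implants=10, seed=0)
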