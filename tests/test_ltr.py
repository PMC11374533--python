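"""LTR detection, divergence, dating, populations and clades."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centroscape.core import Genome, GenomicInterval
from centroscape.enrichment import CentromereCall
from centroscape.ltr import (
    DatingParams,
    LTRElement,
    classify_by_centromere,
    cluster_clades,
    compare_populations,
    find_ltr_pairs,
    insertion_time,
    ltr_divergence,
)
from centroscape.synth import ChromosomeSpec, LTRInsertionSpec, build_chromosome
from conftest import motif_free_dna


def _mutate(rng, s, rate):
    codes = np.frombuffer(s.encode(), np.uint8).copy()
    mask = rng.random(len(codes)) < rate
    lut = {ord(a): [ord(b) for b in "ACGT" if b != a] for a in "ACGT"}
    for i in np.flatnonzero(mask):
        codes[i] = rng.choice(lut[codes[i]])
    return codes.tobytes().decode()


class TestDivergence:
    def test_identical(self, rng):
        s = motif_free_dna(rng, 500)
        assert ltr_divergence(s, s) == (1.0, 0.0)

    def test_five_substitutions_in_500(self, rng):
        s = motif_free_dna(rng, 500)
        codes = list(s)
        for i in (10, 110, 210, 310, 410):
            codes[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[codes[i]]
        ident, k = ltr_divergence(s, "".join(codes))
        assert ident == pytest.approx(0.99)
        assert k == pytest.approx(0.01)

    def test_identity_plus_raw_k_is_one(self, rng):
        for rate in (0.0, 0.01, 0.05, 0.1):
            s = motif_free_dna(rng, 400)
            ident, k = ltr_divergence(s, _mutate(rng, s, rate))
            assert ident + k == pytest.approx(1.0)

    def test_jc69_closed_form(self, rng):
        s = motif_free_dna(rng, 1000)
        ident, k = ltr_divergence(s, _mutate(rng, s, 0.05), correction="JC69")
        p = 1.0 - ident
        assert k == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))
        assert k >= p  # correction only inflates


class TestInsertionTime:
    def test_zero(self):
        assert insertion_time(0.0, DatingParams()) == 0.0

    def test_forced_arithmetic(self):
        t = insertion_time(0.026, DatingParams(r=1.3e-8))
        assert t == pytest.approx(1_000_000, rel=1e-9)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            insertion_time(-0.1, DatingParams())

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 0.5), st.floats(1e-9, 1e-7), st.floats(1.1, 10.0))
    def test_linearity_in_k_and_inverse_in_r(self, k, r, factor):
        t = insertion_time(k, DatingParams(r=r))
        assert insertion_time(factor * k, DatingParams(r=r)) == \
            pytest.approx(factor * t)
        assert insertion_time(k, DatingParams(r=factor * r)) == \
            pytest.approx(t / factor)


class TestDetection:
    def test_identical_ltr_element_recovered(self):
        spec = ChromosomeSpec("c", 60_000, ltr_insertions=[
            LTRInsertionSpec(20_000, 500, 4_000, 0.0)])
        seq, truth = build_chromosome(spec, seed=1)
        els = find_ltr_pairs(seq)
        assert len(els) == 1
        t = truth.ltr_elements[0]
        assert abs(els[0].element.start - t.start) <= 10
        assert abs(els[0].element.end - t.end) <= 10
        assert els[0].ltr_identity == pytest.approx(1.0)

    def test_diverged_ltr_element_recovered(self):
        spec = ChromosomeSpec("c", 60_000, ltr_insertions=[
            LTRInsertionSpec(20_000, 500, 4_000, 0.02)])
        seq, truth = build_chromosome(spec, seed=2)
        els = find_ltr_pairs(seq)
        assert len(els) == 1
        assert els[0].k == pytest.approx(truth.ltr_elements[0].realized_k,
                                         abs=0.01)

    def test_single_unpaired_ltr_yields_nothing(self, rng):
        spec = ChromosomeSpec("c", 60_000, ltr_insertions=[
            LTRInsertionSpec(20_000, 500, 4_000, 0.0)])
        seq, truth = build_chromosome(spec, seed=3)
        t = truth.ltr_elements[0]
        # excise the 3' LTR, leaving a solo copy
        solo = seq.sequence[:t.ltr3[0]] + seq.sequence[t.ltr3[1]:]
        from centroscape.core import GenomeSequence

        assert find_ltr_pairs(GenomeSequence("c", solo)) == []

    def test_nested_insertion_both_reported(self):
        spec = ChromosomeSpec("c", 80_000, ltr_insertions=[
            LTRInsertionSpec(20_000, 500, 8_000, 0.0),
            LTRInsertionSpec(23_000, 300, 2_000, 0.0)])
        seq, _ = build_chromosome(spec, seed=4)
        els = find_ltr_pairs(seq)
        assert len(els) == 2
        flags = sorted((e.element.length, e.nested) for e in els)
        assert flags[0][1] is True and flags[1][1] is False


class TestClassification:
    def _el(self, start, end, chrom="c"):
        return LTRElement(GenomicInterval(chrom, start, end),
                          GenomicInterval(chrom, start, start + 100),
                          GenomicInterval(chrom, end - 100, end), 0.99, 0.01)

    def test_midpoint_rule(self):
        calls = [CentromereCall("c", GenomicInterval("c", 10_000, 20_000), 2.0)]
        inside = self._el(12_000, 18_000)
        arm = self._el(50_000, 56_000)
        straddle = self._el(19_000, 30_000)  # midpoint 24_500, outside
        out = classify_by_centromere([inside, arm, straddle], calls)
        assert [e.location_class for e in out] == \
            ["centromeric", "non_centromeric", "non_centromeric"]

    def test_partition_property(self):
        calls = [CentromereCall("c", GenomicInterval("c", 10_000, 20_000), 2.0)]
        els = [self._el(s, s + 3_000) for s in range(1_000, 90_000, 7_000)]
        classify_by_centromere(els, calls)
        assert all(e.location_class in ("centromeric", "non_centromeric")
                   for e in els)


class TestPopulations:
    def _els(self, idents, cls):
        out = []
        for i, ident in enumerate(idents):
            e = LTRElement(GenomicInterval("c", 1000 * i + 1, 1000 * i + 900),
                           GenomicInterval("c", 1000 * i + 1, 1000 * i + 101),
                           GenomicInterval("c", 1000 * i + 800, 1000 * i + 900),
                           ident, 1 - ident)
            e.location_class = cls
            out.append(e)
        return out

    def test_single_element_medians(self):
        els = self._els([0.98], "centromeric") + self._els([0.95],
                                                          "non_centromeric")
        s = compare_populations(els)
        assert s["classes"]["centromeric"]["median_identity"] == 0.98
        assert s["classes"]["non_centromeric"]["median_identity"] == 0.95

    def test_older_centromeric_population_detected(self, rng):
        """Centromeric elements aged ~2x have lower identity; rank-sum sees it
        at n = 100 per class."""
        noncen = 1 - rng.binomial(500, 0.02, 100) / 500
        cen = 1 - rng.binomial(500, 0.04, 100) / 500
        els = self._els(cen, "centromeric") + self._els(noncen,
                                                        "non_centromeric")
        s = compare_populations(els)
        assert s["classes"]["centromeric"]["median_identity"] < \
            s["classes"]["non_centromeric"]["median_identity"]
        assert s["ranksum_p"] < 1e-6

    def test_absent_class_flagged(self):
        s = compare_populations(self._els([0.99], "centromeric"))
        assert s["classes"]["non_centromeric"]["absent"]
        assert "ranksum_p" not in s


class TestClades:
    def _element_set(self, rng, n_ancestors, per_clade, load=0.02):
        seqs, els = [], []
        for a in range(n_ancestors):
            anc = motif_free_dna(rng, 2_000)
            for i in range(per_clade):
                s = _mutate(rng, anc, load)
                els.append(LTRElement(
                    GenomicInterval("c", 10_000 * len(els) + 1,
                                    10_000 * len(els) + 2_001),
                    GenomicInterval("c", 10_000 * len(els) + 1,
                                    10_000 * len(els) + 301),
                    GenomicInterval("c", 10_000 * len(els) + 1_700,
                                    10_000 * len(els) + 2_001), 0.98, 0.02))
                seqs.append(s)
        return els, seqs

    def test_two_ancestors_two_clades(self, rng):
        els, seqs = self._element_set(rng, 2, 5)
        cluster_clades(els, seqs, linkage_identity=0.7)
        clades = {e.clade for e in els}
        assert len(clades) == 2
        assert {e.clade for e in els[:5]} != {e.clade for e in els[5:]}

    def test_identical_elements_one_clade(self, rng):
        els, seqs = self._element_set(rng, 1, 4, load=0.0)
        cluster_clades(els, seqs)
        assert {e.clade for e in els} == {1}

    def test_clade_count_monotone_in_threshold(self, rng):
        els, seqs = self._element_set(rng, 3, 3, load=0.05)
        counts = []
        for thr in (0.99, 0.9, 0.7, 0.5, 0.1):
            cluster_clades(els, seqs, linkage_identity=thr)
            counts.append(len({e.clade for e in els}))
        assert counts == sorted(counts, reverse=True)

    def test_too_few_elements_rejected(self, rng):
        els, seqs = self._element_set(rng, 1, 1)
        with pytest.raises(ValueError):
            cluster_clades(els, seqs)


def test_simulated_clock_recovery(rng):
    """Divergence of independently mutated LTR pairs matches the clock: mean
    K within 3 binomial sigma, median T within 10% of truth (100 elements)."""
    m = 0.02
    p_diff = 2 * m * (1 - m) + (2 / 3) * m * m
    L = 500
    ks = []
    for _ in range(100):
        base = motif_free_dna(rng, L)
        _, k = ltr_divergence(_mutate(rng, base, m), _mutate(rng, base, m))
        ks.append(k)
    se = math.sqrt(p_diff * (1 - p_diff) / (L * 100))
    assert abs(np.mean(ks) - p_diff) < 3 * se + 1e-3
    params = DatingParams()
    t_med = float(np.median([insertion_time(k, params) for k in ks]))
    t_true = insertion_time(p_diff, params)
    assert abs(t_med - t_true) / t_true < 0.10
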