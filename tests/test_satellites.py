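"""Tandem-array discovery, consensus building, families, dot plots."""

import numpy as np
import pytest

from centroscape.core import GenomeSequence, GenomicInterval, revcomp
from centroscape.enrichment import CentromereCall
from centroscape.satellites import (
    SatelliteArray,
    build_consensus,
    canonical_rotation,
    centromere_composition,
    classify_families,
    dotplot_matrix,
    find_tandem_arrays,
)
from centroscape.synth import ChromosomeSpec, build_chromosome
from conftest import motif_free_dna, rand_dna


def _array_chromosome(rng, period, copies, mutation, seed, flank=20_000):
    master = motif_free_dna(rng, period)
    spec = ChromosomeSpec(
        "c", 2 * flank + (copies + 1) * period,
        centromere=(flank, flank + copies * period + period // 2),
        satellite_monomer=master, satellite_mutation_rate=mutation)
    seq, truth = build_chromosome(spec, seed=seed)
    return seq, truth.satellite_arrays[0]


class TestFindTandemArrays:
    def test_exact_copies_recovered_exactly(self, rng):
        seq, truth = _array_chromosome(rng, 356, 50, 0.0, seed=1)
        arrays = find_tandem_arrays(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.period == 356 and a.copy_number == 50
        assert (a.interval.start, a.interval.end) == (truth.start, truth.end)
        assert a.consensus == canonical_rotation(truth.master)
        assert a.mean_copy_identity == 1.0

    @pytest.mark.parametrize("period", [54, 356, 365, 530, 732])
    def test_recovery_under_mutation(self, rng, period):
        seq, truth = _array_chromosome(rng, period, 40, 0.02, seed=period)
        arrays = find_tandem_arrays(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert abs(a.period - period) <= 2
        assert abs(a.copy_number - truth.copies) <= 1

    def test_random_sequence_yields_nothing(self, rng):
        for s in range(3):
            seq = GenomeSequence("n", rand_dna(np.random.default_rng(s), 100_000))
            assert find_tandem_arrays(seq) == []

    def test_short_sequence_empty(self):
        assert find_tandem_arrays(GenomeSequence("s", "ACGT" * 20)) == []


class TestBuildConsensus:
    def test_identical_copies(self, rng):
        c = motif_free_dna(rng, 120)
        assert build_consensus([c, c, c]) == c

    def test_too_few_copies(self, rng):
        c = motif_free_dna(rng, 120)
        with pytest.raises(ValueError):
            build_consensus([c, c])

    def test_majority_recovers_master(self, rng):
        master = motif_free_dna(rng, 356)
        codes = np.frombuffer(master.encode(), dtype=np.uint8).copy()
        copies = []
        for _ in range(50):
            cp = codes.copy()
            mask = rng.random(len(cp)) < 0.02
            cp[mask] = [ord("ACGT"[(("ACGT".index(chr(b)) + 1) % 4)])
                        for b in cp[mask]]
            copies.append(cp.tobytes().decode())
        assert build_consensus(copies) == master

    def test_unequal_lengths_star_alignment(self, rng):
        master = motif_free_dna(rng, 100)
        short = master[:40] + master[41:]  # one deletion
        cons = build_consensus([master, master, master, short])
        assert cons == master


class TestFamilies:
    def _arr(self, consensus, chrom="c", start=0, copies=40):
        period = len(consensus)
        return SatelliteArray(
            GenomicInterval(chrom, start, start + copies * period), period,
            copies, canonical_rotation(consensus), 0.98)

    def test_same_master_one_family(self, rng):
        m = motif_free_dna(rng, 356)
        fams = classify_families([self._arr(m, start=0),
                                  self._arr(m, start=100_000)])
        assert len(fams) == 1
        assert fams[0].name == "CentFs356"
        assert len(fams[0].arrays) == 2

    def test_unrelated_masters_two_named_families(self, rng):
        fams = classify_families([self._arr(motif_free_dna(rng, 356)),
                                  self._arr(motif_free_dna(rng, 530),
                                            start=100_000)])
        assert sorted(f.name for f in fams) == ["CentFs356", "CentFs530"]

    def test_rotated_monomers_merge(self, rng):
        m = motif_free_dna(rng, 300)
        rotated = m[137:] + m[:137]
        fams = classify_families([self._arr(m), self._arr(rotated,
                                                          start=50_000)])
        assert len(fams) == 1

    def test_length_collision_gets_suffix(self, rng):
        fams = classify_families([self._arr(motif_free_dna(rng, 356)),
                                  self._arr(motif_free_dna(rng, 356),
                                            start=100_000, copies=30)])
        assert sorted(f.name for f in fams) == ["CentFs356", "CentFs356b"]

    def test_permutation_invariance(self, rng):
        arrays = [self._arr(motif_free_dna(rng, L), start=i * 100_000)
                  for i, L in enumerate([356, 356, 530])]
        a = classify_families(arrays)
        b = classify_families(arrays[::-1])
        assert sorted((f.name, len(f.arrays)) for f in a) == \
            sorted((f.name, len(f.arrays)) for f in b)


class TestRotation:
    def test_canonical_rotation_is_rotation_invariant(self, rng):
        s = motif_free_dna(rng, 97)
        for i in range(0, 97, 13):
            assert canonical_rotation(s[i:] + s[:i]) == canonical_rotation(s)


class TestComposition:
    def _call(self, start, end):
        return CentromereCall("c", GenomicInterval("c", start, end), 2.0)

    def test_full_and_half_coverage(self, rng):
        m = motif_free_dna(rng, 100)
        fams = classify_families([SatelliteArray(
            GenomicInterval("c", 0, 10_000), 100, 100,
            canonical_rotation(m), 0.99)])
        full = centromere_composition([self._call(0, 10_000)], fams)
        half = centromere_composition([self._call(5_000, 15_000)], fams)
        name = fams[0].name
        assert full[name].iloc[0] == pytest.approx(1.0)
        assert half[name].iloc[0] == pytest.approx(0.5)
        assert full["dominant"].iloc[0] == name

    def test_interleaved_families_recover_shares(self, rng):
        """60/40 interleaved arrays of two families within one centromere."""
        m1, m2 = motif_free_dna(rng, 100), motif_free_dna(rng, 120)
        arrays = []
        pos = 0
        for i in range(10):
            if i % 2 == 0:
                arrays.append(SatelliteArray(
                    GenomicInterval("c", pos, pos + 6_000), 100, 60,
                    canonical_rotation(m1), 0.99))
                pos += 6_000
            else:
                arrays.append(SatelliteArray(
                    GenomicInterval("c", pos, pos + 4_000), 120, 33,
                    canonical_rotation(m2), 0.99))
                pos += 4_000
        fams = classify_families(arrays)
        comp = centromere_composition([self._call(0, pos)], fams)
        shares = sorted(comp[f.name].iloc[0] for f in fams)
        assert shares[0] == pytest.approx(0.4, abs=0.05)
        assert shares[1] == pytest.approx(0.6, abs=0.05)


class TestDotPlot:
    def test_self_comparison_has_main_diagonal(self, rng):
        s = motif_free_dna(rng, 1000)
        dp = dotplot_matrix(s, s, window=100)
        fwd = {(a, b) for a, b, st in dp.points if st == "+"}
        assert all((i, i) in fwd for i in range(0, 1000, 100))

    def test_tandem_off_diagonals_match_brute_force(self, rng):
        m = motif_free_dna(rng, 200)
        s = m * 5
        dp = dotplot_matrix(s, s, window=100, min_identity=0.8)
        fwd = {(a, b) for a, b, st in dp.points if st == "+"}
        # brute-force oracle: identical windows repeat every 200 bp
        expected = {(a, b) for a in range(0, 1000, 100)
                    for b in range(0, 1000, 100) if (a - b) % 200 == 0}
        assert fwd == expected

    def test_reverse_complement_matches_tagged(self, rng):
        s = motif_free_dna(rng, 400)
        dp = dotplot_matrix(s, revcomp(s), window=100)
        rev = {(a, b) for a, b, st in dp.points if st == "-"}
        # window i of s matches window (len-... ) of revcomp on the antidiagonal
        assert {(0, 300), (100, 200), (200, 100), (300, 0)} <= rev

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            dotplot_matrix("ACGT", "ACGT", window=100)


def test_array_intervals_do_not_overlap(rng):
    """Two planted arrays on one chromosome come back disjoint."""
    m1, m2 = motif_free_dna(rng, 356), motif_free_dna(rng, 530)
    spec1 = ChromosomeSpec("c", 120_000, centromere=(10_000, 10_000 + 40 * 356),
                           satellite_monomer=m1)
    seq1, _ = build_chromosome(spec1, seed=1)
    spec2 = ChromosomeSpec("c", 120_000, centromere=(60_000, 60_000 + 40 * 530),
                           satellite_monomer=m2)
    seq2, _ = build_chromosome(spec2, seed=2)
    combined = GenomeSequence(
        "c", seq1.sequence[:55_000] + seq2.sequence[55_000:])
    arrays = find_tandem_arrays(combined)
    assert len(arrays) == 2
    arrays.sort(key=lambda a: a.interval.start)
    assert arrays[0].interval.end <= arrays[1].interval.start
    assert {a.period for a in arrays} == {356, 530}
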