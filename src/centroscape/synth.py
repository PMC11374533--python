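"""Synthetic genomes with the statistical structure the analysis assumes.

A chromosome is an i.i.d. background (configurable GC) onto which the
generator pastes, at specified coordinates: terminal telomere tracts
(5' CCCTAAA / 3' TTTAGGG), a centromeric tandem-satellite array (each monomer
copy independently substituted at a per-site rate), full-length LTR
retrotransposons whose two LTRs carry independent substitution loads, and
optional extra repeat copies (for dispersed-repeat scenarios).  ChIP and
input fragment sets are then simulated as genomic intervals: input uniform
over the genome, ChIP concentrated on the satellite arrays with optionally
phased midpoints.

Two identifiability choices are built into the generator (not the analysis):

* the background bases immediately flanking a planted satellite array are
  rejection-sampled so the tandem periodicity terminates exactly at the
  planted boundary — otherwise the true array edge is not a well-defined
  quantity a detector could be scored against;
* chance telomere-motif heptamers in the background are scrubbed (one base
  flipped) outside the planted tracts, so exact motif counting round-trips;
  planted master monomers and LTR sequences are rejection-sampled to be
  motif-free so the scrub never touches them systematically.

The mutation model is substitution-only by default, which keeps period and
divergence arithmetic exact for recovery tests.  A single generator is
seeded once per invocation and threaded through every step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    FragmentSet,
    Genome,
    GenomeSequence,
    read_fasta,
    read_fragments_bed,
    read_json,
    write_fasta,
    write_fragments_bed,
    write_json,
)

TELOMERE_5P = "CCCTAAA"
TELOMERE_3P = "TTTAGGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 4


def encode(seq: str) -> np.ndarray:
    """ACGTN string -> uint8 codes 0..3 (N -> 4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


class SpecError(ValueError):
    """A chromosome spec component is inconsistent or does not fit."""


@dataclass
class LTRInsertionSpec:
    """A full-length LTR retrotransposon to plant at ``position``.

    ``per_ltr_mutation_load`` is the expected per-site substitution
    probability applied independently to each of the two LTR copies; the
    element is born with identical LTRs and diverges symmetrically.
    """

    position: int
    ltr_length: int = 500
    internal_length: int = 4000
    per_ltr_mutation_load: float = 0.0

    def __post_init__(self) -> None:
        if self.ltr_length < 100:
            raise SpecError("ltr_length must be >= 100")
        if self.internal_length < 0 or self.position < 0:
            raise SpecError("negative internal_length or position")
        if not 0.0 <= self.per_ltr_mutation_load <= 0.5:
            raise SpecError("per_ltr_mutation_load outside [0, 0.5]")

    @property
    def total_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length


@dataclass
class ChromosomeSpec:
    name: str
    length: int
    telomere_copies_5p: int = 0
    telomere_copies_3p: int = 0
    centromere: tuple[int, int] | None = None
    satellite_monomer: str | None = None
    satellite_mutation_rate: float = 0.02
    ltr_insertions: list[LTRInsertionSpec] = field(default_factory=list)
    extra_repeats: list[tuple[int, str]] = field(default_factory=list)
    gc_background: float = 0.36

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SpecError("chromosome length must be positive")
        if not 0.0 <= self.satellite_mutation_rate <= 0.2:
            raise SpecError("satellite_mutation_rate outside [0, 0.2]")
        if not 0.0 < self.gc_background < 1.0:
            raise SpecError("gc_background outside (0, 1)")
        if self.centromere is not None:
            s, e = self.centromere
            if not (0 <= s < e <= self.length):
                raise SpecError("centromere interval outside chromosome")
            if self.satellite_monomer is None:
                raise SpecError("centromere requires a satellite_monomer")
        tel5 = 7 * self.telomere_copies_5p
        tel3 = 7 * self.telomere_copies_3p
        if tel5 + tel3 > self.length:
            raise SpecError("telomere tracts exceed chromosome length")
        if self.centromere is not None and (
            self.centromere[0] < tel5 or self.centromere[1] > self.length - tel3
        ):
            raise SpecError("telomere tracts overlap centromere")


@dataclass
class TelomereTruth:
    chrom: str
    end: str  # "5p" | "3p"
    start: int
    stop: int
    copies: int


@dataclass
class SatelliteArrayTruth:
    chrom: str
    start: int
    end: int
    period: int
    copies: int
    master: str


@dataclass
class LTRTruth:
    chrom: str
    start: int
    end: int
    ltr_length: int
    internal_length: int
    load: float
    realized_k: float
    nested: bool = False

    @property
    def ltr5(self) -> tuple[int, int]:
        return (self.start, self.start + self.ltr_length)

    @property
    def ltr3(self) -> tuple[int, int]:
        return (self.end - self.ltr_length, self.end)


@dataclass
class TruthAnnotation:
    """Ground truth for parameter-recovery tests."""

    seed: int | None = None
    telomeres: list[TelomereTruth] = field(default_factory=list)
    satellite_arrays: list[SatelliteArrayTruth] = field(default_factory=list)
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    ltr_elements: list[LTRTruth] = field(default_factory=list)
    phase_positions: list[int] | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "telomeres": [vars(t).copy() for t in self.telomeres],
            "satellite_arrays": [vars(a).copy() for a in self.satellite_arrays],
            "centromeres": {c: list(iv) for c, iv in self.centromeres.items()},
            "ltr_elements": [vars(e).copy() for e in self.ltr_elements],
            "phase_positions": self.phase_positions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthAnnotation":
        return cls(
            seed=d.get("seed"),
            telomeres=[TelomereTruth(**t) for t in d["telomeres"]],
            satellite_arrays=[SatelliteArrayTruth(**a) for a in d["satellite_arrays"]],
            centromeres={c: (iv[0], iv[1]) for c, iv in d["centromeres"].items()},
            ltr_elements=[LTRTruth(**e) for e in d["ltr_elements"]],
            phase_positions=d.get("phase_positions"),
        )


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


_MOTIF_RE = re.compile(f"(?={TELOMERE_5P}|{TELOMERE_3P})")


def _motif_free_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random codes guaranteed to contain no telomere-motif heptamer."""
    for _ in range(50):
        codes = _random_codes(rng, n, gc)
        if not _MOTIF_RE.search(decode(codes)):
            return codes
        # scrub in place instead of rejecting whole sequence for long n
        s = decode(codes)
        for m in _MOTIF_RE.finditer(s):
            i = m.start() + 3
            codes[i] = (codes[i] + rng.integers(1, 4)) % 4
        if not _MOTIF_RE.search(decode(codes)):
            return codes
    raise RuntimeError("failed to generate motif-free sequence")  # pragma: no cover


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Per-site substitutions at ``rate``; a substitution always changes the base."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(len(codes)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def build_chromosome(spec: ChromosomeSpec, seed: int | None = None,
                     rng: np.random.Generator | None = None
                     ) -> tuple[GenomeSequence, TruthAnnotation]:
    """Realise one chromosome and its ground-truth annotation.

    Deterministic given ``(spec, seed)``.  Either a seed or an existing
    generator may be supplied (the latter for multi-chromosome genomes that
    share one generator).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    truth = TruthAnnotation(seed=seed)
    L = spec.length
    codes = _random_codes(rng, L, spec.gc_background)
    occupied: list[tuple[int, int]] = []

    def claim(s: int, e: int, what: str) -> None:
        if s < 0 or e > L:
            raise SpecError(f"{what} [{s}, {e}) exceeds chromosome length {L}")
        for a, b in occupied:
            if s < b and a < e:
                raise SpecError(f"{what} [{s}, {e}) overlaps another feature")
        occupied.append((s, e))

    # telomere tracts
    if spec.telomere_copies_5p:
        tract = encode(TELOMERE_5P * spec.telomere_copies_5p)
        claim(0, len(tract), "5p telomere")
        codes[: len(tract)] = tract
        truth.telomeres.append(
            TelomereTruth(spec.name, "5p", 0, len(tract), spec.telomere_copies_5p)
        )
    if spec.telomere_copies_3p:
        tract = encode(TELOMERE_3P * spec.telomere_copies_3p)
        claim(L - len(tract), L, "3p telomere")
        codes[L - len(tract):] = tract
        truth.telomeres.append(
            TelomereTruth(spec.name, "3p", L - len(tract), L,
                          spec.telomere_copies_3p)
        )

    # centromeric satellite array
    if spec.centromere is not None:
        cen_s, cen_e = spec.centromere
        monomer = spec.satellite_monomer.upper()
        p = len(monomer)
        n_copies = (cen_e - cen_s) // p
        if n_copies < 3:
            raise SpecError("centromere interval shorter than 3 monomers")
        arr_s, arr_e = cen_s, cen_s + n_copies * p
        claim(arr_s, arr_e, "satellite array")
        master = encode(monomer)
        tiled = np.tile(master, n_copies)
        codes[arr_s:arr_e] = _mutate(rng, tiled, spec.satellite_mutation_rate)
        # terminate periodicity exactly at the planted boundary
        for j in range(1, 4):
            if arr_s - j >= 0 and codes[arr_s - j] == master[p - j]:
                codes[arr_s - j] = (master[p - j] + rng.integers(1, 4)) % 4
            if arr_e + j - 1 < L and codes[arr_e + j - 1] == master[j - 1]:
                codes[arr_e + j - 1] = (master[j - 1] + rng.integers(1, 4)) % 4
        truth.satellite_arrays.append(
            SatelliteArrayTruth(spec.name, arr_s, arr_e, p, n_copies, monomer)
        )
        truth.centromeres[spec.name] = (cen_s, cen_e)

    # LTR retrotransposons (later elements may nest inside earlier internals)
    planted_internals: list[tuple[int, int]] = []
    for ins in spec.ltr_insertions:
        s, e = ins.position, ins.position + ins.total_length
        nested = any(a <= s and e <= b for a, b in planted_internals)
        if not nested:
            claim(s, e, "LTR element")
        ltr = _motif_free_seq(rng, ins.ltr_length, spec.gc_background)
        internal = _motif_free_seq(rng, ins.internal_length, spec.gc_background)
        ltr5 = _mutate(rng, ltr, ins.per_ltr_mutation_load)
        ltr3 = _mutate(rng, ltr, ins.per_ltr_mutation_load)
        codes[s:s + ins.ltr_length] = ltr5
        codes[s + ins.ltr_length:e - ins.ltr_length] = internal
        codes[e - ins.ltr_length:e] = ltr3
        realized_k = float(np.mean(ltr5 != ltr3))
        truth.ltr_elements.append(
            LTRTruth(spec.name, s, e, ins.ltr_length, ins.internal_length,
                     ins.per_ltr_mutation_load, realized_k, nested=nested)
        )
        planted_internals.append((s + ins.ltr_length, e - ins.ltr_length))

    # extra repeat copies (dispersed-repeat scenarios)
    for pos, repseq in spec.extra_repeats:
        rep = encode(repseq.upper())
        claim(pos, pos + len(rep), "extra repeat")
        codes[pos:pos + len(rep)] = rep

    seq = decode(codes)
    seq = _scrub_telomere_motifs(seq, truth, rng)

    # re-measure realized LTR divergence after the scrub pass
    for el in truth.ltr_elements:
        a = encode(seq[el.ltr5[0]:el.ltr5[1]])
        b = encode(seq[el.ltr3[0]:el.ltr3[1]])
        el.realized_k = float(np.mean(a != b))

    return GenomeSequence(spec.name, seq), truth


def _scrub_telomere_motifs(seq: str, truth: TruthAnnotation,
                           rng: np.random.Generator) -> str:
    """Flip one base of every chance telomere-motif occurrence outside the
    planted tracts, so exact terminal counting is noise-free."""
    tracts = [(t.start, t.stop) for t in truth.telomeres]
    codes = encode(seq)
    for _ in range(10):
        hits = [m.start() for m in _MOTIF_RE.finditer(decode(codes))]
        hits = [h for h in hits if not any(a <= h and h + 7 <= b for a, b in tracts)]
        if not hits:
            return decode(codes)
        for h in hits:
            i = h + 3
            codes[i] = (codes[i] + rng.integers(1, 4)) % 4
    raise RuntimeError("telomere-motif scrub did not converge")  # pragma: no cover


def build_genome(specs: list[ChromosomeSpec], seed: int
                 ) -> tuple[Genome, TruthAnnotation]:
    """Realise a multi-chromosome genome from one seeded generator."""
    rng = np.random.default_rng(seed)
    merged = TruthAnnotation(seed=seed)
    seqs = []
    for spec in specs:
        seq, truth = build_chromosome(spec, rng=rng)
        seqs.append(seq)
        merged.telomeres += truth.telomeres
        merged.satellite_arrays += truth.satellite_arrays
        merged.centromeres.update(truth.centromeres)
        merged.ltr_elements += truth.ltr_elements
    return Genome(seqs), merged


# ---------------------------------------------------------------------------
# fragment simulation
# ---------------------------------------------------------------------------

def _uniform_fragments(rng: np.random.Generator, genome: Genome, n: int,
                       mean_len: float) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    names = genome.names
    lens = np.array([genome[c].length for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n, p=lens / lens.sum())
    lengths = np.maximum(20, np.rint(rng.normal(mean_len, 0.1 * mean_len, n))).astype(np.int64)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i, c in enumerate(names):
        m = chrom_idx == i
        if not m.any():
            continue
        mids = rng.integers(0, genome[c].length, size=int(m.sum()))
        ln = lengths[m]
        starts = np.maximum(0, mids - ln // 2)
        ends = np.minimum(genome[c].length, starts + ln)
        starts = np.maximum(0, np.minimum(starts, ends - 1))
        out[c] = (starts, ends)
    return out


def simulate_fragments(genome: Genome, truth: TruthAnnotation, n_input: int,
                       n_chip: int, chip_centromere_fraction: float,
                       fragment_length: float = 150.0,
                       phase_positions: list[int] | None = None,
                       phase_sd: float = 10.0, seed: int = 0
                       ) -> tuple[FragmentSet, FragmentSet]:
    """Simulate ChIP and input fragment sets as genomic intervals.

    Input fragments are uniform over the genome.  A
    ``chip_centromere_fraction`` share of ChIP fragments (rounded to an exact
    count) has midpoints placed on satellite arrays — at
    ``array_start + k*period + phase + Normal(0, phase_sd)`` when
    ``phase_positions`` are given, else uniform within a monomer copy; the
    remainder is uniform like input.  Counts are exact and the whole
    simulation is deterministic given ``seed``.
    """
    if n_input <= 0 or n_chip <= 0:
        raise ValueError("fragment counts must be positive")
    if not 0.0 <= chip_centromere_fraction <= 1.0:
        raise ValueError("chip_centromere_fraction outside [0, 1]")
    arrays = truth.satellite_arrays
    if chip_centromere_fraction > 0 and not arrays:
        raise ValueError("no satellite arrays in truth to target")
    if phase_positions is not None:
        periods = {a.period for a in arrays}
        if any(p < 0 or p >= min(periods) for p in phase_positions):
            raise ValueError("phase positions outside monomer length")

    rng = np.random.default_rng(seed)
    input_by_chrom = _uniform_fragments(rng, genome, n_input, fragment_length)

    n_cen = int(round(chip_centromere_fraction * n_chip))
    chip_acc: dict[str, list[np.ndarray]] = {}

    if n_cen:
        weights = np.array([a.copies for a in arrays], dtype=float)
        which = rng.choice(len(arrays), size=n_cen, p=weights / weights.sum())
        lengths = np.maximum(
            20, np.rint(rng.normal(fragment_length, 0.1 * fragment_length, n_cen))
        ).astype(np.int64)
        for ai, arr in enumerate(arrays):
            m = which == ai
            cnt = int(m.sum())
            if not cnt:
                continue
            k = rng.integers(0, arr.copies, size=cnt)
            if phase_positions is not None:
                pos = rng.choice(phase_positions, size=cnt).astype(float)
                pos = pos + rng.normal(0.0, phase_sd, size=cnt)
            else:
                pos = rng.uniform(0, arr.period, size=cnt)
            mids = arr.start + k * arr.period + np.rint(pos).astype(np.int64)
            mids = np.clip(mids, arr.start, arr.end - 1)
            ln = lengths[m]
            clen = genome[arr.chrom].length
            starts = np.maximum(0, mids - ln // 2)
            ends = np.minimum(clen, starts + ln)
            chip_acc.setdefault(arr.chrom, []).append(
                np.stack([starts, ends], axis=1)
            )

    bg = _uniform_fragments(rng, genome, n_chip - n_cen, fragment_length) \
        if n_chip - n_cen > 0 else {}
    for c, (s, e) in bg.items():
        chip_acc.setdefault(c, []).append(np.stack([s, e], axis=1))

    chip_by_chrom = {
        c: (np.concatenate(blocks)[:, 0], np.concatenate(blocks)[:, 1])
        for c, blocks in chip_acc.items()
    }
    chip = FragmentSet("chip", chip_by_chrom)
    inp = FragmentSet("input", input_by_chrom)
    chip.validate_against(genome)
    inp.validate_against(genome)
    if phase_positions is not None:
        truth.phase_positions = list(phase_positions)
    return chip, inp


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixture(genome: Genome, truth: TruthAnnotation, chip: FragmentSet,
                  inp: FragmentSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, out / "genome.fa")
    write_json(truth.to_dict(), out / "truth.json")
    write_fragments_bed(chip, out / "chip.bed")
    write_fragments_bed(inp, out / "input.bed")


def read_fixture(out_dir: str | Path
                 ) -> tuple[Genome, TruthAnnotation, FragmentSet, FragmentSet]:
    out = Path(out_dir)
    genome = read_fasta(out / "genome.fa")
    truth = TruthAnnotation.from_dict(read_json(out / "truth.json"))
    chip = read_fragments_bed(out / "chip.bed", genome, label="chip")
    inp = read_fragments_bed(out / "input.bed", genome, label="input")
    return genome, truth, chip, inp
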