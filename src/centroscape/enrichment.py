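"""Windowed ChIP/input enrichment, centromere calling and summaries.

Fragment density is computed in fixed windows (default 100 kb) along each
chromosome: every fragment is assigned to the window containing its
midpoint, and the window value is reads-per-million scaled by 1/100, i.e.
``(count / total) * 1e6 / 100``.  Enrichment is the ratio of ChIP to input
density with a pseudocount (default one fragment-equivalent per track before
normalisation), recorded alongside its log2.  A functional centromere is
called as a maximal run of windows with log2 ratio above a threshold; sizes
and the genome-wide summary mirror the standard per-chromosome reporting
(total / min / max / mean size and percent of genome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BoundsError, FragmentSet, Genome, GenomicInterval

RPM_SCALE = 1e6 / 100  # reads per million / 100


@dataclass
class DensityTrack:
    label: str
    window_size: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]
    total_count: int

    def n_windows(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.window_size)

    def window_bounds(self, chrom: str, i: int) -> tuple[int, int]:
        s = i * self.window_size
        return s, min(s + self.window_size, self.chrom_lengths[chrom])

    def to_bedgraph_rows(self) -> list[tuple[str, int, int, float]]:
        rows = []
        for c in self.values:
            for i, v in enumerate(self.values[c]):
                s, e = self.window_bounds(c, i)
                rows.append((c, s, e, float(v)))
        return rows


@dataclass
class RatioTrack:
    window_size: int
    chrom_lengths: dict[str, int]
    ratio: dict[str, np.ndarray]
    log2: dict[str, np.ndarray]
    zero_input: dict[str, np.ndarray]
    pseudocount: float

    def window_bounds(self, chrom: str, i: int) -> tuple[int, int]:
        s = i * self.window_size
        return s, min(s + self.window_size, self.chrom_lengths[chrom])

    def to_bedgraph_rows(self, which: str = "log2") -> list[tuple[str, int, int, float]]:
        source = self.log2 if which == "log2" else self.ratio
        rows = []
        for c in source:
            for i, v in enumerate(source[c]):
                s, e = self.window_bounds(c, i)
                rows.append((c, s, e, float(v)))
        return rows


@dataclass
class CentromereCall:
    chrom: str
    interval: GenomicInterval
    mean_log2_ratio: float
    primary: bool = True

    @property
    def size_mb(self) -> float:
        return self.interval.length / 1e6


@dataclass
class CentromereSummary:
    """Genome-wide centromere size statistics (raw values retained;
    reporting rounds mean to 1 decimal and percent to 2)."""

    sizes_mb: list[float]
    genome_size_mb: float

    @property
    def total_mb(self) -> float:
        return float(sum(self.sizes_mb))

    @property
    def min_mb(self) -> float:
        return float(min(self.sizes_mb))

    @property
    def max_mb(self) -> float:
        return float(max(self.sizes_mb))

    @property
    def mean_mb(self) -> float:
        return self.total_mb / len(self.sizes_mb)

    @property
    def percent_of_genome(self) -> float:
        return 100.0 * self.total_mb / self.genome_size_mb

    def report(self) -> dict[str, float]:
        return {
            "n": len(self.sizes_mb),
            "total_mb": round(self.total_mb, 1),
            "min_mb": round(self.min_mb, 1),
            "max_mb": round(self.max_mb, 1),
            "mean_mb": round(self.mean_mb, 1),
            "percent_of_genome": round(self.percent_of_genome, 2),
        }


def compute_window_density(fragments: FragmentSet, genome: Genome,
                           window_size: int = 100_000) -> DensityTrack:
    """Per-window fragment density in RPM/100, by fragment midpoint."""
    if window_size < 1000:
        raise ValueError("window_size must be >= 1 kb")
    total = fragments.total_count
    if total == 0:
        raise ValueError("empty fragment set: normalization undefined")
    fragments.validate_against(genome)
    values: dict[str, np.ndarray] = {}
    for c in genome.names:
        nwin = -(-genome[c].length // window_size)
        mids = fragments.midpoints(c)
        counts = np.bincount(mids // window_size, minlength=nwin).astype(float)
        values[c] = counts / total * RPM_SCALE
    return DensityTrack(fragments.label, window_size, genome.lengths(), values, total)


def enrichment_ratio(chip: DensityTrack, inp: DensityTrack,
                     pseudocount: float = 1.0) -> RatioTrack:
    """ChIP/input ratio per window with a pseudocount of ``pseudocount``
    fragment-equivalents added to each track before the ratio."""
    if chip.window_size != inp.window_size or chip.chrom_lengths != inp.chrom_lengths:
        raise BoundsError("chip and input tracks have mismatched windowing")
    pc_chip = pseudocount / chip.total_count * RPM_SCALE
    pc_inp = pseudocount / inp.total_count * RPM_SCALE
    ratio, log2, zero = {}, {}, {}
    for c in chip.values:
        num = chip.values[c] + pc_chip
        den = inp.values[c] + pc_inp
        if pseudocount <= 0 and np.any(den == 0):
            raise ZeroDivisionError(
                f"zero input windows on {c} with no pseudocount"
            )
        ratio[c] = num / den
        log2[c] = np.log2(ratio[c])
        zero[c] = inp.values[c] == 0
    return RatioTrack(chip.window_size, dict(chip.chrom_lengths), ratio, log2,
                      zero, pseudocount)


def _runs(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of True, allowing internal gaps of up to merge_gap."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = int(idx[0])
    for i in idx[1:].tolist():
        if i - prev - 1 <= merge_gap:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def call_centromeres(ratio: RatioTrack, min_log2: float = 1.0,
                     min_windows: int = 3, merge_gap: int = 1
                     ) -> list[CentromereCall]:
    """Call CENH3-enriched intervals as window runs with log2 >= min_log2.

    Runs separated by at most ``merge_gap`` sub-threshold windows are merged;
    merged runs spanning fewer than ``min_windows`` windows are dropped.  All
    surviving runs are reported; per chromosome the run with the highest mean
    log2 is flagged primary.  Boundaries snap to window edges (clipped to the
    chromosome end).
    """
    calls: list[CentromereCall] = []
    w = ratio.window_size
    for c, lg in ratio.log2.items():
        chrom_calls = []
        for a, b in _runs(lg >= min_log2, merge_gap):
            if b - a < min_windows:
                continue
            start = a * w
            end = min(b * w, ratio.chrom_lengths[c])
            chrom_calls.append(CentromereCall(
                c, GenomicInterval(c, start, end),
                float(np.mean(lg[a:b])), primary=False,
            ))
        if chrom_calls:
            best = max(range(len(chrom_calls)),
                       key=lambda i: chrom_calls[i].mean_log2_ratio)
            chrom_calls[best].primary = True
        calls.extend(chrom_calls)
    return calls


def centromere_summary(sizes_mb: list[float], genome_size_mb: float
                       ) -> CentromereSummary:
    if not sizes_mb:
        raise ValueError("no centromere sizes to summarise")
    if any(s <= 0 for s in sizes_mb):
        raise ValueError("centromere sizes must be positive")
    return CentromereSummary(list(sizes_mb), genome_size_mb)


# ---------------------------------------------------------------------------
# feature-level enrichment
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: list[GenomicInterval]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for c, pairs in by_chrom.items():
        pairs.sort()
        out = [list(pairs[0])]
        for s, e in pairs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[c] = np.array(out, dtype=np.int64)
    return merged


def _count_in_features(fragments: FragmentSet, merged: dict[str, np.ndarray]) -> int:
    total = 0
    for c, blocks in merged.items():
        mids = fragments.midpoints(c)
        if len(mids) == 0:
            continue
        starts, ends = blocks[:, 0], blocks[:, 1]
        j = np.searchsorted(starts, mids, side="right") - 1
        ok = (j >= 0) & (mids < ends[np.clip(j, 0, None)])
        total += int(ok.sum())
    return total


@dataclass
class FeatureClassEnrichment:
    feature_class: str
    chip_count: int
    input_count: int
    log2_ratio: float | None  # None when the class is empty (undefined)
    per_feature_log2: list[float] | None = None  # one value per feature


def feature_enrichment(chip: FragmentSet, inp: FragmentSet,
                       features: dict[str, list[GenomicInterval]],
                       pseudocount: float = 1.0
                       ) -> dict[str, FeatureClassEnrichment]:
    """Class-level log2(ChIP/input) over feature interval sets.

    Fragments are counted by midpoint within the merged union of each class's
    intervals (so duplicated features do not double-count), normalised
    per-million per track, and combined with a fragment-equivalent
    pseudocount.  An empty class yields an undefined (None) ratio rather
    than zero.
    """
    out = {}
    for cls, ivs in features.items():
        if not ivs:
            out[cls] = FeatureClassEnrichment(cls, 0, 0, None)
            continue
        merged = _merge_intervals(ivs)
        cc = _count_in_features(chip, merged)
        ic = _count_in_features(inp, merged)
        rpm_c = (cc + pseudocount) / chip.total_count * 1e6
        rpm_i = (ic + pseudocount) / inp.total_count * 1e6
        per_feature = []
        for iv in ivs:
            one = {iv.chrom: np.array([[iv.start, iv.end]], dtype=np.int64)}
            fc = _count_in_features(chip, one)
            fi = _count_in_features(inp, one)
            per_feature.append(math.log2(
                ((fc + pseudocount) / chip.total_count)
                / ((fi + pseudocount) / inp.total_count)))
        out[cls] = FeatureClassEnrichment(cls, cc, ic,
                                          math.log2(rpm_c / rpm_i),
                                          per_feature)
    return out


def calls_to_table(calls: list[CentromereCall]) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "size_mb": c.size_mb,
            "mean_log2_ratio": c.mean_log2_ratio,
            "primary": c.primary,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "size_mb",
                                       "mean_log2_ratio", "primary"])
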