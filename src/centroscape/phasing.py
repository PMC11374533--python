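"""Nucleosome phasing on satellite trimer consensi.

ChIP (CENH3-bound) and input (bulk) fragments are aligned to a trimer — three
concatenated copies of a family's consensus monomer — and the distribution of
fragment midpoints along the trimer reveals whether nucleosomes sit at
preferred monomer offsets.  Midpoints landing in the central copy are
retained by default (the flanking copies absorb alignment edge artifacts), a
modulo-folding mode is available by flag.  The monomer is treated as
circular, consistent with its tandem context: smoothing wraps and peak
calling respects circular separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import revcomp


@dataclass
class PhasingProfile:
    family: str
    monomer_length: int
    counts: np.ndarray         # per-bp midpoint histogram, length = monomer
    smoothed: np.ndarray
    source: str                # "chip" | "input"
    n_mapped: int = 0          # midpoints that entered the fold
    n_retained: int = 0        # midpoints kept (central copy / all in modulo)


@dataclass
class PhasePeaks:
    positions: list[int]       # monomer offsets, sorted
    prominences: list[float]

    @property
    def count(self) -> int:
        return len(self.positions)


def make_trimer(consensus: str) -> str:
    """Three concatenated copies of a consensus monomer."""
    if len(consensus) < 50:
        raise ValueError("consensus shorter than 50 bp")
    third = len(consensus) // 3
    if len(consensus) % 3 == 0 and consensus == consensus[:third] * 3:
        raise ValueError("input is already a perfect 3-fold repeat")
    return consensus * 3


def map_fragments_to_trimer(fragment_seqs: list[str], trimer: str,
                            min_identity: float = 0.8
                            ) -> tuple[np.ndarray, int]:
    """Best-local-alignment midpoints of fragments on the trimer.

    Each fragment is infix-aligned (both strands); if the better strand
    reaches ``min_identity`` (1 - dist/len) its alignment midpoint on the
    trimer is recorded.  Returns (midpoints, n_unmapped).
    """
    mids = []
    unmapped = 0
    center = len(trimer) / 2
    for frag in fragment_seqs:
        if not frag:
            unmapped += 1
            continue
        best = None
        for s in (frag, revcomp(frag)):
            res = edlib.align(s, trimer, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(s)
            # a read from a tandem copy ties at every repeat offset; prefer
            # the location nearest the trimer centre so the central copy
            # collects an unbiased sample
            loc = min(res["locations"],
                      key=lambda ab: abs((ab[0] + ab[1] + 1) / 2 - center))
            if best is None or ident > best[0]:
                best = (ident, loc)
        if best is None or best[0] < min_identity:
            unmapped += 1
            continue
        a, b = best[1]
        mids.append((a + b + 1) // 2)  # edlib locations are inclusive
    return np.asarray(mids, dtype=np.int64), unmapped


def fold_to_monomer(trimer_midpoints: np.ndarray, monomer_length: int,
                    mode: str = "central", bandwidth: float = 5.0,
                    family: str = "", source: str = "chip") -> PhasingProfile:
    """Fold trimer midpoints into monomer coordinates.

    ``central`` keeps only midpoints in the middle copy [L, 2L); ``modulo``
    folds all three copies.  Smoothing is a wrapped Gaussian kernel.
    """
    L = monomer_length
    mids = np.asarray(trimer_midpoints, dtype=np.int64)
    if len(mids) and (mids.min() < 0 or mids.max() >= 3 * L):
        raise ValueError("midpoints outside trimer bounds")
    if mode == "central":
        keep = mids[(mids >= L) & (mids < 2 * L)] - L
    elif mode == "modulo":
        keep = mids % L
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    counts = np.bincount(keep, minlength=L).astype(np.int64)
    smoothed = gaussian_filter1d(counts.astype(float), bandwidth, mode="wrap")
    return PhasingProfile(family, L, counts, smoothed, source,
                          n_mapped=len(mids), n_retained=len(keep))


def call_phase_peaks(profile: PhasingProfile, min_prominence: float = 0.25,
                     min_separation: int = 40) -> PhasePeaks:
    """Circular peak calling on the smoothed profile.

    Local maxima need prominence >= min_prominence * max(profile) and
    pairwise circular separation >= min_separation.  Rotation-equivariant by
    construction (the profile is tiled before peak finding).
    """
    sm = profile.smoothed
    L = profile.monomer_length
    peak_max = float(sm.max())
    if peak_max <= 0:
        return PhasePeaks([], [])
    tiled = np.concatenate([sm, sm, sm])
    idx, props = find_peaks(tiled, prominence=min_prominence * peak_max,
                            distance=max(1, min_separation))
    keep = [(int(i - L), float(p)) for i, p in zip(idx, props["prominences"])
            if L <= i < 2 * L]
    keep.sort()
    # enforce circular separation across the wrap point
    while len(keep) > 1 and (keep[0][0] + L - keep[-1][0]) < min_separation:
        if keep[0][1] <= keep[-1][1]:
            keep.pop(0)
        else:
            keep.pop()
    return PhasePeaks([p for p, _ in keep], [pr for _, pr in keep])


def phase_concordance(chip: PhasingProfile, inp: PhasingProfile
                      ) -> dict[str, float]:
    """Circular cross-correlation of two profiles on the same monomer.

    Reports the Pearson correlation at zero lag and the best correlation
    over all circular shifts of the input profile, with its lag.
    """
    if chip.monomer_length != inp.monomer_length:
        raise ValueError("profiles have different monomer lengths")
    a = chip.smoothed.astype(float)
    b = inp.smoothed.astype(float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return {"r_zero_lag": 0.0, "r_best": 0.0, "best_lag": 0}
    # circular cross-correlation via FFT: corr[k] = sum_i a[i] * b[i + k],
    # so b = roll(a, k) peaks at lag k
    corr = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b),
                        n=len(a)) / denom
    best_lag = int(np.argmax(corr))
    return {
        "r_zero_lag": float(corr[0]),
        "r_best": float(corr[best_lag]),
        "best_lag": best_lag,
    }
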