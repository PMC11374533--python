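"""De-novo tandem-satellite discovery, consensus building and families.

Detection works on exact k-mer recurrence: positions of repeated 12-mers are
collected, the spacings between consecutive occurrences of the same k-mer
vote for candidate periods, and for each well-supported period the per-base
lag-p match indicator ``seq[i] == seq[i+p]`` is smoothed to segment candidate
array regions.  Array edges are then refined by a maximum-likelihood
changepoint on the mismatch pattern against the periodic consensus
prediction (mismatch probability ~0.1 inside an array, 0.75 in random
background).  Monomer copies are cut at the refined start, a per-column
majority consensus is built, and the consensus is canonicalised to its
lexicographically minimal rotation: a tandem array determines its monomer
only up to rotation, so the canonical form is the well-defined
representative (exactly as canonical k-mers are for strand ambiguity).

Family classification merges arrays whose canonical consensi are
reciprocally similar under circular (rotation-aware) comparison, and names
families ``CentFs<consensus length>``; length collisions get letter
suffixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import GenomeSequence, GenomicInterval, revcomp
from .enrichment import CentromereCall
from .synth import decode, encode

# changepoint mismatch probabilities: inside an array vs random background
_P_IN = 0.1
_P_OUT = 0.75


@dataclass
class SatelliteArray:
    interval: GenomicInterval
    period: int
    copy_number: int
    consensus: str  # canonical rotation
    mean_copy_identity: float
    family: str | None = None


@dataclass
class SatelliteFamily:
    name: str
    consensus: str
    arrays: list[SatelliteArray] = field(default_factory=list)

    @property
    def total_span(self) -> int:
        return sum(a.interval.length for a in self.arrays)


def canonical_rotation(s: str) -> str:
    """Lexicographically minimal rotation of ``s``."""
    return min(s[i:] + s[:i] for i in range(len(s)))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers (positions with N excluded)."""
    n = len(codes)
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    valid = (codes < 4).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(valid)])
    ok = (csum[k:] - csum[:-k]) == k  # no N anywhere in the k-mer
    kc = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        kc = kc * 4 + codes[j: n - k + 1 + j]
    pos = np.flatnonzero(ok)
    return kc[pos], pos


def _period_votes(codes: np.ndarray, k: int, min_period: int,
                  max_period: int) -> np.ndarray:
    """Histogram over spacings of consecutive same-k-mer occurrences."""
    kc, pos = _kmer_codes(codes, k)
    if len(kc) == 0:
        return np.zeros(max_period + 1, dtype=np.int64)
    order = np.argsort(kc, kind="stable")  # stable: positions ascend in ties
    kc_s, pos_s = kc[order], pos[order]
    same = kc_s[1:] == kc_s[:-1]
    gaps = (pos_s[1:] - pos_s[:-1])[same]
    gaps = gaps[(gaps >= min_period) & (gaps <= max_period)]
    return np.bincount(gaps, minlength=max_period + 1)


def _segment_regions(codes: np.ndarray, p: int, min_len: int
                     ) -> list[tuple[int, int]]:
    """Rough array regions for period p from the smoothed lag-p match rate."""
    n = len(codes)
    if n <= p:
        return []
    m = (codes[:-p] == codes[p:]) & (codes[:-p] < 4)
    frac = uniform_filter1d(m.astype(np.float64), size=min(p, 501))
    mask = frac > 0.5
    regions = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    start = prev = int(idx[0])
    for i in idx[1:].tolist():
        if i - prev <= p:
            prev = i
        else:
            if prev - start + p >= min_len:
                regions.append((start, min(prev + p, n)))
            start = prev = i
    if prev - start + p >= min_len:
        regions.append((start, min(prev + p, n)))
    return regions


def _majority_consensus_codes(copies: np.ndarray) -> np.ndarray:
    """Column-wise majority over an (n_copies, p) code matrix; ties go to the
    first base in alphabet order."""
    counts = np.stack([(copies == b).sum(axis=0) for b in range(4)])
    return np.argmax(counts, axis=0).astype(np.uint8)  # argmax takes first max


def _refine_edges(codes: np.ndarray, rs: int, re_: int, p: int
                  ) -> tuple[int, int, np.ndarray] | None:
    """ML changepoint refinement of rough region edges for period p.

    Returns (start, end, consensus codes in start phase) or None if the
    region does not hold up (too few copies for a consensus).
    """
    n = len(codes)
    # interior consensus from copies safely inside the rough region
    a = rs
    n_int = (re_ - a) // p
    if n_int < 3:
        return None
    interior = codes[a: a + n_int * p].reshape(n_int, p)
    cons = _majority_consensus_codes(interior)

    lo = max(0, rs - 2 * p)
    hi = min(n, re_ + 2 * p)
    pred_idx = (np.arange(lo, hi) - a) % p
    mis = (codes[lo:hi] != cons[pred_idx]).astype(np.float64)

    in_cost = np.where(mis == 1, -np.log(_P_IN), -np.log(1 - _P_IN))
    out_cost = np.where(mis == 1, -np.log(_P_OUT), -np.log(1 - _P_OUT))
    delta = in_cost - out_cost
    mid = (rs + re_) // 2 - lo
    # left edge t minimises sum(out[:t]) + sum(in[t:mid]); dropping the
    # t-independent term leaves cumsum(out - in)[:t] = -cumsum(delta)[:t]
    left = np.concatenate([[0.0], np.cumsum(-delta[:mid])])
    start = lo + int(np.argmin(left))
    # right edge t minimises sum(in[mid:t]) + sum(out[t:]), i.e.
    # cumsum(delta) over the tail
    right = np.concatenate([[0.0], np.cumsum(delta[mid:])])
    end = lo + mid + int(np.argmin(right))
    if end - start < 2 * p:
        return None
    # array length is an integer number of copies; snap the end
    n_copies = max(1, int(round((end - start) / p)))
    end = start + n_copies * p
    if end > n:
        n_copies -= 1
        end = start + n_copies * p
    if n_copies < 3:
        return None
    copies = codes[start:end].reshape(n_copies, p)
    cons = _majority_consensus_codes(copies)
    return start, end, cons


def find_tandem_arrays(seq: GenomeSequence, min_period: int = 50,
                       max_period: int = 1000, min_copies: int = 3,
                       k: int = 12, min_votes: int = 20,
                       min_identity: float = 0.6) -> list[SatelliteArray]:
    """Detect tandem satellite arrays on one chromosome.

    Candidate periods are taken from the k-mer spacing histogram in
    descending vote order; regions claimed by an earlier (better-supported)
    period suppress harmonic re-detection at its multiples.  Overlapping
    survivors are arbitrated by mean copy identity, then by smaller period.
    """
    if seq.length <= 2 * min_period:
        return []
    codes = encode(seq.sequence)
    votes = _period_votes(codes, k, min_period, max_period)
    candidates: list[SatelliteArray] = []
    claimed: list[tuple[int, int]] = []
    order = np.argsort(votes)[::-1]
    for p in order.tolist():
        if votes[p] < min_votes:
            break
        for rs, re_ in _segment_regions(codes, p, min_len=min_copies * p):
            if any(rs < b and a < re_ for a, b in claimed):
                continue
            refined = _refine_edges(codes, rs, re_, p)
            if refined is None:
                continue
            start, end, cons = refined
            if any(start < b and a < end for a, b in claimed):
                continue
            n_copies = (end - start) // p
            if n_copies < min_copies:
                continue
            copies = codes[start:end].reshape(n_copies, p)
            ident = float(np.mean(copies == cons[None, :]))
            if ident < min_identity:
                continue
            candidates.append(SatelliteArray(
                GenomicInterval(seq.name, start, end), p, n_copies,
                canonical_rotation(decode(cons)), ident,
            ))
            claimed.append((start, end))
    # arbitration: higher mean copy identity wins, near-ties go to the
    # smaller period (more copies), then leftmost
    candidates.sort(key=lambda a: (-round(a.mean_copy_identity, 3), a.period,
                                   a.interval.start))
    kept: list[SatelliteArray] = []
    for cand in candidates:
        if any(cand.interval.overlap(kk.interval) > 0 for kk in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda a: (a.interval.chrom, a.interval.start))
    return kept


# ---------------------------------------------------------------------------
# consensus building (standalone operation)
# ---------------------------------------------------------------------------

def build_consensus(copies: list[str]) -> str:
    """Majority-rule consensus of monomer copies.

    Equal-length copies vote column-wise directly; unequal lengths are
    star-aligned to the medoid copy (edlib global alignment, insertions
    relative to the medoid are dropped) so the consensus length equals the
    medoid length.  Ties go to the first base in alphabet order.
    """
    if len(copies) < 3:
        raise ValueError("need at least 3 copies for a consensus")
    copies = [c.upper() for c in copies]
    lengths = {len(c) for c in copies}
    if len(lengths) == 1:
        mat = np.stack([encode(c) for c in copies])
        return decode(_majority_consensus_codes(mat))
    # medoid: copy minimising total edit distance to the others
    dists = np.zeros((len(copies), len(copies)))
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            d = edlib.align(copies[i], copies[j], mode="NW")["editDistance"]
            dists[i, j] = dists[j, i] = d
    medoid = copies[int(np.argmin(dists.sum(axis=1)))]
    cols: list[list[str]] = [[] for _ in medoid]
    for c in copies:
        res = edlib.align(c, medoid, mode="NW", task="path")
        qi = ti = 0
        for count, op in _iter_cigar(res["cigar"]):
            if op in "=X":
                for t in range(count):
                    cols[ti + t].append(c[qi + t])
                qi += count
                ti += count
            elif op == "I":  # insertion in the copy: not a medoid column
                qi += count
            elif op == "D":  # deletion: medoid column unmatched
                ti += count
    out = []
    for col in cols:
        if not col:
            out.append("A")
            continue
        best = min(sorted(set(col)), key=lambda b: (-col.count(b), b))
        out.append(best)
    return "".join(out)


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def circular_identity(a: str, b: str) -> float:
    """Rotation-aware identity between two monomer consensi.

    ``a`` is globally aligned into the doubled ``b`` (infix mode), which
    scores every rotation of ``b``; identity is 1 - dist/len(a)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b + b, mode="HW")
    return max(0.0, 1.0 - res["editDistance"] / len(a))


def classify_families(arrays: list[SatelliteArray], identity_min: float = 0.8
                      ) -> list[SatelliteFamily]:
    """Merge arrays into families by reciprocal circular consensus identity.

    Union-find over all pairs (order-independent).  A family is named
    CentFs<consensus length> after its representative (the member array with
    the most copies); same-length collisions get suffixes b, c, ...
    """
    n = len(arrays)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrays[i].consensus, arrays[j].consensus
            if (circular_identity(a, b) >= identity_min
                    and circular_identity(b, a) >= identity_min):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    families = []
    for members in groups.values():
        members.sort(key=lambda i: (-arrays[i].copy_number,
                                    arrays[i].interval.chrom,
                                    arrays[i].interval.start))
        rep = arrays[members[0]]
        fam = SatelliteFamily(f"CentFs{len(rep.consensus)}", rep.consensus,
                              [arrays[i] for i in members])
        families.append(fam)
    families.sort(key=lambda f: (-f.total_span, f.name))
    seen: dict[str, int] = {}
    for fam in families:
        k = seen.get(fam.name, 0)
        seen[fam.name] = k + 1
        if k:
            fam.name = f"{fam.name}{'bcdefghijklmnopqrstuvwxyz'[k - 1]}"
        for a in fam.arrays:
            a.family = fam.name
    return families


def centromere_composition(calls: list[CentromereCall],
                           families: list[SatelliteFamily],
                           flank: int = 0) -> pd.DataFrame:
    """Per-centromere family composition as base-pair overlap fractions.

    Each centromere call (optionally extended by ``flank`` on both sides) is
    intersected with every family's arrays; proportions are of the
    centromere call length and the dominant family is flagged.
    """
    rows = []
    for call in calls:
        probe = GenomicInterval(
            call.chrom, max(0, call.interval.start - flank),
            call.interval.end + flank,
        )
        props = {}
        for fam in families:
            bp = sum(probe.overlap(a.interval) for a in fam.arrays)
            props[fam.name] = bp / call.interval.length
        dominant = max(props, key=lambda f: props[f]) if props else ""
        row = {"chrom": call.chrom, "cen_start": call.interval.start,
               "cen_end": call.interval.end, "dominant": dominant}
        row.update(props)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dot plots
# ---------------------------------------------------------------------------

@dataclass
class DotPlotMatches:
    window: int
    points: list[tuple[int, int, str]]  # (posA, posB, strand)


def dotplot_matrix(seq_a: str, seq_b: str, window: int = 100,
                   min_identity: float = 0.8) -> DotPlotMatches:
    """All window pairs (stride = window) with identity >= min_identity.

    Both orientations are scored; reverse-strand matches are tagged '-'.
    Identity is 1 - edit_distance/window.
    """
    if len(seq_a) < window or len(seq_b) < window:
        raise ValueError("both sequences must be at least one window long")
    max_ed = int((1.0 - min_identity) * window)
    wins_a = [seq_a[i:i + window] for i in range(0, len(seq_a) - window + 1, window)]
    wins_b = [seq_b[i:i + window] for i in range(0, len(seq_b) - window + 1, window)]
    wins_b_rc = [revcomp(w) for w in wins_b]
    points = []
    for i, wa in enumerate(wins_a):
        for j, wb in enumerate(wins_b):
            if edlib.align(wa, wb, mode="NW", k=max_ed)["editDistance"] != -1:
                points.append((i * window, j * window, "+"))
            if edlib.align(wa, wins_b_rc[j], mode="NW", k=max_ed)["editDistance"] != -1:
                points.append((i * window, j * window, "-"))
    return DotPlotMatches(window, points)


def arrays_to_table(arrays: list[SatelliteArray]) -> pd.DataFrame:
    rows = [
        {
            "chrom": a.interval.chrom,
            "start": a.interval.start,
            "end": a.interval.end,
            "period": a.period,
            "copy_number": a.copy_number,
            "mean_copy_identity": a.mean_copy_identity,
            "family": a.family or "",
        }
        for a in arrays
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "period",
                                       "copy_number", "mean_copy_identity",
                                       "family"])
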