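"""Full-length LTR retrotransposon detection, dating and population
comparison.

A retroelement is born with two identical long terminal repeats; after
insertion each LTR accumulates substitutions independently, so the per-site
difference K between the two LTRs, divided by twice the per-site per-year
substitution rate r, estimates the insertion age: T = K / (2 r).  The
default clock is r = 1.3e-8 substitutions/site/year, a commonly used plant
LTR rate; it is configurable and recorded in output metadata.  K defaults to
the raw difference proportion (1 - identity, gap columns excluded); a JC69
correction is available by flag.

The detector is a pair-similarity scanner: exact k-mer anchor pairs at a
consistent offset seed candidate LTR pairs, which are extended outwards
under a match/mismatch score until the flanks stop matching.  It has no
notion of target-site duplications or TG...CA termini — adequate for
synthetic-genome recovery and for re-dating externally annotated elements,
which the module also accepts.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import ranksums

from .core import GenomeSequence, GenomicInterval
from .enrichment import CentromereCall
from .synth import encode


@dataclass
class DatingParams:
    r: float = 1.3e-8           # substitutions per site per year
    correction: str = "raw"     # "raw" | "JC69"

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("mutation rate r must be positive")
        if self.correction not in ("raw", "JC69"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class LTRElement:
    element: GenomicInterval
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    ltr_identity: float
    k: float
    t: float | None = None
    location_class: str | None = None   # "centromeric" | "non_centromeric"
    nested: bool = False
    clade: int | None = None
    reliable: bool = True


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _anchor_pairs(codes: np.ndarray, k: int, min_d: int, max_d: int,
                  max_occ: int) -> dict[int, np.ndarray]:
    """Positions of same-k-mer pairs grouped by their offset d.

    k-mers occurring more than ``max_occ`` times are skipped (they belong to
    satellite arrays, not LTR pairs)."""
    n = len(codes)
    if n < k:
        return {}
    valid = (codes < 4).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(valid)])
    ok = (csum[k:] - csum[:-k]) == k
    kc = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        kc = kc * 4 + codes[j: n - k + 1 + j]
    pos = np.flatnonzero(ok)
    kc = kc[pos]
    order = np.argsort(kc, kind="stable")
    kc_s, pos_s = kc[order], pos[order]
    bounds = np.flatnonzero(np.concatenate([[True], kc_s[1:] != kc_s[:-1], [True]]))
    by_offset: dict[int, list[int]] = {}
    for gi in range(len(bounds) - 1):
        a, b = bounds[gi], bounds[gi + 1]
        if b - a < 2 or b - a > max_occ:
            continue
        grp = pos_s[a:b]
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                d = int(grp[j] - grp[i])
                if min_d <= d <= max_d:
                    by_offset.setdefault(d, []).append(int(grp[i]))
    return {d: np.array(sorted(v)) for d, v in by_offset.items()}


def _extend_block(codes: np.ndarray, lo: int, hi: int, d: int,
                  match: int = 1, mismatch: int = -3, max_drop: int = 12
                  ) -> tuple[int, int]:
    """Extend the anchor span [lo, hi) outwards along the diagonal at offset
    d while the running score stays within ``max_drop`` of its maximum."""
    n = len(codes)
    # rightwards
    best, score, end = hi, 0, hi
    i = hi
    while i + d < n and score > -max_drop:
        score += match if codes[i] == codes[i + d] else mismatch
        i += 1
        if score > 0:
            score = 0
            best = i
    # leftwards
    best_l, score = lo, 0
    i = lo
    while i > 0 and score > -max_drop:
        i -= 1
        score += match if codes[i] == codes[i + d] else mismatch
        if score > 0:
            score = 0
            best_l = i
    return best_l, best


def find_ltr_pairs(seq: GenomeSequence, min_ltr_len: int = 100,
                   max_ltr_len: int = 3000, min_element_len: int = 1000,
                   max_element_len: int = 20000,
                   min_pair_identity: float = 0.8, k: int = 16,
                   max_kmer_occ: int = 8) -> list[LTRElement]:
    """Detect candidate full-length LTR pairs on one chromosome.

    Anchors sharing an offset d (the distance between the two LTR starts)
    are clustered into runs, extended to maximal matching blocks, and
    reported as 5'/3' LTR pairs with the intervening internal region.
    Overlapping candidates resolve to the highest pair identity; elements
    contained in another element's internal region are flagged nested.
    """
    if seq.length < min_element_len:
        return []
    codes = encode(seq.sequence)
    # d is the LTR-start to LTR-start distance = ltr_len + internal_len,
    # so d >= min_ltr_len always holds (internal region is non-negative)
    by_offset = _anchor_pairs(
        codes, k, max(min_ltr_len, min_element_len - max_ltr_len),
        max_element_len - min_ltr_len, max_kmer_occ)
    candidates: list[LTRElement] = []
    for d, starts in by_offset.items():
        if len(starts) < 3:
            continue
        # split anchor positions into runs (one run per LTR pair)
        breaks = np.flatnonzero(np.diff(starts) > max_ltr_len)
        run_bounds = np.concatenate([[0], breaks + 1, [len(starts)]])
        for ri in range(len(run_bounds) - 1):
            run = starts[run_bounds[ri]:run_bounds[ri + 1]]
            if len(run) < 3:
                continue
            lo, hi = _extend_block(codes, int(run[0]), int(run[-1]) + k, d)
            ltr_len = hi - lo
            if not (min_ltr_len <= ltr_len <= max_ltr_len):
                continue
            elem_len = d + ltr_len
            if not (min_element_len <= elem_len <= max_element_len):
                continue
            if lo + elem_len > seq.length:
                continue
            a5 = GenomicInterval(seq.name, lo, hi)
            a3 = GenomicInterval(seq.name, lo + d, hi + d)
            ident, kdiff = ltr_divergence(
                seq.sequence[a5.start:a5.end], seq.sequence[a3.start:a3.end])
            if ident < min_pair_identity:
                continue
            candidates.append(LTRElement(
                GenomicInterval(seq.name, lo, hi + d), a5, a3, ident, kdiff))
    # overlap resolution by identity, except true nesting which is kept
    candidates.sort(key=lambda e: (-e.ltr_identity, e.element.start))
    kept: list[LTRElement] = []
    for cand in candidates:
        nested_in = None
        clash = False
        for other in kept:
            internal = GenomicInterval(other.element.chrom, other.ltr5.end,
                                       other.ltr3.start)
            if (internal.start <= cand.element.start
                    and cand.element.end <= internal.end):
                nested_in = other
            elif cand.element.overlap(other.element) > 0:
                clash = True
        if clash and nested_in is None:
            continue
        cand.nested = nested_in is not None
        kept.append(cand)
    kept.sort(key=lambda e: e.element.start)
    return kept


# ---------------------------------------------------------------------------
# divergence and dating
# ---------------------------------------------------------------------------

def ltr_divergence(ltr5: str, ltr3: str, correction: str = "raw"
                   ) -> tuple[float, float]:
    """(identity, K) between an element's two LTRs.

    Global alignment; identity = matches / aligned columns excluding gap
    columns.  K = 1 - identity for ``raw``, or the JC69 distance
    -(3/4) ln(1 - (4/3)(1 - identity)) when selected.
    """
    res = edlib.align(ltr5.upper(), ltr3.upper(), mode="NW", task="path")
    eq = mm = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            if ch == "=":
                eq += int(num)
            elif ch == "X":
                mm += int(num)
            num = ""
    cols = eq + mm
    identity = eq / cols if cols else 0.0
    p = 1.0 - identity
    if correction == "raw":
        k = p
    elif correction == "JC69":
        arg = 1.0 - (4.0 / 3.0) * p
        if arg <= 0:
            raise ValueError("divergence too large for JC69 correction")
        k = -0.75 * float(np.log(arg))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return identity, k


def insertion_time(k: float, params: DatingParams) -> float:
    """Insertion age in years: T = K / (2 r)."""
    if k < 0:
        raise ValueError("K must be non-negative")
    return k / (2.0 * params.r)


def date_elements(elements: list[LTRElement], params: DatingParams
                  ) -> list[LTRElement]:
    for el in elements:
        el.reliable = el.ltr_identity >= 0.5
        el.t = insertion_time(el.k, params) if el.reliable else None
    return elements


# ---------------------------------------------------------------------------
# population comparison
# ---------------------------------------------------------------------------

def classify_by_centromere(elements: list[LTRElement],
                           calls: list[CentromereCall]) -> list[LTRElement]:
    """Centromeric iff the element midpoint falls inside a centromere call."""
    for el in elements:
        mid = el.element.midpoint
        inside = any(c.chrom == el.element.chrom and c.interval.contains(mid)
                     for c in calls)
        el.location_class = "centromeric" if inside else "non_centromeric"
    return elements


def compare_populations(elements: list[LTRElement],
                        bins: int = 50) -> dict:
    """Median LTR identity per location class, rank-sum test, histograms.

    Unreliable elements (degenerate alignments) are excluded; an empty
    class is flagged absent rather than erroring.
    """
    summary: dict = {"classes": {}}
    groups: dict[str, list[float]] = {"centromeric": [], "non_centromeric": []}
    for el in elements:
        if el.location_class and el.reliable:
            groups[el.location_class].append(el.ltr_identity)
    edges = np.linspace(0.5, 1.0, bins + 1)
    for cls, idents in groups.items():
        if not idents:
            summary["classes"][cls] = {"absent": True}
            continue
        hist, _ = np.histogram(idents, bins=edges)
        summary["classes"][cls] = {
            "absent": False,
            "n": len(idents),
            "median_identity": float(np.median(idents)),
            "histogram": hist.tolist(),
        }
    summary["histogram_edges"] = edges.tolist()
    if all(groups.values()):
        stat, p = ranksums(groups["centromeric"], groups["non_centromeric"])
        summary["ranksum_statistic"] = float(stat)
        summary["ranksum_p"] = float(p)
    return summary


# ---------------------------------------------------------------------------
# clades
# ---------------------------------------------------------------------------

def cluster_clades(elements: list[LTRElement], sequences: list[str],
                   linkage_identity: float = 0.7) -> list[LTRElement]:
    """Single-linkage clades on pairwise element identity.

    Pairwise identity is 1 - edit_distance / max(length); clusters are cut
    at distance 1 - linkage_identity.  Clade labels are renumbered by first
    element position for deterministic output.
    """
    if len(elements) < 2:
        raise ValueError("need at least 2 elements to cluster")
    if len(elements) != len(sequences):
        raise ValueError("one sequence per element required")
    n = len(elements)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ed = edlib.align(sequences[i], sequences[j], mode="NW")["editDistance"]
            d = ed / max(len(sequences[i]), len(sequences[j]))
            dist[i, j] = dist[j, i] = d
    labels = fcluster(linkage(squareform(dist), method="single"),
                      t=1.0 - linkage_identity, criterion="distance")
    remap: dict[int, int] = {}
    for i in sorted(range(n), key=lambda i: (elements[i].element.chrom,
                                             elements[i].element.start)):
        if labels[i] not in remap:
            remap[labels[i]] = len(remap) + 1
    for i, el in enumerate(elements):
        el.clade = remap[labels[i]]
    return elements


def elements_to_table(elements: list[LTRElement]) -> pd.DataFrame:
    rows = [
        {
            "chrom": e.element.chrom,
            "start": e.element.start,
            "end": e.element.end,
            "ltr5_start": e.ltr5.start,
            "ltr5_end": e.ltr5.end,
            "ltr3_start": e.ltr3.start,
            "ltr3_end": e.ltr3.end,
            "ltr_identity": e.ltr_identity,
            "K": e.k,
            "T_years": e.t if e.t is not None else float("nan"),
            "location_class": e.location_class or "",
            "nested": e.nested,
            "clade": e.clade if e.clade is not None else -1,
        }
        for e in elements
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "ltr5_start",
                                       "ltr5_end", "ltr3_start", "ltr3_end",
                                       "ltr_identity", "K", "T_years",
                                       "location_class", "nested", "clade"])
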