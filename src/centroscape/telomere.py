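"""Telomere motif counting and per-end presence classification.

The 5' end of a chromosome is scanned for non-overlapping exact copies of
the plant telomere heptamer (CCCTAAA by default) within a terminal window;
the 3' end for its reverse complement (TTTAGGG).  Counting is exact — no
mismatches — which makes simulator round-trips lossless; the terminal
window (default 100 kb) and the presence threshold (default 100 copies) are
configurable because no canonical values exist.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .core import GenomeSequence, GenomicInterval, revcomp


@dataclass
class TelomereReport:
    chrom: str
    end: str  # "5p" | "3p"
    motif: str
    copies: int
    tract_span: GenomicInterval | None
    present: bool


def _count_in_window(window: str, motif: str, offset: int, chrom: str
                     ) -> tuple[int, GenomicInterval | None]:
    hits = [m.start() for m in re.finditer(re.escape(motif), window)]
    if not hits:
        return 0, None
    span = GenomicInterval(chrom, offset + hits[0], offset + hits[-1] + len(motif))
    return len(hits), span


def count_telomere_repeats(seq: GenomeSequence, motif: str = "CCCTAAA",
                           terminal_window: int = 100_000,
                           presence_min: int = 100
                           ) -> tuple[TelomereReport, TelomereReport]:
    """Count telomere motif copies in both terminal windows of a chromosome.

    Returns (5' report, 3' report).  The 5' window is scanned for ``motif``,
    the 3' window for its reverse complement; ``tract_span`` is the minimal
    interval covering the first through last counted occurrence.
    """
    if len(motif) != 7:
        raise ValueError("telomere motif must be a 7-mer")
    if set(motif.upper()) - set("ACGTN"):
        raise ValueError(f"motif contains non-ACGTN characters: {motif!r}")
    motif = motif.upper()
    tw = min(terminal_window, seq.length)

    c5, span5 = _count_in_window(seq.sequence[:tw], motif, 0, seq.name)
    rc = revcomp(motif)
    c3, span3 = _count_in_window(seq.sequence[seq.length - tw:], rc,
                                 seq.length - tw, seq.name)
    return (
        TelomereReport(seq.name, "5p", motif, c5, span5, c5 >= presence_min),
        TelomereReport(seq.name, "3p", rc, c3, span3, c3 >= presence_min),
    )


def telomere_table(reports: list[TelomereReport]) -> tuple[pd.DataFrame, int]:
    """One row per chromosome end, plus the count of ends with a telomere.

    Raises if any chromosome is missing one of its two ends.
    """
    seen: dict[str, set[str]] = {}
    for r in reports:
        seen.setdefault(r.chrom, set()).add(r.end)
    missing = {c: {"5p", "3p"} - ends for c, ends in seen.items() if len(ends) < 2}
    if missing:
        raise ValueError(f"missing chromosome ends: {missing}")
    rows = [
        {
            "chrom": r.chrom,
            "end": r.end,
            "motif": r.motif,
            "copies": r.copies,
            "tract_start": r.tract_span.start if r.tract_span else -1,
            "tract_end": r.tract_span.end if r.tract_span else -1,
            "present": r.present,
        }
        for r in reports
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "end", "motif", "copies", "tract_start",
                       "tract_end", "present"],
    )
    return df, int(df["present"].sum())
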