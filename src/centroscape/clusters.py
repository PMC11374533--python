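"""Repeat-cluster CENH3 association scoring.

Reads sampled from ChIP and input fragment sets are assigned to repeat
clusters by best local alignment against each cluster consensus (an
identity-over-aligned-length criterion: identity >= 0.8 over >= 50 bases,
best hit only — a transparent proxy for a BLAST E-value cutoff).  Each
consensus is doubled head-to-tail before alignment so reads spanning a
tandem junction are not penalised.  The per-cluster ChIP/input ratio after
per-million normalisation, together with the genomic representation
(fraction of input reads hitting the cluster), drives the centromeric
selection rule: ratio strictly above 7 and representation strictly above
0.05% (strict inequalities, matching "surpassing"/"exceeding").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np

from .core import FragmentSet, Genome, revcomp

logger = logging.getLogger(__name__)


@dataclass
class RepeatCluster:
    cluster_id: str
    consensus: str
    classification: str = "unknown"

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if len(self.consensus) < 50:
            raise ValueError("cluster consensus shorter than 50 bp")


@dataclass
class ClusterEnrichment:
    cluster_id: str
    chip_hits: int
    input_hits: int
    ratio: float
    genome_proportion: float


def sample_reads(fragments: FragmentSet, genome: Genome, n: int = 1_000_000,
                 read_length: int = 150, seed: int = 0) -> list[str]:
    """Sample ``n`` fixed-length reads at fragment start positions.

    Fragments are chosen as a random permutation when enough are available,
    otherwise with replacement (logged).  Reads are clipped at chromosome
    ends; deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    starts_all: list[np.ndarray] = []
    for c in sorted(fragments.by_chrom):
        s, _ = fragments.by_chrom[c]
        chroms.extend([c] * len(s))
        starts_all.append(s)
    starts = np.concatenate(starts_all) if starts_all else np.empty(0, np.int64)
    total = len(starts)
    if total == 0:
        raise ValueError("no fragments to sample from")
    if n <= total:
        pick = rng.permutation(total)[:n]
    else:
        logger.warning("sampling %d reads from %d fragments with replacement",
                       n, total)
        pick = rng.integers(0, total, size=n)
    reads = []
    for i in pick.tolist():
        c = chroms[i]
        a = int(starts[i])
        b = min(a + read_length, genome[c].length)
        reads.append(genome[c].sequence[a:b])
    return reads


def align_reads_to_clusters(reads: list[str], clusters: list[RepeatCluster],
                            min_identity: float = 0.8, min_aligned: int = 50
                            ) -> tuple[dict[str, int], int]:
    """Assign each read to at most one cluster (best hit, both strands).

    The read is infix-aligned against each doubled consensus; it counts for
    the cluster with the smallest edit distance if its identity
    (1 - dist/read length) reaches ``min_identity`` and the read is at least
    ``min_aligned`` bases.  Returns (per-cluster counts, n_unassigned).
    """
    if not clusters:
        raise ValueError("no clusters supplied")
    doubled = [c.consensus + c.consensus for c in clusters]
    counts = {c.cluster_id: 0 for c in clusters}
    unassigned = 0
    for read in reads:
        if len(read) < min_aligned:
            unassigned += 1
            continue
        max_ed = int((1.0 - min_identity) * len(read))
        best_ed, best_i = None, None
        rc = revcomp(read)
        for i, target in enumerate(doubled):
            for q in (read, rc):
                ed = edlib.align(q, target, mode="HW", k=max_ed)["editDistance"]
                if ed >= 0 and (best_ed is None or ed < best_ed):
                    best_ed, best_i = ed, i
        if best_i is None:
            unassigned += 1
        else:
            counts[clusters[best_i].cluster_id] += 1
    return counts, unassigned


def cluster_enrichment_ratio(chip_counts: dict[str, int],
                             input_counts: dict[str, int],
                             n_chip_total: int, n_input_total: int,
                             pseudocount: float = 1.0
                             ) -> list[ClusterEnrichment]:
    """Per-cluster ChIP/input enrichment with per-million normalisation.

    ratio = ((chip_hits + pc)/n_chip) / ((input_hits + pc)/n_input);
    genome_proportion = input_hits / n_input (no pseudocount).
    """
    if n_chip_total <= 0 or n_input_total <= 0:
        raise ValueError("read totals must be positive")
    out = []
    for cid in chip_counts:
        ch = chip_counts[cid]
        ih = input_counts.get(cid, 0)
        ratio = ((ch + pseudocount) / n_chip_total) / ((ih + pseudocount) / n_input_total)
        out.append(ClusterEnrichment(cid, ch, ih, ratio, ih / n_input_total))
    return out


def select_centromeric_clusters(enrichments: list[ClusterEnrichment],
                                ratio_min: float = 7.0,
                                proportion_min: float = 0.0005) -> list[str]:
    """Clusters with ratio strictly above ``ratio_min`` AND genomic
    representation strictly above ``proportion_min``, by descending ratio."""
    selected = [e for e in enrichments
                if e.ratio > ratio_min and e.genome_proportion > proportion_min]
    selected.sort(key=lambda e: -e.ratio)
    return [e.cluster_id for e in selected]
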