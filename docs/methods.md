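# Methods

This note records the models, conventions, parameter choices and known
limitations behind each analysis stage, and what the synthetic-genome tests
do and do not demonstrate about real data.

## Coordinates and conventions

All internal coordinates are 0-based half-open; BED and bedGraph are emitted
natively in that convention and GFF3 export converts to 1-based inclusive at
the boundary. A fragment's midpoint is `floor((start + end) / 2)` — one
deterministic integer convention shared by window assignment, feature
overlap and phasing, so no stage can disagree by one base. `N` bases are
legal in sequences but never count as matches in any scan or alignment.

## Synthetic genomes

A chromosome is i.i.d. background at configurable GC (default 0.36, a
typical plant-genome value) onto which features are pasted at specified
coordinates: telomere tracts (5′ `CCCTAAA`×n, 3′ `TTTAGGG`×n), one
centromeric satellite array (a master monomer tiled copy by copy, each copy
independently substituted at a per-site rate ≤ 0.2), full-length LTR
elements (two initially identical LTRs flanking an internal region, each
LTR independently substituted at its mutation load), and optional extra
repeat copies for dispersed-repeat scenarios. The mutation model is
substitution-only, which keeps period and divergence arithmetic exact for
recovery tests; indels are a real-data feature the generator deliberately
omits (see Limitations).

Two identifiability choices are part of the generator, decided up front:

* **Boundary termination.** The three background bases flanking a planted
  array are rejection-sampled so they do not continue the tandem
  periodicity. Without this the planted boundary is not a well-defined
  quantity: a background base that happens to match the periodic
  continuation is statistically indistinguishable from one more array base,
  so no detector could be scored against the "true" edge.
* **Motif scrubbing.** Chance telomere heptamers outside planted tracts are
  removed (one base flipped), and planted masters/LTR sequences are drawn
  motif-free, so exact terminal counting round-trips. Real assemblies do
  contain interstitial telomere-like repeats; the scanner ignores them by
  construction anyway because only terminal windows are scanned.

Fragment simulation emits intervals directly — no read-level error model,
quality scores or mapping step. Input fragments are uniform over the
genome; a configurable share of ChIP fragments has midpoints on satellite
arrays, either uniform within the monomer or at planted phase offsets with
Gaussian jitter (counts are exact, not binomial). One `numpy` generator is
seeded per invocation and threaded through every step, so identical
(spec, seed) yields identical bytes.

## Telomere counting

Non-overlapping exact occurrences of the heptamer within a terminal window
(default 100 kb; presence threshold 100 copies). Exact matching makes the
simulator round-trip lossless; degenerate-copy counting, if ever needed, is
a parameter change away but is not the default because no canonical
mismatch tolerance exists.

## Enrichment and centromere calling

Window values are reads-per-million scaled by 1/100 (so a window holding
all fragments of a one-window chromosome reads 10⁴). The pseudocount is one
fragment-equivalent per track *before* normalisation — it converts to each
track's own RPM units, avoids division by zero in sparse windows, and
leaves deeply covered windows essentially untouched. Calling uses maximal
runs of windows with log2 ratio ≥ 1, at least 3 windows long, merging
single-window gaps; all surviving runs are reported and the run with the
highest mean log2 per chromosome is flagged primary. These thresholds are
conservative, reproducible stipulations — peak appearance in a ChIP track
underdetermines a calling rule — and all are exposed in the configuration.
Reported sizes round to one decimal Mb and the genome percentage to two
decimals, matching standard table precision; raw values are kept in JSON.

## Satellite discovery

Periodicity detection uses exact 12-mer recurrence: spacings between
consecutive occurrences of the same 12-mer vote for candidate periods in
[50, 1000] bp; a period needs ≥ 20 votes (a 3-copy, 50-bp array at 5%
divergence still clears this; 100 kb of random sequence produces ≲ 5 votes
for any single spacing). For each supported period p, the smoothed per-base
indicator `seq[i] == seq[i+p]` (expected ≥ 0.8 inside an array, 0.25 in
background) segments rough regions, and a maximum-likelihood changepoint on
mismatches against the periodic consensus prediction (mismatch probability
0.1 inside, 0.75 outside) fixes the edges; the array length then snaps to a
whole number of copies. Harmonic re-detection at multiples of p is
suppressed by processing periods in descending vote order and claiming
regions; residual overlaps resolve to the higher mean copy identity, with
near-ties going to the smaller period.

The consensus is the per-column majority over copies (ties to the first
base alphabetically), reported as the **lexicographically minimal
rotation**. A tandem array determines its monomer only up to rotation — the
cut phase is arbitrary and a single mutated boundary base shifts any
detector's cut by one — so the canonical rotation is the only well-defined
representative, exactly as canonical k-mers are under strand ambiguity.
Recovery tests compare canonical forms, which is exact string equality in
the only invariant sense.

Families merge arrays whose canonical consensi are reciprocally ≥ 80%
identical under rotation-aware comparison (the query aligned into the
doubled partner), named `CentFs<consensus length>` with letter suffixes on
length collisions. Dot plots compare non-overlapping windows (default
100 bp) in both orientations at ≥ 80% identity.

## Repeat-cluster scoring

One million 150-bp reads (configurable; scaled down in the bundled
simulations) are sampled at fragment starts and assigned to the cluster
with the best infix alignment against the doubled consensus, both strands,
counted when identity ≥ 0.8 over ≥ 50 bases. The identity/length criterion
is a transparent proxy for a BLAST E-value cutoff (Karlin–Altschul
statistics would add complexity without changing which reads pass at these
lengths). The genomic-representation denominator is read counts, following
the read-counting definition of cluster size. Selection is strict:
ratio > 7 *and* representation > 0.05%. De-novo graph-based read clustering
is out of scope — clusters enter as consensus FASTA (e.g. the satellite
families found upstream, or a user-supplied library).

The bundled cluster scenario uses a ChIP centromere fraction of 0.3 with a
dispersed repeat at ~2% genome share: a dispersed element's expected ratio
is `(1 − f) / (1 − cen_fraction)` ≈ 0.7, which a realistic bulk-chromatin
background (f well below 1) keeps within [0.5, 2] at 2 × 20 000 reads,
while the centromere-restricted satellite scores ≈ f/cen_fraction ≈ 30.
At f = 0.8 the dispersed ratio would be ≈ 0.2 — mathematically outside that
band regardless of implementation — so the moderate-background regime is
the one in which the selection rule separates the two cluster types.

## Phasing

Fragments are aligned to the trimer (three concatenated consensus copies);
a read from a tandem copy ties at every repeat offset, and the tie resolves
to the location nearest the trimer centre so the central copy collects an
unbiased sample. Central-copy retention (rather than folding all three
copies) avoids alignment edge artifacts; a modulo mode is available.
Monomer topology is circular throughout: Gaussian smoothing wraps
(bandwidth 5 bp) and peak calling enforces circular separation (default
40 bp) with prominence ≥ 0.25 of the profile maximum. These defaults were
chosen so that 1–5 planted phases at jitter sd ≤ 15 and n ≥ 5000 midpoints
are recovered with the correct count and ≤ 5 bp positional error, and all
are configurable. Note that detected peak positions live in the
canonical-rotation coordinate frame of the consensus, so comparisons across
profiles are meaningful but absolute offsets are arbitrary; peak *spacings*
are rotation-invariant.

## LTR detection and dating

The detector is a pair-similarity scanner: exact 16-mer anchors shared by
two loci at a consistent offset d (the LTR-start distance) are grouped and
extended outwards along the diagonal under +1/−3 match/mismatch scoring
with a drop-off of 12. k-mers occurring more than 8 times are skipped,
which keeps satellite arrays from flooding the anchor table. Candidates
keep the standard structural constraints (LTR 100–3000 bp, element
1–20 kb, pair identity ≥ 0.8); overlaps resolve to the higher identity
except true nesting (an element inside another's internal region), which is
kept and flagged. The detector ignores target-site duplications, TG…CA
termini and PBS signals — it is adequate for synthetic recovery and for
re-dating externally annotated elements (BED/TSV input), not a replacement
for a full structural annotator; small tandem arrays that escape the
k-mer-occurrence filter can masquerade as LTR pairs.

Identity is computed from a global alignment counting only substitution
columns (gap columns excluded), so identity + raw K = 1 exactly.
T = K/(2r) with r = 1.3 × 10⁻⁸ substitutions/site/year by default — a
commonly used plant LTR clock; the rate is configurable and recorded in
output metadata, and JC69 correction is available for older elements.
Population comparison reports per-class median identity and a two-sided
Wilcoxon rank-sum test; clades come from single-linkage clustering of
pairwise element identity cut at 0.7, a deliberate approximation of a
phylogeny that is cheap and deterministic.

## Pipeline and problem sizes

The default end-to-end simulation is three 2-Mb chromosomes with a 60-kb
centromeric array (3% of the chromosome — wide enough for three 20-kb
calling windows, narrow enough that the satellite cluster ratio ≈ 20
clears the selection rule), 2 × 20 000 fragments, two LTR insertions per
chromosome and two planted nucleosome phases. That size exercises every
stage in ~10 s while keeping all recovery margins wide; the bundled
recovery studies use the sizes stated alongside each result (20 genomes ×
10⁵ fragments for boundary recovery, 50 seeds × 5 phase counts for
phasing, 100 elements for the clock). All TSV/JSON/BED/bedGraph/FASTA
outputs are byte-deterministic given (config, seed); the log file alone
records wall-clock times.

## What passing tests do and do not show

The simulator matches the *statistical structure* the analysis assumes —
repeat/non-repeat contrast, enrichment concentration, phased midpoints,
mutation-clock divergence — not real chromatin or real repeat evolution.
Passing recovery tests therefore demonstrates correctness of the
algorithms and arithmetic under the stated model, and calibrated behaviour
of thresholds under realistic noise levels. They do not demonstrate
robustness to indel-rich satellite variation, higher-order repeat
structure, CG-biased substitution, mapping artifacts, MNase bias, or
library-specific ChIP background — all of which real datasets contain and
the generator intentionally does not model. Defaults that matter
(window 100 kb, log2 ≥ 1, ratio > 7, representation > 0.05%, identity 0.8,
bandwidth 5 bp, r = 1.3 × 10⁻⁸) are surfaced in the configuration rather
than buried, precisely so they can be re-examined against real data.
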