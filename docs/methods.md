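# Methods

## Signal model

The observed input is a set of strandless genomic intervals — DNA protected
from micrococcal nuclease. Coordinates are 0-based half-open internally; BED
files on disk follow the BED convention. Fragment strand is ignored
throughout: MNase protection has no orientation.

**Size selection.** Mono-nucleosome fragments are selected with an inclusive
length filter, default [127, 168] bp. Both bounds are closed so that a
fragment of exactly 127 or 168 bp counts as a single-nucleosome read. The
filter reports kept and dropped counts (they always sum to the input) and is
idempotent.

**Occupancy.** `coverage_track` counts, per base, the fragments whose
interval contains it (full-span coverage). A dyad-window mode (midpoint ± W)
is available for dyad-resolution work but is not the default, since
occupancy graphs conventionally show full protection.

**Smoothing.** `fft_smooth` zeroes all but the lowest `ceil(pc_keep × n_rfft)`
components of the real DFT (default `pc_keep = 0.02`, i.e. nothing shorter
than ~100 bp survives — safely above base-pair noise, below the nucleosome
repeat). Component 0 is always retained, so the mean is preserved exactly.
Chromosomes longer than 2^20 bp are filtered in overlapping chunks (2 kb
overlap, inner region kept) to bound memory at one rFFT per chunk; every
chunk uses the cutoff *wavelength* implied by the full track so seams do not
shift the passband. Two caveats are inherent and tested: (i) smoothed values
can dip slightly negative (Gibbs ringing) — they are clamped to zero only at
track export, never before peak calling, because clamping first would bias
the percentile threshold; (ii) if the signal has a strong spectral line
exactly at the cutoff (e.g. the second harmonic of a ~197 bp repeat against
the ~100 bp default cutoff), inclusion of that line can differ between
chunked and whole-track filtering; away from that degenerate alignment,
chunked and whole-track peak calls agree.

## Peak calling

Candidate summits are strict local maxima of the smoothed track with value
strictly above the `threshold_pct` percentile (default 50) of smoothed
values. The percentile is computed over *covered* positions (raw coverage
> 0) by default: long unmappable or undigested stretches would otherwise
deflate the threshold (`threshold_over="all"` restores the naive behaviour).
Summits closer than `min_sep` (default 120 bp — below one footprint, so a
single nucleosome is never double-called, while the short ~120 bp spacings
seen in real internucleosomal-distance distributions remain callable) are
merged greedily by descending height, leftmost on ties.

Each summit is scored in [0, 1]:

- `score_h = Φ((h − m)/s)`, the normal-CDF-standardised smoothed height,
  with m, s the mean and standard deviation of smoothed values over covered
  positions;
- `score_w = max(0, 1 − MAD/(L/4))`, where MAD is the median absolute
  deviation of fragment midpoints within summit ± L/2 (L = 147 bp
  footprint): tightly stacked fragments score near 1, fuzzy ones near 0;
- `score = (score_h + score_w)/2`; peaks with score ≤ `min_score`
  (default 0.25) are discarded.

This mirrors the height-plus-fuzziness structure of non-parametric
nucleosome callers while being fully specified. The called footprint is
summit ± L/2 clipped to the chromosome.

## NDRs and distances

The internucleosomal distance is **center-to-center** between adjacent called
summits. Center-to-center is parameter-free; edge-to-edge would inherit the
assumed footprint width. A nucleosome-depleted region is the interval
between two adjacent summits on the same chromosome, so per chromosome
`#NDRs = max(0, #peaks − 1)`, the NDR size multiset equals the distance
multiset, and regions before the first or after the last summit are not NDRs
(no flanking pair). The size distribution is a Gaussian KDE with Silverman
bandwidth evaluated on a log-spaced grid (linear fallback when kernels spill
below zero, keeping the grid integral at 1); locus NDRs are placed on it by
empirical CDF quantile. No lower floor is applied to distances.

## Site profiles

Scored sites are points (interval midpoint, floored for odd widths); the
default score floor 7.5 is inclusive. Sites are unstranded — no profile
flipping. Meta-occupancy averages the track over offsets −W..+W (default
W = 1000 bp); sites within W of a chromosome end are dropped and counted.
Under genome-mean normalization the profile is divided by the mean track
value over covered positions, so a constant track gives exactly 1. For the
score-vs-NDR-size analysis a site pairs with the NDR whose half-open
interval contains its center; sites at a summit pair with nothing and are
counted as excluded.

## Sequence preference and equilibrium occupancy

The energy of a nucleosome starting at i over window [i, i+L) is

    E(i) = −α · s_per(i) + β · f_AT5(i)

with `s_per(i) = (1/L) Σ_{j=0}^{L−2} cos(2π (j − (L−2)/2)/p) · d(i+j)`,
where d = +1 for AA/TT/TA/AT dinucleotides, −1 for GG/CC/GC/CG, 0 otherwise,
and `f_AT5` the fraction of the L−4 5-mers in the window that are AAAAA or
TTTTT. The cosine is phased on the window center (the dyad): a kernel phased
on the window *start* would make E depend on read strand, and the energy
must be reverse-complement invariant for a strandless particle (this
invariance is tested). Defaults: L = 147 bp, p = 10.1 bp (the helical
repeat of octamer-bent DNA), α = 1, β = 4, μ = 0; all configurable. The
model is a generic representative of the periodic-dinucleotide +
poly(dA:dT)-exclusion class, not a re-trained published parameter set.

Occupancy follows from the exact hard-rod (Tonks-gas) equilibrium:
nucleosomes are non-overlapping L-rods with statistical weight
w(i) = exp(μ − E(i)). Forward partial partition functions obey
F(b) = F(b−1) + w(b−L+1)·F(b−L), mirrored backward as R; then
`start_prob[i] = F(i−1)·w(i)·R(i+L)/Z` with Z = F(N−1), and occupancy is
the L-window sum of start probabilities. All recursion arithmetic is in log
space with log-sum-exp — Z overflows linear doubles within a few hundred bp.
The recursion is exact: it matches exhaustive enumeration of all
non-overlapping configurations to < 1e−9 on every instance tested (N ≤ 12).
Note that per-base occupancy is **not** monotone in μ — raising μ densifies
packing and can rearrange it, lowering occupancy at individual bases (shown
by exact enumeration); the monotone quantity is mean occupancy, and that is
what the test asserts.

Ambiguity handling is conservative and deterministic: dinucleotides touching
an N contribute 0 to s_per, 5-mers containing N never count as poly A/T, N
bases are excluded from composition denominators, and windows containing N
are flagged.

**Poly A:T tracts.** `pure` mode reports maximal runs of A/T of at least
`min_len` (default 20 bp). `windowed` mode reports maximal intervals in
which every 20 bp subwindow is ≥ 90% A/T, trimmed to the outermost A/T
bases. Two passing candidate intervals separated by fewer than 20 bp of
failing windows can overlap; they are merged into one tract whose purity
field records its actual A/T fraction, keeping the output sorted and
disjoint.

## Track and binding comparisons

`compare_tracks` mean-bins both tracks (default 50 bp) and reports Pearson
and Spearman over bins, dropping (and counting) bins where either track is
undefined; fewer than 3 shared bins is an error. For the in-vitro binding
analysis each assayed fragment is summarised by its **mean** occupancy
(sum would overweight long fragments); the headline statistic is Spearman's
rho because the inverse-binding claim is ordinal, with Pearson alongside and
a permutation p-value (y-shuffles) for the independence null. Zero-variance
inputs yield an absent correlation with the reason recorded rather than a
NaN.

## Synthetic libraries: what they emulate, and what they do not

The generator alternates nucleosome-array blocks with depleted blocks:

| parameter | default | meaning |
|---|---|---|
| chrom_length | 1 Mb | one synthetic chromosome |
| repeat_length | 197 bp | planted dyad spacing inside arrays |
| footprint | 147 bp | protected length per nucleosome |
| array_block_length | 3 kb | ~15 nucleosomes between depleted blocks |
| ndr_block_lengths | 300, 700 bp | alternating depleted-block widths |
| gc_rich_fraction | 0.60 | GC content of array sequence |
| at_purity | 0.95 | A/T fraction of depleted-block sequence |
| n_fragments | 200,000 | ~30× fragment coverage |
| frag_len_mean, sd | 150, 8 bp | Normal protected-fragment length law |
| dyad_jitter_sd | 20 bp | Normal positional jitter of fragment centers |
| background_fraction | 0.10 | uniform non-nucleosomal fragments |

Array sequence is GC-biased with AA/TT dinucleotides planted every 10 bp
under each dyad; depleted blocks are concatenated A/T homopolymer runs
(10–40 bp) with G/C contamination at rate 1 − purity — i.e. genuine
poly(dA:dT) tracts, the sequence feature the energy model penalises, not
merely AT-rich composition. Fragment lengths and jitter are Normal: the
real protected-fragment distribution is unimodal near 150 bp without a
published parametric form, and Normal is the simplest testable stand-in.
The 10% uniform background represents sub-/supra-nucleosomal digestion
products and exercises the size filter. Everything is deterministic under
(params, seed); each stage draws from its own seeded stream.

What the simulation does *not* model: sequencing error, mappability gaps,
PCR duplicates, MNase sequence bias, partially unwrapped or multi-nucleosome
particles, and cell-to-cell heterogeneity beyond dyad jitter. Passing the
recovery tests therefore shows the pipeline is correct on an idealised
library at realistic coverage and noise — not that real chromatin meets
these assumptions.

With these defaults the end-to-end run recovers ≈93% of planted dyads
within ±20 bp at ≈93% precision. The residual few percent are genuine
boundary physics, not bugs: summits at array edges shift toward the adjacent
depleted block's coverage cliff, and 20 bp jitter at 30× occasionally moves
a summit just past the tolerance.

On rank vs product-moment agreement between observed and sequence-predicted
occupancy: with depleted blocks occupying ~14% of the genome, a
block-indicator signal caps Spearman's rho near 3p(1−p) ≈ 0.36 even under
perfect block separation, because within-array ranks are dominated by noise
the sequence model does not (and should not) predict. Pearson, which weights
the large depleted-vs-array contrast, runs 0.65–0.92 depending on bin size.
Tests therefore assert the sign structure (predicted occupancy lower over
poly A:T blocks), rho > 0.3 and r > 0.6 at 50 bp bins, rather than a rank
correlation the composition of the genome cannot support.

## Problem sizes and determinism

Default test and acceptance runs use the 1 Mb / 200k-fragment library (the
full default conditions) plus a 60 kb library at the same coverage for
per-module checks; enumeration cross-checks use L = 3 rods on sequences of
N ≤ 12 where exhaustive enumeration is exact and fast. Every stochastic
test fixes its generator seed; hypothesis property tests run derandomised
profiles.

## Known limitations

- BED-PE reading assumes both mates on one chromosome; inter-chromosomal
  pairs are dropped with a logged count.
- Duplicate fragments are kept by default (a `drop_duplicates` flag exists
  for BAM input); duplicate handling upstream is the user's choice.
- The peak caller assumes a single dominant nucleosome class; sub-147 bp
  particles are filtered out, not modelled.
- The energy model is qualitative by design: α, β, p are not fitted to any
  in-vitro nucleosome collection, so predicted occupancy supports sign- and
  rank-level claims, not absolute levels.
- KDE mode estimates of the distance distribution are bandwidth-dependent;
  modes within ±15 bp of planted spacing are recovered at default settings.
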