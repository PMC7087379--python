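# Methods

This note records the models, parameter choices and numerical conventions
behind `hicsv`, including the points where the design was genuinely open.

## Data model and conventions

The genome is cut into fixed-width bins (0-based, half-open; the last bin
of a chromosome may be short). chrY and chrM are excluded by default: chrY
is absent or copy-variable in most samples and chrM's coverage is dominated
by organelle copy number, so both would distort coverage statistics.
Contact matrices hold one dense block per chromosome pair; intra blocks are
kept fully symmetric, and the sparse text format stores only the upper
triangle, mirroring on read. Count matrices are finite and non-negative;
ratio (background-adjusted) matrices carry NaN for masked cells, which every
downstream statistic skips. Matrix "mass" counts each locus pair once
(upper triangle of intra blocks plus inter blocks), so a matrix built from
N valid read pairs has mass N.

## Read-pair classification

An end is *split* when its clipped sequence has its own mapping. Both ends
unique → normal; one end split across loci A/B with the mate at B →
unambiguous chimera (a ligation-junction product, valid); any other split
configuration → ambiguous chimera, excluded from the matrix but retained
for breakpoint refinement; any unmapped/multi-mapped/duplicate-flagged end
→ discarded. Open points resolved here:

* **"Same locus" tolerance** (`join_window`): 1 kb. Any value well under
  the analysis bin size works; 1 kb is conservative for typical insert
  sizes.
* **Multi-mapping**: mapq 0 or a secondary alignment, following BWA-MEM
  conventions.
* **Duplicates**: identical (chrom, pos, strand) of both 5′ ends, first
  kept. Matrix assignment uses each end's 5′ position; restriction-fragment
  assignment is out of scope (binning is positional).

## CNV model

The 1D coverage (row/column sums at 50 kb) is fitted on *usable* bins
(mappability ≥ 0.5 and ≥ 1 restriction site — thresholds are ours and
configurable) with a Poisson GAM: one cubic B-spline smooth (5 df) per
covariate, fitted by penalized IRLS via statsmodels. A near-constant
covariate degenerates to the intercept with a warning. Residuals are
working residuals `log(obs) − log(fitted)` with observed counts floored at
0.5 to avoid −∞ while preserving rank; this matches the interpretation of
residuals as log-coverage corrections. Fit quality is reported as deviance
explained. Log2 ratios are median-centered before segmentation (the
centering convention is a choice; it makes "neutral" mean "median ploidy").

**Segmentation.** Greedy merging of adjacent segments under
`BIC(λ) = RSS/σ̂² + λ·k·ln(n)` per chromosome, where `k` is the number of
breakpoints and `σ̂` is a robust noise scale from first differences
(MAD-based). The merge order (always the pair with the smallest RSS
increase) does not depend on `λ`; `λ` only sets the stopping point, so the
number of segments is non-increasing in `λ` by construction. Exactly-equal
neighbours merge regardless, so a constant profile yields one segment. This
is a BIC-seq-*style* procedure on log2 ratios with `λ`'s documented role
(larger `λ` → smoother profile), not a byte-compatible reimplementation of
any external segmenter. Defaults: `λ = 50`, binsize 50 kb. Calls use
strict thresholds ±0.3 on the segment mean.

**Concordance.** A segment of set A is supported by set B when its overlap
with same-call B segments exceeds half its own length; the supported
fraction can be restricted to segments above a size floor (e.g. 2 Mb).

## Translocation screening

Statistics are computed on background-adjusted blocks: each library in the
background panel is scaled to the panel's mean total mass before averaging
(depth normalization is a choice — un-normalized averaging would let deep
libraries dominate), and adjustment is the cell-wise ratio with pseudocount
0; zero-background cells are masked rather than set to 0/∞.

* **Gini index**: cells of the adjusted block, excluding masked cells and
  cells in rows/columns that form no contacts at all (the "no contacting
  region" exclusion is applied per row/column, a choice the data format
  leaves open). Values are sorted ascending; the Lorenz curve is integrated
  by the trapezoid rule; the index is `2·(0.5 − area)`.
* **Rank product**: rank 1 = largest Gini / largest MIF, ties get average
  ranks (the tie rule is ours), so small RP marks strong candidates;
  `RP ≤ 0.05` defines candidates.

## Breakpoint regions

1D row/column profiles of the candidate block are segmented by an exact
dynamic program (optimal piecewise-constant fit for each breakpoint count
`k ≤ 6`, minimum segment 5 bins; `k` chosen by BIC with penalty
`3·k·ln(n)`). These settings are not externally fixed; the DP is exact, so
it equals exhaustive enumeration on any input.

Change points are *boundary* indices (the corner between two bins), and the
four 5×5-bin quadrants meet at that corner. A quadrant is *high* when its
mean exceeds the 99th percentile (linear interpolation) of the block's
unmasked cells; the remaining quadrants must additionally be *low* (mean at
most half the threshold) — around a real breakpoint the untouched quadrants
sit at background, and without this requirement candidate corners inside
the elevated band leak through. One high quadrant → unbalanced; two
diagonally opposite → balanced; all other patterns are rejected.

Because a balanced event produces a peak, not a step, in the 1D profiles,
the change point can land a few bins off the fusion corner. Each candidate
intersection is therefore refined by a local scan (±8 bins): every corner
is scored by its best quadrant-pattern contrast (weakest elevated quadrant
minus strongest background quadrant) and the maximizing corner wins;
corners within 3 bins of an already-reported one are treated as the same
breakpoint. The strict quadrant test is applied at the refined corner.

## Base-pair refinement

A supporting chimera has its primary alignment's clip boundary inside one
rough region and its clipped-part mapping inside the other (clip ≥ 20 bp,
mapq ≥ 1 — thresholds are ours). The reported coordinates are the modal
(posA, posB) pair, ties broken toward the smaller coordinates; with no
support the rough regions stand.

## Synthetic data

The backbone emulates two features of real Hi-C maps: intra-chromosomal
distance decay `scale·(d+1)^−α` (default `α = 1`, `scale = 1000`) and a
uniform inter-chromosomal background (default 20 expected counts per 1 Mb
cell pair — the regime of a deeply sequenced library, where the adjusted
background ratio concentrates near 1; far sparser maps leave Poisson noise
dominating the Gini statistic for every pair). Poisson sampling is seeded
and bit-reproducible. The background panel is five independent replicate
libraries of the unmodified backbone, averaged.

Translocations are planted by relocating contact expectations under the
fusion's coordinate rearrangement: the derivative `A[:i] + B[j:]` copies
the broken intra-chromosomal entries into the inter-block quadrant (rows
before the breakpoint, columns after), and a balanced exchange adds the
reciprocal quadrant while downgrading the broken intra contacts to
inter-chromosomal background. For balanced homozygous events this is a
pure relocation — mass-conserving, exactly so when the exchanged tails have
equal bin length (unequal tails clamp missing sources to distance-diagonal
means of the partner block, which conserves mass only approximately).
Unbalanced events are modelled as a *gained* derivative on top of intact
homologs, so only one quadrant changes; coupling the lost tail's copy
number into the matrix would entangle the translocation simulator with CNV
state, which is out of scope. Heterozygous events mix original and
rearranged expectations 50:50 (diploid, one derivative allele).

The simulated benchmark uses a 22-chromosome genome (sizes linearly spaced
100 → 45 Mb, 1 Mb bins) with 21 translocations on distinct chromosome
pairs, breakpoints drawn from the central 60% of each chromosome, cycling
through all four balanced × zygosity combinations; results are medians over
3 seeds. These sizes keep a full pipeline run at a few seconds per seed.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: A/B compartments and TAD structure,
centromeres/telomeres and unmappable gaps, cell-type-specific background
differences, copy-number/translocation compound events, and read-level
artifacts (the chimera generator writes clean clip coordinates). Real-data
performance additionally depends on the background panel matching the
sample's cell state.

## Numerical choices and degenerate inputs

* Empty matrices produce all-zero coverage, not errors.
* Gini is undefined (NaN) for empty/zero blocks; such pairs are dropped
  from screening with a warning.
* Change-point BIC uses `ln(RSS/n + 1e-12)` so exactly-constant profiles
  select zero breakpoints.
* Percentiles use numpy's linear interpolation.
* All simulator randomness flows through a single seeded generator; two
  runs with the same seed are bit-identical.

## Known limitations

Intra-chromosomal translocations are out of scope (TAD/loop structure
confounds them). The screening stage needs at least two scorable
chromosome pairs. The GAM's deviance-explained is not comparable to R²
values computed by other definitions. Breakpoint regions inherit the
resolution of the matrix they were localized on; supply a finer matrix for
finer regions, or chimeric reads for exact coordinates.
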