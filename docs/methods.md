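# Methods

## Model and procedure

DamID-seq measures how often each GATC restriction fragment was
methylated — hence visited — by a Dam fusion protein. Binding of the
protein of interest (POI) is inferred by testing, fragment by fragment,
whether Dam-POI samples yield more reads than Dam-only controls.
The pipeline is: fragment partition → read counting → abundance
filtering → normalization → moderated testing → region merging and
FDR control.

### Fragment partition

DpnI cleaves methylated GATC between GA and TC, so cut positions are
placed at offset +2 inside every GATC occurrence; fragment boundaries
are consecutive cuts, with chromosome ends closing terminal fragments.
GATC cannot overlap itself, so no tie-breaking is needed. `N` or any
other non-ACGT base breaks a match; matching is case-insensitive.
Coordinates are 0-based half-open throughout. Any consistent
within-motif cut offset would shift all boundaries identically; +2 is
chosen because it matches the enzyme.

### Counting

Retained reads are primary, mapped, on informative contigs (patterns
`_alt$`, `_random$`, `^chrUn`, `^chrM$`, `^MT$` excluded by default,
configurable) and outside any exclusion BED (e.g. the ENCODE
blacklist); exclusion is by any overlap (1 bp suffices). PCR
duplicates are deliberately retained: reads start at restriction cut
sites, so identical alignments are expected biology, not artifacts.
A read increments exactly one fragment, and only when fully contained
(`start ≥ fragment.start` and `end ≤ fragment.end`); boundary-spanning
reads — partial-digestion products — count toward nothing. Library
size is the number of reads passing the filters, assigned or not,
because normalization should reflect sequencing depth. Semantics are
single-end (50 bp typical); these choices follow the conventions of
window-based differential binding analysis.

### Abundance filter

For fragment *f*, `aveLogCPM_f = log2((ȳ_f + p) / (L̄ + 2p) × 1e6)`
with pseudocount `p = 2`, `ȳ_f` the mean count and `L̄` the mean
library size. Fragments at or below the aveLogCPM equivalent of 10
mean reads are removed ("10 or lower" is inclusive: a fragment
averaging exactly 10 reads is dropped). The cutoff is computed on raw
library sizes by default. Removing fragments never changes another
fragment's aveLogCPM, since the statistic depends only on library
sizes.

### Normalization

TMM (trimmed mean of M-values) composition factors are computed on the
retained fragments: reference = sample whose upper-quartile CPM is
closest to the across-sample mean; per sample, a precision-weighted
mean of M-values after trimming 30% per tail on M and 5% per tail on
A; factors are rescaled to geometric mean 1. Log₂ CPM uses effective
library sizes (library × factor) and a library-proportional pseudocount
`p_s = p·Ê_s/mean(Ê)` so zero counts map to the same abundance in every
sample.

**Smooth quantile normalization.** Dam-only and Dam-POI count
distributions genuinely differ (bound fragments gain reads), so full
quantile normalization would erase signal. At each quantile *i* the
normalized value interpolates between the overall reference `Q̄_i` and
the sample's group reference `Q̄_ig`:

    out = w_i Q̄_i + (1 − w_i) Q̄_ig,
    w_i = clamp(1 − SSB_i / SST_i, 0, 1)

where SST/SSB are total and between-group sums of squares of the
sorted-value matrix at quantile *i* (w_i = 1 where SST_i = 0). Weights
are smoothed by a running median over `round(0.05 × n)` quantiles.
Original row order is restored by rank; tied input values receive the
mean of their tied positions' normalized values, which makes the map
deterministic and order-independent. With a single group this is
exactly full quantile normalization. Because w varies across
quantiles the map is only *nearly* monotone within a sample; tiny
local rank inversions are possible and harmless.

A quantro-style permutation test justifies the choice on a dataset:
the statistic is the ratio of mean between-group to mean within-group
quantile mean squares, with p from label permutations
(`p = (1 + #{perm ≥ obs}) / (B + 1)`). The published two-stage
median-ANOVA construction is collapsed to this single F-ratio — the
test is used only as an appropriateness check, not for inference.

### Moderated tests

Per fragment, ordinary least squares on the two-group design gives the
log₂ fold change (Dam-POI − Dam-only), pooled residual variance `s²` on
`d = n − 2` df, and coefficient variance multiplier
`c = 1/n₁ + 1/n₂`. Only the two-group design is supported — it covers
every DamID comparison the tool targets.

*Variance trend:* lowess (span 0.4, configurable) of `ln(s² + 1e-8)` on
aveLogCPM, bias-corrected by subtracting
`E[ln(χ²_d/d)] = ψ(d/2) − ln(d/2)` before exponentiating, yields the
prior variance `s₀²(abundance)`.

*Empirical Bayes:* under the scaled-F hierarchy,
`z = ln(s²/s₀²)` has `var(z) = ψ′(d/2) + ψ′(d₀/2)`; the prior df `d₀`
is obtained by inverting the monotone trigamma function on the excess
variance (no excess → `d₀ = ∞`). The robust variant winsorizes z at
the 5%/95% quantiles first — a single global `d₀` with outlier-limited
moment matching, simpler than per-fragment outlier df but preserving
the intent of robust moderation. Winsorization biases `d₀` upward
modestly (a true `d₀ = 4` at `d = 4` is typically estimated near 6);
simulations show the estimate stays well inside a factor of two.
Posterior variances `s̃² = (d₀ s₀² + d s²)/(d₀ + d)` feed
`t = logFC / sqrt(s̃² c)` on `d₀ + d` df (normal reference when
`d₀ = ∞`). Setting `d₀ = 0` with the trend off reproduces the
classical two-sample t-test exactly, which the tests use as an oracle.

### Regions and peaks

Retained fragments are linked when the gap to the next fragment is
≤ `tol` = 260 bp (median mm10 GATC fragment size; the boundary is
inclusive). A linked run spanning more than `max_width` = 10,000 bp is
split into `ceil(span/max_width)` sub-clusters of near-equal span with
members assigned by midpoint — any deterministic split satisfying the
cap would do; this one is simplest to verify. Per region the combined
p-value is Simes' `min_k (m p₍k₎/k)`, valid under the positive
dependence expected of neighboring fragments; BH adjustment across
regions gives the FDR. The region's representative logFC is that of
its smallest-p member (ties → smallest fragment index). A peak is a
region with FDR strictly below 0.1 *and* representative logFC above
0.5; only enrichment (positive logFC) is ever called, since DamID
peaks are Dam-POI gains.

High-confidence filtering keeps peaks with mean log₂ peak CPM > 4.5
(strict) and coefficient of variation (sd/mean, ddof = 1) < 0.75,
computed over Dam-POI replicates; peak CPM is the sum of
member-fragment CPM. "Counts" are interpreted as CPM and the mean is
taken over replicates — the thresholds' exact scale is
convention-dependent, so both bounds are parameters.

### Tracks

Coverage is per-base depth collapsed to runs; scaling is CPM on TMM
effective library sizes (recorded in track metadata — other factor
conventions exist, and outputs state which was used). Group tracks
are means of per-replicate scaled tracks. Subtraction is the
piecewise difference over the union of breakpoints with uncovered
positions as zero; negative values are retained. All operations
maintain canonical form (no adjacent runs with equal value). bigWig
output is emitted when pyBigWig is importable, otherwise bedGraph with
a notice.

### qDamID

`%GATC_x = digested/undigested × 100` (DpnII cuts only unmethylated
GATC; surviving template measures methylation). Enrichment is the
difference of normalized shares,
`subtract_x = %x^POI/Σᵢ%ᵢ^POI − %x^Dam/Σᵢ%ᵢ^Dam`, which cancels any
condition-wide scaling and sums to zero across the panel. Triplicate
averaging happens upstream of the formulas (raw replicate rows are
averaged on input as a convenience). Percentages above 100 are
retained as measurement noise but flagged above 120.

## Simulator

The generator emulates what the pipeline must cope with: a genome with
GATC motifs at geometric spacing (default per-position rate 1/256, the
expected density of uniform random sequence; accidental background
motifs are mutated away so the realized rate is exact); a log-normal
fragment *accessibility* propensity (σ = 0.75) shared by both groups,
mimicking Dam-only's preference for nucleosome-free DNA; binding
fragments drawn uniformly (default 1%) with a log₂ effect (default 2)
applied only to Dam-POI samples; negative-binomial counts
(`var = μ + φμ²`, default φ = 0.1) with per-sample means normalized so
expected totals match the configured depth (default 50 reads per
fragment); and 50 bp reads placed uniformly fully inside fragments.
All randomness flows from one seed through a single generator.

It does **not** model sequencing error, mappability, GC/tagmentation
bias, replicate-specific Dam expression, or clustered binding sites —
passing benchmarks therefore demonstrate the statistical machinery
under the assumed noise model, not robustness to those artifacts.
`simulate_fragment_map` draws fragment coordinates directly from the
geometric spacing model without synthesizing sequence, for count-level
benchmarks where nucleotides are irrelevant; note the *median* of the
geometric length distribution (~180 bp) sits below its mean (~256 bp),
whereas real genomes have their own length profile.

## Benchmarks and problem sizes

The acceptance benchmarks run the statistical pipeline from simulated
counts at the standard design — 3 vs 3 replicates, ~20k fragments
(5.2 Mb at the default motif rate), depth 50, φ = 0.1, 1% binding at
log₂ effect 2 — averaged over 20 seeds: planted-peak recall ≥ 0.8 with
false-discovery proportion ≤ 0.15, and ≤ 1 called region on average
when no effect is planted. The read-level counting identity (emitted
reads re-count exactly to the generating matrix) is checked at 2k
fragments and depth 5, where full SAM-level processing is fast. The
moderated-t stage is additionally cross-checked against the
Bioconductor limma implementation on a 500-fragment matrix in the test
suite (identical coefficients; near-identical statistics, since the
trend smoother and prior-df estimator differ in detail).

## Known limitations

- Two-group designs only; no covariates, pairing or precision weights.
- Global robust `d₀` rather than per-fragment outlier df.
- FDR is plain BH over regions; weighted region-level variants are not
  implemented.
- Paired-end data are accepted only as single-end-style spans.
- The quantro check is a simplified one-stage permutation F-test.
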