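# Methods

## Model and procedure

A chromosome is represented by the GC fraction of consecutive
non-overlapping windows of `window_bp` = 32 bp, computed on the null-free
sequence (every character outside A/C/G/T is discarded and the flanks
concatenated; the removed runs are kept so coordinates can be lifted back).
Published median domain lengths from IsoPlotter-based segmentations are all
exact multiples of 32, which is why 32 bp is the native resolution here;
the trailing partial window is dropped.

Segmentation is recursive binary splitting. For a segment of n windows with
mean GC p, a split at s yields parts with means p₁, p₂ and score

    D_JS(s) = H(p) − (s/n) H(p₁) − ((n−s)/n) H(p₂)   [bits],

H being the binary entropy with H(0) = H(1) = 0. The best admissible split
(both children ≥ `min_domain_bp` = 1,024 bp = 32 windows; ties to the
leftmost index) is accepted iff its score exceeds the dynamic threshold,
and the recursion descends depth-first, left child first. The output tiles
the track; a whole track shorter than the minimum domain is emitted as a
single segment flagged sub-minimum. Entropies are evaluated on window-mean
GC rather than raw base counts; at 32-bp windows the two are
indistinguishable in practice.

### Dynamic threshold

The halting criterion is the `null_quantile` (default 0.95) of the maximal
admissible D_JS over `n_null_sims` (default 1,000) simulated homogeneous
segments of the same length whose window GC is i.i.d. normal with the
segment's window-GC standard deviation (clamped to [0, 1]; the mean is
irrelevant and fixed at 0.5). The binomial window distribution of real
i.i.d. sequence is close enough to normal at 32 bp that the false-split
rate stays at the nominal level (measured ≤ a few percent against the 5%
design point).

Thresholds are expensive, so they are evaluated lazily on a grid — integer
powers of two in n, multiples of 0.005 in sd — and interpolated bilinearly
in (log₂ n, sd). Node seeds derive deterministically from the run seed and
the node coordinates, so a query that lands exactly on a node equals a
direct, uncached simulation with the same seed, and results never depend
on evaluation order. Two provable shortcuts avoid most large simulations:
the null quantile scales like sd²·log log n / n (decreasing in n at fixed
sd — asserted numerically in the unit suite), so a split whose score beats
the threshold at 2¹² windows is accepted outright for any longer segment,
and a score below the upper-bracket node value is rejected outright.
Simulation internals use float64 partial sums with float32 entropy
matrices; threshold values carry ~1% Monte-Carlo noise at 1,000 sims,
far below the margin that matters for the 95th-percentile decision.

### Homogeneity, GC class, length class

A domain is *homogeneous* when its window-GC variance is significantly
smaller than the variance of its chromosome: with n windows,
(n−1)·var/chrom_var is referred to the lower tail of chi-square(n−1)
(the large-sample limit of an F reference) at α = 0.05. Everything else —
including a domain statistically indistinguishable from its chromosome —
is *nonhomogeneous*; a chromosome that is one single i.i.d. domain is
therefore classified nonhomogeneous, a known boundary case of the
definition. The chromosome (not the whole genome) is the reference, per
the definition of the classification.

GC-rich means GC strictly above the cohort critical value (the unweighted
mean of the cohort's per-genome mean GC; 40.9% for the published ten-mammal
cohort). Length classes are half-open decades: sub-short < 10³ bp (only
possible on sub-minimum tracks), short [10³, 10⁴), medium-short [10⁴, 10⁵),
medium-long [10⁵, 10⁶), and long ≥ 10⁶ bp (open-ended, since real genomes
contain domains beyond 10⁷ bp). *Isochoric* = homogeneous and ≥ 300 kb
(100 kb available as an alternative cutoff). Density uses the sequenced
length by default; the null-free span is available via
`density_denominator="nullfree"` because the two differ in gapped
assemblies and the published tables do not say which was used.

## Cross-genome statistics

Lengths are compared on the natural-log scale, GC contents raw. Smoothing
sorts the transformed values into 1,000 nearly equal consecutive groups
(sizes differ by ≤ 1, larger groups at the lower tail) and histograms the
group means on 38 equal bins — ln-lengths on [8, 16] (≈ 3 kb to 8.9 Mb,
the observed domain range; log base e is the only base for which [8, 16]
spans it), GC on [0, 1]; out-of-range means are clipped into the end bins.
The KS test runs on the raw transformed samples (asymptotic p), FDR is
Benjamini–Hochberg within one comparison family (all pairs of one
attribute × domain type), and the effect sizes are the nonoverlap
percentage 100·(1 − Σ min(f₁, f₂)) of the smoothed histograms and Hedges'
g on the transformed scale. The meaningful-difference rule (overlap > 98%
and |g| < 0.05 ⇒ not meaningful) is calibrated for genome-scale samples:
at n ≈ 4×10⁴ domains the histogram noise sits well under the 2% clause
and identical generators are flagged in 0/15 replicates, but at n = 10⁴
the noise alone is 2–3% and the rule over-flags — it should not be applied
to small samples. Lilliefors normality uses the statsmodels table p-values
(deterministic); skewness uses population central moments, no bias
correction.

## Power-law fits

Continuous treatment (domain lengths span 10³–10⁷ bp): MLE exponent
α = 1 + n_tail/Σ ln(xᵢ/xmin); xmin minimizes the KS distance between the
tail ECDF (evaluated as i/m at the i-th order statistic) and the fitted
CDF over candidate xmins at the unique data values, thinned to ≤ 250
log-spaced candidates above 10⁵ points; semi-parametric bootstrap p
(empirical body + parametric tail, full refit per replicate, default
1,000 replicates, deterministic per seed), with p < 0.01 as the rule-out
level. Exponent recovery on Pareto data is accurate to ±0.05 at n = 10⁴,
and the bootstrap is calibrated under the null. Two honest limitations:
the xmin estimate itself is noisy (anywhere in the lower half of a pure
Pareto sample), and the free-xmin test has little power against smooth
heavy-tailed alternatives at desk scale — a pure lognormal is usually
*not* rejected at n = 10⁴ because the selected tail is locally
power-law-like (the power-law family is closed under power transforms, so
the lognormal σ is irrelevant to this). Rejections like those reported for
real domain-length samples require the genuine multi-scale curvature and
sample sizes (≈ 4×10⁴–10⁵) of real segmentations.

## Synthetic genomes

The generator emulates the statistical structure the analysis assumes:
per-chromosome mosaics of domains with lognormal lengths (median 8 kb,
ln-sd 1.5, clipped below at the minimum domain; heavy right tail reaching
Mb scale at 100-Mb genomes), truncated-normal mean GC (0.41 ± 0.06 on
[0.25, 0.65]), and a configurable nonhomogeneous fraction (default 0.3).
Bases are drawn independently: G/C with the local GC probability (G = C),
else A/T. Nonhomogeneous domains default to fine-grained mosaics whose
32-bp sub-blocks have GC jittered with sd 0.10 — heterogeneity below the
segmenter's resolution limit, which raises within-domain window variance
(the operational meaning of "nonhomogeneous") without creating any single
significant breakpoint. Sub-blocks much longer than a window would instead
be real sub-domains: they make window GC autocorrelated, break the i.i.d.
null, and get recursively shredded. Within-domain gradients are available
as a second kind but are not the default: a gradient steep enough to beat
chromosome-level variance (ΔGC ≳ 0.2) is itself segmented into
near-homogeneous pieces, so gradients are used for testing the classifier
in isolation. Optional N-runs *replace* sequence (keeping original
coordinates aligned) and truth breakpoints are recoverable in both
coordinate systems.

What the generator does not model: repeats and transposons, gene
structure, GC skew, mutation processes, autocorrelated long-range GC
trends. Passing the full loop therefore shows that segmentation +
classification + summary arithmetic are mutually consistent under the
stated statistical model, not that real-genome tables are reproduced;
real chromosomes violate the i.i.d.-within-domain assumption in ways that
shift absolute counts.

## Numerical choices and problem sizes

Ties in D_JS break to the leftmost split; recursion order does not affect
output (tiling invariant). Coordinates are 0-based half-open in the
null-free system. GC values are stored as fractions and reported as
percentages at one decimal. The acceptance script and test suite use the
sizes the analyses were designed at: 100 × 1-Mb tracks for calibration and
boundary recovery, n = 10⁴ with 200 bootstrap replicates for the
power-law checks, and one 100-Mb genome (20 × 5 Mb chromosomes) for the
full loop.

Boundary localization is information-limited: with a 10-point GC contrast
the per-window signal-to-noise is ≈ 1.15, the breakpoint estimate is the
argmax of a two-sided random walk, and about a quarter of replicates land
more than two windows (64 bp) from the truth no matter the estimator —
measured recall within ±64 bp is ≈ 0.75 (recomputed by the acceptance
script), while 20-point contrasts localize within a few windows (unit
suite).
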