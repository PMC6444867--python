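# Methods

## Binning and bookkeeping

Coordinates are 0-based half-open throughout. Each autosome is tiled with
`ceil(length / bin_size)` bins of `bin_size` (default 1 Mb); the final
partial bin is kept, which is what makes the hg19 autosomes come out at
exactly 2897 bins. Sex chromosomes are excluded by construction: a
`GenomeBuild` lists autosomes only.

Blacklisting uses any-overlap semantics — a bin is unusable if any BED
interval overlaps it by at least 1 bp. No overlap fraction is configurable
because any threshold other than "any" would need a justification we do
not have; any-overlap is the conservative choice and the easiest to reason
about in tests. The classic exclusion list for this kind of analysis
(centromeres, telomeres, low-mappability bins) is deployment-specific, so
the blacklist is an input, not a constant; the test suite constructs a
deterministic centromere/telomere-style BED covering exactly 163 hg19 bins
to exercise the 2897 → 2734 bookkeeping.

## Read counting

A read is retained iff mapped, primary (not secondary/supplementary), not
flagged as a duplicate, and MAPQ ≥ `mapq_min` (default 60; with BWA-MEM
this keeps uniquely mapped reads). Each retained record counts once, in
the bin containing its leftmost aligned base — the standard choice for
shallow-WGS bin counting and deterministic for reads straddling a bin
boundary. Duplicate flags are trusted as written upstream (Picard-style);
no re-deduplication. Paired-end data would count each retained primary
record once; the fixtures are single-end 75 bp reads, matching the typical
shallow-WGS configuration.

GC content per bin is (G+C)/(A+C+G+T); ambiguous bases count only toward a
separate `n_fraction`, and an all-N bin has missing GC and drops out of
the model.

## GC correction

Depth bias is treated as multiplicative in GC: a LOESS curve (locally
linear, span 0.3, one robustness iteration; all exposed) of raw count on
GC fraction is fitted over usable bins, and each bin is rescaled by
`median(fitted) / fitted_i`. A multiplicative correction keeps counts
non-negative and matches how coverage bias actually enters sequencing
depth; additive residuals can go negative at low depth. The smoother is
statsmodels' lowess; because its direct-evaluation path does not combine
with robustness iterations, fitted values at each bin's GC are read off
the sorted smoother output by linear interpolation (identical at the data
points, and well-defined for tied GC values). Fitting requires ≥ 50 usable
bins and non-constant GC; a constant-GC panel is an error advising the
user to skip correction rather than silently returning the identity.

Normalization to percentages happens after correction and over usable
bins only, so that a sample's usable bins always sum to exactly 100. This
makes per-bin values comparable across samples with different depths
(percentages are scale-invariant), at the cost of coupling bins through
the total — a genuinely aneuploid genome slightly depresses the
percentage of its unaffected bins, which is inherent to the method, not a
bug.

## Reference panel and scores

Panel statistics are the per-bin mean and sample standard deviation
(n−1 denominator) of control percentages; bins with zero SD are flagged
unscorable, since the Z-score is undefined there. Controls pass through
the identical GC-correction and normalization path as test samples —
scoring raw against corrected would encode the bias difference as signal.

The I-score sums |Z| over bins with |Z| strictly greater than the
threshold (default 2); strictness matters at the boundary and is mirrored
in the gain/loss calls (gain iff Z > t, loss iff Z < −t). The S-score
sums Z² over all scorable bins with no threshold. By construction the
exact-panel-mean sample scores I = 0; a control-like sample drawn from the
panel distribution keeps a small positive I-score baseline from chance
excursions (≈ 2φ(2)·n_bins·E|Z| in expectation under normality — about
40–55 on the 200-bin toy genome), which is why the zero-identity check
uses the exact-mean sample and the simulator documents the baseline
rather than pretending it away.

## ddPCR copy number

Occupancy per droplet is modelled as Poisson, so the positive-droplet
fraction k/n inverts to λ = −ln(1 − k/n) mean copies per droplet —
the standard instrument-side computation, chosen over the raw
positive-droplet ratio. The VEGFA ratio is 2·λ_target/λ_ref with the
reference gene (EIF2C1) fixed at 2 copies per genome (configurable).
Channels may have different accepted-droplet counts. Saturated wells
(k = n) are an error, not a clamp. The amplification cutoff is
mean + 3·(sample SD) of healthy-control copy numbers, with a strict
greater-than call; a fixed cutoff (e.g. an established 2.60) can be
supplied instead.

## Survival layer

Median dichotomization sends ties to the low group, matching the
"≤ median" / "> median" convention of biomarker tables; quartile
boundaries assign ties downward for consistency. The binomial CI on rates
(DCR, elevated fraction) is the unclipped Wald interval p ± 1.96·√(pq/N),
which is what published intervals of this form reproduce. Kaplan-Meier,
log-rank and Cox fits are delegated to lifelines; ties use the Efron
approximation (duplicating every subject therefore shifts the HR by a
fraction of a percent — exact invariance holds only under Breslow).
Multivariable models take the covariates whose univariable Wald p < 0.05,
i.e. screen-then-adjust. Median survival is the earliest time with
S(t) ≤ 0.5, with a log-log transformed CI; "not reached" is reported as
an infinite median.

## Synthetic data

The generator's defaults are the study conditions the package is designed
around: 14 healthy controls; arm-level CNAs +1q, +8q, −1p, −4q, −8p
(hg19 arm coordinates, or the same gain/loss/loss pattern mapped onto the
first three chromosomes of a toy build); 20,000-droplet ddPCR wells; and
survival with a group hazard ratio of 3.5 over low-group medians of 4.1
months (time to progression) and 14.8 months (overall survival) with 20%
censoring.

Bin counts follow a diploid-relative admixture: expected depth ∝
bin width × gc_bias(gc) × (1 + tf·(c − 2)/2) for copy state c and tumor
fraction tf, drawn negative-binomial (Gamma-Poisson) with dispersion 0.01
so that panel SDs sit above the Poisson floor, as in real panels; the GC
bias is a smooth concave polynomial equal to 1 at GC 0.45. The default
toy genome is 4 chromosomes × 50 Mb (200 bins) — large enough that the
I-score's mean response to tumor fraction is resolvable at desk scale,
small enough that the whole pipeline runs in seconds — and the default
depth of 3×10⁶ reads/sample puts per-bin counts in the ten-thousands
(the real depth per sample is not pinned down by the study design; what
matters is that dispersion, not shot noise, dominates, which holds from a
few hundred reads per bin upward). A copy state's bin assignment uses the
bin midpoint.

Survival times are exponential with the group hazard multiplied by the
hazard ratio; an optional shared lognormal frailty correlates TTP and OS.
Censoring is independent Uniform(0, u), with u solved by bisection so the
expected censored fraction equals the configured rate.

What the generator does *not* emulate: real mappability structure and
wavy coverage, subclonal or focal CNAs, fragment-size signal, droplet
"rain", and covariate-dependent censoring. Tests passing on this
generator show the pipeline's arithmetic and statistical behaviour are
right under the stated model, not that the model captures every artefact
of real plasma sequencing.

## Numerical and degenerate-input choices

Unusable or unfittable bins propagate as NaN and are excluded from sums;
a sample missing a value on a scorable bin is an error (grids out of
sync) rather than a silent skip. Zero total counts, empty builds,
non-positive bin sizes, saturated ddPCR wells, all-identical biomarker
values and single-group log-rank calls all raise with specific messages.
Random generation is `numpy.random.default_rng` seeded explicitly
everywhere; identical configurations and seeds give bit-identical output.

## Problem sizes in tests

The test and acceptance runs use the 200-bin toy genome with 14-control
panels, 25-replicate paired-seed batteries for the tumor-fraction
monotonicity check, 100 replicates for Cox CI coverage, and 200
Monte-Carlo wells for ddPCR recovery — sizes at which every check runs in
seconds while Monte-Carlo error stays well inside the asserted margins.
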