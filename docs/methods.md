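# Methods

This note documents the models behind each estimator, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducing
results.

## Selection model and estimators

All selection coefficients are per-generation log-fitness differences
of a haploid competitor. With fitness weight e^s per generation, the
focal/reference log ratio grows linearly, giving the endpoint
estimator s = ln(R_f/R_i)/(t·Δdays). The day→generation conversion
uses t = 18 generations/day (an ~80-minute generation time in the
streptomycin-treated mouse gut); it is a configurable constant on every
trajectory object, and 24 days correspond to 432 generations.

Design choices:

* **Zero colony counts abort estimation** with the offending day named.
  No pseudocounts are added — there is no defensible smoothing rule for
  plate counts at this depth; callers should widen or shift the window.
* **Replicate aggregation** estimates s per replicate and reports
  mean ± 2SE across replicates (the 2SE convention is flagged on the
  result object), rather than pooling counts. This matches the usual
  "average of n independent competitions" reporting and keeps
  between-host variation in the error bar.
* **Default window is 3 days** from the first observation, the standard
  competition design; exceptions (fast sweeps, frequency-dependent
  competitors) are handled by passing an explicit window.
* The **logit estimator** s = Δlogit(f)/Δgenerations is provided for
  frequency trajectories and is exactly the endpoint estimator when
  reference = all non-focal cells (unit-tested to 1e-12). It is the
  default for haplotype trajectories because population typing yields
  frequencies, not pairwise counts.

## Frequency-dependent selection

The FDS regression fits the daily map Δf_{i→i+1} = a + b·f_i by OLS on
(f, Δf) pairs pooled across replicate trajectories (per-replicate fits
are available by calling the function per series). Pooling is the
default because a single panel-level line is the quantity of interest;
with b < 0 the stable equilibrium −a/b is reported, clipped to [0, 1]
with a flag.

Two caveats the user should know:

* Observed frequencies enter both the regressor and the response, so
  binomial typing noise induces a small errors-in-variables
  attenuation: at 200 typed colonies/day the fitted slope is biased by
  about −0.006 for a true slope of −0.52 (measured by simulation).
  This is far inside the ~0.06 SE such regressions carry and is left
  uncorrected.
* The regression is on the *daily frequency* scale. The Wright-Fisher
  simulator converts a frequency-dependent pair (a, b) to a
  per-generation coefficient s_g(f) = (a + b·f)/t, which preserves the
  sign change (and hence the equilibrium) at f* = −a/b; the
  two-competitor competition simulator instead iterates the daily
  linear map literally, because that is the generating model the
  regression assumes.

Epistasis between backgrounds is classified by a two-sided
Mann-Whitney-Wilcoxon test on replicate s estimates (exact null
distribution when there are no ties), with the verdict gated at
α = 0.05 and signed by the median difference (evolved minus ancestral
background).

## Fluctuation analysis

Mutant counts per culture follow the Lea-Coulson distribution: a
Poisson(m) number of mutational events, each founding a clone whose
final size X has P(X = j) = 1/(j(j+1)) under neutrality. The pmf is
computed by the Ma-Sandri-Sarkar recursion

    p_0 = e^{-m},   p_k = (m/k) · Σ_{i<k} p_i/(k−i+1)

up to a support k_max (default 1500), and by numerical inversion of the
generating function G(z) = exp(m(1−z)ln(1−z)/z) on the unit circle
(FFT) when the needed support exceeds 4096; the two backends agree to
the FFT's aliasing error, O(m/n²) per coefficient.

* **Tail handling.** The Lea-Coulson tail is a power law
  (P(X > k) ≈ m/k), so no finite support captures it; counts at or
  above k_max enter the likelihood as an explicit censored class. This
  keeps the likelihood proper, so profile-CI coverage is unaffected by
  the truncation. The estimator picks k_max adaptively (≈ 2× the
  largest count, capped at 2^19−1 so one pmf evaluation stays at a
  2^20-point transform).
* **MLE and CI.** m̂ maximizes the censored log likelihood by bounded
  search on ln m, initialized from the Lea-Coulson median relation
  r_med/m − ln m ≈ 1.24 (p0 method when the median is 0). The 95% CI is
  the profile-likelihood interval (Δlogℓ = 1.92), with Stewart's
  closed-form approximation as fallback when the profile cannot be
  bracketed. All-zero counts sit on the m = 0 boundary; the result is
  flagged and the one-sided bound −ln(0.05)/C is reported instead.
* **Conventions.** μ = m/N_t (not m/(N_t−N_0)) to match the standard
  maximum-likelihood fluctuation calculators; pass an adjusted N_t for
  the other convention. Plating fraction is assumed 1. Selection during
  assay growth is not modeled in the estimator (a deleterious scored
  phenotype makes μ̂ conservative); the simulator accepts a mutant
  relative-fitness parameter to generate such non-neutral data.
* Simulated assays at the system's two measured rates (hotspot 1e-5
  and background 4e-8 per locus per generation, N_t = 2e9, 10
  cultures) recover the simulating rate inside the 95% CI in ≥ 90% of
  200 seeds; CI calibration is additionally checked at m ∈ {0.2, 1, 5}
  with 250 simulations each (band 0.90-0.985, the 99% binomial
  envelope of a nominal 0.95).

## Coverage CNV screen

Depth is averaged in fixed 250 bp windows and normalized by the mean
depth of windows with the same integer GC% (bins with fewer than 10
windows are merged into the nearest populated bin, with a warning).
Duplications are maximal runs of windows with normalized ratio > 1.4;
deletions are runs with ratio < 0.05 ("absence of coverage"
operationalized — the threshold is a package choice, as is the run
machinery: ≥ 4 qualifying windows (1 kb) and runs separated by ≤ 1
sub-threshold window merged. At depth 100 these defaults yield ≲ 0.1
false calls per CNV-free 4.6 Mb genome (measured over 50 simulated
genomes). Coordinates are 0-based half-open internally and in BED-style
output; mutation-table positions are 1-based.

## Muller reconstruction

Haplotype frequency = (clone fraction within its marker class) ×
(marker class frequency from plate counts). The genealogy is inferred
from strict-subset relations among mutation sets within a marker
background; incomparable candidate parents raise an explicit ambiguity
error rather than guessing. Days with marker counts but no typing are
filled by linear interpolation of the within-marker composition
(rescaled to that day's marker frequency) and flagged `interpolated`.
An untyped marker class is attributed to its root (the least-derived
compatible haplotype) — conservative, and matching the convention of
drawing unknown-background mutations without a tone change.

Frequencies are stored exclusively (each cell counted once, under its
full genotype); clade ("inclusive") frequencies are sums over
descendants. Nesting — child clade ≤ parent clade — is validated on
every reconstruction and simulator output rather than assumed.

Sweep vs clonal-interference labels use thresholds 0.95 (a derived
clade crossing it marks a sweep) and 0.10 (two non-nested derived
clades both above it mark interference); both are arguments. Clean
windows for trajectory-based s require every other derived clade —
including the focal clade's own later descendants, which would
otherwise contaminate the estimate — to stay below 0.05, a
quantification of "no other mutation segregating".

## Synthetic-data generator

The Wright-Fisher simulator runs per-generation multinomial resampling
of genotype counts weighted by e^{Σs} at fixed population size N
(default 1e7), with per-locus Poisson mutation seeding (one derived
allele class per locus) and daily multinomial colony/marker/clone
observation. `deterministic=True` replaces every draw with its
expectation, reproducing the logistic closed form of haploid selection
to 1e-12 over 432 generations.

What it emulates: the daily 18-generation cycle, hotspot (1e-5) vs
background (4e-8) mutation supply, constant and frequency-dependent
fitness with background-specific (epistatic) overrides, marker
dimorphism and hitchhiking, colony-count and clone-typing sampling
noise, Lea-Coulson fluctuation counts (exact compound-Poisson sampler,
validated against the MSS pmf by chi-square), and Poisson read depth
with a smooth GC bias and embedded duplications/deletions.

What it does not emulate: host-to-host migration, bottlenecks and
census fluctuations (the gut effective size is not parameterized by
the study; N is an explicit knob, not a claim), multiple allele
classes per locus, linkage to anything other than the single marker
locus, sequencing artifacts beyond Poisson depth noise, and phenotypic
lag or plating inefficiency in fluctuation assays. Passing tests
therefore demonstrate estimator correctness under the stated model,
not robustness to those unmodeled features.

The synthetic population time courses (`synthetic_population_series`)
are hand-shaped stand-ins for the study's two sequenced populations —
a hard sweep at 0.14/generation with a late low-frequency *srlR*
lineage, and an interference scenario with an *arcA* sweep at
0.09/generation interrupted by *pphB* and an opposite-marker *focA*
lineage. They exercise the clean-window and classification machinery
at the published effect sizes; they are not the original data. The
packaged mutation tables are likewise synthetic reconstructions that
reproduce published marginal totals (30 mutations over 15 clones, the
category/region breakdown, and exactly seven parallel targets when
combined with the 14-clone first-colonization table).

## Problem sizes and runtime

Stochastic checks use sizes chosen to make the suite complete in a few
minutes on one core while keeping binomial error bands tight enough to
be meaningful: 200 seeds for the fluctuation-recovery checks, 100
seeds for FDS slope recovery, 250 simulations per m for CI
calibration, 50 genomes for the CNV false-positive rate, and 20-50
replicates for Wright-Fisher establishment/interference checks. The
establishment check compares against a branching-process oracle
(extinction probability q = exp(e^s(q−1)), supply Nμπ per generation,
deterministic post-establishment sweep time ln(2sN)/s).

## Known limitations

* qPCR amplification efficiencies default to 2.0 per gene; when true
  efficiencies are unknown, reported fold changes are upper bounds on
  the efficiency-corrected values, and published panel values cannot
  be reproduced numerically without them.
* The FDS regression inherits OLS assumptions (homoscedastic,
  uncorrelated errors); daily frequencies from one trajectory are
  serially dependent, so its p-values are approximate.
* The Mann-Whitney epistasis test at n = 4 per background cannot reach
  p < 0.029 two-sided; smaller effects need more replicates.
* One published furazolidone-resistance CI is printed with its bounds
  apparently inverted in the source text; values derived from it are
  not used anywhere in the package.
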