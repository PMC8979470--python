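# Methods

This note documents the models implemented in `meioscope`, the design
decisions taken where the methodology was genuinely open, the numerical
choices, and the limits of what the synthetic-data tests demonstrate.

## Tetrad models

### Notation

A tetrad (bivalent) carries `r` crossovers; `E_r` (r = 0..4) is the frequency
of tetrads with `r` crossovers, with `sum_r E_r = 1`.  Only one of the four
meiotic products is recovered per meiosis, observed as a chromatid with
`j` crossovers (classes NCO, 1CO, ... 4CO with frequencies `f_j`).  Tetrads
are modeled up to `E_4` because quadruple-crossover chromatids occur (rarely)
in real data; the cap is the module constant `MAX_CO`.

### Weinstein inversion

Under random sister assignment of each crossover and random segregation,
`P(j | r) = C(r, j) / 2^r`, giving the triangular system

    f4 = E4/16
    f3 = E3/8  + E4/4
    f2 = E2/4  + 3E3/8 + 3E4/8
    f1 = E1/2  + E2/2  + 3E3/8 + E4/4
    f0 = E0    + E1/2  + E2/4  + E3/8 + E4/16

`weinstein_invert` solves it top-down and reports `E_0 = 1 - sum_{r>0} E_r`.
Negative entries are legal output (flagged `feasible = False`); they arise
from sampling noise or violated assumptions and are the analysis's object of
interest, not an error.  Forward-inverse identity (`invert(probs(E)) == E`)
holds to machine precision and is property-tested.

### Crossover-associated meiotic drive (MD_CO)

The transmitted dyad splits its `r` crossovers Binomial(r, 1/2) between the
two sisters.  When exactly one sister is recombinant, meiosis II places the
recombinant sister in the oocyte nucleus with probability `b in [0.5, 1]`;
otherwise segregation is fair.  Analytically:

    P(0 | 0) = 1
    P(j | r) = C(r, j)/2^r          for 1 <= j <= r-1
    P(0 | r) = 2 (1 - b) / 2^r      for r >= 1
    P(r | r) = 2 b / 2^r            for r >= 1

At `b = 0.5` this reduces to Weinstein.  The transmitted mean is
`sum_r E_r [r/2 + r (2b - 1)/2^r]` (property-tested against the simulator).
The model is implemented analytically rather than by stochastic simulation:
exact, fast and deterministic; the simulator provides the independent
stochastic cross-check.

### Positive chromatid interference (PCI)

Crossovers are assigned sequentially to the sisters of the transmitted dyad;
each prefers the sister with fewer previous crossovers with probability `b`
(fair coin on ties); the recovered sister is uniform.  `P(j | r)` is computed
by exact dynamic programming over sister-count states and unit-tested against
brute-force enumeration of all `2^r` assignment sequences.  PCI redistributes
crossovers among chromatids without changing the transmitted mean
(`sum_r E_r r / 2` for every `b`), which is the model's defining invariant.

### Maximum-likelihood fitting and the ridge

`fit_tetrad_model` maximizes the multinomial log-likelihood of the class
counts.  For fixed `b` the likelihood is concave in `E` (class probabilities
are linear in `E`), and is maximized by EM on mixture weights (relative
tolerance 1e-11).  `b` is profiled on a deterministic grid (step 0.002 over
[0.5, 1]) with bisection refinement of plateau edges; parameter pins
(`fixed={"E0": 0}` etc.) are honored inside the EM.

With five observed classes and five tetrad frequencies plus a bias, the
drive models are structurally over-parameterized: whenever the exactly
fitting `E(b) = M(b)^{-1} f` stays non-negative over an interval of `b`, the
likelihood maximum is a perfectly flat ridge, independent of sample size.
For the bundled X-chromosome counts the saturated ridge spans
`b in [0.638, 1.0]` with `E0` running from 0 to 0.276.  The fit therefore:

* detects the ridge (profile log-likelihood within 1e-7 of the maximum),
* reports the per-parameter maximum-likelihood intervals in `fit.ridge`, and
* quotes as point estimates the midpoints of those intervals
  (`ridge_policy="midpoint"`, the default) — the convention that matches how
  a central ridge value is conventionally reported for this analysis;
  `ridge_policy="min_b"` gives the conservative lower edge instead.

Consequence for interpretation: the drive bias is only identified up to its
ridge interval unless some parameter is pinned.  Parameter-recovery tests
accordingly check (a) that the truth lies inside the fitted intervals and
(b) exact recovery of `b` within ±0.03 once `E0` is pinned at truth.

Known discrepancy: published analyses of the same X-chromosome table based
on simulation-driven fitting report a ridge `E0 = 0 at b = 0.73` to
`E0 = 0.22 at b = 1` with midpoint-like point estimates `b = 0.86`,
`E0 = 0.10`.  The literal analytic model above cannot reproduce those
endpoints (at `b = 1` it forces `E0 = f0 = 0.276`), so its ridge midpoints
are `b = 0.819`, `E0 = 0.138` — close to, but not within ±0.03 of, the
published pair.  The same applies to the PCI point estimate (our profile
maximum is `b = 0.68` versus a published 0.59), while the likelihood-ratio
statistic between the two models (41.8 vs 41.2) agrees.  The published
fitting procedure evidently embodies a subtly different recovery rule that
is not stated precisely enough to reimplement; we keep the literal model.

### Goodness of fit, LRT, profiles

Goodness of fit is a Monte-Carlo exact multinomial test: simulate `reps`
(default 1e5) tables of size `n` from the fitted probabilities and report the
fraction with multinomial log-probability <= the observed table's (ties
count).  It is verified against exhaustive enumeration on a 3-class, n = 10
toy case.  The LRT uses `2 (logL_A - logL_B)` with chi-square df equal to
the difference in free parameters, floored at 1 (the floor covers the
non-nested drive-vs-PCI comparison; both spend the same parameter count).
`profile_surface` re-optimizes the remaining frequencies at every pinned
`(E0, b)` cell; note that in the `(E0, b)` plane the ridge is a thin curve,
so coarse rectangular grids show high relative likelihood only where a cell
happens to land on it — goodness-of-fit probabilities are the flatter,
more interpretable surface.

### Negative-E0 resampling

`e0_sampling_experiment` draws multinomial class tables of size `n` and
reports the fraction whose raw inversion gives `E0 < 0`.  For class
distributions confined to <= 2CO, `E0 = 1 - 2 f1` exactly, so the fraction
equals a binomial tail — the closed-form oracle used in tests.  For the
50/45/5 example this oracle gives ~4-5% at n = 250 and ~11-13% at n = 100;
published figures of 10% and 22% for the same setup are not reproducible
from the stated scheme and are treated as a documented discrepancy, not a
calibration target.

### Combining arms

`combine_arms` offers pooled-counts and chromatid-weighted per-arm-average
inversions, labeled; the two differ whenever arms differ in class
composition and neither is privileged.

## Synthetic meioses

The generator emulates the data-generating process, not sequencing:

* `r` is drawn per tetrad from `E`; positions are placed on the detectable
  interval by gamma-renewal gaps of shape `nu` rescaled to the interval
  (for `nu = 1` this reproduces uniform order statistics exactly; larger
  `nu` spaces crossovers more evenly), then accepted or rejected as a whole
  set against a piecewise suppression profile.  Interference and
  centromere/telomere suppression are thus two orthogonal knobs.
* each crossover lands on one sister of the transmitted dyad (fair coin, or
  the PCI rule when `pci_bias > 0.5`) — the transmitted dyad is a sufficient
  statistic for recovery, so the other dyad is not materialized;
* recovery applies the MD_CO rule with bias `drive_bias`.

Interference is applied at the tetrad level (one position set per tetrad);
whether real interference acts at tetrad or chromatid level is not settled,
and the simulator makes no claim either way.

Genotype streams place diagnostic-SNP sites with exponential gaps of mean
1.3 kb (the empirical genome-wide density); real diagnostic-SNP spacing is
clustered, so masking behavior on real data can be harsher than these tests
show.  No read-level effects (sequencing error, coverage, demultiplexing)
are modeled: caller accuracy results on synthetic data bound what the rule
cascade itself loses, not what noisy genotyping would add.  Seeding: one
master seed; arms and the stream emitter consume independent spawned
substreams, so runs are bit-reproducible.

## Crossover calling

The filter cascade follows the published rules: arms under 100 diagnostic
SNPs rejected (dot-chromosome preset: 10 SNPs, block support >= 4 SNPs);
100-kb windows stepped by 25 kb masked when the A:B call ratio leaves
[0.1, 10]; parent-label blocks spanning < 100 kb removed (shortest first)
with flank re-merging; one event per surviving block boundary, its position
drawn uniformly in the flanking inter-SNP gap; events closer than 250 kb
resolved by deleting the enclosed block and both boundary events and
re-merging (mirroring the short-block rule — the enclosed tract is treated
as a conversion-like artifact; the source rules do not specify this
resolution).  500 kb is a supported `min_sep` preset.

Two implementation decisions matter:

* the ratio mask is computed from calls **pooled across chromatids**
  (`compute_bias_mask`).  A single F2 chromatid is legitimately
  single-parent over megabases, so a per-chromatid mask would erase every
  real block; only pooled counts isolate systematic mapping bias.  Passing a
  single stream reproduces per-stream masking where that is wanted.
* event positions come from a substream keyed by `(seed, crc32(chromatid
  id))`, making calls reproducible per chromatid independent of processing
  order.

Coordinates are 1-based inclusive; mask windows are half-open, anchored at
the arm origin; BED export converts to 0-based half-open.  Calling is
idempotent on its own regenerated label stream (tested), provided
regeneration preserves each chromatid's starting parent — forcing a common
start parent changes the pooled mask.

## Landscape statistics

The proximal-fraction test compares the observed count in the proximal
third (configurable) of the *detectable span* against uniform placement;
the null proximal count is Binomial(n, fraction), sampled rather than
evaluated, to keep the replicate semantics.  The extent scan slides 1-Mb
windows by 100 kb from the scanned end, scoring each window with the
binomial CDF `P(X <= n_obs)` at success probability equal to the window's
share of the detectable span (final partial window keeps its true share);
the suppressed extent ends at the first run of five consecutive
non-significant windows (`stop_rule`).  No multiple-testing correction is
applied inside the scan — thresholds are fixed per window by design.  Note
the window p-value is discrete; calibration checks need enough events that
the atoms are small.  Rates are `100 x (events / chromatids) / Mb`; with
non-overlapping windows the profile integrates exactly to the arm map
length (tested).

## Interference

The null for 2CO spacing resamples pairs **with replacement** from the
empirical 1CO position list (exact ties redrawn), the literal reading of the
resampling scheme; a without-replacement variant is a one-line change in
`_draw_pairs`.  The test p-value conditions on replicate-**set means** (each
set as large as the observed 2CO sample); whether the original analysis
conditioned on set means or single draws is not stated — set means are
implemented.  p-values smaller than `1 / n_sets` are reported with the
resolution bound.  The gamma shape is the exact MLE, solved on the profile
score equation `log(nu) - digamma(nu) = log(mean) - mean(log)` by Brent's
method (cross-checked against `scipy.stats.gamma.fit` and, in tests,
method-of-moments behavior).  Because the 1CO landscape itself inflates the
null shape to ~1.6-2, observed `nu` is compared to the resampled
expectation, never to 1.

## Viability curves

Chromatids are discretized to 1-kb genotype bins; all ordered bin pairs are
classified AA/BB/AB/BA (telomere-proximal marker first), pair separations
converted to cM through an empirical cumulative map (called events x 100 /
chromatids), and class frequencies averaged in sliding 1-cM windows stepped
by 0.1 cM.  Pair enumeration is quadratic in bins, so bins are subsampled
deterministically (`bin_stride`); matrix products over the 0/1 genotype
matrix give the four pair-count matrices in one pass.

## Problem sizes and runtime

Test and acceptance runs use sizes chosen to make Monte-Carlo standard
errors small relative to the asserted tolerances while keeping the full
suite under a couple of minutes: 1e5 meioses for mean-invariant and
parameter-recovery checks, 1,200 chromatids at full SNP density for caller
accuracy, 1e5 draws for gamma-shape recovery (±2%), 2-4e5 pair draws for
ICD expectations (±1%), and 150-250 replicate datasets for p-value
calibration at KS alpha = 0.001.  The published-scale settings (1e7
randomization replicates, 1e6 ICD replicates, 1e5 goodness-of-fit tables)
remain the documented defaults of the corresponding functions.

## Known limitations

* The drive and PCI point estimates differ from the published ones as
  detailed above; the likelihood-ratio comparison and every Weinstein-level
  number agree.
* Genome-wide/autosome-combined `E0` values depend on an unspecified
  combining rule; both supported combiners are labeled, neither reproduces
  the published -0.005 / 0.059 exactly.
* The caller's accuracy guarantees are conditional on crossovers separated
  by more than the 250-kb resolution rule; closer exchanges are removed by
  design, which biases dense-double-crossover recovery on any data.
* No gene-conversion calling, no heterozygosity-aware genotyping, no
  inversion detection (excluded arms are handled by whitelisting).
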