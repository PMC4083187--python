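# Methods

## The estimator

One sample contributes three treatment groups of per-comet tail
intensities (percent of DNA fluorescence in the tail, values in
[0, 100]): undigested **control**, **HpaII**-digested and
**MspI**-digested nucleoids. Writing `H`, `M`, `C` for the group means
after outlier removal, the global CpG methylation estimate is

    %CpG = (100 − 100·H/M) − C .

MspI cuts every accessible CCGG site, so `M` proxies total digestible
sites; `H/M` is the unmethylated fraction; `C` removes baseline damage
shared by all three groups (same cell batch). The estimate is reported
**unclipped**: values below 0 (control damage exceeding the digestion
contrast) or above 100 are legal outputs and are flagged in `summary()`.
Because the enzymes mainly cut outside CpG islands, the quantity measured
is global methylation of CCGG sites outside islands, not island
methylation.

### Outlier rejection

Each group is filtered independently with the modified Thompson Tau rule:
repeatedly, the single point with the largest |value − mean| is removed if
that deviation exceeds `τ·SD`, where

    τ = t · (n−1) / (√n · √(n−2+t²)) ,

`t` the two-sided Student-t critical value at level α (default 0.05) on
`n−2` degrees of freedom, recomputing mean, SD and τ after every removal.
Groups with n < 3 pass through unfiltered (the SD-based test is undefined;
a warning is emitted), and an all-identical group stops immediately
(SD = 0). When the minimum and maximum are exactly equidistant from the
mean — possible only for discrete-valued data — the maximum is removed, a
deterministic tie-break shared by every code path.

A property worth knowing: as n grows, τ approaches the fixed t quantile
(≈1.96 at α = 0.05), so on large clean samples the iteration trims
everything beyond roughly ±1.5–2 SD — about 10–13% of a normal sample.
The rule is designed for small replicate sets; applied to hundreds of
comets it behaves as a heavy symmetric trim. This is why the bootstrap
must treat the filter as part of the estimator (next section).

### Bootstrap inference

Uncertainty is a percentile bootstrap over comets: each replicate
resamples every **original** group with replacement at its own size,
**re-applies the Tau filter**, and recomputes the statistic; the CI is the
(α/2, 1−α/2) quantile pair of the replicates (default 10,000 replicates,
95% interval). Re-filtering inside each replicate matters: the trim level
of an iterative Tau filter is itself sample-dependent, and bootstrapping
the already-filtered (truncated) data ignores that variability —
simulations under the linear-regime validation scenario put the coverage
of such a naive interval near 60%, versus ~97% when the whole
filter-plus-statistic estimator is resampled. Replicates whose filtered
MspI mean is zero leave the statistic undefined; they are discarded and
counted, and more than 1% of them aborts inference (it signals a failed
MspI digestion rather than sampling noise).

The resampling unit is the individual comet. Wells are carried as labels
only; a well-level (cluster) bootstrap would be the natural extension if
strong inter-well effects were present, but the generator does not create
any and the single-cell framing of the assay argues for comet-level
resampling.

Condition comparisons difference the point estimates (untreated −
treated) and, when both fits carry bootstrap replicate streams of equal
length and level, take the percentile interval of the paired difference
of the two independent streams. Plain numbers (e.g. published point
estimates) are accepted too, yielding the difference without an interval.

The inner loop uses an O(n) trimmed-mean implementation on sorted
resamples (the most deviant point is always the current minimum or
maximum, so filtering walks inward from the sorted ends with running
sums); it is unit-tested to agree with the reference filter to 1e-9.

## The forward simulator

Per cell, strand breaks are

    control: B = B0,            B0 ~ Poisson(λ0)
    MspI:    B = B0 + Binomial(S·(1−e), d)
    HpaII:   B = B0 + Binomial(S·(1−m−h−e), d) + Binomial(S·h, d·f)

with `m` the internally methylated site fraction (blocks HpaII), `h` the
hemimethylated fraction (HpaII cuts at reduced rate `d·f`, `f` = 0.5 by
default), `e` the externally methylated fraction (blocks both enzymes,
MspI included), `S` an abstract per-nucleoid CCGG site count, and `d` the
per-site digestion probability. Site-count products are rounded to the
nearest integer. Breaks map to tail intensity through a saturating
exponential dose response

    tail(B) = 100·(1 − exp(−B/κ)) ,

chosen because it is monotone, bounded in [0, 100), and linear for
B ≪ κ — the regime in which the ratio statistic is interpretable — with a
single tunable constant κ (units: breaks). Gaussian measurement noise
(SD σ, percentage points) is added per cell and the result clipped to
[0, 100] (clipping after noise keeps the invariant). Only cell-level
noise is modelled; there is no well-level random effect, so wells are
exchangeable replicates.

In the linear, zero-baseline limit, E[tail] ≈ 100·E[B]/κ, hence
E[H]/E[M] = 1 − m (for h = e = 0) and the statistic's expectation is
100·m; the first correction from curvature is a bias of approximately
−100·m(1−m)·S·d/(2κ).

**Realistic defaults** (one untreated cultured-cell sample): m = 0.6,
h = e = 0, S = 200, d = 0.9, λ0 = 10, κ = 150, σ = 5, 50 comets per
group per well, 9 wells. These produce control tails ≈ 6%, MspI ≈ 72%,
HpaII ≈ 42% — the qualitative ordering seen on real gels — and 450 comets
per treatment per sample, matching the medium-throughput design (≥9
wells, 50–100 comets/well, ≥400 comets/sample). At these defaults the
response is deep into saturation, so the ratio statistic *compresses*
(the m = 0.6 sample reads ≈ 37%, not 60%): a deliberate illustration that
the statistic is calibrated only in the linear regime. Estimator
validation therefore uses the linear scenario below.

**Linear-regime validation scenario** (`SimulationParams.linear_regime`):
λ0 = σ = h = e = 0, κ = 100·S·d (the linearity threshold), with S = 1000
and d = 0.1. Two considerations fix S and d. Partial digestion (d = 0.1)
keeps the per-comet binomial coefficient of variation large relative to
the curvature bias — the bias-to-standard-error ratio grows like
√(n·S·d/(1−d)) and is independent of κ, so near-complete digestion would
bias coverage no matter how linear the response. The large site count
(S = 1000) keeps break counts fine-grained (≈ 40 distinct levels within
±2 SD), so Tau trimming of the near-normal break distribution stays
symmetric; with coarse counts the trim boundary lands on discrete levels
and jitters the trimmed means. Under this scenario the estimator is
empirically unbiased for 100·m and 95% intervals cover at ≈ 97%.

### CEA counterpart

The cytosine extension assay incorporates [³H]dCTP at enzyme-cut CCGG
overhangs; counts are Poisson with means proportional to expected cut
sites (`scale_dpm·S·(1−e)·d` for MspI, the HpaII-susceptible analogue for
HpaII), plus a common background. The estimate is

    %CpG = 100·(1 − H/M) ,

with `H`, `M` the background-subtracted counts normalised to 0.5 mg DNA
(`dpm·0.5/mass`); `H` is floored at zero with a warning when counting
noise drives it below background, and M ≤ 0 is an error (failed MspI
digestion). Expected readout given the simulator truth is
100·(m + h·(1−f))/(1−e), i.e. exactly 100·m when h = e = 0 — the basis of
the comet/CEA concordance check. Duplicate scintillation readings of the
same reaction are averaged at the I/O layer. Treated-vs-control changes
are reported as 100·(treated − control)/control.

## Image scoring

Synthetic comets are rendered as an isotropic 2-D Gaussian head
(SD `head_sigma`) plus an exponential tail band (decay length
`tail_length`) extending toward +x from the head centre, sharing the
head's vertical profile; in-frame head and tail masses are normalised so
the recorded `truth_tail_fraction` is exact before noise (none, Poisson,
or additive Gaussian). The frame must hold ≥3 decay lengths past the head
and ±4σ around it, else a geometry error.

Scoring: background = median of the four corner patches (or a fixed
value); threshold at max(2×robust corner SD, 10⁻⁴×peak); morphological
closing; largest above-background connected component (a comparable
second object triggers an ambiguity warning); head centre from the
smoothed maximum (`brightest-disk`) or 1-D Gaussian least-squares
refinements of the vertical and left-half horizontal profiles
(`fit-gaussian`); head σ from the second moment of the vertical profile
through the head (tail-free up to its shared width). Tail = component
signal at columns past the head centre outside a disk of radius
`k·FWHM` (k = 1.5, chosen so a pure-head image scores ≈ 0); tail% is that
signal over total component signal, and head% + tail% = 100 by
construction.

The dominant systematic is tail signal hidden inside the head disk,
≈ tail_fraction·(1 − exp(−1.5·FWHM/tail_length)); defaults
(σ = 2 px, L = 500 px, 64×3072 frames) keep the noise-free sweep error
≤ 2 percentage points across tail fractions 0.1–0.9 (measured MAE
≈ 1.4) and ≤ 4 under Poisson noise at 10⁵ total counts. Tail direction is
fixed as +x by convention; images with the tail elsewhere must be
rotated/flipped first.

## Validation problem sizes

The test suite and acceptance script size their simulations as the
package's validation design: analytic-limit recovery on 2,250 comets per
group (9 wells × 250), coverage on 200 samples of 450 comets per group
with 2,000 bootstrap replicates, filter-oracle agreement on 500 random
datasets of size 3–50, a 9-point noise-free imaging sweep, and paired
comet/CEA samples at m ∈ {0.25, 0.5, 0.75}. CLI defaults keep the
published analysis settings (10,000 replicates, 95% CI, α = 0.05).

## What the synthetic data does and does not show

The generator reproduces the assay's *statistical structure* — group
sizes, enzyme logic, shared baseline damage, bounded noisy tail
intensities, count-proportional CEA readings — with known truth, so
passing tests demonstrate the estimator, filter, bootstrap and scorer are
internally correct and mutually consistent. It does not emulate
electrophoresis physics, staining chemistry, inter-well or inter-slide
effects, heterogeneous digestion across nucleoids, comet overlap, halo
artefacts, or real scorer/software idiosyncrasies; agreement on synthetic
data therefore does not certify accuracy on any particular wet-lab
dataset, especially outside the linear response regime where the ratio
statistic compresses.

## Known limitations

- The statistic is calibrated only where tail response is ≈ linear in
  breaks; saturation biases it downward (quantified above).
- Thompson-Tau trimming of large groups is aggressive by construction;
  the re-filtering bootstrap makes the *interval* honest but the trimmed
  point estimate can be biased for coarse, skewed break distributions.
- Comet-level resampling understates uncertainty if strong well effects
  exist in real data.
- The image scorer assumes one comet per frame, tail toward +x, and a
  near-Gaussian head.
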