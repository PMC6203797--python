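# Methods

This note documents the models, estimators and numerical choices behind
`iticoder`, and what the synthetic sessions do and do not emulate.

## Data model and conventions

All timestamps are seconds from session start.  All binning uses half-open
intervals `[start, end)`; a spike exactly on a bin edge belongs to the
upper bin.  The ITI preceding trial *n* runs from trial *n−1*'s offset
(US offset if reinforced, else CS offset) to trial *n*'s CS onset.  Neural
analyses align forward from trial offset; behavioral ITI analyses align
backward to the next CS — two first-class views of the same interval.
Sessions serialize to plain CSV/JSON with floats printed at 17 significant
digits, so write→read round-trips are exact.

## Synthetic sessions

The generator emulates one conditioning day: 10 habituation, 30
acquisition (optionally ~1/3 un-reinforced catch trials) and 20 extinction
trials.  The extinction count is a package choice — the analysis splits
extinction into two 10-trial sub-stages, so 20 is the smallest session
that fills both.  ITIs are Normal(38.7, 4.4) s truncated below at 5 s (the
truncation point is ~7.7 s.d. below the mean; the induced moment shift is
orders of magnitude below test tolerances).  ISIs are Normal(1.6, 0.24) s.

**Respiration** is a train of raised-cosine inhale lobes (40% duty cycle,
small negative exhale lobe) at ~0.4 Hz with 5% period and amplitude
jitter.  An inhale is aligned to each CS onset, emulating the
respiration-triggered stimulus delivery; its amplitude follows a learning
gate *g* (0 in habituation, `1 − exp(−(j+1)/8)` over acquisition trials
*j*, linear decay over extinction), so the CR roughly doubles by late
acquisition.  An optional coefficient couples the CR amplitude to the
previous ITI duration (used to verify the behavioral correlations
recover).  The model reproduces what the CR measure sees — inhale area in
a 350 ms window — not airflow physics; breath-to-breath variability is
white, so it cannot exhibit the slow physiological drifts of real
respiration.

**Spike trains** are inhomogeneous Poisson by thinning, with families:

* *tuned* — within each ITI, rate = baseline × (1 + gain · exp(−(t−peak)²/2σ²)).
  The configured `tuning_width_s` (default 5–8 s) is the total extent of
  the time field; σ = width/5, so ±2.5σ spans the stated width.  This
  makes the generator's width commensurate with the analysis' width
  measure (the supra-95%-band extent) at gains ~2–6.
* *acquisition-gated* — tuning amplitude multiplied by the learning gate
  (a subset of the tuned units; defaults 35% tuned, 23% gated, matching
  the observed population fractions).
* *hazard* — rate = baseline × (1 + gain · H(t)), H the empirical CDF of
  the session's ITI durations.
* *CS-evoked* — additive rate bump in the 350 ms after CS onset.
* *synchronized pairs* — excess coincidence events (Poisson, default
  2 Hz) confined to the early/mid/late third (or the whole, "diffuse") of
  each ITI, with the partner spike jittered uniformly within ±20 ms.

All draws flow from one `numpy` generator seeded from the config; the same
seed reproduces every output file byte-for-byte.  Units are independent
(no shared slow states, no refractoriness, no non-Poisson count
statistics), so passing tests demonstrate correctness of the estimators
under the stated model, not robustness to every failure mode of real data.

## Modulation detection

Spikes between trial offset and the session mean ITI are binned into
6/12/20/40 equal bins; a trial's bin is *valid* iff it ends within that
trial's actual ITI, and invalid bins contribute no spikes to any
statistic.  The shuffle null permutes each trial's counts among its valid
bins, independently per trial and shuffle (100 by default), preserving
per-trial totals exactly — so slow rate drift cannot mimic tuning, and the
null band widens over late bins where fewer trials remain.  A bin is
modulated when |observed mean − shuffle mean| > 2 shuffle s.d. (s.d. with
ddof 0); bins with zero shuffle s.d. are non-significant by definition.

On homogeneous Poisson populations the per-bin flag rate sits slightly
above the Gaussian 2·Φ(−2) ≈ 4.6% (the s.d. is estimated from 100
shuffles), giving a mean flagged fraction of ~5% of the ITI.  At 40 bins
the distribution of per-unit flagged fractions is almost exactly tied
between its two attainable values around the mean (2.5% and 5.0%), so the
*mode* of a 500-unit sample is a near-fair coin between them while the
mean is stable at ~5%.

## Learning stages

Stage strength is the RMS of the stage's across-trial mean rate curve
after bin-wise standardization by the stage's own shuffle null.  A
per-trial RMS variant was implemented and rejected: within-trial
permutation conserves each trial's count histogram, so any single-trial
RMS normalized by it is ≈1 identically — only across-trial consistency
carries the signal.  Because the z-curve RMS grows with trial count for
genuine structure, all stages use 10 trials (habituation; early/mid/late
acquisition; early/late extinction), and the reinforced/un-reinforced
comparison subsamples classes to the smallest class size.

Significance comes from the shuffle ensemble: each shuffled dataset yields
one null RMS per stage; the omnibus statistic is the variance of the four
learning-stage RMS values against the paired null variances, and per-stage
increases vs habituation use the paired RMS differences (permutation-style
p with the +1 correction, so p ≥ 1/(n_shuffles+1); 100 shuffles resolve
p = 0.01).  A unit is *acquisition responsive* when the omnibus test and
at least one increase are significant at α = 0.05.  Gated units at the
default 2× gain are recovered in ~10/10 seeded runs; stationary units in
≤1/10.

## Tuning

Peak = argmax of the 40-bin mean rate (ties broken to the earliest bin and
logged); width = contiguous bins around the peak exceeding their 95th
shuffle percentile; units whose band is ≤1 bin, or whose peak itself is
not above its band, are excluded.  The center of mass is computed per
trial over that trial's valid bins (skipped when fewer than 3 bins are
valid or the rate sums to zero).  Correlations of the center of mass with
the ITI duration 1–4 trials back use Pearson r per lag plus a joint OLS
regression over all four lags; population prevalence is tested binomially
against the 5% test size.

Regional peak distributions are compared with a label-permutation test
(statistic: two-sample Kolmogorov–Smirnov distance; 10 000 permutations by
default, seeded).  KS is the package's choice of statistic — the
comparison needs sensitivity to both location and shape — and is
swappable.  Two-Gaussian fits use bounded least squares on
density-normalized histograms, initialized at the two largest modes;
degenerate samples are flagged unfit rather than fitted.

## Synchrony

Windows of 3 s advance in 1-s steps from trial offset to 5 s before the
mean ITI; a window enters a trial's tally only if it fits inside that
trial's ITI.  Lags span [−750, +750) ms in 75 bins of 20 ms, so the
zero-lag bin [−10, +10) is centered; the binning phase is a package
convention.  Both nulls (within-ITI redraw; across-ITI phase-preserving
trial permutation, with phases wrapped modulo the recipient ITI duration)
default to 100 shuffles.  A cell is significant when the observed count
exceeds the 0.99 quantile of *both* nulls; a window needs a ≥2-bin
contiguous significant lag run (an anti-speckle choice); a pair needs
significant windows in ≥15% of the window grid.  On independent Poisson
pairs the compound rule flags ≤~1/8 pairs at these defaults.

For clustering, each significant pair's profile (fraction of significant
lag bins per window) is resampled onto a common normalized-ITI axis (pairs
from different sessions have different window counts), standardized *per
window position across pairs* — per-profile z-scoring would erase the
"widespread low modulation" family's defining feature, its overall level —
then reduced by PCA (components to ≥90% variance) and grouped by k-means
(k = 3, 50 restarts, seeded).  Cluster labels are ordered by profile peak
time, making early/diffuse/late labels stable across input orderings.

## Decoding and hazard

Each unit's 40-bin rates are z-scored over its valid (trial, bin) samples;
the validity mask is shared across units (it depends only on trial ITIs).
The OLE regresses bin-center time on the population rate vector with
intercept via `numpy.linalg.lstsq` (minimum-norm on rank-deficient
designs, equal to the normal equations otherwise — no explicit ridge
constant).  25 train / 5 test acquisition trials, 100 repetitions; error
is the mean absolute error in seconds, with RMSE reported alongside.  The
bias curve (mean estimate per true bin) shows the floor/ceiling shrinkage
of any bounded least-squares readout: edge bins biased inward, central
bins nearly unbiased.  A 554-unit population with regional peak mixtures,
5–8 s widths and 2× gain decodes with MAE ≈ 2 s.

The hazard is the empirical CDF of the session's ITI durations (warped to
the maximum ITI for cross-session averaging).  Unit rates are computed in
1-s windows advancing 0.5 s, divided by the number of trials whose ITI
still covers each window, and z-scored.  The correlation with the hazard's
rising phase (first nonzero point up to the first crossing of 0.75 — the
cutoff avoids the few-trial tail) is evaluated on every *other* window:
adjacent half-overlapping windows share spikes, and testing on the full
grid inflated the null flag rate ~5-fold; on disjoint windows the null
rate is ~5%.  A unit is hazard-correlated when p < 0.05 with r > 0, and is
then subclassified by whether its rate peak precedes the minimum ITI
duration.

## Behavior

The CR is the trapezoidal area under the inhale-positive pressure in the
350 ms after CS onset, normalized by the mean habituation CR window area.
ITI respiration analyses use the last 30 s before the next CS (trials with
shorter ITIs excluded), 7-s windows with 2-s overlap.  The spectrum is a
Thomson multitaper estimate built on DPSS tapers with NW = 2 and 3 tapers:
over 7-s windows that gives a ±0.29 Hz half-bandwidth, the widest setting
that still resolves structure within the 0.2–2 Hz respiration band
(interpolated onto a 0.01 Hz grid).  For both power and spectrum, the
primary null check is the along-ITI window-position ANOVA with trials as
independent replicates — the single-session answer to "does breathing
anticipate the next CS?".  A trial-wise ANOVA using windows as replicates
is also reported but is anticonservative, because breathing is
autocorrelated within a trial; comparing learning trials properly requires
many sessions as replicates, which a single session cannot supply.
ANOVAs on exactly constant data report F = 0, p = 1 rather than NaN.

## Problem sizes

Simulation-based tests use 8–20 seeded replicates per property, 40–100
shuffles, populations of 15–500 units and 15–40 trials per session; the
calibration and decoding benchmarks use the full 500-unit and 554-unit
populations.  These sizes give Monte-Carlo error comfortably inside each
test's tolerance while keeping the whole suite under two minutes.

## Known limitations

* Poisson spiking only; no refractoriness, bursting or shared latent
  states, so detector sizes on real data may differ from the calibrated
  values.
* The stage analysis assumes equal-sized stages; sessions with other
  trial counts are split into equal thirds/halves.
* The across-ITI null's phase wrapping slightly distorts phases longer
  than the recipient ITI (a few percent of spikes at the default ITI
  spread).
* Decoding treats units as independent (pooled across sessions); noise
  correlations in simultaneously recorded populations would raise the
  true error.
* NWB or other neurophysiology containers are not read; an adapter to the
  CSV session format is the intended route.
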