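# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic data can and cannot establish.

## Wavelet transform

The mother wavelet is the complex Morlet
ψ(t) = (π·f<sub>b</sub>)^(−1/2) · exp(2πi·f<sub>c</sub>·t) · exp(−t²/f<sub>b</sub>)
with center frequency f<sub>c</sub> = 1 Hz.  The stated "envelope
bandwidth of 2 s" is mapped to the Gaussian bandwidth parameter
f<sub>b</sub> = 2 s² at scale 1, so the ±1 SD envelope window spans two
full carrier cycles — the narrowest envelope that keeps at least two
cycles, favouring temporal precision.  This mapping is a convention
choice (the toolbox parameter it paraphrases is not uniquely
recoverable); `WaveletSpec.bandwidth` exposes it, and no result in the
package depends on its exact value.

Scales are continuous reals computed exactly from the pseudo-frequency
relation f = f<sub>c</sub>/(a·Δt) for the six analysis frequencies
(5–30 Hz, step 5).  Power is |W(a,t)|², same time axis as the input.
The transform runs through PyWavelets' `cmor` implementation with FFT
convolution and `precision=16`: at the default precision the
interpolated integrated wavelet leaves a staircase ripple at large
scales that injects thousands of spurious micro-troughs per epoch at the
5 Hz scale; at precision 16 the trough counts match an analytic
direct-convolution reference.

Edges are zero-padded.  Each scale records a cone-of-influence
half-width of 4 envelope SDs (⌈4·a·√(f<sub>b</sub>/2)⌉ samples);
departures inside the cone are dropped by default, since boundary
troughs are padding artifacts.  Signals shorter than four times the
longest wavelet support are rejected with the minimum length named.

## Departure detection

A message departure is an interior local minimum of one channel × scale
power series whose topographic prominence is at least
`threshold_ratio` × (max − min) of that series (default 0.05).
Prominence is the standard formalization of a "local neighborhood
threshold": the candidate survives if, on each side, power rises by at
least the threshold before a deeper minimum is reached; at a series end
the rise toward the end counts.  The range is computed per
channel × scale × epoch series.  A flat run of equal minima yields one
event at the run's midpoint (rounded down).  A constant series yields an
empty train; NaNs are an error.  The implementation is
`scipy.signal.find_peaks` on the negated series, whose prominence and
plateau semantics match this definition exactly; the test suite proves
set equality against an independent O(n²) brute-force oracle.

Intervals are computed within epochs only — no interval spans an epoch
boundary — and epochs of the same subject × condition cell are pooled
after detection (detect-then-pool; concatenation before detection is
deliberately not offered).  τ is stored in digitization intervals with a
converter to ms.  Cells with fewer than two events in every epoch are
flagged empty, never imputed.

## Distribution fitting

The Gamma MLE profiles out the scale (θ = mean/k) and solves
log k − ψ(k) = log(mean) − mean(log τ) by Brent's method with a bracket
grown from the method-of-moments start (tolerance 1e-10 on k).  The fit
reports shape, scale, maximized log-likelihood, n, and CV = k^(−1/2).
Zero-variance samples raise a degenerate-sample error (the shape
diverges); fewer than 10 intervals (configurable) raise an
insufficient-sample error.  Weibull, exponential, lognormal and normal
candidates are fitted via scipy's MLE with location fixed at zero where
the support demands it.

Goodness of fit is Pearson's χ² on bins equiprobable under each fitted
distribution, n_bins = min(max(6, n/50), 50) by default, with degrees of
freedom n_bins − 1 − (parameters estimated).  Equiprobable binning keeps
the df adjustment honest and the ranking stable: on Gamma-simulated
data the Gamma fit outranks Weibull and normal across n_bins ∈
{10, 20, 30}.  Kolmogorov–Smirnov and Anderson–Darling are deliberately
absent: their critical values are wrong when parameters come from the
data.

## Erlang serial-server model

A server of k exponential stages with rate μ has total service time
distributed as Gamma(shape k, scale 1/μ): mean k/μ, variance k/μ²,
Laplace transform (μ/(μ+s))^k (Re s > −μ), density
μ^k x^(k−1) e^(−μx)/(k−1)!.  Its CV is k^(−1/2) — exactly the Gamma CV —
so CV < 1 for any k ≥ 2 (hypoexponential, serial stages), while a
two-branch parallel mixture of exponentials has CV > 1
(hyperexponential).  The simulator draws each service time as an
explicit sum of k exponentials from a mandatory seed; the parallel
contrast is provided only as a 2-branch mixture, not a general queueing
network.

## Mean-centered task PLS

The data matrix stacks subjects within condition blocks (identical
subject order per block) against channel × frequency elements.  The
condition-mean matrix is centered column-wise by the grand condition
mean and decomposed by SVD; latent variables are truncated to
n_conditions − 1 (the rank bound after centering) and ordered by
descending singular value.  Effect size is s_i²/Σs_j².

*Permutation test*: each replication independently reshuffles the
condition labels within every subject (sampling without replacement) and
recomputes the singular values; p is the plain proportion of permuted
values ≥ the observed one per LV (a (b+1)/(n+1) variant is switchable).
*Bootstrap*: subjects are resampled with replacement, the same draw
applied to every condition block to preserve pairing; each bootstrap
LV's sign is flipped to align with the original element saliences before
standard errors accumulate.  Per-LV sign flipping fully resolves the
indeterminacy with two conditions; with more conditions a Procrustes
rotation would be preferable, and this is a documented limitation.
Bootstrap ratio = original salience / bootstrap SE; an element is
reliable when |ratio| ≥ 2.57.  That constant is the standard-normal 99%
two-sided critical value at two-decimal precision (Φ⁻¹(0.995) = 2.5758);
the conventional printed cutoff truncates rather than rounds, and the
package follows the convention.  Zero bootstrap SEs yield ±∞ sentinels
with a warning.  One seed drives both procedures through separate
spawned substreams.

Defaults are 500 permutations and 500 bootstrap replications.

## Synthetic data

`SynthSpec` defaults mirror the emulated acquisition: 56 subjects, 128
channels at 500 Hz, two conditions in 8 alternating 30 s epochs (4 per
condition), of which preprocessing keeps the middle 20 s (5–25 s),
band-passes 0.5–55 Hz (zero-phase Butterworth, order 4), notches 60 Hz,
and subtracts each epoch's temporal mean.  Tests and the acceptance
script run deliberately smaller designs (e.g. one subject for the
threshold sweep, 4–8 channels, 12–20 subjects for PLS simulations, 20 s
epochs generated at analysis length), chosen to exercise every code path
with the statistics the checks require.

Each channel is 1/f^α Gaussian background (spectral synthesis,
α = 1 by default, unit SD before scaling by `noise_amplitude`) plus
band-limited oscillations (default one 10 Hz band, amplitude 1) whose
amplitude envelope is a sum of Gaussian bumps (SD half a cycle) at
Gamma-renewal onset times (shape `burst_shape` = 3, mean interval 4
cycles).  A per-subject log-normal multiplier (SD 0.1) on the renewal
shape models individual differences and cancels in the paired design.
The condition effect multiplies the renewal shape by
(1 + `effect_magnitude`) on designated channels only — changing burst
*regularity*, not band power, so detected condition differences cannot
be explained by a power-spectral-density shift.  Everything is
bit-reproducible from `seed` (per-subject spawned streams).

What the generator emulates: the paired design, realistic spectra,
burst-driven scalogram troughs whose regularity maps monotonically onto
the downstream fitted shape, and a localizable condition effect.  What
it does not emulate: volume conduction and channel correlations, ocular
and muscle artifacts (and hence artifact correction), non-stationarity
across epochs, and the alpha-peak topography of real recordings.
Passing tests therefore validate the machinery and its statistical
calibration, not claims about any particular real dataset.

## Threshold sensitivity: a negative finding

The detection threshold's claimed innocuousness (2–10% of range leaving
fitted parameters essentially unchanged) does **not** hold on these
surrogates, and the acceptance script quantifies this honestly
(`threshold_sweep_worst_change_pct`, typically ~100–200%).  The reason
is structural: for stochastic signals the prominence distribution of
scalogram troughs is continuous, so a population of marginal troughs
always sits between 2% and 10% of the range; and the fitted Gamma shape
amplifies small event-set differences, because adding or removing a few
events merges or splits intervals and reshapes the tail.  Range
normalization compounds this: |W|² is heavy-tailed, so "the range" is
set by rare extreme peaks.  Stability would require a gap in the
prominence distribution, which none of the stochastic envelope models we
examined (Gaussian-bump renewal, square bursts, long bursts/gaps,
common broadband envelopes, phase-diffusing carriers) produces.  Users
sweeping the threshold on real data should expect parameter shifts and
treat the threshold as part of the operational definition of a
departure, not a nuisance constant.

## Numerical and interface choices

- Trough ties: plateau midpoint, rounded down — deterministic and
  symmetric.
- Pseudo-frequency labels are rounded to 1e-6 Hz in table keys to avoid
  float-noise duplication.
- The pipeline drops channel × frequency elements with any missing cell
  from PLS (recorded in provenance) rather than imputing.
- Recordings serialize as raw float64 matrices plus a JSON sidecar;
  EDF is read via mne when available.  EDF writing is not offered.
- Scalograms export to HDF5, keyed by channel.
- `run_pipeline` writes `fits_shape.tsv`, `fits_scale.tsv`,
  `fits_full.tsv`, `pls_shape/`, `pls_scale/` and `provenance.json`
  (package versions, seed, config hash, cell counts) per run directory;
  reruns with the same config and seed are byte-identical.
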