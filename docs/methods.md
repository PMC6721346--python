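# Methods

## Signal model and feature pathway

The package targets two-class (left vs right hand) motor-imagery EEG from
the C3/C4 electrode pair sampled at 250 Hz. The physiological signature is
a lateralized change of mu (~7–13 Hz) and beta (~13–30 Hz) rhythm
amplitude during the imagery period (ERD/ERS). The feature pathway
converts each 2000-sample trial into per-window feature vectors:

band-pass (8–32 Hz) → dyadic DWT (db4, 4 levels) → reconstruct D4 and D3 →
EMD per sub-band → keep in-band IMFs → sliding-window ApEn → SVM.

The rationale for decomposing twice: EMD applied to a broadband signal
produces a first mode with too wide a frequency support; narrowing the
input with the wavelet pyramid first yields modes confined to the mu and
beta ranges, and the approximate entropy of those modes then reflects how
noise-like the rhythm is in each window. ERD lowers the rhythm-to-noise
ratio on one channel during imagery, which raises that channel's windowed
entropy — the asymmetry is the classifiable feature.

## Wavelet stage

An L-level Mallat decomposition splits (0, fs/2) into an approximation
band and L one-octave detail bands; at fs = 250 Hz, L = 4 the band edges
are 7.8125, 15.625, 31.25, 62.5, 125 Hz. The customary printed table
rounds the lowest edge to one decimal (7.8) and doubles it upward
(15.6, 31.2, 62.4, 124.8); `subband_edges(..., rounding="paper")`
reproduces that convention, everything else uses exact edges. The
transform uses symmetric (half-sample mirror) extension — fixed rather
than configurable so coefficient layouts are reproducible — and the db4
basis by default. Per-band time-domain signals are obtained by zeroing all
other coefficient arrays before the inverse transform, so the band signals
sum to the input exactly (linearity); full-pyramid reconstruction is exact
to float rounding.

## EMD stage

Sifting subtracts the mean of cubic-spline envelopes through the local
maxima and minima until the candidate is an intrinsic mode function.
Choices the textbook recipe leaves open:

* **Stop rule.** A sift pass ends the inner loop when the Cauchy criterion
  SD = Σ(c_prev − c_new)² / Σc_prev² < 0.2 holds or the candidate already
  satisfies the IMF conditions (extrema/zero-crossing counts within one,
  envelope mean within 5% of the signal range); hard cap 100 passes. The
  SD threshold 0.2 is the canonical choice. On broadband noise this halts
  while the envelope mean is still a noticeable fraction of the range, so
  noise-derived modes meet the IMF conditions only approximately; sifting
  until the conditions hold exactly (4–8 extra passes) was tried and
  rejected because it over-smooths the modes' amplitude structure and
  measurably degrades the downstream entropy contrast.
* **Edges.** The two nearest extrema are mirrored across each signal end
  before spline fitting (natural boundary conditions), the standard remedy
  for envelope collapse at the borders.
* **Plateaus** count as a single extremum at their midpoint; a zero
  crossing is a strict sign change, an exact zero sample counts once.
* Decomposition stops when the remainder has fewer than two interior
  extrema (it becomes the residual) or after `max_imfs` (default 10)
  modes. Input = Σ IMFs + residual holds to float precision by
  construction and is asserted to 1e-10.

One caveat worth knowing: on *clean* narrowband inputs EMD shows its
classic intermittency. The D4 reconstruction of a pure tone is a
near-sinusoid carrying a small wavelet ripple, and sifting can surface
that ripple (plus edge effects) as a low-amplitude first mode while the
tone itself lands in the second. On realistic noisy sub-band signals the
first mode carries the rhythm, and its mu-band power confinement is an
ensemble property — asserted in the tests as a mean over trials and
channels, and reported by the acceptance script the same way — not a
per-trial guarantee.

## Approximate entropy

ApEn(m, r) = φ^m(r) − φ^(m+1)(r) with φ^m the mean log fraction of
m-length templates within Chebyshev distance r. Conventions: self-matches
counted (so every count is positive and the logarithm defined), match test
d ≤ r, N − m + 1 templates at dimension m and N − m at m + 1. Defaults
m = 2, r = 0.25·SD. Because the two φ terms average over different
template counts, series in which only self-matches occur (a strict ramp
with r below the step) give a small negative value, ln((N−m)/(N−m+1)) at
the extreme; with realistic tolerances on noisy data ApEn is positive.

The fast path (`apen_fast`, and the compiled sliding kernel) derives the
(m+1)-dimension match counts by extending the m-dimension Chebyshev
distances one lag instead of re-embedding, and visits each symmetric pair
once; it agrees with the naive two-pass implementation to 1e-10 and with
an exhaustive brute-force enumeration (kept independent, in the tests and
the acceptance script).

Sliding mode: window w (1-based) covers [(w−1)·step, (w−1)·step + L);
the number of windows is (N − L)//step — the final full-length window
position is deliberately not emitted, matching the convention that a
2000-sample trial with L = 500, step 1 yields 1500 windows. r is resolved
from each window's own SD (per-window, not per-trial), which keeps the
statistic amplitude-invariant window by window; an absolute-r override is
available.

## Classification

Features are standardized per dimension (fit on training folds only)
inside an RBF-SVM pipeline. C and γ are grid-searched over powers of two
(default 2⁻⁵, 2⁻¹, 2³ each — a coarse log-grid in the LIBSVM tradition;
the cross-validation landscape of the windowed-entropy features is flat,
so a finer grid moves the selected point without changing the achieved
accuracy, and the grid ranges are configurable), scored by stratified
3-fold cross-validation whose folds are
assigned at the *trial* level: heavily overlapping windows of one trial
never appear on both sides of a fold or of the train/test split. Ties are
broken toward the smallest C, then the smallest γ.

A trial-level decision is the sign of the mean SVM decision value over the
trial's windows (soft vote). Hard majority voting was tried and rejected:
windows that do not overlap the imagery period sit near the decision
boundary, and counting their hard votes injects the classifier's bias on
ambiguous inputs into every trial decision. The report carries both the
trial-level accuracy (the headline figure, one decision per cued trial)
and the window-level accuracy.

The per-class channel extraction sometimes described for this feature
construction (take C4 for left-hand trials, C3 for right-hand) needs the
label at feature time and therefore cannot be used for prediction; the
implemented pathway stacks both channels symmetrically.

## Synthetic data

Each generated trial is, per channel, mu tone + beta tone + 1/f noise +
slow sinusoidal drift, with phases randomized per trial and channel.
Defaults: fs 250 Hz, 2000-sample trials, mu 10 Hz (amplitude 1.0), beta
22 Hz (amplitude 0.5), noise amplitude 0.5 (1/f power above 0.5 Hz, unit
variance before scaling), drift amplitude 0.5 at a random frequency in
0.3–4.5 Hz, imagery window spanning seconds 4–7 of the 8-s trial (samples
1000–1750), ERD depth 0.8, 40 trials per class. During the imagery window
the suppressed channel's rhythm amplitudes are scaled by 1 − erd_depth
with 50-sample raised-cosine ramps.

Which channel is suppressed is a convention flag. `laterality="paper"`
(default) makes the electrode contralateral to the imagined hand the more
active one (left-hand imagery suppresses C3); `laterality="classic"` is
the textbook contralateral-ERD account (left-hand imagery suppresses C4).
The two are mirror images and equally classifiable; the flag only fixes
which physical channel carries which class.

All randomness flows from one seed through spawned per-trial substreams,
so datasets are bit-reproducible and single trials can be regenerated
independently of generation order.

What the generator does *not* emulate: volume conduction and electrode
mixing, trial-to-trial variability of rhythm frequency and ERD latency,
EOG/EMG artifacts, non-stationary noise floors. Passing the end-to-end
recovery experiment therefore shows the pipeline recovers lateralized
amplitude modulation under realistic SNR — not that it attains any
particular accuracy on real competition recordings.

## Problem sizes and experiment design

The end-to-end experiments (tests and acceptance script) use 40 trials per
class, an 80/20 stratified trial-level split, and sliding-window step 10
(150 windows per trial) — step 1 changes the feature values' density, not
their information content, and the coarser step keeps the experiment
tractable on a single CPU. The strong-contrast condition (ERD depth 0.8)
is expected to reach ≥90% trial accuracy; the null condition (depth 0)
must sit at chance. With 16 held-out trials the null accuracy is measured
at a granularity of 1/16, so the chance-level check tolerates ±10
percentage points.

## Known limitations

* EMD has no uniqueness guarantee; mode mixing appears when tones are
  close in frequency (separation below ~a factor 2 is unreliable).
* ApEn is biased for short series (self-matches); values are comparable
  only at fixed m, r convention and window length.
* The wavelet band edges are nominal: db4 band-splitting filters leak a
  few percent of a tone's power into neighbouring sub-bands.
* The SVM grid is coarse by design; refining it buys little on the
  synthetic task but would matter for weaker contrasts.
* File I/O accepts only delimited text; acquisition-format parsing (GDF or
  EDF) is out of scope and must be done upstream.
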