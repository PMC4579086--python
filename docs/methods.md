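# Methods

This note documents the models, estimators and numerical choices behind
`gammaflow`, and what the synthetic-generator experiments do and do not
demonstrate about real recordings.

## Scientific setting

The package analyses multi-trial, multi-electrode recordings from a small
cortical grid (a 4x4 layout with 1-2.5 mm spacing is the reference
geometry): a band-limited field signal (LFP) and a nonnegative firing-rate
envelope (MUA) per electrode, with a naturalistic stimulus segmented into
piecewise-constant "scenes".  The central question is directional: does the
*phase* of the gamma-band (50-80 Hz) oscillation at one site exert a
Wiener-Granger causal influence on the *firing rate* at another site, and
is that influence organised in space as a travelling wave whose direction
the stimulus can steer?

## Estimators

**Binning.**  All information quantities are computed on discretised
responses.  Binning is equipopulated and rank-based (stable ranks; bin
occupancies differ by at most one), which makes every estimate invariant
under monotone transforms of the raw signal.  Defaults: 4 bins for sensory
information, 3 bins per variable for transfer entropy, keeping the
27-cell conditional joints well sampled at desk scale.  A constant series
admits no informative binning and is an error (sensory information guards
this case to 0 bits, flagged).

**Entropy / mutual information.**  Plug-in estimates in bits.  The
limited-sampling bias is removed by default with the Panzeri-Treves
residual term: for each conditional distribution the effective number of
occupied bins R is estimated by solving
`R_occ = R * (1 - (1 - 1/R)^N)` ("bayescount"), and the bias
`[sum_s (R_s - 1) - (R - 1)] / (2 N ln 2)` is subtracted.  Corrected
estimates can dip slightly below zero; that is expected and harmless
because downstream inference is Z-scored against a null.  Shuffle
subtraction is available as an alternative correction.

**Transfer entropy and LCI.**  `T(Y->X) = I(X_t ; Y_past | X_past)` with
dimension-1 embeddings of each past, a configurable lag (default 10 ms)
and a 2 ms evaluation step; embeddings never cross trial boundaries or
masked (filter-edge) samples.  The lagged conditional information (LCI)
swaps the conditioner for the sender's past rate, and the localised LCI
for the receiver's past phase; all three share one estimator core.

**Common-stimulus bootstrap null.**  Stimulus-locked structure can
masquerade as causation.  The null pairs the source series of trial m with
the target series of a different trial m' at identical movie time (a
random derangement of trials), preserving everything the stimulus imposes
and destroying within-trial interaction.  Estimates are reported as
`Z = (TE_obs - mean_null) / SD_null`; default 40 resamples.  On uncoupled
but commonly-stimulated synthetic pairs this null is calibrated
(|mean Z| << 0.5, ~2% beyond Z = 3 over 200 pairs).  Note that the Z
denominator is itself an estimate: with 40 resamples each Z carries ~11%
multiplicative noise, which matters only where a downstream rule is a
ratio of Z-scores (see classification below).

**Sensory information.**  Mutual information between scene identity and a
response read out once per scene: slow variables are smoothed over a
300 ms sliding window (circular mean for circular variables) and sampled
at scene centres; individual phases are fast and are instead point-sampled
on windows of one oscillation period.  Significance uses a bootstrap that
circularly shifts each trial's scene sequence by a random nonzero number
of scenes.  A within-trial scene *permutation* is not exchangeable for
slowly precessing circular responses (the trial-offset constellation makes
windows ordered), and was measurably miscalibrated; circular shifts
preserve that structure and calibrate (single-site phase Z within about
+-2 under the null).

## Phase, waves and blocks

* Band-passing is a forward-backward (zero-phase) 8th-order Butterworth
  IIR filter; "order" counts the overall band-pass order.  Phase and
  amplitude come from the Hilbert analytic signal; samples within one
  settling length (three cycles of the low band edge) of either end are
  masked, and zero-amplitude samples carry an undefined-phase flag.
* The phase shift of an ordered pair is `wrap(phi_send - phi_recv)`;
  positive means the sender leads.  Windowed circular means and PLV use a
  300 ms sliding window.  Rayleigh tests come from pingouin.
* Pair classification: per unordered pair the two directed TE magnitudes
  (clipped at zero) are compared after excluding the 20% of pairs with
  the lowest maximum TE; ratio >= 10 makes a pair strongly asymmetric,
  relative difference < 20% symmetric.  The asymmetry index is
  `|T_ab - T_ba| / max(T_ab, T_ba)`.  The magnitude these rules operate
  on is *null-mean-subtracted TE in bits*, not the bootstrap Z: the Z
  denominator is estimated from trial-level resamples and carries
  relative noise of order `1/sqrt(2 n_trials)` (~20% at 12 trials), which
  straddles the 20% symmetric boundary — planted-symmetric pairs whose TE
  magnitudes agree to a few percent can show Z-ratios off by 20-40%.
  Null-mean subtraction keeps the common-stimulus correction; Z remains
  the significance measure.  Group-level significance across pairs uses a
  one-sample t-test on Z-scores with Benjamini-Hochberg FDR at q = 0.05.
* Block segmentation: per-sample majority vote of the shift sign across
  trials (exact ties stay unlabeled and break runs); runs of at least
  300 ms become blocks.  Before block-conditioned TE, the sign with the
  larger total duration is randomly down-sampled (and its last kept block
  trimmed) so both conditions use the same amount of data within 10%.
* Wave speed: for each strongly asymmetric "reference" pair, candidate
  electrodes whose displacement toward the receiving site lies within 45
  degrees of the causal axis contribute (projected distance, mean shift)
  samples, the receiver sitting at the origin; if another strongly
  asymmetric receiver among the candidates attains the minimum shift, the
  origin is re-anchored there (the origin always marks the wave's final
  target).  Pooled samples are fit with a cubic smoothing spline
  (GCV-selected penalty; an interpolating natural cubic spline when only
  four distinct distances exist, since the GCV fit needs five), and
  `v = 2*pi*f / |slope at 0|` with f the band centre (65 Hz) by default.
  Slopes below 0.01 rad/mm are flagged as near-global synchrony (infinite
  speed).  Because an ideal planted wave produces shifts beyond +-pi at
  realistic spacings (1.13 rad/mm at 0.36 m/s and 65 Hz), the wrapped
  shifts are first congruence-corrected (+-2*pi) using a preliminary
  circular-regression slope bounded by the array's spatial aliasing limit
  (pi / electrode spacing); the spline then sees unwrapped values.  Real
  cortical profiles flatten with distance and do not wrap, so this
  correction is inert there.

## Receptive fields and movie features

Reverse correlation maps gamma power onto movie luminance: frames are
smoothed with a 6x6 mean window and down-sampled by 4, optionally
de-correlated by removing the largest spatiotemporal SVD components, both
series are read on a common 66 Hz grid with a 60 ms neural lag, and the
per-pixel temporal correlations are Z-scored across pixels per repeat and
averaged over repeats.  The RF is the smallest square around the map
argmax whose border falls below 75% of the peak.

Features within an RF: time contrast (RMS frame-to-frame luminance change,
normalised by the mean RF luminance; a stated stand-in, configurable, as
the exact pooling is an open choice); orientation activation
(gradient-magnitude-weighted mean of cos^2 between the local gradient
orientation and the preferred orientation — orientation meaning the
direction of luminance change mod 180 degrees); orientation tuning
(per-orientation gradient energy in 8 bins on [0, 180) correlated with
MUA over frames, similarity = covariance of curves); directed motion (the
positive part of the sending-RF optic-flow vector projected on the
sender->receiver RF axis; flow fields are consumed, never computed — a
rigid-translation toy generator exists for tests).  Feature-to-signal
correlations support send/recv/sum/diff combinations with a group-level
signed-rank test.

## The synthetic generator

The generator realises, with known ground truth, exactly the statistical
structure the analysis assumes; no biophysics is modelled.

* Wave field: `phi_e(t) = 2*pi*f0*t - k(t) . x_e + eta_e(t)` wrapped, with
  `|k| = 2*pi*f0 / v`, scene-wise constant direction, per-electrode phase
  jitter (smoothed over 20 ms so the carrier stays in band), and — when
  trial offsets are enabled — a per-trial uniform global offset plus a
  slow (500 ms, 1.5 rad) global within-trial wander shared by all
  electrodes.  The wander matters: a constant offset alone makes the
  across-trial phase constellation a single rigidly rotating pattern, and
  chance clustering of 20 offsets then fakes stimulus locking at single
  sites; ongoing gamma has finite phase memory and no such geometry.
* LFP: `A cos(phi)` plus white noise (default A = 1, noise SD 0.2).
* Rates: `rate_j(t) = softplus(b + sum_i g_ij(t) cos(phi_i(t - lag) -
  psi) + c s_j(t)) + a rate_j(t-1) + noise`, clipped at zero.  The linear
  AR self-history sits outside the softplus so the uncoupled fixed point
  is exactly `softplus(b)/(1 - a)`.  The stimulus drive s is scene-locked
  and shared across trials — deliberately, to exercise the bootstrap
  null.  Direction gating scales each edge's gain by
  `max(gate_floor, (k_hat . u_hat)^+)`.
* One seed per session, split into independent per-component streams, so
  changing one noise source never perturbs another; sessions are
  bit-reproducible from (config, seed).

Defaults: 4x4 grid, 2 mm spacing, fs = 1 kHz, f0 = 65 Hz, v = 0.36 m/s,
40 trials, 60 scenes of 300 ms, phase jitter 0.3 rad.

## Validation experiments and their problem sizes

`gammaflow.validation` packages the recovery experiments used by the test
suite and `scripts/acceptance.py`.  Sessions are desk-scale (2-16
electrodes, 10-20 trials, 10-30 scenes); counts are 200 null pairs, 50
sessions for direction/classification and shift-TE correlation, 50 + 20
for block gating, 30 for the sensory dissociation, 20 seeds for wave
speed, 20 runs for RF recovery.  Two experiment-specific choices deserve
emphasis:

* The *wave-speed* experiment evaluates TE and classification on the
  planted coupling graph (both directions per planted edge) rather than on
  all 240 ordered pairs.  An idealised plane wave makes every site's phase
  mutually deterministic, so unrestricted Wiener-Granger classification
  also nominates pairs whose axes are unrelated to the propagation
  direction ("phantom" causality: the phase anywhere predicts any driven
  rate).  Those pairs violate the alignment assumption behind the
  projected-distance procedure — an assumption that holds in real
  recordings, where spatial coherence decays with distance.  Restricting
  the candidate graph realises the stated assumption that reference causal
  pairs lie along the propagation direction.
* The *gating* experiment plants a with-wave : against-wave TE ratio of
  ~4 via a gate floor of 0.35; at the operating gains TE grows as roughly
  gain^1.4, which is what maps a gain ratio to the planted TE ratio.

What passing these experiments shows: the estimator chain recovers planted
direction, speed, gating and dissociation structure under the generator's
assumptions (plane-wave geometry, cosine phase-to-rate coupling, scene-
locked gating, stationary noise).  What it does not show: robustness to
non-stationarity, volume conduction, spike bleed-through, electrode drift,
or waves that attenuate, curve or interfere — none of which the generator
emulates.

## Known limitations

* Transfer entropy on deterministic, spatially coherent oscillations
  over-attributes causality to any informative phase (see above); on such
  data the classification output should be read as "informative
  direction", not a synaptic arrow.
* The PT bias term assumes roughly equally sampled conditioning strata;
  with fewer than ~10 samples per occupied joint cell estimates should be
  treated as low-confidence (the estimator flags this when a minimum cell
  count is requested).
* The smoothing-spline tangent at the origin is sensitive to the
  distance support; with fewer than four distinct projected distances no
  speed is reported.
* Movie features use stand-in pooling formulas where the exact published
  ones are not specified; they are isolated behind small functions and
  configurable.
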