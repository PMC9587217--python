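# Methods

`micromod` analyses micro-scale functional organization in multichannel
microelectrode LFP: it estimates a weighted directed functional network
per recording session, tracks module structure across sessions with
multilayer modularity, measures module geometry on the electrode
lattice, decomposes connectivity by frequency, and tests whether spiking
units inside a module carry shared stimulus information. A synthetic
generator with planted ground truth drives all validation.

## Preprocessing

Inputs are 1 kHz LFP matrices (channels × samples, mV) with lattice
coordinates. The cleaning chain runs in a fixed order:

1. **Electrode rejection.** Channels whose RMS amplitude or variance
   exceeds the across-channel mean + 3 SD are removed before
   referencing, so outliers never contaminate the common average.
2. **Common average reference** across retained channels.
3. **Local detrending** (window 0.5 s, step 0.25 s): a local linear fit
   evaluated at window centres, interpolated and subtracted. This
   attenuates <~2 Hz drift by >10 dB while passing 40 Hz within 5%.
   The window/step are package defaults (exposed in the config); any
   window ≥ 0.5 s with step ≤ window/2 behaves similarly.
4. **Line-noise regression.** The signal is FFT-resampled to 1020 Hz
   (an integer multiple of 60 Hz), a sine/cosine pair per harmonic
   below the original Nyquist is least-squares fitted per 30-s clip and
   subtracted, and the signal is resampled back. Regression avoids the
   phase distortion of notch filters, which matters because Granger
   estimates are phase-sensitive. FFT resampling makes the round trip
   lossless for band-limited signals.
5. **Artifact interpolation and block extraction.** Each session is cut
   into twenty 30-s clips; samples beyond 4 scaled MADs
   (scale 1.4826, Gaussian-consistent) are flagged, padded by ±5
   samples, and replaced by monotone piecewise-cubic (PCHIP)
   interpolation. From each clip the 5-s window with the fewest
   interpolated samples is kept (earliest start on ties, and selection
   ignores task timing). A clip with >50% interpolation is flagged
   unusable.

## Conditional Granger causality

For every ordered pair (source *j* → target *i*) the pairwise
conditional Granger causality is

  F_{j→i} = ln [ var(ε′_i) / var(ε_i) ],

where ε_i is the residual of the full VAR predicting channel *i* from
the past of **all** channels and ε′_i the residual of the reduced model
omitting the source's past (conditioning on everything else, which
suppresses common-input and volume-conduction artifacts). VAR models
are fitted by multi-realization least squares: per-block lagged moment
matrices are pooled and regressions never span block boundaries. The
model order is a config choice (AIC selection over 1–20 is available);
significance uses the large-sample null n·F ~ χ²(p) with Bonferroni
correction over all N(N−1) ordered pairs, non-significant entries set
exactly to zero and significant ones keeping their raw value.

**Two reduced-model conventions.** The network estimator re-regresses
the reduced model at the same order (nested in the full model, so
F ≥ 0 and the χ² null is exact). For the *spectral* decomposition this
convention is provably inadequate: the marginal of a VAR is ARMA, and a
same-order reduced VAR loses the minimum-phase consistency that the
frequency-integral identity requires (we measured 2–15% integral error
even with population-exact models). The spectral path therefore derives
each reduced model from the fitted full model's implied autocovariance
(companion-form Lyapunov equation, then Whittle's multivariate
Levinson–Durbin recursion at a depth where the autocovariance has
decayed below 1e-8, capped at 256 lags) — an exact spectral
factorization of the marginal spectrum. The matching time-domain
estimator is available as `conditional_gc_matrix(..., reduced="model")`;
the two estimators differ only by the truncation bias of the
re-regression route and agree closely on strong edges.

**Spectral decomposition.** With full-model transfer H(ω), innovation
covariance Σ, and reduced inverse transfer BR(ω), the transformed
transfer is Q(ω) = blkdiag(BR, I) H(ω); after rotating the innovations
so the target's innovation is uncorrelated with all others (Q̃ = Q L),
the conditional causal spectrum is

  f(ω) = ln [ Σᴿ_xx / ( |Q̃_xx(ω)|² Σ_xx ) ],

whose average over normalized frequency equals the model-implied
time-domain F — to ~1e-12 in our tests; tiny negative values (a known
artifact of the conditional measure) are clipped to zero and counted.
Band values average f over delta (2–4), theta (4–8), alpha (8–16), beta
(16–32) and broadband gamma (70–150 Hz); per-pair spectra may first be
normalized to unit area so band shares compare the *relative* frequency
content of strong and weak connections.

## Networks, surrogates, multilayer modularity

The thresholded GC matrix of each session is one layer of a temporal
network; session similarity is the Pearson correlation of vectorized
off-diagonal adjacencies (zeros included — sparsity is part of network
identity). Chance baselines are degree-matched surrogates: directed
double-edge swaps (a→b, c→d) ⇒ (a→d, c→b), rejecting self-loops and
multi-edges, 100 passes of |E| attempts per surrogate, weights riding
the out-going stub; in/out degree sequences are asserted equal to the
original on every surrogate.

Layers are stacked chronologically with uniform diagonal-ordinal
coupling ω between each electrode and itself in the next layer; by
default ω is the median nonzero intra-layer weight. Partition quality is

  Q_ml = (1/μ) Σ_ijst [ (A_ijs − γ P_ijs) δ_st + δ_ij ω_jst ] δ(c_is, c_jt),

with the directed null P_ijs = k_i^in(s) k_j^out(s)/m_s per layer, μ the
total intra- plus inter-layer weight, γ = 1 by default. Interlayer links
enter the coupling term only (never the null), each counted once in the
sum and in μ, which preserves the analytic bound Q_ml ≤ 1.

Maximization uses a generalized Louvain heuristic on node-layer
supernodes with three non-standard ingredients that we found necessary
to reach exhaustively-verified optima on small instances: node-level
repair moves between aggregation rounds, moves into a fresh empty
community (splits), and random selection among improving moves so
restarts explore the near-degenerate quality landscape. 500 restarts by
default (each with its own child RNG); the best partition is reported
with all restart qualities. An exhaustive enumerator (restricted-growth
strings with incremental quality, compiled) provides exact maxima up to
~12 supernodes.

Partition dynamics: **stationarity** is the co-classification Jaccard
between consecutive layers (pairs co-assigned in both / in either; a
Pearson variant on co-assignment indicators is available);
**normalized persistence** is the fraction of node transitions that keep
their label.

## Geometry

Module diameter is 2R_g, twice the RMS distance of member electrodes to
their centroid. Compactness is members / all electrodes inside the
module's convex hull; electrodes exactly on the hull count as inside
(lattice points are frequently collinear with hull edges, and excluding
them would deny rectangular modules the metric's stated maximum of 1);
degenerate hulls (1–2 members or collinear sets) are treated as
points/segments. Boundary analysis takes module members on the hull
that have at least one lattice 4-neighbour inside and one outside the
module, so within- and across-boundary comparisons are matched at
exactly one pitch.

## Decoding

Spike counts in 200-ms boxcars sliding by 20 ms are square-root
transformed and z-scored per unit with statistics from non-overlapping
200-ms bins tiled over the task baseline periods. The bin-start grid
runs from −0.2 to 1.12 s relative to image onset so that "every third
bin from 0.1 s" yields the 18 response-period bins used by the overall
classifier (predictors = units × 18; a per-bin mode uses single bins).

Per module (units on its electrodes, ≥2 required): 20-fold CV with
hold-out trials spread uniformly across the session (~5%); per fold, a
stratified quarter of the training trials is drawn as the early-stop
set (50 fresh draws), feature z-scoring is fitted on the remaining
trials only, and a multinomial softmax classifier is trained by
full-batch gradient descent until the early-stop loss rises. Weights
are mapped back to raw-feature space (folding in the z-scoring) and
averaged over draws, so fold classifiers can be applied to permuted or
substituted hold-out features. Significance: identical machinery with
training/early-stop labels shuffled, compared by a two-tailed paired
t-test across folds. **Shuffle-within** permutes hold-out unit
identities inside the module (100 iterations); **shuffle-across**
substitutes another module's units (subsample without replacement if
larger, resample with replacement if smaller). Boundary response
similarity correlates two units' binned response curves per trial
(bins ≥ 0 s) and averages over trials, keeping units that spiked in at
least half the correct trials.

## Synthetic generator

The generator emulates the study conditions: square lattices (8×8 at
0.4 mm pitch; a 10×10-minus-corners variant), ~20 five-second blocks per
session over a few sessions, contiguous modules on the order of 1.3 mm,
sparse spiking (baseline 1.5 sp/s) with module-shared category tuning
over four balanced categories.

*LFP.* A stable VAR whose directed couplings are damped-oscillator lag
kernels r^k cos(2πf₀k/fs): within-module couplings centred at 100 Hz
(bandwidth 60 Hz), across-module at 8 Hz (bandwidth 12 Hz), so
within-module causality is gamma-weighted and across-module causality
low-frequency-weighted by construction. Lattice neighbours are coupled
within modules at unit strength and across boundaries at 0.25 (a 4:1
ratio — comfortably above the recovery threshold; pipeline recovery
degrades as the ratio approaches ~1.5 at these sample sizes), plus a
sparse sprinkling of longer-range couplings. Fan-in is normalized and
the cross-coupling tensor uniformly shrunk to a companion spectral
radius of 0.9 (ratios preserved); unstable ground truths are rejected
with the radius in the error. Blocks are independent realizations with
discarded burn-in. Innovations are white (σ = 0.05 mV): the generator
emulates the statistical structure the analysis consumes, not
biophysics — no volume conduction, 1/f background, or non-stationarity,
so passing tests demonstrate correctness of the estimators, not
robustness to every property of real recordings. VAR order 8 and the
noise scale are documented defaults, not values fitted to data.

*Spikes.* Inhomogeneous Poisson units, one per electrode by default;
module *m* prefers category *m* mod 4 with peak gain 3 and a Gaussian
response kernel (latency 200 ms, width 150 ms); a tuning-correlation
parameter sets the probability a unit inherits its module's preference.
Trials come in sets of 60 flanked by 2-s baselines; all trials are
marked correct (the analysis uses correct trials only).

## Numerical choices and degenerate inputs

- GC values are clipped at 0; failed reduced fits yield NaN entries and
  a log message; a (near-)unstable fitted full model aborts the
  model-implied reduced derivation with an informative error.
- Whittle depth: autocovariance decay to 1e-8, clipped to [4p, 256].
- Louvain ties in Q are broken first-found; move threshold 1e-14.
- MAD = 0 (constant channels) disables artifact flagging for that
  channel; a window tie in block extraction takes the earliest start.
- Zero-variance features get unit scale in classifier z-scoring;
  classes are kept present in early-stop sets by stratified draws.
- Seeds: every stochastic routine takes an explicit seed; the pipeline
  expands one global seed through named SeedSequence paths so stages
  can be re-run in isolation and reproduce byte-identical outputs.

## Validation problem sizes

The test suite validates at reduced, documented sizes chosen to keep
the full suite fast while leaving each effect far from its decision
threshold: the spectral/time integral identity on a 16-channel order-4
VAR with twenty 5-s blocks (observed median relative error ~1e-12
against the matching estimator); analytic GC recovery at 10⁵ samples
against the Kolmogorov closed form; optimizer exactness on twenty
6-node/2-layer networks against exhaustive enumeration; planted-module
recovery on 6×6 lattices (2 sessions × 10 × 2.5-s blocks) over 20
seeds; null calibration with 200 independent-channel runs (GC
family-wise error) and 60 label-shuffle runs (decoding type-I); and the
functional contrasts (gamma share, shuffle-within vs across, boundary
sharpness) paired over 20 seeds each.

## Known limitations

- The parametric spectral GC inherits VAR model error; nonparametric
  (multitaper-factorization) and time-varying variants are out of scope.
- The conditional spectral measure can be pointwise negative in
  pathological systems; we clip and count, which slightly biases band
  integrals when clipping occurs.
- Consensus clustering across Louvain restarts is not implemented; the
  restart-quality distribution is returned for degeneracy inspection.
- The generator's modules are rectangular when the module count tiles
  the lattice; irregular planted shapes use the region-growing fallback
  and need not have compactness exactly 1.
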