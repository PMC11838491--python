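# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `synbmi`.

## Data model and conventions

All analysis operates on a `BinnedSession`: time-binned neural features
(`T × N`, spiking-band-power-like, nonnegative), EMG envelopes (`T × E`,
normalized to [0, 1] per channel per day), kinematics (`T × 4`: index and
middle-ring-small (MRS) positions and velocities), and a trial table
(target 1–9, context, artifact window). All matrices are **time-major**
(`T × channels`); channel-major textbook equations are transposed
accordingly, and the PCA/dPCA oracle-equivalence tests pin this
convention down.

Bins are 20 ms wide and start at t = 0; trial boundaries are snapped to
bin edges. The reward-pump ("juicer") artifact window at each trial
start (100 ms = 5 bins by default) is **masked, never interpolated**:
masked bins are excluded from every training and evaluation index set,
and lagged designs drop any row whose history touches a masked bin.
Masking (rather than deleting) preserves the time-lag structure that
history decoders rely on.

## Signal processing

- **EMG envelope chain**: 800 Hz anti-alias low-pass → downsample to
  2000 Hz (skipped if already there) → 100–500 Hz band-pass → full-wave
  rectification → 6 Hz low-pass → clip at 0.
- **Spiking-band power (SBP)**: 300–1000 Hz band-pass, per-sample
  magnitude, mean per 20 ms bin (trailing partial bin dropped). The
  per-bin statistic is mean |x| by default — the common low-bandwidth SBP
  convention — with mean x² as an option, since either reading is
  defensible; the homogeneity property (scaling the signal by c scales
  SBP by c) holds for the default.
- **Threshold crossings**: threshold = −4.5 × RMS of a calibration
  segment (first 10 s by default, configurable) per channel; downward
  crossings, merged within a 1 ms refractory window; a positive
  multiplier detects upward crossings symmetrically. Channels are
  "active" at ≥ 1 crossing/s on average.
- All filters are 4th-order Butterworth applied forward–backward
  (zero phase). This is offline analysis; no causal constraint applies,
  and zero-phase filtering avoids lag between envelopes and kinematics.

## Decompositions

- **PCA**: SVD of the centered data; decoder rows orthonormal; the VAF
  curve equals cumulative eigenvalue fractions (tested against a dense
  eigendecomposition at 1e-8).
- **NMF**: multiplicative updates on ‖X − HW‖², loss trace recorded and
  non-increasing by construction. EMG is *not* centered for NMF
  (nonnegativity forbids it) but is centered for PCA/dPCA; the VAF
  denominator is the centered total variance for every method so curves
  are comparable (a raw denominator is exposed as an option).
  *Initialization*: the default is a deterministic SVD-based nonnegative
  start (NNDSVD-a). Random multi-start frequently stalls on near-flat
  plateaus where rotated factors fit marginally better but correspond to
  a different, non-sparse factorization; the SVD start lands in the
  structured basin and is the standard choice in mature NMF
  implementations. Seeded random restarts remain available
  (`n_restarts`, `init="random"`); when restarts are used, final losses
  within 1e-6 of relative VAF are treated as ties and resolved toward
  the earlier (deterministic) start.
- **dPCA**: trials are cropped to a fixed aligned window (default 40
  bins = 800 ms from trial start; truncated to the shortest trial with a
  warning), the grand mean removed, and the data split into a
  condition-independent time marginalization, a target marginalization
  (per-target per-bin mean minus grand and time terms, so it includes the
  target × time interaction), and a residual; the decomposition identity
  is exact and tested. Per parameter φ the unconstrained ridge solution
  `A_φ = X_φᵀ X (XᵀX + μI)⁻¹` is rank-truncated through the SVD of its
  prediction, giving encoder `F_φ` and decoder `D_φ`. μ defaults to
  `1e-6 · trace(XᵀX)/N` for numerical stability; μ = 0 with a singular
  Gram matrix raises an error directing the user to μ > 0. Stored
  activations use the **target** decoder. The dPCA VAF curve is computed
  against the full data and asymptotes below 1 by construction (the fit
  only sees trial-averaged structure) — asserted, not "fixed". dPCA is
  applied to brain data only.
- **NMF transform** of new data solves nonnegative least squares per time
  bin against the fixed weights; PCA/dPCA transforms are linear maps
  after mean subtraction.

## Decoding

Ridge regression with history: row t of the design holds
`[1, X_t, …, X_{t−lags+1}]` with 10 lags (200 ms) by default; the
intercept is unpenalized and the solution is the closed-form penalized
normal equation. λ is selected by **blocked 5-fold cross-validation on
the training split** over the grid 1e-4…1e4 (9 log-spaced points), scored
by validation **mean squared error** with ties to the smallest λ. MSE
rather than CC is deliberate: MSE is invariant under the orthonormal
output rotations used by the muscle-synergy-output models, so a model
predicting full-rank PCA activations selects exactly the λ of the
corresponding raw-output model and the baseline-equivalence identity
holds to numerical precision. Evaluation is the per-output Pearson CC;
a constant prediction or truth scores 0 with a warning rather than NaN.

Target classification uses one-vs-one linear max-margin discriminants
(hinge loss, Pegasos-style subgradient with iterate averaging, seeded) on
per-trial mean features, with macro-averaged accuracy; classes absent
from a test set are skipped with a warning. Any linear max-margin
surrogate preserves the analysis; this one avoids an external solver and
is fully deterministic given its seed.

All experiments split **chronologically by trial, 80/20**; the
generalization experiment's off-context decoders train on 100% of the
normal context and are tested on each perturbed context's final 20%, the
same bins their on-context counterparts are tested on (asserted). DR
fits, λ selection, and normalization statistics use training bins only;
each experiment returns index-set audits (train/test disjoint, masked
bins excluded) that the suite and the reports check.

## Correlation statistics

Pearson correlations between all channel/synergy pairs, organized into
four groups (brain↔muscle, brain↔muscle-synergy, brain-synergy↔muscle,
brain-synergy↔muscle-synergy). Significance thresholds come from
permutation nulls: 1000 permutations per pair, per-pair threshold at the
empirical `1 − α/m` quantile of |CC| with α = 0.05 and Bonferroni m = the
batch size (logged). The default scheme fully permutes one series' time
order — which destroys autocorrelation and is anticonservative for
smooth signals — matching the method's literal description; a
circular-shift option preserves autocorrelation for stricter inference.
Requesting a quantile finer than 1/n_perm raises an error instead of
silently extrapolating. Group-level comparison uses an
independent-groups Fisher r-to-z test on the mean transformed
correlations with variance 1/(T−3) per element; this is a documented
simplification of a full dependent-correlations battery, named in the
output metadata.

## Compression statistic

`corr(x) = k1 + k2·(1 + e^(−k3·x))` is fit to the (synergy count,
held-out CC) curve by multi-start (5 seeded starts) bounded L-BFGS-B on
squared error with k3 > 0. One published form of this curve reuses k2 in
the exponent while naming three fitted constants; this package places k3
in the exponent, which is the only reading under which three constants
are identifiable. `x95` — the smallest x with corr(x) ≥ 0.95·(k1+k2) —
is obtained by closed-form inversion when k2 < 0 (else a dense grid scan
over [1, total_dims]; ties to the smallest x); a flat curve yields
x95 = 1 by convention, and a non-saturating fit is flagged with the
ratio marked unsuccessful. The 95%-of-asymptote rule is primary; a
95%-of-full-data-baseline reference is available from the stored curves.

## Synthetic sessions

The generator emulates the statistical structure of a 2-degree-of-freedom
center-out finger task: 96 neural channels, 7 EMG channels (4 flexor-type,
3 extensor-type), 20 ms bins, 500 ms move + 750 ms hold per trial, center
target every second trial, 100 ms artifact window per trial, and neural
activity leading kinematics by 2 bins (40 ms) so lagged designs are
meaningfully exercised.

L latent activations (default 3) drive everything:

- **EMG** = clip≥0(emg_mixing · latents + noise), then scaled to [0, 1]
  per channel (the daily-peak convention). emg_mixing is nonnegative:
  flexor channels load latent 0, extensors latent 1, and latent 2 is a
  broad supportive synergy with one dominant mid channel.
- **Neural** = softplus(neural_mixing · latents_led + noise); softplus
  keeps the features nonnegative (like a power feature) while preserving
  an approximately linear latent readout.
- **Velocities** = velocity_readout · latents; positions are their
  cumulative integral.

Latent temporal profiles are raised-cosine bumps whose centers tile the
move+hold epoch and whose widths leave each latent active *alone* in part
of every trial; together with the per-latent anchor channels this is a
separability condition that makes the nonnegative factorization of the
EMG essentially unique, so NMF parameter recovery is a well-posed test
(with fully overlapping profiles, exact-fit NMF factors are
rotation-ambiguous and recovery is undefined, not merely hard). Target
amplitudes scale latents 0/1 with total flexion/extension demand, making
all nine target classes linearly separable; out-targets are presented in
shuffled blocks covering all eight peripheral classes, so every class
appears in any session of ≥ 16 trials.

Context perturbations share the base mixing across the four contexts:
the spring context multiplies flexor-type EMG rows by (1 + context_gain);
the wrist context adds a fixed random offset (scaled by context_offset)
to both mixing matrices; the combined context composes both. Target
sequences are identical across contexts; noise streams differ. With both
magnitudes at 0 the four sessions are statistically identical up to the
noise seed — the null-perturbation control used by the generalization
tests.

One root seed feeds named, independently spawned random streams
(structure, targets, neural noise, EMG noise, raw EMG), so regeneration
is bitwise reproducible and single components can be varied without
disturbing others.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic noise spectra and inter-channel noise
correlations (noise is white and isotropic; real SBP noise is neither),
nonstationarity and electrode drift within a session, trial-to-trial
latent variability beyond additive noise (latents repeat exactly per
target), biomechanical coupling between fingers, and spike-level
structure (no 30 kHz point-process simulation; raw-EMG fixtures use
band-limited carriers at ≥ 2 kHz). Decoding CCs on synthetic sessions
are therefore optimistic; the pipeline's comparative statements (synergy
vs baseline, on- vs off-context) are the meaningful outputs.

## Problem sizes

The default study conditions are 96 neural channels, 7 EMG channels,
3 latents, 20 ms bins, 750 ms holds, 500-trial days. The acceptance
script uses a full 500-trial, 96-channel session for signal quality,
VAF counts, and correlation groups; the experiment sweeps run on
32-channel, 80–100-trial sessions, and the null-perturbation control on
16 channels — sizes chosen so a complete run is comfortable on a single
CPU while every qualitative contrast (synergy counts, saturation,
baseline equivalence, context gaps, null calibration) is preserved. The
test suite uses smaller sessions still (10–16 channels, 40–60 trials)
for the same reason.

## Known limitations

- dPCA trial alignment crops to a fixed window from trial start and
  averages per target without re-balancing unequal trial counts; the
  aligned window includes the masked artifact bins (the marginalization
  is a fit, not an evaluation), which slightly biases the time
  marginalization toward trial-onset structure.
- The NMF VAF curve requires a refit per component count (solutions are
  not nested), so `components_for_vaf` with NMF is quadratic in the
  count; PCA is used for the 90% rule by default, as is conventional.
- The permutation default destroys autocorrelation; for strongly
  autocorrelated signals the circular-shift scheme is the statistically
  honest choice and thresholds will be noticeably higher.
- The Fisher-z group comparison ignores the dependence between
  correlations sharing a channel; its p-values are approximate.
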