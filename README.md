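# synbmi

Brain/muscle **synergy** analysis for intracortical brain–machine-interface
(iBMI) recordings: extract low-dimensional synergies from spiking-band
power and EMG with PCA, NMF, and demixed PCA; decode finger kinematics and
muscle activity with ridge regression with history; quantify the
correlation structure between brain, muscles, and their synergies with
permutation statistics; and run three decoder experiments — **compression**
(how few synergies preserve decoding), **denoising** (does discarding
low-variance dimensions ever *help* decoding), and **generalization**
(do synergy-space decoders transfer across task contexts).

The package is aimed at motor-neuroscience and neural-engineering work on
multi-degree-of-freedom finger BMIs. Real intracortical/EMG sessions of
this kind are rarely shareable, so `synbmi` ships a first-class synthetic
session generator with known ground truth (latent synergy activations,
mixing matrices, context perturbations) that makes every stage of the
pipeline testable end to end.

## The models

**Synergy extraction.** A session's feature matrix `X` (time × channels,
e.g. 20 ms-binned spiking-band power of 96 channels, or 7 EMG envelopes)
is factored into `M ≤ N` synergies:

- **PCA** — `argmin_D ‖X − DᵀDX‖²` over orthonormal decoders `D`
  (channel-major notation); weights = principal axes, activations =
  scores, solved by SVD.
- **NMF** — `argmin_{W≥0, H≥0} ‖X − HW‖²` by multiplicative updates
  (monotone non-increasing loss), deterministic SVD-based initialization.
- **dPCA** — per task parameter φ ∈ {target, time},
  `argmin_{F,D} Σ_φ ‖X_φ − F_φ D_φ X‖²` with `X_φ` the trial-aligned
  marginalization; a reduced-rank ridge regression giving separate
  encoder/decoder axes per parameter (applied to brain data only).

Synergy counts are chosen by the **90% VAF** rule,
`VAF = 1 − ‖X − X̂‖²_F / ‖X − mean‖²_F`.

**Decoding.** Ridge regression on the current and previous 10 bins
(200 ms) of features, intercept unpenalized, λ by blocked 5-fold
cross-validation; performance is the held-out Pearson correlation (CC)
on a chronological 80/20 trial split. Target classification over the
9 task targets (flex/rest/extend × index/MRS fingers) uses one-vs-one
linear max-margin discriminants; accuracy is macro-averaged.

**Compression statistic.** The CC-vs-synergy-count curve is fit with
`corr(x) = k1 + k2·(1 + e^(−k3·x))`; `x95` is the smallest x reaching
95% of the asymptote `k1 + k2`, and the compression ratio is
`total_dims / x95` (e.g. `3.00:1`).

## Worked example

```python
from synbmi import decoding, dimred, experiments
from synbmi.signals import blank_artifact_windows
from synbmi.synth import SynthConfig, generate_session

cfg = SynthConfig(n_neural_channels=32, n_trials=100, seed=42)
session, truth = generate_session(cfg)
session = blank_artifact_windows(session)     # mask reward-pump artifacts

n_syn = dimred.components_for_vaf(session.emg, "pca", threshold=0.90)
print(f"muscle synergies for 90% VAF: {n_syn} of {session.n_emg_channels}")

nmf = dimred.fit_nmf(session.emg, n_syn, seed=0, compute_curve=False)
print(f"NMF reconstruction VAF: "
      f"{dimred.vaf(session.emg, nmf.activations @ nmf.weights):.3f}")

cc, dec = decoding.decode_session(session, "brain", "velocity")
print(f"held-out velocity CC (index, MRS): {cc[0]:.3f}, {cc[1]:.3f}  "
      f"(lambda = {dec.lam:g})")

comp = experiments.run_compression(
    session, methods={"brain": ("pca",), "muscle": ()},
    component_grid={"brain": [1, 2, 3, 4, 6, 8, 16, 32], "muscle": [7]},
    seed=42)
fit = comp.metadata["fits"][("brain", "pca", "velocity")]
print(f"brain->velocity saturation: x95 = {fit.x95:.2f}, "
      f"compression {fit.ratio_label}")
```

prints

```
muscle synergies for 90% VAF: 3 of 7
NMF reconstruction VAF: 0.950
held-out velocity CC (index, MRS): 0.999, 0.999  (lambda = 10)
brain->velocity saturation: x95 = 1.26, compression 25.45:1
```

Three of seven muscle synergies explain 90% of the EMG variance (the
generator drives EMG from three latents); neural features decode finger
velocity almost perfectly at this noise level; and the decoding curve
saturates after roughly one synergy, so the 32 neural channels compress
about 25-fold with no loss for this easy synthetic session.

## Command line

```bash
synbmi simulate --seed 7 --out session.h5            # one session
synbmi simulate --seed 7 --out suite/ --contexts     # 4 task contexts
synbmi decode          --session session.h5 --out dec/
synbmi run-compression --session session.h5 --out comp/
synbmi run-denoising   --session session.h5 --out den/
synbmi run-generalization --session suite/ --out gen/
synbmi report --results comp --results den --results gen --out report/
```

Every command takes an optional `--config cfg.yaml|cfg.toml` and writes a
`provenance.json` sufficient to rerun it identically.

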