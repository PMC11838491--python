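"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure of an intracortical
brain-machine-interface recording during a 2-degree-of-freedom center-out
finger task: a small number of latent synergy activations drive (i) EMG
envelopes through a nonnegative mixing matrix, (ii) neural spiking-band
power through a linear mixing followed by a softplus, and (iii) finger
velocities through a linear readout (positions are their integral).
Targets combine {flex, rest, extend} for the index and middle-ring-small
finger groups (9 classes); the center class appears every second trial,
each trial ends with a hold epoch, and the first bins of every trial are
flagged as the reward-pump artifact window.

Everything is deterministic given the root seed: per-component random
streams are spawned from it, so regenerating a session with the same
configuration is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import (CENTER_TARGET, CONTEXTS, N_TARGETS, BinnedSession,
                      TrialTable, target_class)

#: EMG channel labels for the default 7-channel montage: four flexor-type
#: channels followed by three extensor-type channels.
EMG_LABELS = ("FCR", "FDPd", "FDPp", "FDP", "ECRB", "EIP", "EDC")
FLEXOR_CHANNELS = (0, 1, 2, 3)
EXTENSOR_CHANNELS = (4, 5, 6)

#: Bins flagged as the reward-pump artifact at each trial start
#: (100 ms at the default 20 ms bin width).
ARTIFACT_BINS = 5


@dataclass
class SynthConfig:
    """Parameters of the synthetic session generator.

    Defaults mirror the study conditions: 96 neural channels, 7 EMG
    channels, 20 ms bins, a 750 ms hold, and neural activity leading the
    kinematics by 2 bins (40 ms).
    """

    n_neural_channels: int = 96
    n_emg_channels: int = 7
    n_latents: int = 3
    n_trials: int = 100
    bin_width: float = 0.020
    move_time: float = 0.500
    hold_time: float = 0.750
    neural_noise_sd: float = 0.10
    emg_noise_sd: float = 0.05
    neural_lead: int = 2
    context_gain: float = 0.3
    context_offset: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_latents > min(self.n_neural_channels, self.n_emg_channels):
            raise ValueError(
                "n_latents must not exceed min(n_neural_channels, n_emg_channels)"
            )
        if self.neural_noise_sd < 0 or self.emg_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    @property
    def bins_per_trial(self) -> int:
        move = int(round(self.move_time / self.bin_width))
        hold = int(round(self.hold_time / self.bin_width))
        return move + hold


@dataclass
class GroundTruth:
    """Latents and mixing matrices a session was generated from."""

    latent_activations: np.ndarray      # T x L
    emg_mixing: np.ndarray              # E x L, nonnegative
    neural_mixing: np.ndarray           # N x L
    velocity_readout: np.ndarray        # 2 x L
    target_amplitudes: np.ndarray       # 9 x L
    context: str = "normal"
    context_perturbations: dict = field(default_factory=dict)


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Independent, named random streams derived from one root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


_STREAM_NAMES = ("structure", "targets", "neural_noise", "emg_noise", "raw_emg")


def _target_amplitudes(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """9 x L nonnegative amplitude matrix with flexor/extensor structure.

    Latent 0 scales with total flexion, latent 1 with total extension, and
    any further latents carry target-specific jitter so all nine classes
    stay linearly separable.
    """
    amps = np.zeros((N_TARGETS, cfg.n_latents))
    for idx_state in (-1, 0, 1):
        for mrs_state in (-1, 0, 1):
            k = target_class(idx_state, mrs_state) - 1
            flex = 0.6 * (idx_state == -1) + 0.4 * (mrs_state == -1)
            ext = 0.6 * (idx_state == 1) + 0.4 * (mrs_state == 1)
            amps[k, 0] = 0.2 + 0.8 * flex
            amps[k, 1] = 0.2 + 0.8 * ext
            if cfg.n_latents > 2:
                amps[k, 2] = 0.5 + 0.3 * (flex + ext) / 2.0
    if cfg.n_latents > 3:
        amps[:, 3:] = rng.uniform(0.1, 0.6, size=(N_TARGETS, cfg.n_latents - 3))
    # small fixed jitter keeps amplitude rows distinct even in degenerate L
    amps += rng.uniform(0.0, 0.05, size=amps.shape)
    return amps


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    out = np.zeros_like(t)
    inside = np.abs(t - center) < width
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * (t[inside] - center) / width))
    return out


def _latent_profiles(cfg: SynthConfig) -> np.ndarray:
    """bins_per_trial x L unit-amplitude raised-cosine bumps.

    Bump centers tile the move+hold epochs and widths are narrow enough
    that each latent has time bins where it is active alone — the
    separability that makes a nonnegative factorization of the resulting
    EMG essentially unique (up to permutation and scale).
    """
    nb = cfg.bins_per_trial
    L = cfg.n_latents
    t = np.linspace(0.0, 1.0, nb)
    centers = np.linspace(0.2, 0.8, L) if L > 1 else np.array([0.5])
    width = max(0.18, 0.55 / L)
    return np.stack([_raised_cosine(t, c, width) for c in centers], axis=1)


def _target_sequence(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Center-out sequence: every second trial is the center class.

    Out targets are drawn in shuffled blocks covering all eight
    peripheral classes, so every class appears at a balanced rate.
    """
    targets = np.empty(cfg.n_trials, dtype=np.int64)
    out_classes = np.array([k for k in range(1, N_TARGETS + 1)
                            if k != CENTER_TARGET])
    n_out = (cfg.n_trials + 1) // 2
    blocks = [rng.permutation(out_classes)
              for _ in range(-(-n_out // len(out_classes)))]
    seq = np.concatenate(blocks)[:n_out]
    targets[0::2] = seq
    targets[1::2] = CENTER_TARGET
    return targets


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _make_mixing(cfg: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (emg_mixing, neural_mixing, velocity_readout)."""
    E, N, L = cfg.n_emg_channels, cfg.n_neural_channels, cfg.n_latents
    emg_mixing = 0.02 * rng.uniform(0.0, 1.0, size=(E, L))
    # flexor channels load on latent 0, extensor channels on latent 1;
    # latent 2 is a broad supportive synergy anchored on one mid channel
    # (each latent dominating some channel keeps the nonnegative
    # factorization identifiable)
    anchor = min(3, E - 1)
    for ch in FLEXOR_CHANNELS:
        if ch < E and ch != anchor:
            emg_mixing[ch, 0] += rng.uniform(0.6, 1.0)
    for ch in EXTENSOR_CHANNELS:
        if ch < E and L > 1:
            emg_mixing[ch, 1] += rng.uniform(0.6, 1.0)
    if L > 2:
        emg_mixing[:, 2] += rng.uniform(0.15, 0.35, size=E)
        emg_mixing[anchor, 2] += rng.uniform(0.7, 1.0)
    else:
        emg_mixing[anchor, 0] += rng.uniform(0.6, 1.0)
    neural_mixing = rng.normal(0.0, 1.0, size=(N, L))
    velocity_readout = rng.normal(0.0, 1.0, size=(2, L))
    return emg_mixing, neural_mixing, velocity_readout


def _assemble_latents(cfg: SynthConfig, targets: np.ndarray,
                      amps: np.ndarray) -> np.ndarray:
    profiles = _latent_profiles(cfg)          # nb x L
    nb = cfg.bins_per_trial
    T = nb * cfg.n_trials
    latents = np.empty((T, cfg.n_latents))
    for i, k in enumerate(targets):
        latents[i * nb:(i + 1) * nb] = profiles * amps[k - 1]
    return latents


def _shift_lead(latents: np.ndarray, lead: int) -> np.ndarray:
    """Latents as seen by the neural features, which lead the kinematics."""
    if lead == 0:
        return latents
    shifted = np.empty_like(latents)
    shifted[:-lead] = latents[lead:]
    shifted[-lead:] = latents[-1]
    return shifted


def _build_session(cfg: SynthConfig, targets: np.ndarray, amps: np.ndarray,
                   emg_mixing: np.ndarray, neural_mixing: np.ndarray,
                   velocity_readout: np.ndarray,
                   rng_neural: np.random.Generator,
                   rng_emg: np.random.Generator,
                   context: str, day_id: str,
                   perturbations: dict) -> tuple[BinnedSession, GroundTruth]:
    nb = cfg.bins_per_trial
    latents = _assemble_latents(cfg, targets, amps)
    T = latents.shape[0]

    emg = latents @ emg_mixing.T
    emg += rng_emg.normal(0.0, cfg.emg_noise_sd, size=emg.shape)
    emg = np.clip(emg, 0.0, None)
    peaks = emg.max(axis=0)
    peaks[peaks == 0] = 1.0
    emg = emg / peaks

    neural = _shift_lead(latents, cfg.neural_lead) @ neural_mixing.T
    neural += rng_neural.normal(0.0, cfg.neural_noise_sd, size=neural.shape)
    neural = _softplus(neural)

    vel = latents @ velocity_readout.T
    pos = np.cumsum(vel, axis=0) * cfg.bin_width
    kinematics = np.column_stack([pos, vel])

    starts = np.arange(cfg.n_trials) * nb
    ends = starts + nb
    trials = TrialTable(
        start_bin=starts, end_bin=ends, target=targets,
        context=np.array([context] * cfg.n_trials, dtype=object),
        artifact_start=starts, artifact_end=starts + ARTIFACT_BINS,
    )
    session = BinnedSession(
        neural=neural, emg=emg, kinematics=kinematics, trials=trials,
        bin_width=cfg.bin_width, day_id=day_id,
        metadata={"seed": cfg.seed, "context": context, "generator": "synbmi.synth"},
    )
    truth = GroundTruth(
        latent_activations=latents, emg_mixing=emg_mixing,
        neural_mixing=neural_mixing, velocity_readout=velocity_readout,
        target_amplitudes=amps, context=context,
        context_perturbations=perturbations,
    )
    return session, truth


def generate_session(config: SynthConfig, day_id: str = "day0") -> tuple[BinnedSession, GroundTruth]:
    """Generate one normal-context session with its ground truth."""
    streams = _streams(config.seed, _STREAM_NAMES)
    emg_mix, neural_mix, vel_readout = _make_mixing(config, streams["structure"])
    amps = _target_amplitudes(config, streams["structure"])
    targets = _target_sequence(config, streams["targets"])
    return _build_session(
        config, targets, amps, emg_mix, neural_mix, vel_readout,
        streams["neural_noise"], streams["emg_noise"], "normal", day_id, {},
    )


def _context_mixing(cfg: SynthConfig, context: str,
                    emg_mixing: np.ndarray, neural_mixing: np.ndarray,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, dict]:
    """Perturb the base mixing matrices for a task context.

    The spring resisting flexion raises the loading of flexor-type EMG
    channels by (1 + context_gain); the wrist flexion adds a fixed random
    offset (scaled by context_offset) to both mixing matrices, emulating a
    postural remapping.  The combined context composes both.
    """
    emg_pert = rng.normal(0.0, 1.0, size=emg_mixing.shape)
    neural_pert = rng.normal(0.0, 1.0, size=neural_mixing.shape)
    e, n = emg_mixing.copy(), neural_mixing.copy()
    applied: dict = {"context": context}
    if context in ("spring", "spring_wrist"):
        flex = [ch for ch in FLEXOR_CHANNELS if ch < e.shape[0]]
        e[flex] *= (1.0 + cfg.context_gain)
        applied["spring_gain"] = cfg.context_gain
    if context in ("wrist", "spring_wrist"):
        e = np.clip(e + cfg.context_offset * 0.1 * np.abs(emg_pert), 0.0, None)
        n = n + cfg.context_offset * neural_pert
        applied["wrist_offset"] = cfg.context_offset
    return e, n, applied


def generate_context_suite(config: SynthConfig) -> list[tuple[BinnedSession, GroundTruth]]:
    """Four sessions (normal, spring, wrist, spring_wrist) sharing base mixing.

    Target sequences are identical across contexts; noise streams differ.
    With ``context_gain = context_offset = 0`` the four sessions are
    statistically identical up to the noise seed.
    """
    streams = _streams(config.seed, _STREAM_NAMES)
    emg_mix, neural_mix, vel_readout = _make_mixing(config, streams["structure"])
    amps = _target_amplitudes(config, streams["structure"])
    targets = _target_sequence(config, streams["targets"])

    suite = []
    for ci, context in enumerate(CONTEXTS):
        # fixed perturbation directions shared across contexts
        pert_rng_ctx = np.random.default_rng(config.seed + 10_000)
        e, n, applied = _context_mixing(config, context, emg_mix, neural_mix, pert_rng_ctx)
        noise_seed = np.random.SeedSequence([config.seed, 777, ci])
        c1, c2 = noise_seed.spawn(2)
        sess, truth = _build_session(
            config, targets, amps, e, n, vel_readout,
            np.random.default_rng(c1), np.random.default_rng(c2),
            context, f"day0_{context}", applied,
        )
        suite.append((sess, truth))
    return suite


def generate_raw_emg(config: SynthConfig, duration: float = 10.0,
                     sampling_rate: float = 4000.0,
                     carrier: str = "noise") -> tuple[np.ndarray, np.ndarray, float]:
    """Multichannel raw-EMG-like waveform with a known envelope.

    Each channel is a band-limited carrier with energy concentrated in
    100-500 Hz, amplitude-modulated by a slow nonnegative ground-truth
    envelope.  Returns ``(waveform, envelope, sampling_rate)`` with shapes
    channels x samples.

    Parameters
    ----------
    carrier:
        ``"noise"`` uses band-passed white noise; ``"sine"`` a 250 Hz tone.
    """
    from scipy import signal as sps

    if sampling_rate < 2000.0:
        raise ValueError(
            "source rate must be >= 2000 Hz: the 100-500 Hz band-pass of the "
            "envelope chain is infeasible below that"
        )
    rng = _streams(config.seed, _STREAM_NAMES)["raw_emg"]
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    E = config.n_emg_channels

    freqs = rng.uniform(0.4, 1.5, size=E)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=E)
    envelope = 0.5 * (1.0 + np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None]))

    if carrier == "sine":
        carriers = np.sin(2.0 * np.pi * 250.0 * t)[None, :].repeat(E, axis=0)
    else:
        sos = sps.butter(4, [100.0, 500.0], btype="bandpass", fs=sampling_rate,
                         output="sos")
        white = rng.normal(0.0, 1.0, size=(E, n))
        carriers = sps.sosfiltfilt(sos, white, axis=1)
        rms = np.sqrt(np.mean(carriers ** 2, axis=1, keepdims=True))
        carriers = carriers / np.where(rms > 0, rms, 1.0)

    waveform = carriers * envelope
    return waveform, envelope, sampling_rate
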