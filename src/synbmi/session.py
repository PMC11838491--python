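"""Core containers for time-binned recording sessions.

A session holds the three synchronized data streams used throughout the
pipeline -- neural features (spiking-band power per channel), muscle
activity (EMG envelopes), and finger kinematics -- together with a trial
table describing the center-out task structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Task contexts, in canonical order.  ``normal`` is the unperturbed task;
#: ``spring`` adds a spring resisting finger flexion; ``wrist`` flexes the
#: wrist by a fixed angle; ``spring_wrist`` combines both.
CONTEXTS = ("normal", "spring", "wrist", "spring_wrist")

#: Target classes: all combinations of {flex, rest, extend} for the index
#: finger and the middle-ring-small (MRS) finger group, coded 1..9.
N_TARGETS = 9

#: The center (rest/rest) target class; the task presents it every second
#: trial (center-out structure).
CENTER_TARGET = 5

#: Column order of the kinematics matrix.
KINEMATIC_LABELS = ("index_pos", "mrs_pos", "index_vel", "mrs_vel")


def target_class(index_state: int, mrs_state: int) -> int:
    """Map finger states (-1 flex, 0 rest, +1 extend) to a 1..9 target class."""
    if index_state not in (-1, 0, 1) or mrs_state not in (-1, 0, 1):
        raise ValueError("finger states must be -1 (flex), 0 (rest) or +1 (extend)")
    return 3 * (index_state + 1) + (mrs_state + 1) + 1


@dataclass
class TrialTable:
    """Per-trial task annotations.

    All bin indices are 0-based and half-open: trial ``i`` occupies bins
    ``start_bin[i] .. end_bin[i]-1``.  ``artifact_start/end`` delimit the
    reward-pump ("juicer") electrical artifact window at trial start; a
    trial with no artifact has ``artifact_start == artifact_end``.
    """

    start_bin: np.ndarray          # (n_trials,) int
    end_bin: np.ndarray            # (n_trials,) int
    target: np.ndarray             # (n_trials,) int in 1..9
    context: np.ndarray            # (n_trials,) object array of context names
    artifact_start: np.ndarray     # (n_trials,) int
    artifact_end: np.ndarray       # (n_trials,) int

    def __post_init__(self) -> None:
        for name in ("start_bin", "end_bin", "target", "artifact_start", "artifact_end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.context = np.asarray(self.context, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.start_bin)
        for name in ("end_bin", "target", "context", "artifact_start", "artifact_end"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trial table column {name!r} has wrong length")
        if n == 0:
            return
        if np.any(self.start_bin >= self.end_bin):
            raise ValueError("every trial must satisfy start_bin < end_bin")
        if np.any((self.target < 1) | (self.target > N_TARGETS)):
            raise ValueError(f"targets must lie in 1..{N_TARGETS}")
        order = np.argsort(self.start_bin, kind="stable")
        if np.any(self.end_bin[order][:-1] > self.start_bin[order][1:]):
            raise ValueError("trial windows must be disjoint")
        bad = set(self.context) - set(CONTEXTS)
        if bad:
            raise ValueError(f"unknown context labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.start_bin)

    def trial_bins(self, i: int) -> np.ndarray:
        return np.arange(self.start_bin[i], self.end_bin[i])

    def subset(self, ids: np.ndarray | list) -> "TrialTable":
        ids = np.asarray(ids, dtype=np.int64)
        return TrialTable(
            self.start_bin[ids], self.end_bin[ids], self.target[ids],
            self.context[ids], self.artifact_start[ids], self.artifact_end[ids],
        )


@dataclass
class BinnedSession:
    """Time-binned neural, muscle, and kinematic data plus trial structure.

    ``neural`` is T x N (spiking-band-power-like, nonnegative), ``emg`` is
    T x E in [0, 1], ``kinematics`` is T x 4 in the order
    :data:`KINEMATIC_LABELS`.  ``artifact_mask`` is a length-T boolean
    vector; True marks bins excluded from every training or evaluation
    index set (masked, never interpolated).
    """

    neural: np.ndarray
    emg: np.ndarray
    kinematics: np.ndarray
    trials: TrialTable
    bin_width: float
    day_id: str = "day0"
    artifact_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neural = np.asarray(self.neural, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.kinematics = np.asarray(self.kinematics, dtype=float)
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        T = self.neural.shape[0]
        if self.emg.shape[0] != T or self.kinematics.shape[0] != T:
            raise ValueError("neural, emg and kinematics must share the time axis")
        if self.kinematics.shape[1] != len(KINEMATIC_LABELS):
            raise ValueError(f"kinematics must have {len(KINEMATIC_LABELS)} columns")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.emg.size and self.emg.min() < 0:
            raise ValueError("emg must be nonnegative")
        if self.artifact_mask is not None and self.artifact_mask.shape != (T,):
            raise ValueError("artifact_mask must be a length-T boolean vector")
        if len(self.trials) and self.trials.end_bin.max() > T:
            raise ValueError("trial windows must lie within [0, T)")

    @property
    def n_bins(self) -> int:
        return self.neural.shape[0]

    @property
    def n_neural_channels(self) -> int:
        return self.neural.shape[1]

    @property
    def n_emg_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def velocity(self) -> np.ndarray:
        """T x 2 finger velocities (index, MRS)."""
        return self.kinematics[:, 2:4]

    def valid_mask(self) -> np.ndarray:
        """Boolean length-T vector of bins usable for training/evaluation."""
        if self.artifact_mask is None:
            return np.ones(self.n_bins, dtype=bool)
        return ~self.artifact_mask

    def replace(self, **kwargs) -> "BinnedSession":
        return dataclasses.replace(self, **kwargs)
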