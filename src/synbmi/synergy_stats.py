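"""Correlation structure between brain/muscle channels and synergies.

Quantifies how directly each recorded channel and each synergy activation
relates to movement, and whether brain activity correlates more strongly
with raw muscle activity than with muscle synergies:

* per-channel maximum |CC| against the four kinematic outputs;
* all-pairs Pearson correlation matrices;
* permutation significance thresholds (1000 permutations per pair by
  default) at alpha = 0.05 with Bonferroni correction over the batch of
  comparisons;
* four correlation groups (brain-muscle, brain-muscle-synergy,
  brain-synergy-muscle, brain-synergy-muscle-synergy) summarized by mean
  |CC| and fraction significant;
* a Fisher r-to-z independent-groups comparison of mean correlations
  between groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .session import BinnedSession

logger = logging.getLogger(__name__)

GROUP_LABELS = ("brain_muscle", "brain_muscleSyn",
                "brainSyn_muscle", "brainSyn_muscleSyn")


@dataclass
class PermutationThreshold:
    alpha: float
    n_perm: int
    n_comparisons: int
    thresholds: np.ndarray       # a x b per-pair absolute-CC thresholds
    seed: int
    scheme: str = "permute"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class CorrelationGroupResult:
    label: str
    cc: np.ndarray
    significant: np.ndarray

    @property
    def mean_abs_cc(self) -> float:
        return float(np.mean(np.abs(self.cc)))

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.significant))


def _columns_standardized(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    norm = np.sqrt(np.sum(Xc ** 2, axis=0))
    ok = norm > 0
    if not np.all(ok):
        logger.warning("constant column(s) in correlation input score 0")
    Z = np.zeros_like(Xc)
    Z[:, ok] = Xc[:, ok] / norm[ok]
    return Z, ok


def pairwise_correlation_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """a x b matrix of Pearson CCs between columns of A and columns of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must share the time axis")
    Za, _ = _columns_standardized(A)
    Zb, _ = _columns_standardized(B)
    return Za.T @ Zb


def kinematic_correlation_profile(session: BinnedSession,
                                  data: str = "neural") -> np.ndarray:
    """Per-channel max |CC| against the four kinematic outputs."""
    keep = session.valid_mask()
    X = getattr(session, data)[keep]
    K = session.kinematics[keep]
    cc = pairwise_correlation_matrix(X, K)
    return np.max(np.abs(cc), axis=1)


def permutation_threshold(A: np.ndarray, B: np.ndarray, n_perm: int = 1000,
                          alpha: float = 0.05,
                          bonferroni_m: int | None = None,
                          seed: int = 0,
                          scheme: str = "permute",
                          paired: bool = False) -> PermutationThreshold:
    """Per-pair significance thresholds for |CC| from a permutation null.

    One series' time order is destroyed per draw (full random permutation
    by default; ``scheme="circular"`` uses a random circular shift, which
    preserves autocorrelation and is more conservative for smooth
    signals).  The per-pair threshold is the empirical
    ``1 - alpha/bonferroni_m`` quantile of the null |CC| distribution.

    With ``paired=True`` only matched columns (A[:, i] with B[:, i]) are
    analyzed and the returned thresholds are a length-a vector.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must share the time axis")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    a, b = A.shape[1], B.shape[1]
    if paired and a != b:
        raise ValueError("paired mode requires equally many columns")
    if bonferroni_m is None:
        bonferroni_m = a if paired else a * b
        logger.info("Bonferroni m set to the batch size %d", bonferroni_m)
    if bonferroni_m < 1:
        raise ValueError("bonferroni_m must be >= 1")
    level = alpha / bonferroni_m
    if level < 1.0 / n_perm:
        raise ValueError(
            f"alpha/bonferroni_m = {level:.2e} is below 1/n_perm = "
            f"{1.0 / n_perm:.2e}: the required quantile is unresolvable; "
            f"raise n_perm")
    T = A.shape[0]
    Za, _ = _columns_standardized(A)
    Zb, _ = _columns_standardized(B)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, a) if paired else (n_perm, a, b))
    for p in range(n_perm):
        if scheme == "permute":
            perm = rng.permutation(T)
        elif scheme == "circular":
            perm = np.roll(np.arange(T), rng.integers(1, T))
        else:
            raise ValueError("scheme must be 'permute' or 'circular'")
        Zp = Za[perm]
        if paired:
            null[p] = np.abs(np.sum(Zp * Zb, axis=0))
        else:
            null[p] = np.abs(Zp.T @ Zb)
    thresholds = np.quantile(null, 1.0 - level, axis=0)
    return PermutationThreshold(alpha=alpha, n_perm=n_perm,
                                n_comparisons=bonferroni_m,
                                thresholds=thresholds, seed=seed,
                                scheme=scheme)


def significance_mask(cc: np.ndarray,
                      threshold: PermutationThreshold) -> np.ndarray:
    return np.abs(cc) > threshold.thresholds


def group_correlation_summary(groups: dict[str, CorrelationGroupResult]):
    """Per-group mean |CC| and fraction significant, as a DataFrame."""
    import pandas as pd

    if not groups:
        raise ValueError("at least one group is required")
    rows = [{"group": g.label,
             "n_pairs": int(g.cc.size),
             "mean_abs_cc": g.mean_abs_cc,
             "fraction_significant": g.fraction_significant}
            for g in groups.values()]
    return pd.DataFrame(rows)


def compare_group_correlations(g1: np.ndarray, g2: np.ndarray,
                               T: int) -> tuple[float, float]:
    """Fisher r-to-z two-sample comparison of mean correlations.

    Each correlation is transformed with the Fisher z and assigned
    sampling variance 1/(T-3); the statistic compares the two group means
    under independence.  This is a documented simplification of a full
    dependent-correlations battery.
    """
    g1 = np.abs(np.ravel(np.asarray(g1, dtype=float)))
    g2 = np.abs(np.ravel(np.asarray(g2, dtype=float)))
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be nonempty")
    if T <= 3:
        raise ValueError("need T > 3 time points for the Fisher variance")
    if g1.size == 1 or g2.size == 1:
        warnings.warn("single-element correlation group: the comparison has "
                      "minimal power")
    clip = 1.0 - 1e-12
    z1 = np.arctanh(np.clip(g1, -clip, clip))
    z2 = np.arctanh(np.clip(g2, -clip, clip))
    var = 1.0 / (T - 3)
    se = np.sqrt(var / g1.size + var / g2.size)
    z_stat = float((z1.mean() - z2.mean()) / se)
    p = float(2.0 * spstats.norm.sf(abs(z_stat)))
    return z_stat, min(p, 1.0)
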