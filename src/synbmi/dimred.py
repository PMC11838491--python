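"""Synergy extraction: PCA, NMF, and demixed PCA (dPCA), with VAF machinery.

All three methods factor a time-major data matrix X (T x N) into M <= N
synergies, each described by a weight vector over channels and an
activation time course:

* PCA minimizes ||X - D^T D X||^2 over orthonormal decoders D (written
  here in the channel-major convention); solved analytically by SVD of
  the centered data.  Weights and decoder coincide.
* NMF minimizes ||X - H W||^2 with H (T x M) and W (M x N) elementwise
  nonnegative, by multiplicative updates (no centering: nonnegativity
  forbids it).
* dPCA relaxes PCA's encoder = decoder restriction and is supervised: for
  each task parameter phi (target identity, time) it solves a reduced-rank
  ridge regression of the marginalized data X_phi onto X, yielding a
  separate encoder F_phi and decoder D_phi per parameter.

VAF (variance accounted for) is 1 - ||X - Xhat||_F^2 / ||X - mean||_F^2,
computed against the centered total variance for every method so the
curves are directly comparable (a raw, uncentered denominator is exposed
as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as spopt

from .session import N_TARGETS, BinnedSession

logger = logging.getLogger(__name__)

METHODS = ("pca", "nmf", "dpca")


@dataclass
class SynergyDecomposition:
    """A fitted decomposition.

    ``weights`` (M x N) holds the synergy weights: the principal axes for
    PCA, W for NMF, the transposed encoder for dPCA.  ``decoder`` (M x N)
    maps centered data to activations (equals ``weights`` for PCA;
    pseudo-inverse-based for NMF; the target-parameter decoder D_phi for
    dPCA).  ``activations`` is T x M.  ``vaf_curve[m-1]`` is the VAF using
    the first m components.
    """

    method: str
    n_components: int
    weights: np.ndarray
    decoder: np.ndarray
    channel_means: np.ndarray
    activations: np.ndarray
    vaf_curve: np.ndarray
    fit_metadata: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]


@dataclass
class MarginalizedData:
    """Trial-aligned data split by task parameter for dPCA.

    ``aligned`` is the stacked trial-aligned data ((n_trials *
    aligned_len) x N); ``marginals`` maps each parameter name
    ('time', 'target') to a matrix of the same shape; ``residual`` is the
    remainder.  The decomposition identity

        aligned = grand_mean + marginals['time'] + marginals['target'] + residual

    holds exactly.
    """

    aligned: np.ndarray
    grand_mean: np.ndarray
    marginals: dict[str, np.ndarray]
    residual: np.ndarray
    aligned_len: int
    trial_targets: np.ndarray


# ---------------------------------------------------------------------------
# VAF

def vaf(X: np.ndarray, Xhat: np.ndarray, centered: bool = True) -> float:
    """Variance accounted for by a reconstruction (<= 1)."""
    X = np.asarray(X, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    if X.shape != Xhat.shape:
        raise ValueError("X and Xhat must share a shape")
    if centered:
        denom = np.sum((X - X.mean(axis=0)) ** 2)
    else:
        denom = np.sum(X ** 2)
    if denom == 0:
        raise ValueError("VAF is undefined for constant data")
    return 1.0 - np.sum((X - Xhat) ** 2) / denom


# ---------------------------------------------------------------------------
# PCA

def fit_pca(X: np.ndarray, n_components: int) -> SynergyDecomposition:
    """PCA via SVD of the centered data.

    Decoder rows are the top right singular vectors; the VAF curve equals
    the cumulative eigenvalue fractions of the channel covariance.
    """
    X = np.asarray(X, dtype=float)
    T, N = X.shape
    if T < 2:
        raise ValueError("need at least two time bins")
    if n_components > N:
        raise ValueError(f"n_components {n_components} exceeds channel count {N}")
    means = X.mean(axis=0)
    Xc = X - means
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = np.sum(s ** 2)
    if total == 0:
        raise ValueError("PCA is undefined for constant data")
    curve = np.cumsum(s[:n_components] ** 2) / total
    decoder = vt[:n_components]
    activations = Xc @ decoder.T
    return SynergyDecomposition(
        method="pca", n_components=n_components, weights=decoder.copy(),
        decoder=decoder, channel_means=means, activations=activations,
        vaf_curve=curve,
        fit_metadata={"singular_values": s[:n_components]},
    )


# ---------------------------------------------------------------------------
# NMF

def _nndsvda_init(X: np.ndarray, M: int) -> tuple[np.ndarray, np.ndarray]:
    """SVD-based nonnegative initialization (zeros filled with the mean).

    Splits each singular-vector pair into positive and negative parts and
    keeps the dominant section; a far better basin for multiplicative
    updates than random starts on structured data.
    """
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    T, N = X.shape
    H = np.zeros((T, M))
    W = np.zeros((M, N))
    H[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    W[0] = np.sqrt(s[0]) * np.abs(Vt[0])
    for j in range(1, min(M, len(s))):
        x, y = U[:, j], Vt[j]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        mp, mn = np.linalg.norm(xp) * np.linalg.norm(yp), \
            np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn and mp > 0:
            u, v, sig = xp / np.linalg.norm(xp), yp / np.linalg.norm(yp), mp
        elif mn > 0:
            u, v, sig = xn / np.linalg.norm(xn), yn / np.linalg.norm(yn), mn
        else:
            continue
        H[:, j] = np.sqrt(s[j] * sig) * u
        W[j] = np.sqrt(s[j] * sig) * v
    fill = X.mean() if X.mean() > 0 else 1e-6
    H[H <= 0] = fill
    W[W <= 0] = fill
    return H, W


def _nmf_once(X: np.ndarray, M: int, rng: np.random.Generator | None,
              max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    T, N = X.shape
    if rng is None:
        H, W = _nndsvda_init(X, M)
    else:
        scale = np.sqrt(X.mean() / max(M, 1)) if X.mean() > 0 else 1.0
        H = scale * rng.uniform(0.1, 1.0, size=(T, M))
        W = scale * rng.uniform(0.1, 1.0, size=(M, N))
    eps = 1e-12
    loss_trace = [float(np.sum((X - H @ W) ** 2))]
    for _ in range(max_iter):
        H *= (X @ W.T) / (H @ (W @ W.T) + eps)
        W *= (H.T @ X) / ((H.T @ H) @ W + eps)
        loss = float(np.sum((X - H @ W) ** 2))
        loss_trace.append(loss)
        prev = loss_trace[-2]
        if prev > 0 and (prev - loss) / prev < tol:
            break
    return H, W, loss_trace


def fit_nmf(X: np.ndarray, n_components: int, max_iter: int = 500,
            tol: float = 1e-7, seed: int = 0, n_restarts: int = 1,
            init: str = "nndsvda", compute_curve: bool = True
            ) -> SynergyDecomposition:
    """NMF by multiplicative updates.

    The default start is the deterministic SVD-based nonnegative
    initialization (``init="nndsvda"``); additional seeded random
    restarts can be requested via ``n_restarts`` and the best loss is
    kept, with ties going to the earlier start.  The squared-error loss
    is non-increasing at every multiplicative update; the full trace is
    recorded.  When ``compute_curve`` is set the VAF curve is obtained by
    refitting at each smaller component count (NMF solutions are not
    nested).
    """
    if init not in ("nndsvda", "random"):
        raise ValueError("init must be 'nndsvda' or 'random'")
    X = np.asarray(X, dtype=float)
    if X.size and X.min() < 0:
        ch = int(np.argmin(X.min(axis=0)))
        raise ValueError(f"NMF requires nonnegative data; channel {ch} has "
                         f"minimum {X.min(axis=0)[ch]:.4g}")
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds channel count")

    # losses closer than this are ties (VAF differences below 1e-6);
    # ties go to the earlier start, so the deterministic SVD-based start
    # wins whenever the fit is effectively exact
    tie_tol = 1e-6 * np.sum(X ** 2)

    def _best(M: int):
        best = None
        rng_root = np.random.SeedSequence([seed, M])
        n_random = n_restarts if init == "random" else n_restarts - 1
        rngs = [np.random.default_rng(c)
                for c in rng_root.spawn(max(n_random, 0))]
        if init == "nndsvda":
            rngs = [None] + rngs
        for rng in rngs:
            H, W, trace = _nmf_once(X, M, rng, max_iter, tol)
            if best is None or trace[-1] < best[2][-1] - tie_tol:
                best = (H, W, trace)
        return best

    H, W, trace = _best(n_components)
    curve = np.full(n_components, np.nan)
    curve[-1] = vaf(X, H @ W)
    if compute_curve:
        for m in range(1, n_components):
            Hm, Wm, _ = _best(m)
            curve[m - 1] = vaf(X, Hm @ Wm)
    decoder = np.linalg.pinv(W).T           # quick linear inverse; exact
    return SynergyDecomposition(            # transform uses NNLS instead
        method="nmf", n_components=n_components, weights=W, decoder=decoder,
        channel_means=np.zeros(X.shape[1]), activations=H, vaf_curve=curve,
        fit_metadata={"loss_trace": trace, "seed": seed, "init": init,
                      "n_restarts": n_restarts, "iterations": len(trace) - 1},
    )


# ---------------------------------------------------------------------------
# dPCA

def marginalize_trials(session: BinnedSession, aligned_len: int = 40,
                       data: str = "neural") -> MarginalizedData:
    """Trial-align a session and split it into time/target marginalizations.

    Each trial is cropped to its first ``aligned_len`` bins; the grand
    mean is removed; the time marginalization is the across-target mean
    per aligned bin; the target marginalization is each target's per-bin
    mean minus (grand mean + time marginalization), replicated over that
    target's trials; the residual is the remainder.
    """
    X = getattr(session, data)
    tr = session.trials
    lengths = tr.end_bin - tr.start_bin
    if aligned_len > lengths.min():
        aligned_len = int(lengths.min())
        logger.warning("aligned_len truncated to shortest trial (%d bins)",
                       aligned_len)
    present = set(tr.target.tolist())
    missing = sorted(set(range(1, N_TARGETS + 1)) - present)
    if missing:
        raise ValueError(f"target classes with zero trials: {missing}")

    n_trials = len(tr)
    N = X.shape[1]
    tensor = np.stack([X[tr.start_bin[i]:tr.start_bin[i] + aligned_len]
                       for i in range(n_trials)])       # trials x L x N
    grand = tensor.mean(axis=(0, 1))
    centered = tensor - grand

    # across-trial mean per aligned bin = condition-independent (time) part,
    # averaging targets with equal weight
    targets = tr.target
    per_target_mean = np.stack(
        [centered[targets == k].mean(axis=0) for k in range(1, N_TARGETS + 1)])
    time_marg = per_target_mean.mean(axis=0)            # L x N
    target_marg_by_class = per_target_mean - time_marg  # 9 x L x N

    time_full = np.broadcast_to(time_marg, tensor.shape).reshape(-1, N).copy()
    target_full = np.stack([target_marg_by_class[k - 1] for k in targets]) \
        .reshape(-1, N)
    aligned = centered.reshape(-1, N) + grand
    residual = aligned - grand - time_full - target_full
    return MarginalizedData(
        aligned=aligned, grand_mean=grand,
        marginals={"time": time_full, "target": target_full},
        residual=residual, aligned_len=aligned_len, trial_targets=targets,
    )


def fit_dpca(X: np.ndarray, marginals: dict[str, np.ndarray],
             n_components: int, ridge_mu: float | None = None,
             activation_param: str = "target") -> SynergyDecomposition:
    """Demixed PCA by per-parameter reduced-rank ridge regression.

    For each parameter phi the unconstrained ridge solution
    ``A_phi = X_phi^T X (X^T X + mu I)^{-1}`` (time-major) is truncated to
    rank M via the SVD of its prediction ``X A_phi^T``, giving encoder
    F_phi and decoder D_phi.  Stored activations and decoder belong to
    ``activation_param``; all parameters' encoders/decoders live in
    ``fit_metadata['axes']``.
    """
    X = np.asarray(X, dtype=float)
    T, N = X.shape
    if n_components > N:
        raise ValueError("n_components exceeds channel count")
    means = X.mean(axis=0)
    Xc = X - means
    G = Xc.T @ Xc
    if ridge_mu is None:
        ridge_mu = 1e-6 * np.trace(G) / N
    if ridge_mu == 0:
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "X^T X is singular; refit with ridge_mu > 0")
    Ginv = np.linalg.inv(G + ridge_mu * np.eye(N))

    axes: dict[str, dict] = {}
    for phi, Xphi in marginals.items():
        Xphi = np.asarray(Xphi, dtype=float)
        if Xphi.shape != X.shape:
            raise ValueError(f"marginalization {phi!r} shape mismatch")
        A = Xphi.T @ Xc @ Ginv                   # N x N
        Y = Xc @ A.T                             # T x N predicted marginal
        _, s, vt = np.linalg.svd(Y, full_matrices=False)
        U = vt[:n_components].T                  # N x M: principal axes of Y
        F = U                                    # encoder
        D = U.T @ A                              # decoder, M x N
        total_phi = np.sum(Xphi ** 2)
        expl = np.array([
            np.sum((Xc @ D[:m + 1].T @ F[:, :m + 1].T) * (2 * Xphi)) -
            np.sum((Xc @ D[:m + 1].T @ F[:, :m + 1].T) ** 2)
            for m in range(n_components)
        ]) / total_phi if total_phi > 0 else np.zeros(n_components)
        axes[phi] = {"encoder": F, "decoder": D,
                     "explained_marginal_variance": expl}

    if activation_param not in axes:
        raise ValueError(f"activation_param {activation_param!r} not among "
                         f"marginalizations {sorted(axes)}")
    F = axes[activation_param]["encoder"]
    D = axes[activation_param]["decoder"]
    activations = Xc @ D.T
    total = np.sum(Xc ** 2)
    curve = np.array([
        1.0 - np.sum((Xc - Xc @ D[:m + 1].T @ F[:, :m + 1].T) ** 2) / total
        for m in range(n_components)])
    return SynergyDecomposition(
        method="dpca", n_components=n_components, weights=F.T, decoder=D,
        channel_means=means, activations=activations, vaf_curve=curve,
        fit_metadata={"ridge_mu": ridge_mu, "axes": axes,
                      "activation_param": activation_param},
    )


def fit_dpca_session(session: BinnedSession, n_components: int,
                     aligned_len: int = 40, ridge_mu: float | None = None,
                     data: str = "neural") -> SynergyDecomposition:
    """Convenience: marginalize a session's trials and fit dPCA."""
    marg = marginalize_trials(session, aligned_len=aligned_len, data=data)
    return fit_dpca(marg.aligned, marg.marginals, n_components,
                    ridge_mu=ridge_mu)


# ---------------------------------------------------------------------------
# transform / reconstruct

def transform(decomp: SynergyDecomposition, Xnew: np.ndarray) -> np.ndarray:
    """Project new data onto a fitted decomposition's activations."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.shape[1] != decomp.n_channels:
        raise ValueError(
            f"channel count mismatch: data has {Xnew.shape[1]}, "
            f"decomposition expects {decomp.n_channels}")
    if decomp.method == "nmf":
        W = decomp.weights
        H = np.empty((Xnew.shape[0], decomp.n_components))
        for t in range(Xnew.shape[0]):
            H[t], _ = spopt.nnls(W.T, Xnew[t])
        return H
    return (Xnew - decomp.channel_means) @ decomp.decoder.T


def reconstruct(decomp: SynergyDecomposition,
                activations: np.ndarray) -> np.ndarray:
    """Map activations back to channel space."""
    activations = np.asarray(activations, dtype=float)
    if activations.shape[1] != decomp.n_components:
        raise ValueError("activation count mismatch")
    if decomp.method == "nmf":
        return activations @ decomp.weights
    if decomp.method == "dpca":
        F = decomp.weights.T                 # N x M encoder
        return activations @ F.T + decomp.channel_means
    return activations @ decomp.weights + decomp.channel_means


def components_for_vaf(X: np.ndarray, method: str = "pca",
                       threshold: float = 0.90,
                       max_components: int | None = None,
                       **fit_kwargs) -> int:
    """Smallest component count whose VAF reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    N = X.shape[1]
    M = N if max_components is None else min(max_components, N)
    if method == "pca":
        curve = fit_pca(X, M).vaf_curve
    elif method == "nmf":
        curve = fit_nmf(X, M, compute_curve=True, **fit_kwargs).vaf_curve
    else:
        raise ValueError("components_for_vaf supports 'pca' and 'nmf'")
    hits = np.flatnonzero(curve >= threshold)
    if hits.size == 0:
        raise ValueError(
            f"{method} never reaches VAF {threshold} with {M} components "
            f"(max {curve.max():.3f})")
    return int(hits[0]) + 1
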