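"""Decoding: ridge regression with spike history and target classification.

The decoder regresses kinematics or EMG on the current and previous time
bins of the input features (10 bins = 200 ms of history by default) with
an L2 penalty; the intercept is unpenalized and the solution is the
closed-form penalized normal equation.  Performance is the per-output
Pearson correlation between prediction and ground truth.

Target classification over the nine task targets uses one-vs-one linear
max-margin discriminants trained by a seeded Pegasos-style subgradient
scheme; accuracy is the unweighted (macro) mean of per-class accuracies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as spla

from .session import BinnedSession, TrialTable

logger = logging.getLogger(__name__)

DEFAULT_LAGS = 10
LAMBDA_GRID = np.logspace(-4, 4, 9)


# ---------------------------------------------------------------------------
# correlation

def pearson_cc(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Per-column Pearson correlation; constant series score 0 (warned)."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float).T).T
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float).T).T
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    a = y_true - y_true.mean(axis=0)
    b = y_pred - y_pred.mean(axis=0)
    sa = np.sqrt(np.sum(a ** 2, axis=0))
    sb = np.sqrt(np.sum(b ** 2, axis=0))
    out = np.zeros(y_true.shape[1])
    ok = (sa > 0) & (sb > 0)
    if not np.all(ok):
        logger.warning("pearson_cc: %d constant column(s) scored as 0",
                       int((~ok).sum()))
    out[ok] = np.sum(a[:, ok] * b[:, ok], axis=0) / (sa[ok] * sb[ok])
    return out


# ---------------------------------------------------------------------------
# history design

def build_history_design(X: np.ndarray, lags: int = DEFAULT_LAGS,
                         mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix with intercept column.

    Row for time t holds ``[1, X_t, X_{t-1}, ..., X_{t-lags+1}]`` for
    t = lags .. T-1, giving (T - lags) rows of width lags*P + 1.  When a
    boolean ``mask`` marks artifact bins, every row touching a masked bin
    is dropped.  Returns ``(design, kept_time_indices)``.
    """
    X = np.asarray(X, dtype=float)
    T, P = X.shape
    if T <= lags:
        raise ValueError(f"need more than {lags} time bins, got {T}")
    t_idx = np.arange(lags, T)
    cols = [np.ones((t_idx.size, 1))]
    for d in range(lags):
        cols.append(X[t_idx - d])
    design = np.concatenate(cols, axis=1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        touched = np.zeros(t_idx.size, dtype=bool)
        for d in range(lags):
            touched |= mask[t_idx - d]
        design = design[~touched]
        t_idx = t_idx[~touched]
    return design, t_idx


@dataclass
class RidgeDecoder:
    lags: int
    lam: float
    weights: np.ndarray                 # (lags*P + 1) x Q
    n_inputs: int
    fit_metadata: dict = field(default_factory=dict)

    def predict_design(self, design: np.ndarray) -> np.ndarray:
        return design @ self.weights

    def predict(self, X: np.ndarray, mask: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
        design, t_idx = build_history_design(X, self.lags, mask)
        return design @ self.weights, t_idx


def fit_ridge(design: np.ndarray, Y: np.ndarray, lam: float,
              lags: int = DEFAULT_LAGS) -> RidgeDecoder:
    """Closed-form ridge solve; first (intercept) column unpenalized."""
    design = np.asarray(design, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if design.shape[0] != Y.shape[0]:
        raise ValueError("design and Y must have the same number of rows")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    G = design.T @ design
    pen = np.eye(G.shape[0])
    pen[0, 0] = 0.0
    A = G + lam * pen
    b = design.T @ Y
    if lam == 0:
        if np.linalg.matrix_rank(G) < G.shape[0]:
            raise np.linalg.LinAlgError(
                "design is rank deficient at lambda=0; use lambda > 0")
        W = np.linalg.solve(A, b)
    else:
        W = np.linalg.solve(A, b)
    P = (design.shape[1] - 1) // lags if lags else design.shape[1] - 1
    return RidgeDecoder(lags=lags, lam=lam, weights=W, n_inputs=P)


def _blocked_folds(n: int, n_folds: int) -> list[np.ndarray]:
    edges = np.linspace(0, n, n_folds + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_folds)]


def select_ridge_lambda(design: np.ndarray, Y: np.ndarray,
                        grid: np.ndarray = LAMBDA_GRID,
                        n_folds: int = 5) -> tuple[float, np.ndarray]:
    """Blocked cross-validation over a lambda grid.

    Folds are contiguous time blocks (fixed boundaries, deterministic);
    the score is the validation mean squared error, which is invariant
    under orthonormal rotations of the output space — so models that
    predict a rotated target (e.g. PCA synergy activations) select the
    same lambda as the corresponding raw-output model.  Ties go to the
    smallest grid value.
    """
    design = np.asarray(design, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    folds = _blocked_folds(design.shape[0], n_folds)
    pen = np.eye(design.shape[1])
    pen[0, 0] = 0.0
    mse = np.zeros(len(grid))
    for val_idx in folds:
        train = np.ones(design.shape[0], dtype=bool)
        train[val_idx] = False
        Xtr, Ytr = design[train], Y[train]
        Xva, Yva = design[val_idx], Y[val_idx]
        G = Xtr.T @ Xtr
        b = Xtr.T @ Ytr
        for j, lam in enumerate(grid):
            try:
                W = np.linalg.solve(G + lam * pen, b)
            except np.linalg.LinAlgError:
                mse[j] = np.inf
                continue
            mse[j] += np.mean((Xva @ W - Yva) ** 2)
    best = int(np.argmin(mse))
    return float(grid[best]), mse


def fit_ridge_cv(design: np.ndarray, Y: np.ndarray,
                 grid: np.ndarray = LAMBDA_GRID, n_folds: int = 5,
                 lags: int = DEFAULT_LAGS) -> RidgeDecoder:
    lam, mse = select_ridge_lambda(design, Y, grid, n_folds)
    dec = fit_ridge(design, Y, lam, lags=lags)
    dec.fit_metadata.update({"cv_mse": mse, "lambda_grid": np.asarray(grid)})
    return dec


def predict_and_score(decoder: RidgeDecoder, Xnew: np.ndarray,
                      Ytrue: np.ndarray,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Per-output Pearson CC of decoder predictions on new data."""
    pred, t_idx = decoder.predict(Xnew, mask)
    Ytrue = np.asarray(Ytrue, dtype=float)
    if Ytrue.ndim == 1:
        Ytrue = Ytrue[:, None]
    return pearson_cc(Ytrue[t_idx], pred)


# ---------------------------------------------------------------------------
# target classification

@dataclass
class TargetClassifier:
    """One-vs-one linear max-margin discriminants over task targets."""

    classes: np.ndarray
    pairs: list[tuple[int, int]]
    weights: dict[tuple[int, int], np.ndarray]
    feature_mean: np.ndarray
    feature_scale: np.ndarray


def _pegasos(X: np.ndarray, y: np.ndarray, reg: float, epochs: int,
             rng: np.random.Generator) -> np.ndarray:
    """Pegasos subgradient solver for a linear hinge classifier.

    y in {-1, +1}; returns an augmented weight vector (bias last),
    averaged over the second half of the iterates for stability.
    """
    n, p = X.shape
    Xa = np.column_stack([X, np.ones(n)])
    w = np.zeros(p + 1)
    w_sum = np.zeros(p + 1)
    n_avg = 0
    t = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        for i in order:
            t += 1
            eta = 1.0 / (reg * t)
            margin = y[i] * (Xa[i] @ w)
            w[:p] *= (1.0 - eta * reg)
            if margin < 1:
                w += eta * y[i] * Xa[i]
            if epoch >= epochs // 2:
                w_sum += w
                n_avg += 1
    return w_sum / max(n_avg, 1)


def fit_classifier(features: np.ndarray, labels: np.ndarray,
                   reg: float = 1e-2, epochs: int = 100,
                   seed: int = 0) -> TargetClassifier:
    """Train one-vs-one linear discriminants on per-trial features."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training labels contain fewer than two classes")
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (features - mean) / scale
    rng = np.random.default_rng(seed)
    pairs, weights = [], {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            sel = (labels == a) | (labels == b)
            y = np.where(labels[sel] == a, 1.0, -1.0)
            w = _pegasos(Z[sel], y, reg, epochs, rng)
            pairs.append((int(a), int(b)))
            weights[(int(a), int(b))] = w
    return TargetClassifier(classes=classes, pairs=pairs, weights=weights,
                            feature_mean=mean, feature_scale=scale)


def classify(clf: TargetClassifier, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    Z = (features - clf.feature_mean) / clf.feature_scale
    Za = np.column_stack([Z, np.ones(Z.shape[0])])
    votes = np.zeros((Z.shape[0], clf.classes.size))
    cls_index = {int(c): i for i, c in enumerate(clf.classes)}
    for (a, b), w in clf.weights.items():
        score = Za @ w
        votes[score >= 0, cls_index[a]] += 1
        votes[score < 0, cls_index[b]] += 1
    return clf.classes[np.argmax(votes, axis=1)]


def macro_accuracy(y_true: np.ndarray, y_pred: np.ndarray,
                   all_classes: np.ndarray | None = None) -> float:
    """Unweighted mean of per-class accuracies over classes present in truth.

    Classes listed in ``all_classes`` but absent from ``y_true`` are
    skipped with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    present = np.unique(y_true)
    if all_classes is not None:
        absent = sorted(set(np.asarray(all_classes).tolist()) -
                        set(present.tolist()))
        if absent:
            warnings.warn(f"classes absent from the test set skipped in the "
                          f"macro average: {absent}")
    accs = [np.mean(y_pred[y_true == c] == c) for c in present]
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# splits

def chronological_split(trials: TrialTable, train_frac: float = 0.8
                        ) -> tuple[np.ndarray, np.ndarray]:
    """First ceil(train_frac * n) trials train, the rest test; no shuffling."""
    n = len(trials)
    if n < 5:
        raise ValueError("need at least 5 trials to split")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    order = np.argsort(trials.start_bin, kind="stable")
    n_train = int(np.ceil(train_frac * n))
    if n_train >= n:
        raise ValueError("train_frac leaves an empty test set")
    return order[:n_train], order[n_train:]


def trial_bin_mask(session: BinnedSession, trial_ids: np.ndarray) -> np.ndarray:
    """Boolean length-T mask of bins in the given trials, minus artifacts."""
    mask = np.zeros(session.n_bins, dtype=bool)
    tr = session.trials
    for i in np.asarray(trial_ids):
        mask[tr.start_bin[i]:tr.end_bin[i]] = True
    return mask & session.valid_mask()


# ---------------------------------------------------------------------------
# ridge engine over session splits (shared design, cached fold Gram matrices)

class LaggedRidgeEngine:
    """Ridge-with-history trainer over fixed train/test bin sets.

    Builds the lagged design once per feature matrix, drops rows touching
    masked bins, and caches per-fold Gram matrices so multiple outputs
    reuse the expensive part of blocked-CV lambda selection.
    """

    def __init__(self, feats: np.ndarray, lags: int,
                 artifact_mask: np.ndarray | None,
                 train_mask: np.ndarray, test_mask: np.ndarray | None,
                 grid: np.ndarray = LAMBDA_GRID, n_folds: int = 5):
        design, t_idx = build_history_design(feats, lags, artifact_mask)
        self.lags = lags
        self.grid = np.asarray(grid, dtype=float)
        self.t_idx = t_idx
        self.train_rows = train_mask[t_idx]
        self.test_rows = (test_mask[t_idx] if test_mask is not None
                          else np.zeros(t_idx.size, dtype=bool))
        if np.any(self.train_rows & self.test_rows):
            raise AssertionError("train and test bin sets overlap")
        self.Xtr = design[self.train_rows]
        self.Xte = design[self.test_rows]
        self.train_bins = t_idx[self.train_rows]
        self.test_bins = t_idx[self.test_rows]
        n = self.Xtr.shape[0]
        edges = np.linspace(0, n, n_folds + 1).astype(int)
        self._folds = [np.arange(edges[i], edges[i + 1])
                       for i in range(n_folds)]
        self.G = self.Xtr.T @ self.Xtr
        self._G_va = [self.Xtr[f].T @ self.Xtr[f] for f in self._folds]
        p = self.G.shape[0]
        self._pen = np.eye(p)
        self._pen[0, 0] = 0.0

    def cv_lambda(self, Ytr: np.ndarray) -> tuple[float, np.ndarray]:
        b = self.Xtr.T @ Ytr
        mse = np.zeros(self.grid.size)
        for f, Gva in zip(self._folds, self._G_va):
            Xva, Yva = self.Xtr[f], Ytr[f]
            Gtr = self.G - Gva
            btr = b - Xva.T @ Yva
            for j, lam in enumerate(self.grid):
                try:
                    W = spla.solve(Gtr + lam * self._pen, btr,
                                   assume_a="pos")
                except np.linalg.LinAlgError:
                    mse[j] = np.inf
                    continue
                mse[j] += np.mean((Xva @ W - Yva) ** 2)
        return float(self.grid[np.argmin(mse)]), mse

    def fit(self, Y: np.ndarray, lam: float | None = None) -> RidgeDecoder:
        Ytr = Y[self.train_bins]
        if Ytr.ndim == 1:
            Ytr = Ytr[:, None]
        if lam is None:
            lam, mse = self.cv_lambda(Ytr)
        else:
            mse = None
        W = spla.solve(self.G + lam * self._pen, self.Xtr.T @ Ytr,
                       assume_a="pos")
        P = (self.G.shape[0] - 1) // self.lags
        dec = RidgeDecoder(lags=self.lags, lam=lam, weights=W, n_inputs=P)
        dec.fit_metadata["cv_mse"] = mse
        return dec

    def predict_test(self, dec: RidgeDecoder) -> np.ndarray:
        return self.Xte @ dec.weights

    def audit(self, artifact_mask: np.ndarray | None) -> dict:
        train, test = set(self.train_bins.tolist()), set(self.test_bins.tolist())
        masked = (set(np.flatnonzero(artifact_mask).tolist())
                  if artifact_mask is not None else set())
        return {
            "n_train_rows": len(train),
            "n_test_rows": len(test),
            "train_test_disjoint": not (train & test),
            "masked_excluded": not ((train | test) & masked),
        }


def decode_session(session: BinnedSession, input_kind: str = "brain",
                   output_kind: str = "velocity", lags: int = DEFAULT_LAGS,
                   train_frac: float = 0.8,
                   grid: np.ndarray = LAMBDA_GRID) -> tuple[np.ndarray, RidgeDecoder]:
    """Train and evaluate a ridge-with-history decoder on one session.

    Chronological trial split, artifact bins masked, lambda chosen by
    blocked cross-validation on the training bins.  Returns the held-out
    per-output Pearson CCs and the fitted decoder.
    """
    X = session.neural if input_kind == "brain" else session.emg
    Y = session.velocity if output_kind == "velocity" else session.emg
    train_tr, test_tr = chronological_split(session.trials, train_frac)
    eng = LaggedRidgeEngine(X, lags, session.artifact_mask,
                            trial_bin_mask(session, train_tr),
                            trial_bin_mask(session, test_tr), grid=grid)
    dec = eng.fit(Y)
    cc = pearson_cc(Y[eng.test_bins], eng.predict_test(dec))
    return cc, dec
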