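"""The three decoder experiments: compression, denoising, generalization.

All three share the same machinery: extract synergies on training data
only, decode an output (muscle activity, finger velocity, or muscle
synergy activations projected back to muscle space) with ridge regression
with history, and score the held-out Pearson correlation.

* **Compression** sweeps the synergy count, fits the saturation curve
  ``corr(x) = k1 + k2 * (1 + exp(-k3 * x))`` to the held-out correlation
  as a function of synergy count x, finds the smallest x reaching 95% of
  the asymptote (k1 + k2), and reports the compression ratio
  total_dims / x95.
* **Denoising** runs the eight-model grid (inputs: brain, brain
  synergies, muscle, muscle synergies; outputs: muscle, velocity, muscle
  synergies) and normalizes every synergy model to its full-data baseline
  (models 1, 2, 7); values above 100 would indicate denoising.
* **Generalization** trains off-context models on the unperturbed
  (normal) context and tests them on the last 20% of each perturbed
  context, against on-context models trained on that context's first 80%.

Train/test splits are chronological by trial (80/20 by default) for every
experiment; artifact-masked bins never enter any index set, which the
returned audits assert.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as spopt

from . import dimred
from .decoding import (DEFAULT_LAGS, LaggedRidgeEngine,
                       chronological_split, pearson_cc, trial_bin_mask)
from .session import CONTEXTS, BinnedSession

logger = logging.getLogger(__name__)

#: The eight-model grid: model id -> (input, output).
MODEL_TABLE = {
    1: ("brain", "muscle"),
    2: ("brain", "velocity"),
    3: ("brain", "muscle_syn"),
    4: ("brain_syn", "muscle"),
    5: ("brain_syn", "velocity"),
    6: ("brain_syn", "muscle_syn"),
    7: ("muscle", "velocity"),
    8: ("muscle_syn", "velocity"),
}

#: Full-data baseline model for each synergy model.
BASELINE_OF = {1: 1, 2: 2, 3: 1, 4: 1, 5: 2, 6: 1, 7: 7, 8: 7}

BRAIN_METHODS = ("pca", "nmf", "dpca")
MUSCLE_METHODS = ("pca", "nmf")       # dPCA is applied to brain data only

DEFAULT_FRACTIONS = (0.125, 0.25, 0.5, 0.75, 1.0)


@dataclass
class ModelSpec:
    id: int
    input: str
    output: str

    def __post_init__(self) -> None:
        if MODEL_TABLE.get(self.id) != (self.input, self.output):
            raise ValueError(f"model {self.id} must map "
                             f"{MODEL_TABLE.get(self.id)}, got "
                             f"({self.input}, {self.output})")


@dataclass
class CompressionFit:
    k1: float
    k2: float
    k3: float
    x95: float
    total_dims: int
    curve: np.ndarray              # (n_points, 2): (n_components, CC)
    success: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def ratio(self) -> float:
        return self.total_dims / self.x95

    @property
    def ratio_label(self) -> str:
        return f"{self.ratio:.2f}:1"


@dataclass
class ExperimentResult:
    name: str
    table: pd.DataFrame
    baselines: dict
    metadata: dict = field(default_factory=dict)
    audits: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# synergy fitting / feature preparation

def _fit_dr(session: BinnedSession, data: str, method: str,
            n_components: int, train_bins: np.ndarray,
            train_trials: np.ndarray | None, seed: int,
            aligned_len: int, nmf_kwargs: dict | None
            ) -> dimred.SynergyDecomposition:
    X = getattr(session, data)
    if method == "pca":
        return dimred.fit_pca(X[train_bins], n_components)
    if method == "nmf":
        kw = {"n_restarts": 1, "max_iter": 300, "tol": 1e-6}
        kw.update(nmf_kwargs or {})
        return dimred.fit_nmf(X[train_bins], n_components, seed=seed,
                              compute_curve=False, **kw)
    if method == "dpca":
        if train_trials is None:
            raise ValueError("dPCA needs the training trial ids")
        sub = session.replace(trials=session.trials.subset(train_trials))
        marg = dimred.marginalize_trials(sub, aligned_len=aligned_len,
                                         data=data)
        return dimred.fit_dpca(marg.aligned, marg.marginals, n_components)
    raise ValueError(f"unknown method {method!r}")


def _outputs_for(session: BinnedSession, output: str,
                 emg_decomp=None) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (regression target, evaluation target in muscle space)."""
    if output == "velocity":
        return session.velocity, None
    if output == "muscle":
        return session.emg, None
    if output == "muscle_syn":
        H = dimred.transform(emg_decomp, session.emg)
        return H, session.emg
    raise ValueError(f"unknown output {output!r}")


# ---------------------------------------------------------------------------
# saturation curve

def _sat_curve(x: np.ndarray, k1: float, k2: float, k3: float) -> np.ndarray:
    return k1 + k2 * (1.0 + np.exp(-k3 * x))


def fit_saturation_curve(curve, total_dims: int,
                         seed: int = 0) -> CompressionFit:
    """Fit ``corr(x) = k1 + k2 (1 + e^{-k3 x})`` and locate x95.

    Multi-start bounded quasi-Newton least squares (5 seeded starts,
    k3 > 0).  x95 is the smallest x with ``corr(x) >= 0.95 (k1 + k2)``:
    closed-form inversion when k2 < 0 and k3 > 0, otherwise a dense grid
    scan over [1, total_dims]; a flat fitted curve yields x95 = 1.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2:
        raise ValueError("curve must be (n_points, 2): (n_components, CC)")
    under_determined = curve.shape[0] < 3
    x, y = curve[:, 0], curve[:, 1]

    def loss(theta):
        return np.sum((_sat_curve(x, *theta) - y) ** 2)

    rng = np.random.default_rng(seed)
    bounds = [(-2.0, 2.0), (-2.0, 2.0), (1e-4, 10.0)]
    best = None
    y_hi, y_lo = y.max(), y.min()
    starts = [np.array([y_hi, y_lo - y_hi, 0.3])]
    for _ in range(4):
        starts.append(np.array([
            rng.uniform(0.0, 1.0), rng.uniform(-1.0, 0.0),
            rng.uniform(0.05, 2.0)]))
    for theta0 in starts:
        res = spopt.minimize(loss, theta0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    k1, k2, k3 = best.x
    asymptote = k1 + k2
    target = 0.95 * asymptote

    success = True
    if np.isclose(k2, 0.0, atol=1e-10):
        x95 = 1.0
    elif k2 < 0 and k3 > 0:
        arg = 0.05 * asymptote / (-k2)
        if 0 < arg <= 1:
            x95 = max(1.0, -np.log(arg) / k3)
        else:
            x95 = 1.0
    else:
        grid = np.linspace(1.0, float(total_dims), 2000)
        ok = _sat_curve(grid, k1, k2, k3) >= target
        if np.any(ok):
            x95 = float(grid[np.argmax(ok)])
        else:
            x95 = float(total_dims)
            success = False
            logger.warning("saturation fit never reaches 95%% of its "
                           "asymptote; ratio undefined")
    diagnostics = {"sse": float(best.fun),
                   "under_determined": under_determined}
    if under_determined:
        logger.warning("saturation fit on %d point(s) is under-determined",
                       curve.shape[0])
    return CompressionFit(k1=float(k1), k2=float(k2), k3=float(k3),
                          x95=float(x95), total_dims=int(total_dims),
                          curve=curve, success=success,
                          diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# compression experiment

def default_component_grid(n_dims: int, n_points: int = 8) -> list[int]:
    """A small-to-full grid of component counts for an n-dim input."""
    grid = np.unique(np.round(
        np.geomspace(1, n_dims, n_points)).astype(int))
    return [int(g) for g in grid]


def run_compression(session: BinnedSession,
                    methods: dict | None = None,
                    component_grid: dict | None = None,
                    lags: int = DEFAULT_LAGS, train_frac: float = 0.8,
                    seed: int = 0, aligned_len: int = 40,
                    nmf_kwargs: dict | None = None) -> ExperimentResult:
    """Sweep synergy counts, fit saturation curves, report compression.

    ``methods`` maps input kind ('brain', 'muscle') to the DR methods to
    run; ``component_grid`` maps input kind to the counts to sweep.
    """
    has_emg = session.n_emg_channels > 0
    if methods is None:
        methods = {"brain": BRAIN_METHODS,
                   "muscle": MUSCLE_METHODS if has_emg else ()}
    train_tr, test_tr = chronological_split(session.trials, train_frac)
    train_mask = trial_bin_mask(session, train_tr)
    test_mask = trial_bin_mask(session, test_tr)
    train_bins = np.flatnonzero(train_mask)
    inputs = {"brain": session.neural}
    if has_emg:
        inputs["muscle"] = session.emg
    if component_grid is None:
        component_grid = {k: default_component_grid(v.shape[1])
                          for k, v in inputs.items()}

    outputs_of = {"brain": (["muscle", "velocity"] if has_emg
                            else ["velocity"]),
                  "muscle": ["velocity"]}
    rows, fits, audits = [], {}, []
    amask = session.artifact_mask
    for kind, X in inputs.items():
        total = X.shape[1]
        grid = sorted({min(c, total) for c in component_grid[kind]})
        if max(component_grid[kind]) > total:
            logger.warning("component grid trimmed to %d dims", total)
        base_engine = LaggedRidgeEngine(X, lags, amask, train_mask, test_mask)
        audits.append(base_engine.audit(amask))
        base_cc: dict[str, float] = {}
        for out in outputs_of[kind]:
            Y, _ = _outputs_for(session, out)
            dec = base_engine.fit(Y)
            cc = pearson_cc(Y[base_engine.test_bins],
                            base_engine.predict_test(dec))
            base_cc[out] = float(np.mean(cc))
        for method in methods.get(kind, ()):
            curves: dict[str, list] = {o: [] for o in outputs_of[kind]}
            for M in grid:
                decomp = _fit_dr(session, "neural" if kind == "brain" else "emg",
                                 method, M, train_bins, train_tr, seed,
                                 aligned_len, nmf_kwargs)
                feats = dimred.transform(decomp, X)
                engine = LaggedRidgeEngine(feats, lags, amask,
                                            train_mask, test_mask)
                for out in outputs_of[kind]:
                    Y, _ = _outputs_for(session, out)
                    dec = engine.fit(Y)
                    cc = float(np.mean(pearson_cc(
                        Y[engine.test_bins], engine.predict_test(dec))))
                    curves[out].append((M, cc))
                    rows.append({"input": kind, "method": method,
                                 "output": out, "n_components": M,
                                 "cc": cc, "baseline_cc": base_cc[out],
                                 "seed": seed})
            for out in outputs_of[kind]:
                fits[(kind, method, out)] = fit_saturation_curve(
                    np.array(curves[out]), total_dims=total, seed=seed)
    table = pd.DataFrame(rows).sort_values(
        ["input", "method", "output", "n_components"]).reset_index(drop=True)
    return ExperimentResult(
        name="compression", table=table,
        baselines={"full_data_cc": base_cc},
        metadata={"seed": seed, "lags": lags, "train_frac": train_frac,
                  "fits": fits},
        audits=audits)


# ---------------------------------------------------------------------------
# denoising experiment

def _side_counts(fraction: float, n_dims: int) -> int:
    return max(1, int(round(fraction * n_dims)))


def run_denoising(session: BinnedSession,
                  methods: tuple = BRAIN_METHODS,
                  component_fractions: tuple = DEFAULT_FRACTIONS,
                  lags: int = DEFAULT_LAGS, train_frac: float = 0.8,
                  seed: int = 0, aligned_len: int = 40,
                  nmf_kwargs: dict | None = None) -> ExperimentResult:
    """Run the eight-model denoising grid.

    Synergy models are swept over ``component_fractions`` of each input's
    total dimension; every model is normalized (x100) to its full-data
    baseline (models 1, 2, 7).  Muscle-synergy outputs are projected back
    to muscle space before scoring.
    """
    has_emg = session.n_emg_channels > 0
    train_tr, test_tr = chronological_split(session.trials, train_frac)
    train_mask = trial_bin_mask(session, train_tr)
    test_mask = trial_bin_mask(session, test_tr)
    train_bins = np.flatnonzero(train_mask)
    amask = session.artifact_mask
    fractions = tuple(sorted(set(component_fractions)))

    N, E = session.n_neural_channels, session.n_emg_channels
    engines: dict = {}
    decomps: dict = {}

    def engine_for(key, feats):
        if key not in engines:
            engines[key] = LaggedRidgeEngine(feats, lags, amask,
                                              train_mask, test_mask)
        return engines[key]

    def decomp_for(kind, method, M):
        key = (kind, method, M)
        if key not in decomps:
            data = "neural" if kind == "brain" else "emg"
            decomps[key] = _fit_dr(session, data, method, M, train_bins,
                                   train_tr, seed, aligned_len, nmf_kwargs)
        return decomps[key]

    # baselines: models 1, 2, 7 on the full data
    baselines: dict[int, float] = {}
    rows = []
    for mid in (1, 2, 7):
        inp, out = MODEL_TABLE[mid]
        if "muscle" in (inp, out) and not has_emg:
            logger.warning("model %d skipped: session has no EMG", mid)
            continue
        feats = session.neural if inp == "brain" else session.emg
        eng = engine_for(inp, feats)
        Y, _ = _outputs_for(session, out)
        dec = eng.fit(Y)
        cc = float(np.mean(pearson_cc(Y[eng.test_bins],
                                      eng.predict_test(dec))))
        baselines[mid] = cc
        rows.append({"model_id": mid, "input": inp, "output": out,
                     "method": "full", "n_components": (N if inp == "brain"
                                                        else E),
                     "fraction": 1.0, "cc": cc,
                     "baseline_id": mid, "baseline_cc": cc,
                     "normalized": 100.0, "seed": seed})

    # synergy models 3, 4, 5, 6, 8
    for mid in (3, 4, 5, 6, 8):
        inp, out = MODEL_TABLE[mid]
        needs_emg = "muscle" in inp or "muscle" in out
        if needs_emg and not has_emg:
            logger.warning("model %d skipped: session has no EMG", mid)
            continue
        bid = BASELINE_OF[mid]
        for method in methods:
            # dPCA only applies to the brain side; sweeping it for a model
            # whose synergy side is muscle-only would duplicate the PCA run
            if method == "dpca" and inp != "brain_syn":
                continue
            muscle_method = method if method in MUSCLE_METHODS else "pca"
            for frac in fractions:
                if inp == "brain":
                    feats, n_in = session.neural, N
                elif inp == "brain_syn":
                    Mb = _side_counts(frac, N)
                    bd = decomp_for("brain", method, Mb)
                    feats = dimred.transform(bd, session.neural)
                    n_in = Mb
                else:   # muscle_syn input (model 8)
                    Me = _side_counts(frac, E)
                    in_decomp = decomp_for("muscle", muscle_method, Me)
                    feats = dimred.transform(in_decomp, session.emg)
                    n_in = Me
                if out == "muscle_syn":
                    Me = _side_counts(frac, E)
                    out_decomp = decomp_for("muscle", muscle_method, Me)
                    Y, Y_eval = _outputs_for(session, out, out_decomp)
                else:
                    out_decomp = None
                    Y, Y_eval = _outputs_for(session, out)
                key = (inp, method, frac) if inp.endswith("_syn") else inp
                eng = engine_for(key, feats)
                dec = eng.fit(Y)
                pred = eng.predict_test(dec)
                if out == "muscle_syn":
                    pred = dimred.reconstruct(out_decomp, pred)
                    truth = Y_eval[eng.test_bins]
                else:
                    truth = Y[eng.test_bins]
                cc = float(np.mean(pearson_cc(truth, pred)))
                rows.append({
                    "model_id": mid, "input": inp, "output": out,
                    "method": method, "n_components": n_in
                    if inp.endswith("_syn") else _side_counts(frac, E),
                    "fraction": frac, "cc": cc,
                    "baseline_id": bid, "baseline_cc": baselines[bid],
                    "normalized": 100.0 * cc / baselines[bid],
                    "seed": seed})
    table = pd.DataFrame(rows).sort_values(
        ["model_id", "method", "fraction"]).reset_index(drop=True)
    audits = [eng.audit(amask) for eng in engines.values()]
    return ExperimentResult(
        name="denoising", table=table, baselines=baselines,
        metadata={"seed": seed, "lags": lags, "train_frac": train_frac,
                  "fractions": fractions},
        audits=audits)


# ---------------------------------------------------------------------------
# generalization experiment

def run_generalization(suite: list, methods: tuple = BRAIN_METHODS,
                       component_fractions: tuple = (0.25, 0.5, 1.0),
                       lags: int = DEFAULT_LAGS, train_frac: float = 0.8,
                       seed: int = 0, aligned_len: int = 40,
                       nmf_kwargs: dict | None = None) -> ExperimentResult:
    """On- vs off-context decoding across task contexts.

    ``suite`` is a list of sessions (or (session, truth) pairs) covering
    the normal context plus at least one perturbed context.  Off-context
    models (and their synergy fits) are trained on all normal-context
    bins and tested on each perturbed context's last 20% of trials;
    on-context models are trained on that context's first 80%.
    """
    sessions = {}
    for item in suite:
        sess = item[0] if isinstance(item, tuple) else item
        ctx = sess.trials.context[0]
        sessions[ctx] = sess
    if "normal" not in sessions:
        raise ValueError("suite must contain the normal context")
    non_normal = [c for c in CONTEXTS if c != "normal" and c in sessions]
    if not non_normal:
        raise ValueError("suite must contain at least one perturbed context")

    normal = sessions["normal"]
    has_emg = normal.n_emg_channels > 0
    N, E = normal.n_neural_channels, normal.n_emg_channels
    norm_mask = normal.valid_mask()
    norm_bins = np.flatnonzero(norm_mask)
    fractions = tuple(sorted(set(component_fractions)))
    all_trials = np.arange(len(normal.trials))

    model_ids = [1, 2, 7, 3, 4, 5, 6, 8] if has_emg else [2, 5]

    rows, audits = [], []
    decomp_cache: dict = {}
    engine_cache: dict = {}
    decoder_cache: dict = {}
    splits = {ctx: chronological_split(sessions[ctx].trials, train_frac)
              for ctx in non_normal}

    def get_decomp(scope, kind, method, M):
        """DR fit; scope is 'off' (all normal bins) or a context name
        (that context's first 80% of trials)."""
        key = (scope, kind, method, M)
        if key not in decomp_cache:
            data = "neural" if kind == "brain" else "emg"
            if scope == "off":
                decomp_cache[key] = _fit_dr(normal, data, method, M,
                                            norm_bins, all_trials, seed,
                                            aligned_len, nmf_kwargs)
            else:
                sess = sessions[scope]
                tr_on, _ = splits[scope]
                bins = np.flatnonzero(trial_bin_mask(sess, tr_on))
                decomp_cache[key] = _fit_dr(sess, data, method, M, bins,
                                            tr_on, seed, aligned_len,
                                            nmf_kwargs)
        return decomp_cache[key]

    def feats_for(sess, inp, method, frac, scope):
        muscle_method = method if method in MUSCLE_METHODS else "pca"
        if inp == "brain":
            return sess.neural, ("brain",), N
        if inp == "muscle":
            return sess.emg, ("muscle",), E
        if inp == "brain_syn":
            Mb = _side_counts(frac, N)
            bd = get_decomp(scope, "brain", method, Mb)
            return (dimred.transform(bd, sess.neural),
                    ("brain_syn", method, Mb, scope), Mb)
        Me = _side_counts(frac, E)
        ed = get_decomp(scope, "muscle", muscle_method, Me)
        return (dimred.transform(ed, sess.emg),
                ("muscle_syn", muscle_method, Me, scope), Me)

    def targets_for(sess, out, method, frac, scope):
        if out != "muscle_syn":
            Y, Yev = _outputs_for(sess, out)
            return Y, Yev, None, (out,)
        muscle_method = method if method in MUSCLE_METHODS else "pca"
        Me = _side_counts(frac, E)
        ed = get_decomp(scope, "muscle", muscle_method, Me)
        Y, Yev = _outputs_for(sess, out, ed)
        return Y, Yev, ed, ("muscle_syn", muscle_method, Me, scope)

    def get_engine(label, feats, amask, train_mask, test_mask):
        if label not in engine_cache:
            engine_cache[label] = LaggedRidgeEngine(
                feats, lags, amask, train_mask, test_mask)
            audits.append(engine_cache[label].audit(amask))
        return engine_cache[label]

    def run_model(mid, method, frac, ctx):
        """Return (cc_off, cc_on, n_components)."""
        inp, out = MODEL_TABLE[mid]
        sess = sessions[ctx]
        tr_on, te = splits[ctx]
        on_train_mask = trial_bin_mask(sess, tr_on)
        test_mask = trial_bin_mask(sess, te)

        # ---- off-context: DR + decoder trained on all normal bins
        feats_n, key_in, n_in = feats_for(normal, inp, method, frac, "off")
        eng_norm = get_engine(("normal", key_in), feats_n,
                              normal.artifact_mask, norm_mask, None)
        Y_n, _, _, key_out = targets_for(normal, out, method, frac, "off")
        dkey = (("normal", key_in), key_out)
        if dkey not in decoder_cache:
            decoder_cache[dkey] = eng_norm.fit(Y_n)
        dec_off = decoder_cache[dkey]

        feats_c, key_in_c, _ = feats_for(sess, inp, method, frac, "off")
        eng_ctx = get_engine((ctx, key_in_c), feats_c, sess.artifact_mask,
                             on_train_mask, test_mask)
        Y_c, Yev_c, emg_dec_off, _ = targets_for(sess, out, method, frac,
                                                 "off")
        pred_off = eng_ctx.Xte @ dec_off.weights
        if out == "muscle_syn":
            pred_off = dimred.reconstruct(emg_dec_off, pred_off)
            truth = Yev_c[eng_ctx.test_bins]
        else:
            truth = Y_c[eng_ctx.test_bins]
        cc_off = float(np.mean(pearson_cc(truth, pred_off)))

        # ---- on-context: DR + decoder trained on this context's first 80%
        feats_on, key_on, _ = feats_for(sess, inp, method, frac, ctx)
        eng_on = get_engine((ctx, key_on), feats_on, sess.artifact_mask,
                            on_train_mask, test_mask)
        Y_on, Yev_on, emg_dec_on, key_out_on = targets_for(
            sess, out, method, frac, ctx)
        dkey_on = ((ctx, key_on), key_out_on)
        if dkey_on not in decoder_cache:
            decoder_cache[dkey_on] = eng_on.fit(Y_on)
        dec_on = decoder_cache[dkey_on]
        pred_on = eng_on.predict_test(dec_on)
        if out == "muscle_syn":
            pred_on = dimred.reconstruct(emg_dec_on, pred_on)
            truth_on = Yev_on[eng_on.test_bins]
        else:
            truth_on = Y_on[eng_on.test_bins]
        if not np.array_equal(eng_on.test_bins, eng_ctx.test_bins):
            raise AssertionError("on/off test bins differ")
        cc_on = float(np.mean(pearson_cc(truth_on, pred_on)))
        return cc_off, cc_on, n_in

    baselines: dict = {}
    for ctx in non_normal:
        for mid in model_ids:
            inp, out = MODEL_TABLE[mid]
            if not inp.endswith("_syn") and out != "muscle_syn":
                cc_off, cc_on, n_in = run_model(mid, "full", 1.0, ctx)
                baselines[(ctx, mid)] = {"off": cc_off, "on": cc_on}
                for mode, cc in (("off", cc_off), ("on", cc_on)):
                    rows.append({"context": ctx, "model_id": mid,
                                 "input": inp, "output": out,
                                 "method": "full", "fraction": 1.0,
                                 "n_components": n_in, "mode": mode,
                                 "cc": cc, "baseline_id": mid,
                                 "normalized": 100.0 * cc / cc_off
                                 if cc_off != 0 else np.nan,
                                 "seed": seed})
    for ctx in non_normal:
        for mid in model_ids:
            inp, out = MODEL_TABLE[mid]
            if inp.endswith("_syn") or out == "muscle_syn":
                bid = BASELINE_OF[mid]
                for method in methods:
                    if method == "dpca" and inp != "brain_syn":
                        continue
                    for frac in fractions:
                        cc_off, cc_on, n_in = run_model(mid, method, frac,
                                                        ctx)
                        base_off = baselines[(ctx, bid)]["off"]
                        for mode, cc in (("off", cc_off), ("on", cc_on)):
                            rows.append({
                                "context": ctx, "model_id": mid,
                                "input": inp, "output": out,
                                "method": method, "fraction": frac,
                                "n_components": n_in, "mode": mode,
                                "cc": cc, "baseline_id": bid,
                                "normalized": 100.0 * cc / base_off
                                if base_off != 0 else np.nan,
                                "seed": seed})
    table = pd.DataFrame(rows).sort_values(
        ["context", "model_id", "method", "fraction", "mode"]
    ).reset_index(drop=True)
    summary = (table.groupby(["model_id", "method", "fraction", "mode"],
                             as_index=False)["cc"].mean())
    return ExperimentResult(
        name="generalization", table=table, baselines=baselines,
        metadata={"seed": seed, "lags": lags, "train_frac": train_frac,
                  "contexts": non_normal,
                  "context_average": summary},
        audits=audits)


# ---------------------------------------------------------------------------
# reporting

def make_report(results: dict[str, ExperimentResult], outdir) -> dict:
    """Write every experiment's table as CSV plus a JSON summary.

    Deterministic: re-running on the same inputs produces byte-identical
    files.  Returns the summary dictionary.
    """
    import pathlib

    if not results:
        raise ValueError("no experiment results to report")
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for name, res in sorted(results.items()):
        path = outdir / f"{name}.csv"
        res.table.to_csv(path, index=False, float_format="%.10g")
        entry: dict = {
            "table": path.name,
            "n_rows": int(len(res.table)),
            "audits_pass": all(a.get("train_test_disjoint", True) and
                               a.get("masked_excluded", True)
                               for a in res.audits),
        }
        fits = res.metadata.get("fits")
        if fits:
            entry["compression"] = {
                "|".join(k): {"k1": f.k1, "k2": f.k2, "k3": f.k3,
                              "x95": f.x95, "ratio": f.ratio,
                              "ratio_label": f.ratio_label,
                              "success": f.success}
                for k, f in fits.items()}
        if isinstance(res.baselines, dict) and res.baselines:
            entry["baselines"] = {
                str(k): v for k, v in res.baselines.items()}
        summary[name] = entry
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
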