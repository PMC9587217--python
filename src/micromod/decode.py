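"""Population decoding of image category and module-level shuffle tests.

Spike trains are converted to baseline-normalised rates: spike counts
in 200-ms boxcar windows sliding in 20-ms steps are square-root
transformed (variance-stabilising for sparse counts) and z-scored with
the mean and SD of square-root counts during task baseline periods.

A multinomial logistic-regression classifier with gradient training and
early stopping decodes the image category from the units of one module:
20-fold cross-validation with hold-out trials uniformly spread across
the session, one quarter of each fold's training trials held aside
(fresh random draw, 50 times per fold) to stop training when the
early-stopping loss rises, and feature z-scoring fitted on the
remaining training trials only.  Fold weights are averaged over the
early-stopping draws.

Module-level controls: trial-label shuffling (chance calibration);
shuffle-within (permute hold-out unit identities inside the module --
accuracy survives if units carry similar information) versus
shuffle-across (substitute units from a different module -- accuracy
collapses if modules code differently); and trial-wise response
similarity for distance-matched boundary pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import SpikeTrainSet, TrialTable
from .geometry import BoundaryPairSet

__all__ = [
    "RateTensor",
    "ClassifierResult",
    "transform_rates",
    "train_module_classifier",
    "per_bin_accuracy",
    "trial_shuffle_significance",
    "shuffle_within_accuracy",
    "shuffle_across_accuracy",
    "boundary_response_similarity",
    "BIN_WIDTH",
    "BIN_STEP",
]

logger = logging.getLogger(__name__)

BIN_WIDTH = 0.2
BIN_STEP = 0.02
#: Analysis window relative to image onset; the last bin starts at
#: 1.12 s so the 200-ms windows tile the response period through 1.2 s+.
WINDOW = (-0.2, 1.32)


def bin_starts() -> np.ndarray:
    return np.round(np.arange(WINDOW[0], WINDOW[1] - BIN_WIDTH + 1e-9, BIN_STEP), 10)


def overall_bin_indices(starts: np.ndarray) -> np.ndarray:
    """Every third bin covering the 0.1-1.2 s response period (18 bins)."""
    sel = []
    for k, s in enumerate(starts):
        if s >= 0.1 - 1e-9 and abs((s - 0.1) / BIN_STEP % 3) < 1e-6:
            sel.append(k)
    return np.array(sel)


@dataclass
class RateTensor:
    """Baseline-z-scored square-root rates, trials x units x bins."""

    values: np.ndarray
    counts: np.ndarray
    starts: np.ndarray
    unit_ids: np.ndarray
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def unit_pos(self, unit_ids) -> np.ndarray:
        pos = {u: k for k, u in enumerate(self.unit_ids)}
        missing = [u for u in unit_ids if u not in pos]
        if missing:
            raise KeyError(f"units not in rate tensor (dropped or unknown): {missing}")
        return np.array([pos[u] for u in unit_ids])


def _bin_counts(times: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.searchsorted(times, hi) - np.searchsorted(times, lo)


def transform_rates(spikes: SpikeTrainSet, trials: TrialTable) -> RateTensor:
    """Binned, square-root, baseline-z-scored rates for every trial/unit.

    Baseline statistics are computed per unit from non-overlapping
    200-ms bins tiled over the task's baseline periods; units with zero
    baseline SD (e.g. silent units) are dropped with a warning.
    """
    if not trials.baseline_periods:
        raise ValueError("trial table has no baseline periods")
    starts = bin_starts()
    onsets = trials.trials["onset_s"].to_numpy()
    n_trials, n_bins = onsets.size, starts.size

    base_lo = []
    for b0, b1 in trials.baseline_periods:
        for s in np.arange(b0, b1 - BIN_WIDTH + 1e-9, BIN_WIDTH):
            base_lo.append(s)
    base_lo = np.array(base_lo)
    if base_lo.size < 2:
        raise ValueError("baseline periods too short for baseline statistics")

    kept_vals, kept_counts, kept_ids, kept_mu, kept_sd = [], [], [], [], []
    for u in spikes.unit_ids:
        t = spikes.times_for(u)
        bc = np.sqrt(_bin_counts(t, base_lo, base_lo + BIN_WIDTH))
        mu, sd = bc.mean(), bc.std()
        if sd == 0:
            warnings.warn(f"unit {u}: zero baseline SD; dropped", stacklevel=2)
            continue
        lo = (onsets[:, None] + starts[None, :]).ravel()
        c = _bin_counts(t, lo, lo + BIN_WIDTH).reshape(n_trials, n_bins)
        kept_counts.append(c)
        kept_vals.append((np.sqrt(c) - mu) / sd)
        kept_ids.append(u)
        kept_mu.append(mu)
        kept_sd.append(sd)
    if not kept_ids:
        raise ValueError("no units with usable baseline statistics")
    return RateTensor(
        values=np.stack(kept_vals, axis=1),
        counts=np.stack(kept_counts, axis=1),
        starts=starts,
        unit_ids=np.array(kept_ids),
        baseline_mean=np.array(kept_mu),
        baseline_sd=np.array(kept_sd),
    )


# ---------------------------------------------------------------------------
# softmax classifier with early stopping
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xent(p: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(p[np.arange(y.size), y] + 1e-12)))


def _fit_softmax_es(
    Xtr, ytr, Xes, yes, n_classes, lr=0.5, max_iter=300, check_every=5, patience=3
):
    """Full-batch gradient training stopped when the early-stop loss rises."""
    n, d = Xtr.shape
    W = np.zeros((d, n_classes))
    b = np.zeros(n_classes)
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), ytr] = 1.0
    best = (W.copy(), b.copy())
    best_loss = np.inf
    bad = 0
    for it in range(1, max_iter + 1):
        P = _softmax(Xtr @ W + b)
        G = P - Y
        W -= lr * (Xtr.T @ G) / n
        b -= lr * G.mean(axis=0)
        if it % check_every == 0:
            loss = _xent(_softmax(Xes @ W + b), yes)
            if loss < best_loss - 1e-9:
                best_loss = loss
                best = (W.copy(), b.copy())
                bad = 0
            else:
                bad += 1
                if bad > patience:
                    break
    return best


def _stratified_quarter(y: np.ndarray, pos: np.ndarray, rng) -> np.ndarray:
    """Pick ~1/4 of positions, at least one per class present."""
    es = []
    for c in np.unique(y[pos]):
        cpos = pos[y[pos] == c]
        k = max(1, int(round(cpos.size / 4)))
        es.append(rng.choice(cpos, size=k, replace=False))
    return np.concatenate(es)


def _fit_fold(X, y, train_pos, n_classes, es_draws, rng, shuffle_labels=False, **gd):
    """Average affine (raw-feature) classifier over early-stop draws.

    Per draw: stratified quarter of the training trials becomes the
    early-stop set, z-scoring is fitted on the remaining trials, and the
    trained weights are mapped back to raw-feature space so draws can be
    averaged and later applied to permuted hold-out data.
    """
    y_use = y.copy()
    if shuffle_labels:
        y_use[train_pos] = rng.permutation(y_use[train_pos])
    Wsum = None
    bsum = None
    for _ in range(es_draws):
        es = _stratified_quarter(y_use, train_pos, rng)
        fit_pos = np.setdiff1d(train_pos, es)
        mu = X[fit_pos].mean(axis=0)
        sd = X[fit_pos].std(axis=0)
        sd[sd == 0] = 1.0
        W, b = _fit_softmax_es(
            (X[fit_pos] - mu) / sd,
            y_use[fit_pos],
            (X[es] - mu) / sd,
            y_use[es],
            n_classes,
            **gd,
        )
        Wraw = W / sd[:, None]
        braw = b - mu @ Wraw
        Wsum = Wraw if Wsum is None else Wsum + Wraw
        bsum = braw if bsum is None else bsum + braw
    return Wsum / es_draws, bsum / es_draws


@dataclass
class ClassifierResult:
    """Cross-validated decoding result for one module.

    Holds per-fold affine classifiers in raw-feature space plus the
    feature bookkeeping needed by the shuffle analyses.
    """

    fold_accuracies: np.ndarray
    fold_weights: list
    fold_holdout: list
    unit_subset: np.ndarray
    n_units: int
    n_bins: int
    n_classes: int
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    correct_rows: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    es_draws: int = 50
    seed: int = 0
    gd_params: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def _module_features(rates: RateTensor, unit_pos, bin_idx) -> np.ndarray:
    """Trials x (units * bins) feature matrix, unit-major layout."""
    v = rates.values[:, unit_pos][:, :, bin_idx]
    return v.reshape(v.shape[0], -1)


def train_module_classifier(
    rates: RateTensor,
    trials: TrialTable,
    unit_subset,
    mode: str = "overall",
    bin_index: int | None = None,
    seed: int = 0,
    n_folds: int = 20,
    es_draws: int = 50,
    **gd_params,
) -> ClassifierResult:
    """Cross-validated category decoding from one module's units.

    ``mode="overall"`` concatenates every third bin across the response
    period (predictors = units x 18); ``mode="perbin"`` uses the single
    bin ``bin_index`` (predictors = units).  Only correct trials enter.
    Hold-out sets are every ``n_folds``-th correct trial, so ~5% of
    trials uniformly spread across the session at the default 20 folds.
    """
    unit_subset = np.asarray(list(unit_subset))
    if unit_subset.size < 2:
        raise ValueError("need at least two units in the module")
    correct = np.nonzero(trials.trials["correct"].to_numpy())[0]
    if correct.size < 20:
        raise ValueError("need at least 20 correct trials")
    cats = trials.categories
    cat_map = {c: k for k, c in enumerate(cats)}
    y = np.array([cat_map[c] for c in trials.trials["category"].iloc[correct]])

    if mode == "overall":
        bin_idx = overall_bin_indices(rates.starts)
    elif mode == "perbin":
        if bin_index is None:
            raise ValueError("perbin mode requires bin_index")
        bin_idx = np.array([bin_index])
    else:
        raise ValueError("mode must be 'overall' or 'perbin'")
    unit_pos = rates.unit_pos(unit_subset)
    X = _module_features(rates, unit_pos, bin_idx)[correct]

    rng_root = np.random.SeedSequence(seed).spawn(n_folds)
    accs, weights, holdouts = [], [], []
    all_pos = np.arange(correct.size)
    for k in range(n_folds):
        hold = all_pos[k::n_folds]
        train_pos = np.setdiff1d(all_pos, hold)
        rng = np.random.default_rng(rng_root[k])
        W, b = _fit_fold(X, y, train_pos, len(cats), es_draws, rng, **gd_params)
        pred = np.argmax(X[hold] @ W + b, axis=1)
        accs.append(float(np.mean(pred == y[hold])))
        weights.append((W, b))
        holdouts.append(hold)
    return ClassifierResult(
        fold_accuracies=np.array(accs),
        fold_weights=weights,
        fold_holdout=holdouts,
        unit_subset=unit_subset,
        n_units=unit_subset.size,
        n_bins=bin_idx.size,
        n_classes=len(cats),
        X=X,
        y=y,
        correct_rows=correct,
        es_draws=es_draws,
        seed=seed,
        gd_params=gd_params,
    )


def per_bin_accuracy(
    rates: RateTensor, trials: TrialTable, unit_subset, seed: int = 0, es_draws: int = 10
) -> pd.DataFrame:
    """Decoding-accuracy time course, one classifier per time bin."""
    rows = []
    for k, s in enumerate(rates.starts):
        res = train_module_classifier(
            rates, trials, unit_subset, mode="perbin", bin_index=k, seed=seed, es_draws=es_draws
        )
        rows.append({"bin_start_s": s, "accuracy": res.accuracy})
    return pd.DataFrame(rows)


def trial_shuffle_significance(
    result: ClassifierResult, n_surrogates: int = 1, seed: int = 0
) -> dict:
    """Chance calibration by trial-label shuffling.

    Surrogate classifiers are trained with identical machinery but with
    the category labels of the training and early-stopping trials
    shuffled; hold-out labels stay true.  Significance is a two-tailed
    paired t-test of real vs surrogate accuracy across folds.
    """
    X, y = result.X, result.y
    n_folds = len(result.fold_holdout)
    all_pos = np.arange(X.shape[0])
    sur_accs = np.zeros((n_surrogates, n_folds))
    root = np.random.SeedSequence([seed, result.seed]).spawn(n_surrogates * n_folds)
    for si in range(n_surrogates):
        for k in range(n_folds):
            hold = result.fold_holdout[k]
            train_pos = np.setdiff1d(all_pos, hold)
            rng = np.random.default_rng(root[si * n_folds + k])
            W, b = _fit_fold(
                X, y, train_pos, result.n_classes, result.es_draws, rng,
                shuffle_labels=True, **result.gd_params,
            )
            pred = np.argmax(X[hold] @ W + b, axis=1)
            sur_accs[si, k] = float(np.mean(pred == y[hold]))
    sur_mean = sur_accs.mean(axis=0)
    if np.allclose(result.fold_accuracies - sur_mean, (result.fold_accuracies - sur_mean)[0]):
        # constant difference (degenerate classifier): no evidence either way
        p = 1.0 if np.allclose(result.fold_accuracies, sur_mean) else np.nan
        t = np.nan
    else:
        t, p = stats.ttest_rel(result.fold_accuracies, sur_mean)
    return {
        "p": float(p) if p == p else float("nan"),
        "t": float(t) if t == t else float("nan"),
        "surrogate_fold_accuracies": sur_mean,
        "surrogate_mean": float(sur_accs.mean()),
    }


def _apply_folds_with_units(result: ClassifierResult, unit_source) -> float:
    """Mean fold accuracy when hold-out unit rows are substituted.

    ``unit_source(rng, fold)`` returns a (n_hold, n_units, n_bins) array
    to feed the fold's classifier.
    """
    accs = []
    for k, hold in enumerate(result.fold_holdout):
        W, b = result.fold_weights[k]
        feats = unit_source(k).reshape(hold.size, -1)
        pred = np.argmax(feats @ W + b, axis=1)
        accs.append(float(np.mean(pred == result.y[hold])))
    return float(np.mean(accs))


def shuffle_within_accuracy(
    result: ClassifierResult, n_iter: int = 100, seed: int = 0
) -> float:
    """Accuracy after permuting hold-out unit identities within the module."""
    if result.n_units == 1:
        logger.warning("single-unit module: shuffle-within is the identity")
    rng = np.random.default_rng([seed, 17, result.seed])
    u, nb = result.n_units, result.n_bins
    vals = []
    for _ in range(n_iter):
        perm = rng.permutation(u)

        def source(k, perm=perm):
            hold = result.fold_holdout[k]
            return result.X[hold].reshape(hold.size, u, nb)[:, perm, :]

        vals.append(_apply_folds_with_units(result, source))
    return float(np.mean(vals))


def shuffle_across_accuracy(
    result: ClassifierResult,
    rates: RateTensor,
    other_units,
    n_iter: int = 100,
    seed: int = 0,
) -> float:
    """Accuracy when hold-out data come from a different module's units.

    The classifier (and its z-scoring, folded into the affine weights)
    stays fitted on this module; hold-out features are replaced by units
    of the other module -- subsampled without replacement if the other
    module is larger, resampled with replacement if smaller -- with a
    fresh draw per iteration.
    """
    other_units = np.asarray(list(other_units))
    rng = np.random.default_rng([seed, 29, result.seed])
    u, nb = result.n_units, result.n_bins
    bin_idx = overall_bin_indices(rates.starts) if nb > 1 else None
    if bin_idx is None or bin_idx.size != nb:
        # per-bin classifiers carry a single bin; reconstruct from width
        raise ValueError("shuffle_across_accuracy supports overall-mode results")
    other_pos = rates.unit_pos(other_units)
    other_X = _module_features(rates, other_pos, bin_idx)[result.correct_rows]
    other_X = other_X.reshape(-1, other_pos.size, nb)
    vals = []
    for _ in range(n_iter):
        if other_pos.size >= u:
            pick = rng.choice(other_pos.size, size=u, replace=False)
        else:
            pick = rng.choice(other_pos.size, size=u, replace=True)

        def source(k, pick=pick):
            hold = result.fold_holdout[k]
            return other_X[hold][:, pick, :]

        vals.append(_apply_folds_with_units(result, source))
    return float(np.mean(vals))


def boundary_response_similarity(
    rates: RateTensor,
    units: pd.DataFrame,
    pairs: BoundaryPairSet,
    trials: TrialTable,
    min_trial_frac: float = 0.5,
) -> dict:
    """Trial-wise response correlation for distance-matched boundary pairs.

    For each qualifying unit pair (one unit on a boundary electrode, one
    on its inside or outside lattice neighbour), the Pearson correlation
    of their binned response time courses (bins starting at >= 0 s) is
    computed per correct trial and averaged.  Units must have spiked in
    at least ``min_trial_frac`` of the correct trials.  Returns
    per-module mean within- and across-boundary similarity.
    """
    correct = np.nonzero(trials.trials["correct"].to_numpy())[0]
    resp = rates.starts >= -1e-9
    present = {int(r.unit_id): int(r.electrode) for r in units.itertuples()}
    by_elec: dict[int, list[int]] = {}
    fired = {}
    for u, e in present.items():
        try:
            p = rates.unit_pos([u])[0]
        except KeyError:
            continue
        frac = np.mean(rates.counts[correct, p, :].sum(axis=1) > 0)
        if frac >= min_trial_frac:
            by_elec.setdefault(e, []).append(p)
            fired[p] = frac

    def pair_sim(p1: int, p2: int) -> float:
        a = rates.values[correct][:, p1, resp]
        b = rates.values[correct][:, p2, resp]
        rs = []
        for t in range(a.shape[0]):
            if a[t].std() == 0 or b[t].std() == 0:
                continue
            rs.append(np.corrcoef(a[t], b[t])[0, 1])
        return float(np.mean(rs)) if rs else np.nan

    out = {"per_module": {}, "within": [], "across": []}
    for m in pairs.inside:
        sims_in, sims_out = [], []
        for eb, en in pairs.inside[m]:
            for p1 in by_elec.get(eb, []):
                for p2 in by_elec.get(en, []):
                    s = pair_sim(p1, p2)
                    if s == s:
                        sims_in.append(s)
        for eb, en in pairs.outside[m]:
            for p1 in by_elec.get(eb, []):
                for p2 in by_elec.get(en, []):
                    s = pair_sim(p1, p2)
                    if s == s:
                        sims_out.append(s)
        if not sims_in or not sims_out:
            logger.info("module %s: no qualifying boundary unit pairs; excluded", m)
            continue
        wm, am = float(np.mean(sims_in)), float(np.mean(sims_out))
        out["per_module"][m] = (wm, am)
        out["within"].append(wm)
        out["across"].append(am)
    out["within_mean"] = float(np.mean(out["within"])) if out["within"] else np.nan
    out["across_mean"] = float(np.mean(out["across"])) if out["across"] else np.nan
    return out
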