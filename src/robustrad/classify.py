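"""Selection-bias-free nested cross-validated classification.

Four feature-selection methods (univariate AUC filtering, ReliefF with a
permutation null, L1-penalized multinomial logistic regression, greedy
backward elimination) combined with four classifiers (LDA, k-NN, RBF
SVM, small feed-forward neural network) inside repeated stratified
5-fold cross-validation. Every selector × classifier pair consumes the
identical pre-drawn fold plan, selection and hyperparameter tuning see
only the training folds of each split, and the held-out fold is scored
on the binary malignant-vs-benign task (sensitivity = malignant recall,
specificity = benign recall).

Selection operates on the three tumor classes (adenoma / Warthin /
malignant) while evaluation is binary — the class structure carries
information the binary labels collapse.

The module also provides the non-nested ("biased") protocol — selection
once on the full data set before cross-validation — solely to quantify
the optimism this shortcut induces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SELECTOR_NAMES = ("auc", "relieff", "lasso", "backward")
CLASSIFIER_NAMES = ("lda", "knn", "svm", "nnet")

AUC_THRESHOLD_DEFAULT = 0.8
RELIEFF_K_DEFAULT = 10
RELIEFF_PERMUTATIONS_DEFAULT = 500
BACKWARD_MAX_START_DEFAULT = 30

#: hyperparameter grids searched by inner cross-validation
CLASSIFIER_GRIDS: dict[str, list[dict]] = {
    "lda": [{}],
    "knn": [{"n_neighbors": k} for k in (3, 5, 7, 9, 11)],
    "svm": [{"C": c} for c in (0.25, 0.5, 1.0, 2.0, 4.0)],
    "nnet": [
        {"hidden_layer_sizes": (h,), "alpha": a}
        for h in (1, 3, 5)
        for a in (0.0, 0.01, 0.1)
    ],
}


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Pre-drawn fold assignments shared by every selector × classifier pair."""

    assignments: np.ndarray  # (repetitions, n_samples) fold index in 0..k-1
    k: int
    seed: int

    @property
    def repetitions(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_samples(self) -> int:
        return self.assignments.shape[1]

    def split(self, rep: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, test_indices) of one repetition/fold."""
        test = np.nonzero(self.assignments[rep] == fold)[0]
        train = np.nonzero(self.assignments[rep] != fold)[0]
        return train, test


def make_fold_plan(labels, k: int = 5, repetitions: int = 100, seed: int = 0) -> FoldPlan:
    """Stratified fold plan: per repetition, a shuffled stratified k-fold
    partition of the cohort. Deterministic given ``seed``."""
    y = np.asarray(labels)
    n = y.size
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    _, counts = np.unique(y, return_counts=True)
    stratify = True
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} < k={k} members; "
            "falling back to unstratified folds",
            stacklevel=2,
        )
        stratify = False
    assignments = np.empty((repetitions, n), dtype=np.int8)
    for rep in range(repetitions):
        rep_seed = _child_seed(seed, rep)
        if stratify:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            splits = splitter.split(np.zeros((n, 1)), y)
        else:
            rng = np.random.default_rng(rep_seed)
            perm = rng.permutation(n)
            splits = ((None, perm[i::k]) for i in range(k))
        for fold, (_, test) in enumerate(splits):
            assignments[rep, test] = fold
    return FoldPlan(assignments=assignments, k=k, seed=int(seed))


# ---------------------------------------------------------------------------
# univariate AUC selection
# ---------------------------------------------------------------------------

def pairwise_auc_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature mean one-vs-one AUC over all class pairs.

    Each pairwise AUC is orientation-corrected (max(AUC, 1-AUC)); a
    constant feature scores 0.5.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    scores = np.zeros(X.shape[1])
    n_pairs = 0
    for a in range(classes.size):
        for b in range(a + 1, classes.size):
            sel = (y == classes[a]) | (y == classes[b])
            ya = y[sel] == classes[a]
            na, nb = int(ya.sum()), int((~ya).sum())
            ranks = stats.rankdata(X[sel], axis=0)
            ra = ranks[ya].sum(axis=0)
            auc = (ra - na * (na + 1) / 2) / (na * nb)
            scores += np.maximum(auc, 1 - auc)
            n_pairs += 1
    return scores / n_pairs


def select_auc(X, y3, threshold: float = AUC_THRESHOLD_DEFAULT):
    """Keep features whose mean one-vs-one AUC strictly exceeds ``threshold``."""
    scores = pairwise_auc_scores(X, y3)
    selected = np.nonzero(scores > threshold)[0]
    return selected, scores


# ---------------------------------------------------------------------------
# ReliefF with per-feature permutation null
# ---------------------------------------------------------------------------

def _relieff_machinery(X: np.ndarray):
    """Range-normalized features, per-pair feature differences and the
    Manhattan distance matrix (label-independent, so shareable across
    label permutations)."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    Z = (X - lo) / rng_
    fdiff = np.abs(Z[:, None, :] - Z[None, :, :])
    D = fdiff.sum(axis=2)
    np.fill_diagonal(D, np.inf)
    return fdiff, D


def _relieff_pair_weights(D: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Neighbour-pair weight matrix A with W[f] = sum_ij A_ij |z_if - z_jf|."""
    n = y.size
    classes, counts = np.unique(y, return_counts=True)
    prior = counts / n
    A = np.zeros((n, n))
    for ci, c in enumerate(classes):
        members = np.nonzero(y == c)[0]
        order = members[np.argsort(D[:, members], axis=1)]
        # hits: same-class neighbours (self excluded via inf diagonal)
        rows = members
        k_hit = min(k, members.size - 1)
        if k_hit > 0:
            cols = order[rows, :k_hit]
            np.add.at(A, (rows[:, None], cols), -1.0 / (n * k_hit))
        # misses: neighbours of class c for samples of other classes
        rows = np.nonzero(y != c)[0]
        k_miss = min(k, members.size)
        if rows.size and k_miss > 0:
            cols = order[rows, :k_miss]
            w = prior[ci] / (1.0 - prior[np.searchsorted(classes, y[rows])])
            np.add.at(A, (rows[:, None], cols), (w / (n * k_miss))[:, None])
    return A


def relieff_weights(X, y, k: int = RELIEFF_K_DEFAULT) -> np.ndarray:
    """Multi-class ReliefF feature weights (all samples, k neighbours,
    misses weighted by class prior)."""
    fdiff, D = _relieff_machinery(X)
    A = _relieff_pair_weights(D, np.asarray(y), k)
    return np.einsum("ij,ijf->f", A, fdiff)


def select_relieff(
    X,
    y3,
    n_permutations: int = RELIEFF_PERMUTATIONS_DEFAULT,
    k: int = RELIEFF_K_DEFAULT,
    seed: int = 0,
    percentile: float = 95.0,
):
    """Keep features whose ReliefF weight exceeds the ``percentile`` of the
    feature's own label-permutation null distribution."""
    if n_permutations < 20:
        raise ValueError("n_permutations < 20 makes the null percentile unstable")
    y3 = np.asarray(y3)
    if np.unique(y3).size < 2:
        raise ValueError("all labels identical")
    fdiff, D = _relieff_machinery(X)
    A = _relieff_pair_weights(D, y3, k)
    observed = np.einsum("ij,ijf->f", A, fdiff)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, observed.size))
    for p in range(n_permutations):
        yp = rng.permutation(y3)
        Ap = _relieff_pair_weights(D, yp, k)
        null[p] = np.einsum("ij,ijf->f", Ap, fdiff)
    cutoff = np.percentile(null, percentile, axis=0)
    selected = np.nonzero(observed > cutoff)[0]
    return selected, observed


# ---------------------------------------------------------------------------
# LASSO (L1 multinomial logistic) selection
# ---------------------------------------------------------------------------

def select_lasso(X, y3, seed: int = 0, Cs=None, inner_k: int = 3):
    """Features with a non-zero coefficient in an L1-penalized multinomial
    logistic fit, the penalty chosen by inner cross-validation.

    Features are standardized on the given (training) data. If the chosen
    penalty zeroes everything, the single feature with the largest
    coefficient magnitude on the weakest penalty is returned (flagged).
    """
    X = np.asarray(X, dtype=float)
    y3 = np.asarray(y3)
    if Cs is None:
        Cs = np.logspace(-2, 1, 7)
    Z = StandardScaler().fit_transform(X)
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegressionCV(
            Cs=Cs, cv=inner, penalty="l1", solver="saga", max_iter=3000,
            tol=1e-3, random_state=seed, n_jobs=1,
        ).fit(Z, y3)
    mags = np.abs(model.coef_).max(axis=0)
    selected = np.nonzero(mags > 1e-8)[0]
    if selected.size == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loose = LogisticRegression(
                C=float(np.max(Cs)), penalty="l1", solver="saga",
                max_iter=3000, tol=1e-3, random_state=seed,
            ).fit(Z, y3)
        mags = np.abs(loose.coef_).max(axis=0)
        selected = np.array([int(np.argmax(mags))])
    return selected, mags


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

def _fast_lda_cv_accuracy(X: np.ndarray, y_codes: np.ndarray, folds) -> float:
    """Inner-CV accuracy of a ridge-stabilized linear discriminant.

    A minimal LDA (class means, pooled covariance + small ridge, linear
    scores) — sklearn-free to keep the quadratic backward search cheap.
    """
    correct = 0
    total = 0
    n_classes = y_codes.max() + 1
    for train, test in folds:
        Xtr, ytr = X[train], y_codes[train]
        mu = np.stack([Xtr[ytr == c].mean(axis=0) for c in range(n_classes)])
        centered = Xtr - mu[ytr]
        cov = centered.T @ centered / max(len(train) - n_classes, 1)
        cov.flat[:: cov.shape[0] + 1] += 1e-4 * max(np.trace(cov) / cov.shape[0], 1e-12)
        prec_mu = np.linalg.solve(cov, mu.T).T
        prior = np.bincount(ytr, minlength=n_classes) / len(train)
        prior = np.log(np.clip(prior, 1e-12, None))
        scores = X[test] @ prec_mu.T - 0.5 * np.einsum("cf,cf->c", mu, prec_mu) + prior
        correct += int((scores.argmax(axis=1) == y_codes[test]).sum())
        total += len(test)
    return correct / total


def select_backward(
    X,
    y3,
    seed: int = 0,
    max_start_features: int = BACKWARD_MAX_START_DEFAULT,
    inner_k: int = 3,
    inner_repeats: int = 5,
):
    """Greedy backward elimination on inner-CV accuracy.

    Starts from the top ``max_start_features`` features by univariate AUC
    ranking, then repeatedly drops the feature whose removal maximizes the
    repeated inner-CV accuracy of a linear discriminant, while no removal
    makes it worse. Ties between equally good removals are broken by
    dropping the feature with the weakest univariate AUC (then by feature
    order), so strongly informative features survive accuracy plateaus.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y3 = np.asarray(y3)
    p = X.shape[1]
    if p < 2:
        return np.arange(p), np.zeros(p)
    scores = pairwise_auc_scores(X, y3)
    order = np.argsort(-scores, kind="stable")
    current = sorted(order[: min(p, max_start_features)].tolist())
    prescreen_rank = np.empty(p, dtype=int)  # 0 = strongest feature
    prescreen_rank[order] = np.arange(p)

    _, y_codes = np.unique(y3, return_inverse=True)
    Z = StandardScaler().fit_transform(X)
    folds = []
    for r in range(inner_repeats):
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed + r)
        folds.extend(inner.split(Z, y_codes))

    best_acc = _fast_lda_cv_accuracy(Z[:, current], y_codes, folds)
    while len(current) > 1:
        accs = [
            _fast_lda_cv_accuracy(Z[:, current[:i] + current[i + 1 :]], y_codes, folds)
            for i in range(len(current))
        ]
        mx = max(accs)
        if mx < best_acc:
            break
        tied = [i for i, a in enumerate(accs) if a == mx]
        i_drop = max(tied, key=lambda i: prescreen_rank[current[i]])
        best_acc = mx
        current.pop(i_drop)
    return np.array(current), scores


# ---------------------------------------------------------------------------
# classifiers and nested evaluation
# ---------------------------------------------------------------------------

def _make_classifier(name: str, params: dict, seed: int, n_train: int | None = None):
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "knn":
        params = dict(params)
        if n_train is not None:  # tiny training folds: clamp k
            params["n_neighbors"] = min(params["n_neighbors"], n_train)
        return KNeighborsClassifier(**params)
    if name == "svm":
        return SVC(kernel="rbf", gamma="scale", **params)
    if name == "nnet":
        return MLPClassifier(
            solver="lbfgs", max_iter=300, random_state=seed, **params
        )
    raise ValueError(f"unknown classifier {name!r}")


def _tune_and_fit(name: str, X_tr: np.ndarray, y_tr: np.ndarray, seed: int, inner_k: int = 3):
    """Grid search by inner stratified CV accuracy (tie -> first grid entry),
    then refit the winning configuration on the full training fold."""
    grid = CLASSIFIER_GRIDS[name]
    best_params = grid[0]
    if len(grid) > 1:
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
        folds = list(inner.split(X_tr, y_tr))
        best_acc = -1.0
        for params in grid:
            correct = total = 0
            for tr, te in folds:
                clf = _make_classifier(name, params, seed, n_train=len(tr))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X_tr[tr], y_tr[tr])
                correct += int((clf.predict(X_tr[te]) == y_tr[te]).sum())
                total += len(te)
            acc = correct / total
            if acc > best_acc:
                best_acc, best_params = acc, params
    clf = _make_classifier(name, best_params, seed, n_train=len(X_tr))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_tr, y_tr)
    return clf, best_params


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); recall of an absent class is NaN."""
    acc = float((y_true == y_pred).mean())
    pos = y_true == 1
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    neg = ~pos
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else np.nan
    return acc, sens, spec


def _run_selector(name: str, X_tr, y3_tr, seed: int, params: dict) -> np.ndarray:
    if name == "auc":
        sel, scores = select_auc(X_tr, y3_tr, **params)
        if sel.size == 0:
            sel = np.array([int(np.argmax(scores))])  # fallback: top-ranked feature
    elif name == "relieff":
        sel, scores = select_relieff(X_tr, y3_tr, seed=seed, **params)
        if sel.size == 0:
            sel = np.array([int(np.argmax(scores))])
    elif name == "lasso":
        sel, _ = select_lasso(X_tr, y3_tr, seed=seed, **params)
    elif name == "backward":
        sel, _ = select_backward(X_tr, y3_tr, seed=seed, **params)
    else:
        raise ValueError(f"unknown selector {name!r}")
    return sel


@dataclass
class NestedCVResult:
    """Per-fold scores, aggregated performance and selection frequencies."""

    records: pd.DataFrame        # selector, classifier, rep, fold, metrics
    performance: pd.DataFrame    # selector, classifier, metric, mean, p5, p95
    selection_frequency: pd.DataFrame  # selector, feature, frequency
    n_skipped_folds: int = 0


def _aggregate(records: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (sel, clf), grp in records.groupby(["selector", "classifier"], sort=False):
        for metric in ("accuracy", "sensitivity", "specificity"):
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rows.append({
                "selector": sel, "classifier": clf, "metric": metric,
                "mean": vals.mean() if vals.size else np.nan,
                "p5": np.percentile(vals, 5) if vals.size else np.nan,
                "p95": np.percentile(vals, 95) if vals.size else np.nan,
            })
    return pd.DataFrame(rows)


def run_nested_cv(
    X,
    y2,
    y3,
    fold_plan: FoldPlan,
    selectors=SELECTOR_NAMES,
    classifiers=CLASSIFIER_NAMES,
    seed: int = 0,
    selector_params: dict | None = None,
    feature_names=None,
) -> NestedCVResult:
    """The full nested protocol: per fold, selection on the training rows
    (3-class labels), hyperparameter tuning by inner CV, evaluation of the
    held-out fold on the binary task. All pairs share the fold plan."""
    X = np.asarray(X, dtype=float)
    y2 = np.asarray(y2, dtype=int)
    y3 = np.asarray(y3)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    feature_names = list(feature_names)
    selector_params = selector_params or {}

    recs = []
    sel_counts = {s: np.zeros(X.shape[1]) for s in selectors}
    n_folds_done = 0
    n_skipped = 0
    for rep in range(fold_plan.repetitions):
        for fold in range(fold_plan.k):
            train, test = fold_plan.split(rep, fold)
            if np.unique(y2[train]).size < 2:
                n_skipped += 1
                continue
            fold_seed = _child_seed(fold_plan.seed, rep, fold)
            n_folds_done += 1
            for sel_name in selectors:
                sel = _run_selector(
                    sel_name, X[train], y3[train], fold_seed,
                    selector_params.get(sel_name, {}),
                )
                sel_counts[sel_name][sel] += 1
                scaler = StandardScaler().fit(X[np.ix_(train, sel)])
                Xtr = scaler.transform(X[np.ix_(train, sel)])
                Xte = scaler.transform(X[np.ix_(test, sel)])
                for clf_name in classifiers:
                    clf, _ = _tune_and_fit(clf_name, Xtr, y2[train], fold_seed)
                    acc, sens, spec = _binary_metrics(y2[test], clf.predict(Xte))
                    recs.append({
                        "selector": sel_name, "classifier": clf_name,
                        "rep": rep, "fold": fold, "accuracy": acc,
                        "sensitivity": sens, "specificity": spec,
                        "n_selected": int(sel.size),
                    })
    records = pd.DataFrame(recs)
    freq_rows = [
        {"selector": s, "feature": feature_names[i],
         "frequency": sel_counts[s][i] / max(n_folds_done, 1)}
        for s in selectors
        for i in range(X.shape[1])
        if sel_counts[s][i] > 0
    ]
    return NestedCVResult(
        records=records,
        performance=_aggregate(records),
        selection_frequency=pd.DataFrame(
            freq_rows, columns=["selector", "feature", "frequency"]
        ),
        n_skipped_folds=n_skipped,
    )


def run_naive_cv(
    X,
    y2,
    y3,
    fold_plan: FoldPlan,
    selectors=("auc",),
    classifiers=("lda",),
    seed: int = 0,
    selector_params: dict | None = None,
) -> NestedCVResult:
    """The biased protocol: selection once on ALL rows, then cross-validation
    restricted to the pre-selected features. Provided only to measure the
    selection-bias optimism the nested protocol avoids."""
    X = np.asarray(X, dtype=float)
    y2 = np.asarray(y2, dtype=int)
    y3 = np.asarray(y3)
    selector_params = selector_params or {}
    recs = []
    for sel_name in selectors:
        sel = _run_selector(
            sel_name, X, y3, _child_seed(seed, 0), selector_params.get(sel_name, {})
        )
        for rep in range(fold_plan.repetitions):
            for fold in range(fold_plan.k):
                train, test = fold_plan.split(rep, fold)
                if np.unique(y2[train]).size < 2:
                    continue
                fold_seed = _child_seed(fold_plan.seed, rep, fold)
                scaler = StandardScaler().fit(X[np.ix_(train, sel)])
                Xtr = scaler.transform(X[np.ix_(train, sel)])
                Xte = scaler.transform(X[np.ix_(test, sel)])
                for clf_name in classifiers:
                    clf, _ = _tune_and_fit(clf_name, Xtr, y2[train], fold_seed)
                    acc, sens, spec = _binary_metrics(y2[test], clf.predict(Xte))
                    recs.append({
                        "selector": sel_name, "classifier": clf_name,
                        "rep": rep, "fold": fold, "accuracy": acc,
                        "sensitivity": sens, "specificity": spec,
                        "n_selected": int(sel.size),
                    })
    records = pd.DataFrame(recs)
    return NestedCVResult(
        records=records,
        performance=_aggregate(records),
        selection_frequency=pd.DataFrame(
            columns=["selector", "feature", "frequency"]
        ),
    )
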