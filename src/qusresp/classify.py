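"""Imbalance-corrected feature selection and response classification.

The prediction protocol mirrors the clinical analysis: (1) the majority
class is repeatedly down-sampled to the minority size until every
majority patient has appeared in at least one balanced set; (2) within a
balanced set, features are ranked by univariate p-value and a sequential
floating forward selection (SFFS, capped at 5 features) maximizes a
validation-AUC criterion; (3) a single-hidden-layer neural network
(hidden size tuned over 1-10 nodes on the validation split) or a KNN
comparator (k tuned over {1,3,5,7,9}) is trained on stratified
70/15/15 train/validation/test splits, repeated over 10 bootstrap
re-splits; (4) test-set sensitivity, specificity, accuracy and AUC are
averaged per balanced set and reported as mean +/- SD across sets.

`TunedShallowANN`, `TunedKNN` and `SFFSSelector` follow the scikit-learn
estimator API and compose with sklearn pipelines; the module-level
functions are thin orchestration over them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from ._seeding import child_rng, child_seed
from .feature_stats import univariate_rank

__all__ = [
    "GroupingScheme", "SCHEMES", "BalancedSet", "SelectionResult",
    "TunedShallowANN", "TunedKNN", "SFFSSelector",
    "make_balanced_sets", "sffs_select", "train_eval_ann", "train_eval_knn",
    "compile_report", "run_classification", "report_to_json",
]


# ---------------------------------------------------------------------------
# Outcome grouping schemes

@dataclass(frozen=True)
class GroupingScheme:
    """Binary outcome definition over MR scores (1-5) or survival.

    Responder groupings: R = MR 3-5 vs NR2 = MR 1-2 (binary scheme);
    in the three-class scheme CR = MR 4-5, PR = MR 2-3, NR3 = MR 1,
    combined pairwise.  ``subset`` restricts which patients enter.
    """

    name: str
    positive: str       # description of label 1
    label_column: str = "mr_score"

    def labels(self, table: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
        """(binary labels, boolean inclusion mask) for a patient table."""
        if self.name == "survival":
            y = table["recurrence_free_5yr"].to_numpy(int)
            return y, np.ones(len(table), dtype=bool)
        mr = table["mr_score"].to_numpy(int)
        if self.name == "R_vs_NR2":
            return (mr >= 3).astype(int), np.ones(len(mr), bool)
        if self.name == "CR_vs_PRNR3":
            return (mr >= 4).astype(int), np.ones(len(mr), bool)
        if self.name == "CRPR_vs_NR3":
            return (mr >= 2).astype(int), np.ones(len(mr), bool)
        if self.name == "PR_vs_NR3":
            return (mr >= 2).astype(int), mr <= 3
        raise ValueError(f"unknown grouping scheme {self.name!r}")


SCHEMES: Dict[str, GroupingScheme] = {
    "R_vs_NR2": GroupingScheme("R_vs_NR2", "responder (MR 3-5)"),
    "CR_vs_PRNR3": GroupingScheme("CR_vs_PRNR3", "complete responder (MR 4-5)"),
    "CRPR_vs_NR3": GroupingScheme("CRPR_vs_NR3", "any response (MR 2-5)"),
    "PR_vs_NR3": GroupingScheme("PR_vs_NR3", "partial responder (MR 2-3)"),
    "survival": GroupingScheme("survival", "5-year recurrence-free",
                               label_column="recurrence_free_5yr"),
}


# ---------------------------------------------------------------------------
# Class balancing by majority down-sampling

@dataclass
class BalancedSet:
    indices: np.ndarray     # positions into the label vector
    set_id: int
    seed: int


def make_balanced_sets(labels: Sequence[int], seed: int = 0,
                       minority_label: Optional[int] = None,
                       max_sets: int = 10000) -> List[BalancedSet]:
    """Down-sample the majority class until every patient is covered.

    Each set contains all minority patients plus a uniform draw of
    minority-size patients from the majority (without replacement within
    a set, with replacement across sets).  Sets are generated until every
    majority patient has appeared at least once.  With equal class sizes
    a single set containing everyone is returned.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    min_cls = classes[np.argmin(counts)]
    if minority_label is not None and minority_label != min_cls:
        warnings.warn("designated minority class is the larger one; "
                      "classes swapped", stacklevel=2)
        min_cls = classes[np.argmin(counts)]
    maj_cls = classes[0] if classes[1] == min_cls else classes[1]
    min_idx = np.flatnonzero(y == min_cls)
    maj_idx = np.flatnonzero(y == maj_cls)
    n_min = len(min_idx)
    rng = child_rng(seed, "balance")
    uncovered = set(maj_idx.tolist())
    sets: List[BalancedSet] = []
    while uncovered and len(sets) < max_sets:
        draw = rng.choice(maj_idx, size=n_min, replace=False)
        uncovered.difference_update(draw.tolist())
        idx = np.concatenate([min_idx, draw])
        sets.append(BalancedSet(indices=np.sort(idx), set_id=len(sets),
                                seed=seed))
    return sets


# ---------------------------------------------------------------------------
# Split protocol

def stratified_70_15_15(y: np.ndarray, random_state: int,
                        max_retries: int = 100):
    """Stratified 70/15/15 split with a class-presence verification.

    Stratification satisfies the presence requirement constructively for
    feasible class counts; a resample fallback is retained for the corner
    cases where it cannot.
    """
    n = len(y)
    idx = np.arange(n)
    for attempt in range(max_retries):
        rs = random_state + attempt
        try:
            rest, test = train_test_split(
                idx, test_size=0.15, random_state=rs,
                stratify=y if attempt < max_retries // 2 else None)
            train, val = train_test_split(
                rest, test_size=0.15 / 0.85, random_state=rs,
                stratify=y[rest] if attempt < max_retries // 2 else None)
        except ValueError:
            continue
        parts = (train, val, test)
        if all(len(np.unique(y[p])) == 2 for p in parts):
            return parts
    raise ValueError("could not produce a split with both classes in "
                     "every part")


def _check_finite(X: pd.DataFrame) -> None:
    for col in X.columns:
        if not np.all(np.isfinite(X[col].to_numpy(dtype=float))):
            raise ValueError(f"feature {col!r} contains non-finite values")


# ---------------------------------------------------------------------------
# Tuned classifiers (scikit-learn estimator API)

class TunedShallowANN(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer neural network with hidden-size tuning.

    Sigmoidal hidden units, logistic output and cross-entropy loss,
    trained to tolerance by L-BFGS; the hidden-layer size is chosen over
    ``hidden_range`` by AUC on a validation split (passed explicitly to
    :meth:`fit` or carved from the training data).  Features are
    standardized by the training-split mean/SD only.
    """

    def __init__(self, hidden_range=(1, 10), max_iter=300, tol=1e-4,
                 val_fraction=0.18, random_state=0):
        self.hidden_range = hidden_range
        self.max_iter = max_iter
        self.tol = tol
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X_val is None:
            X, X_val, y, y_val = train_test_split(
                X, y, test_size=self.val_fraction,
                random_state=self.random_state, stratify=y)
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=int)
        if len(np.unique(y_val)) < 2:
            raise ValueError("validation part must contain both classes")
        self.classes_ = np.unique(y)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        Xv = self.scaler_.transform(X_val)
        best = (-np.inf, None, None)
        lo, hi = self.hidden_range
        for h in range(lo, hi + 1):
            net = MLPClassifier(hidden_layer_sizes=(h,),
                                activation="logistic", solver="lbfgs",
                                max_iter=self.max_iter, tol=self.tol,
                                random_state=self.random_state)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net.fit(Xs, y)
            scores = net.predict_proba(Xv)[:, 1]
            auc = roc_auc_score(y_val, scores)
            if auc > best[0]:
                best = (auc, h, net)
        self.val_auc_, self.best_hidden_size_, self.model_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self.scaler_.transform(
            np.asarray(X, dtype=float)))

    def predict(self, X):
        return self.classes_[
            (self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def decision_scores(self, X):
        return self.predict_proba(X)[:, 1]


class TunedKNN(ClassifierMixin, BaseEstimator):
    """K-nearest-neighbour comparator with k tuned by validation AUC.

    Euclidean distance on standardized features; the AUC score is the
    neighbour vote fraction.
    """

    def __init__(self, ks=(1, 3, 5, 7, 9), val_fraction=0.18,
                 random_state=0):
        self.ks = ks
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X_val is None:
            X, X_val, y, y_val = train_test_split(
                X, y, test_size=self.val_fraction,
                random_state=self.random_state, stratify=y)
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=int)
        if len(np.unique(y_val)) < 2:
            raise ValueError("validation part must contain both classes")
        self.classes_ = np.unique(y)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        Xv = self.scaler_.transform(X_val)
        best = (-np.inf, None, None)
        for k in self.ks:
            if k > len(y):
                continue
            knn = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
            knn.fit(Xs, y)
            auc = roc_auc_score(y_val, knn.predict_proba(Xv)[:, 1])
            if auc > best[0]:
                best = (auc, k, knn)
        self.val_auc_, self.best_k_, self.model_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self.scaler_.transform(
            np.asarray(X, dtype=float)))

    def predict(self, X):
        return self.classes_[
            (self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def decision_scores(self, X):
        return self.predict_proba(X)[:, 1]


def _make_model(model: str, random_state: int):
    if isinstance(model, BaseEstimator):
        est = clone(model)
        est.set_params(random_state=random_state)
        return est
    if model == "ann":
        return TunedShallowANN(random_state=random_state)
    if model == "knn":
        return TunedKNN(random_state=random_state)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Metrics

def _test_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                  scores: np.ndarray) -> Dict[str, float]:
    """Sensitivity/specificity/accuracy in percent, trapezoidal AUC.

    Sensitivity = TP / positives, specificity = TN / negatives,
    accuracy = correct / total; positives are label 1 (responders).
    """
    pos = y_true == 1
    neg = ~pos
    tp = int(np.sum(pos & (y_pred == 1)))
    tn = int(np.sum(neg & (y_pred == 0)))
    sens = 100.0 * tp / max(pos.sum(), 1)
    spec = 100.0 * tn / max(neg.sum(), 1)
    acc = 100.0 * float(np.mean(y_pred == y_true))
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    else:       # degenerate test part (prevented by split verification)
        auc = float("nan")
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "auc": auc}


def _train_eval(table: pd.DataFrame, labels: Sequence[int],
                features: Sequence[str], seed: int, model: str = "ann",
                n_bootstrap: int = 10) -> pd.DataFrame:
    """The full split/tune/test protocol on one (balanced) sample.

    Returns one row of test metrics per bootstrap re-split.
    """
    X_df = table[list(features)]
    _check_finite(X_df)
    X = X_df.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 samples per class")
    rows = []
    for b in range(n_bootstrap):
        rs = child_seed(seed, "split", b)
        train, val, test = stratified_70_15_15(y, random_state=rs)
        est = _make_model(model, random_state=rs)
        est.fit(X[train], y[train], X_val=X[val], y_val=y[val])
        m = _test_metrics(y[test], est.predict(X[test]),
                          est.decision_scores(X[test]))
        m["bootstrap"] = b
        if hasattr(est, "best_hidden_size_"):
            m["hidden_size"] = est.best_hidden_size_
        if hasattr(est, "best_k_"):
            m["k"] = est.best_k_
        rows.append(m)
    return pd.DataFrame(rows)


def train_eval_ann(table, labels, features, seed=0, n_bootstrap=10):
    """ANN protocol: per-bootstrap test metrics (DataFrame)."""
    return _train_eval(table, labels, features, seed, "ann", n_bootstrap)


def train_eval_knn(table, labels, features, seed=0, n_bootstrap=10):
    """KNN comparator under the identical protocol."""
    return _train_eval(table, labels, features, seed, "knn", n_bootstrap)


# ---------------------------------------------------------------------------
# Sequential floating forward selection

@dataclass
class SelectionResult:
    chosen_features: List[str]
    criterion: float
    criterion_trace: List[dict] = field(default_factory=list)


def evaluate_subset(table: pd.DataFrame, labels: Sequence[int],
                    subset: Sequence[str], seed: int = 0,
                    model: str = "ann", n_splits: int = 3) -> float:
    """The SFFS criterion for an arbitrary feature subset.

    Validation AUC of the configured classifier averaged over the fixed
    inner splits; identical to the value the floating search optimizes,
    so alternative search strategies can be compared against it.
    """
    y = np.asarray(labels, dtype=int)
    X = table[list(subset)].to_numpy(dtype=float)
    splits = [stratified_70_15_15(y, random_state=child_seed(seed, "sffs", s))
              for s in range(n_splits)]
    aucs = []
    for s, (train, val, _test) in enumerate(splits):
        est = _make_model(model, random_state=child_seed(seed, "sffs_fit", s))
        est.fit(X[train], y[train], X_val=X[val], y_val=y[val])
        aucs.append(roc_auc_score(y[val], est.decision_scores(X[val])))
    return float(np.mean(aucs))


def sffs_select(table: pd.DataFrame, labels: Sequence[int],
                ranked: Optional[pd.DataFrame] = None, max_k: int = 5,
                seed: int = 0, model: str = "ann",
                n_splits: int = 3) -> SelectionResult:
    """p-value-initialized sequential floating forward selection.

    Starting from the top-ranked feature, the search adds the candidate
    that maximizes the criterion — the validation AUC of the configured
    classifier under the module's split protocol, averaged over
    ``n_splits`` fixed inner splits — then conditionally removes any
    included feature whose removal improves on the best subset of the
    smaller size, until all candidates have been evaluated or the subset
    would exceed ``max_k``.  The best subset over all sizes is returned
    (ties prefer fewer features).  Deterministic given ``seed``.
    """
    y = np.asarray(labels, dtype=int)
    if ranked is None:
        ranked = univariate_rank(table, y)
    candidates = list(ranked.index)
    if len(candidates) < 1:
        raise ValueError("no candidate features")
    _check_finite(table[candidates])
    X_all = table[candidates].to_numpy(dtype=float)
    col_of = {f: i for i, f in enumerate(candidates)}
    splits = [stratified_70_15_15(y, random_state=child_seed(seed, "sffs", s))
              for s in range(n_splits)]
    cache: Dict[frozenset, float] = {}
    trace: List[dict] = []

    def criterion(subset: Sequence[str]) -> float:
        key = frozenset(subset)
        if key in cache:
            return cache[key]
        cols = [col_of[f] for f in subset]
        aucs = []
        for s, (train, val, _test) in enumerate(splits):
            est = _make_model(model,
                              random_state=child_seed(seed, "sffs_fit", s))
            est.fit(X_all[np.ix_(train, cols)], y[train],
                    X_val=X_all[np.ix_(val, cols)], y_val=y[val])
            aucs.append(roc_auc_score(
                y[val], est.decision_scores(X_all[np.ix_(val, cols)])))
        val = float(np.mean(aucs))
        cache[key] = val
        return val

    current = [candidates[0]]
    best_by_size: Dict[int, Tuple[float, List[str]]] = {
        1: (criterion(current), list(current))}
    trace.append({"action": "init", "feature": candidates[0],
                  "subset": list(current), "criterion": best_by_size[1][0]})

    while len(current) < max_k:
        remaining = [f for f in candidates if f not in current]
        if not remaining:
            break
        scored = [(criterion(current + [f]), f) for f in remaining]
        crit_add, f_add = max(scored, key=lambda t: (t[0], -candidates.index(t[1])))
        current = current + [f_add]
        k = len(current)
        if k not in best_by_size or crit_add > best_by_size[k][0]:
            best_by_size[k] = (crit_add, list(current))
        trace.append({"action": "add", "feature": f_add,
                      "subset": list(current), "criterion": crit_add})
        # conditional (floating) exclusion
        while len(current) > 2:
            scored_rm = [(criterion([g for g in current if g != f]), f)
                         for f in current]
            crit_rm, f_rm = max(scored_rm, key=lambda t: t[0])
            k_rm = len(current) - 1
            if crit_rm > best_by_size.get(k_rm, (-np.inf,))[0]:
                current = [g for g in current if g != f_rm]
                best_by_size[k_rm] = (crit_rm, list(current))
                trace.append({"action": "remove", "feature": f_rm,
                              "subset": list(current), "criterion": crit_rm})
            else:
                break

    best_crit, best_subset = max(
        best_by_size.values(), key=lambda t: (t[0], -len(t[1])))
    return SelectionResult(chosen_features=best_subset, criterion=best_crit,
                           criterion_trace=trace)


class SFFSSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping :func:`sffs_select`.

    ``fit(X, y)`` ranks features univariately, runs the floating search
    and exposes ``support_`` / ``selected_features_``; composes with
    sklearn pipelines via the usual ``transform``.
    """

    def __init__(self, max_features=5, model="ann", n_splits=3,
                 random_state=0):
        self.max_features = max_features
        self.model = model
        self.n_splits = n_splits
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            table = X.copy()
            names = list(X.columns)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(X.shape[1])]
            table = pd.DataFrame(X, columns=names)
        result = sffs_select(table, y, max_k=self.max_features,
                             seed=self.random_state, model=self.model,
                             n_splits=self.n_splits)
        self.selected_features_ = result.chosen_features
        self.criterion_ = result.criterion
        self.trace_ = result.criterion_trace
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = np.array([n in result.chosen_features for n in names])
        self.n_features_in_ = len(names)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# Reporting

def compile_report(per_set_metrics: List[Dict], scheme: str,
                   model: str = "ann",
                   config: Optional[dict] = None) -> dict:
    """Aggregate per-balanced-set metrics into mean +/- SD (n-1).

    ``per_set_metrics`` holds one dict per balanced set with keys
    sensitivity/specificity/accuracy (percent), auc, and optionally
    ``chosen_features`` and ``set_id``.
    """
    if len(per_set_metrics) == 0:
        raise ValueError("need at least one evaluated balanced set")
    df = pd.DataFrame(per_set_metrics)
    aggregate = {}
    for metric in ("sensitivity", "specificity", "accuracy", "auc"):
        vals = df[metric].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        aggregate[metric] = {"mean": float(np.mean(vals)), "sd": sd}
    report = {
        "scheme": scheme,
        "model": model,
        "n_sets": int(len(per_set_metrics)),
        "aggregate": aggregate,
        "per_set": [
            {k: (v if not isinstance(v, (np.floating, np.integer))
                 else v.item())
             for k, v in row.items()} for row in per_set_metrics],
        "config": config or {},
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-reproducible) JSON rendering of a report."""
    return json.dumps(report, sort_keys=True, indent=1, default=float)


def run_classification(table: pd.DataFrame, scheme: str | GroupingScheme,
                       model: str = "ann", seed: int = 0,
                       features: Optional[Sequence[str]] = None,
                       max_features: int = 5, n_bootstrap: int = 10,
                       select_per_set: bool = True,
                       sffs_splits: int = 3) -> dict:
    """End-to-end protocol for one grouping scheme on a feature table.

    ``table`` needs the QUS/molecular feature columns plus ``mr_score``
    (and ``recurrence_free_5yr`` for the survival scheme).  Per balanced
    set: univariate ranking, SFFS selection (unless ``features`` pins the
    subset), the tuned-classifier protocol, and metric averaging over the
    bootstraps; the report aggregates across sets.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    y_all, mask = scheme.labels(table)
    sub = table.loc[mask].reset_index(drop=True)
    y = y_all[mask]
    label_cols = {"mr_score", "recurrence_free_5yr", "label"}
    if features is None:
        candidate_feats = [c for c in sub.columns if c not in label_cols]
    else:
        candidate_feats = list(features)
    sets = make_balanced_sets(y, seed=child_seed(seed, scheme.name))
    per_set = []
    for bs in sets:
        st = sub.iloc[bs.indices].reset_index(drop=True)
        sy = y[bs.indices]
        set_seed = child_seed(seed, scheme.name, "set", bs.set_id)
        if select_per_set and features is None:
            ranked = univariate_rank(st[candidate_feats], sy)
            sel = sffs_select(st, sy, ranked=ranked, max_k=max_features,
                              seed=set_seed, model=model,
                              n_splits=sffs_splits)
            chosen = sel.chosen_features
        else:
            chosen = candidate_feats[:max_features] if features is None \
                else candidate_feats
        boot = _train_eval(st, sy, chosen, seed=set_seed, model=model,
                           n_bootstrap=n_bootstrap)
        entry = {m: float(boot[m].mean())
                 for m in ("sensitivity", "specificity", "accuracy", "auc")}
        entry["set_id"] = bs.set_id
        entry["chosen_features"] = list(chosen)
        per_set.append(entry)
    config = {"seed": int(seed), "model": model,
              "max_features": int(max_features),
              "n_bootstrap": int(n_bootstrap),
              "select_per_set": bool(select_per_set),
              "scheme": scheme.name}
    return compile_report(per_set, scheme.name, model=model, config=config)
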