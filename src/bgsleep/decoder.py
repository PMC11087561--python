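"""Multi-class sleep-stage decoding with gradient-boosted trees.

The decoder is a LightGBM multi-class classifier wrapped in the sklearn
estimator contract, with class-imbalance handling (SMOTE inside
training folds only), nested cross-validation (4 outer x 4 inner folds)
with a 50-round Bayesian hyperparameter search scored by balanced
accuracy, leave-one-subject-out evaluation across decoding contexts,
and additive (TreeSHAP) feature attribution.

Any classifier exposing fit / predict_proba can replace the boosted-tree
core through the ``base_estimator`` parameter; the evaluation code is
agnostic to the backend.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, METADATA_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "SearchSpec",
    "DecodingContext",
    "DecodingMetrics",
    "SmoteOversampler",
    "SleepStageDecoder",
    "oversample_minority",
    "tune_and_train",
    "predict_stages",
    "compute_metrics",
    "evaluate_loso",
    "feature_importance",
    "save_decoder",
    "load_decoder",
]


@dataclass(frozen=True)
class SearchSpec:
    """Nested cross-validation and hyperparameter-search settings."""

    outer_folds: int = 4
    inner_folds: int = 4
    search_rounds: int = 50
    objective: str = "balanced_accuracy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.search_rounds < 0:
            raise ValueError("search_rounds must be >= 0")


@dataclass(frozen=True)
class DecodingContext:
    """Which subjects train together and how stages are grouped."""

    mode: Literal["individualized", "cross_subject"] = "cross_subject"
    grouping: Literal[
        "same_disease_same_target",
        "same_disease_cross_target",
        "cross_disease_same_target",
        "cross_all",
    ] = "cross_all"
    scheme: Literal["three_class", "five_class", "nrem_substages"] = "three_class"


@dataclass
class DecodingMetrics:
    """Staging metrics for one evaluation.

    ``mislabeling_rate`` is minutes mislabeled per hour of recording,
    (1 - accuracy) x 60 for 30-s epochs.
    """

    accuracy: float
    balanced_accuracy: float
    weighted_f1: float
    per_class_recall: dict[str, float]
    confusion: pd.DataFrame
    mislabeling_rate: float
    n_epochs: int


# ---------------------------------------------------------------------------
# SMOTE


class SmoteOversampler(BaseEstimator):
    """Synthetic minority oversampling by neighbour interpolation.

    Every minority class is grown to the majority count; each synthetic
    row is a convex combination of a real row and one of its k nearest
    same-class neighbours. Classes smaller than k+1 fall back to fewer
    neighbours (logged); singleton classes are duplicated with a small
    jitter (logged). Apply inside training folds only — never to test
    data.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("oversampling needs at least 2 classes")
        target = counts.max()
        rng = np.random.default_rng(self.random_state)
        new_X, new_y = [X], [y]
        for cls, count in zip(classes, counts):
            need = int(target - count)
            if need == 0:
                continue
            Xc = X[y == cls]
            if count == 1:
                logger.warning(
                    "class %r is a singleton: duplicating with jitter", cls
                )
                scale = 1e-6 * (np.abs(Xc).mean() + 1.0)
                synth = Xc[np.zeros(need, dtype=int)] + rng.normal(
                    0.0, scale, size=(need, X.shape[1])
                )
            else:
                k = min(self.k_neighbors, count - 1)
                if k < self.k_neighbors:
                    logger.warning(
                        "class %r has %d members; reducing k to %d", cls, count, k
                    )
                nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
                _, nbrs = nn.kneighbors(Xc)
                base = rng.integers(0, count, size=need)
                pick = rng.integers(1, k + 1, size=need)
                lam = rng.uniform(0.0, 1.0, size=(need, 1))
                anchors = Xc[base]
                partners = Xc[nbrs[base, pick]]
                synth = anchors + lam * (partners - anchors)
            new_X.append(synth)
            new_y.append(np.full(need, cls, dtype=y.dtype))
        return np.vstack(new_X), np.concatenate(new_y)


def oversample_minority(
    matrix: pd.DataFrame,
    label_column: str = "stage",
    k_neighbors: int = 5,
    random_state: int = 0,
) -> pd.DataFrame:
    """Balance a feature matrix by SMOTE on its feature columns.

    Synthetic rows inherit the metadata of their anchor's class (subject
    set to ``synthetic``). Only for use on training data.
    """
    feat_cols = [c for c in matrix.columns if c not in METADATA_COLUMNS]
    X = matrix[feat_cols].to_numpy(dtype=float)
    y = matrix[label_column].to_numpy()
    Xr, yr = SmoteOversampler(k_neighbors, random_state).fit_resample(X, y)
    n_orig = len(matrix)
    out = pd.DataFrame(Xr[n_orig:], columns=feat_cols)
    for col in METADATA_COLUMNS:
        if col in matrix.columns:
            out[col] = "synthetic" if col != label_column else ""
    out[label_column] = yr[n_orig:]
    return pd.concat([matrix, out[matrix.columns]], ignore_index=True)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search (GP + expected improvement)

_SEARCH_SPACE: list[tuple[str, str, float, float]] = [
    # (name, kind, low, high) — log kinds are searched in log10 space
    ("learning_rate", "log", 0.01, 0.3),
    ("num_leaves", "int", 8, 64),
    ("n_estimators", "int", 50, 300),
    ("max_depth", "int", 3, 12),
    ("min_child_samples", "int", 5, 50),
    ("subsample", "float", 0.5, 1.0),
    ("colsample_bytree", "float", 0.5, 1.0),
    ("reg_lambda", "log", 1e-3, 10.0),
]


def _decode_point(u: np.ndarray) -> dict:
    params = {}
    for ui, (name, kind, lo, hi) in zip(u, _SEARCH_SPACE):
        if kind == "log":
            v = 10 ** (np.log10(lo) + ui * (np.log10(hi) - np.log10(lo)))
            params[name] = float(v)
        else:
            v = lo + ui * (hi - lo)
            params[name] = int(round(v)) if kind == "int" else float(v)
    return params


def _bayes_search(objective, n_rounds: int, rng: np.random.Generator) -> dict:
    """Maximise ``objective(params)`` with a GP surrogate and EI acquisition."""
    dim = len(_SEARCH_SPACE)
    n_init = min(max(dim, 5), n_rounds)
    U = list(rng.uniform(size=(n_init, dim)))
    scores = [objective(_decode_point(u)) for u in U]
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5, length_scale_bounds=(1e-2, 1e2)),
        alpha=1e-4, normalize_y=True, random_state=0,
    )
    for _ in range(n_rounds - n_init):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(U), np.asarray(scores))
        cand = rng.uniform(size=(256, dim))
        mu, sd = gp.predict(cand, return_std=True)
        best = max(scores)
        z = (mu - best) / np.maximum(sd, 1e-12)
        from scipy.stats import norm

        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        u = cand[int(np.argmax(ei))]
        U.append(u)
        scores.append(objective(_decode_point(u)))
    return _decode_point(U[int(np.argmax(scores))])


# ---------------------------------------------------------------------------
# the decoder


class SleepStageDecoder(ClassifierMixin, BaseEstimator):
    """Gradient-boosted multi-class sleep-stage classifier.

    Parameters
    ----------
    search_rounds : int
        Rounds of Bayesian hyperparameter search inside ``fit`` (0 uses
        the backend defaults — no inner cross-validation).
    inner_folds : int
        Stratified folds of the inner search cross-validation.
    oversample : bool
        Apply SMOTE to the training data (and to every inner training
        fold during the search).
    smote_k : int
        SMOTE neighbour count.
    base_estimator : estimator or None
        Alternative backend with fit / predict_proba; the default is a
        LightGBM classifier. The search only runs on the default
        backend.
    backend_params : dict or None
        Fixed parameters for the LightGBM backend.
    random_state : int
        Seed for SMOTE, folding, the search, and the trees.

    Attributes
    ----------
    classes_ : ndarray of trained classes.
    feature_names_in_ : the feature-name contract (when fit on a
        DataFrame); prediction rejects matrices whose columns differ.
    best_params_ : chosen hyperparameters (search only).
    booster_ : the fitted LightGBM booster (default backend).
    """

    def __init__(
        self,
        search_rounds: int = 0,
        inner_folds: int = 4,
        oversample: bool = True,
        smote_k: int = 5,
        base_estimator=None,
        backend_params: dict | None = None,
        random_state: int = 0,
    ):
        self.search_rounds = search_rounds
        self.inner_folds = inner_folds
        self.oversample = oversample
        self.smote_k = smote_k
        self.base_estimator = base_estimator
        self.backend_params = backend_params
        self.random_state = random_state

    # -- helpers

    def _coerce(self, X, check_contract: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if check_contract:
                expected = list(self.feature_names_in_)
                got = list(X.columns)
                if got != expected:
                    missing = [c for c in expected if c not in got]
                    extra = [c for c in got if c not in expected]
                    raise ValueError(
                        "feature contract mismatch: "
                        f"missing={missing} extra={extra} "
                        f"(order must match training)"
                    )
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if check_contract and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def _make_backend(self, params: dict | None = None) -> lgb.LGBMClassifier:
        base = {
            "n_estimators": 100,
            "learning_rate": 0.1,
            "num_leaves": 31,
            "n_jobs": 1,
            "verbose": -1,
            "random_state": self.random_state,
        }
        if self.backend_params:
            base.update(self.backend_params)
        if params:
            base.update(params)
        return lgb.LGBMClassifier(**base)

    def _resample(self, X: np.ndarray, y: np.ndarray):
        if not self.oversample or np.unique(y).size < 2:
            return X, y
        return SmoteOversampler(self.smote_k, self.random_state).fit_resample(X, y)

    def _cv_score(self, X: np.ndarray, y: np.ndarray, params: dict) -> float:
        skf = StratifiedKFold(
            self.inner_folds, shuffle=True, random_state=self.random_state
        )
        scores = []
        for tr, te in skf.split(X, y):
            Xr, yr = self._resample(X[tr], y[tr])
            est = self._make_backend(params).fit(Xr, yr)
            with warnings.catch_warnings():
                # lightgbm autogenerates feature names for array input,
                # which trips sklearn's name validation on predict
                warnings.simplefilter("ignore", UserWarning)
                y_pred = est.predict(X[te])
            scores.append(balanced_accuracy_score(y[te], y_pred))
        return float(np.mean(scores))

    # -- sklearn API

    def fit(self, X, y):
        y = np.asarray(y)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        Xa = np.asarray(
            X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else X,
            dtype=float,
        )
        self.n_features_in_ = Xa.shape[1]
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        _, counts = np.unique(y, return_counts=True)
        if self.search_rounds > 0 and counts.min() < self.inner_folds:
            raise ValueError(
                "a class is too small for stratified inner folding"
            )

        self.best_params_ = {}
        if self.base_estimator is not None:
            est = clone(self.base_estimator)
            Xr, yr = self._resample(Xa, y)
            est.fit(Xr, yr)
            self._estimator = est
            self.booster_ = None
            return self

        if self.search_rounds > 0:
            rng = np.random.default_rng(self.random_state)
            self.best_params_ = _bayes_search(
                lambda p: self._cv_score(Xa, y, p), self.search_rounds, rng
            )
        Xr, yr = self._resample(Xa, y)
        est = self._make_backend(self.best_params_).fit(Xr, yr)
        self._estimator = est
        self.booster_ = est.booster_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        Xa = self._coerce(X, check_contract=True)
        if self.booster_ is not None:
            raw = self.booster_.predict(Xa)
            if raw.ndim == 1:  # binary backend emits P(class 1)
                raw = np.column_stack([1.0 - raw, raw])
            return raw
        return self._estimator.predict_proba(Xa)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def tune_and_train(
    matrix: pd.DataFrame,
    spec: SearchSpec = SearchSpec(),
    label_column: str = "stage",
    **decoder_kwargs,
) -> SleepStageDecoder:
    """Fit a decoder on a feature matrix with the nested-CV search.

    The inner search (``spec.inner_folds`` folds, ``spec.search_rounds``
    rounds, balanced-accuracy objective) selects hyperparameters; the
    final model refits on all provided training rows. Outer folds are
    the caller's responsibility (they define evaluation, not fitting).
    """
    feat_cols = [c for c in matrix.columns if c not in METADATA_COLUMNS]
    dec = SleepStageDecoder(
        search_rounds=spec.search_rounds,
        inner_folds=spec.inner_folds,
        random_state=spec.seed,
        **decoder_kwargs,
    )
    return dec.fit(matrix[feat_cols], matrix[label_column].to_numpy())


def predict_stages(
    decoder: SleepStageDecoder, matrix: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Predict per-epoch labels (and class probabilities) for a matrix."""
    feat_cols = [c for c in matrix.columns if c not in METADATA_COLUMNS]
    proba = decoder.predict_proba(matrix[feat_cols])
    labels = decoder.classes_[np.argmax(proba, axis=1)]
    return labels, proba


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(
    y_true: Sequence, y_pred: Sequence, epoch_length: float = 30.0
) -> DecodingMetrics:
    """Accuracy, balanced accuracy, weighted F1, recalls, confusion.

    Balanced accuracy averages recall over classes present in the true
    labels; predicted-only classes are excluded (and logged).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("need equal, non-empty label sequences")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    true_labels = np.unique(y_true)
    if true_labels.size < labels.size:
        logger.info(
            "classes %s absent from true labels: excluded from balanced accuracy",
            sorted(set(labels) - set(true_labels)),
        )
    acc = float(np.mean(y_true == y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bal = float(balanced_accuracy_score(y_true, y_pred))
        f1 = float(f1_score(y_true, y_pred, average="weighted"))
        rec = recall_score(
            y_true, y_pred, labels=true_labels, average=None, zero_division=0.0
        )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    frac_hour = 60.0  # minutes mislabeled per hour
    return DecodingMetrics(
        accuracy=acc,
        balanced_accuracy=bal,
        weighted_f1=f1,
        per_class_recall={str(c): float(r) for c, r in zip(true_labels, rec)},
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        mislabeling_rate=(1.0 - acc) * frac_hour,
        n_epochs=len(y_true),
    )


# ---------------------------------------------------------------------------
# leave-one-subject-out evaluation


def _context_groups(meta: pd.DataFrame, grouping: str) -> list[pd.Index]:
    subj = meta.drop_duplicates("subject")
    if grouping == "cross_all":
        return [subj["subject"].reset_index(drop=True)]
    keys = {
        "same_disease_same_target": ["disease", "target"],
        "same_disease_cross_target": ["disease"],
        "cross_disease_same_target": ["target"],
    }[grouping]
    return [
        g["subject"].reset_index(drop=True)
        for _, g in subj.groupby(keys, sort=True)
    ]


def evaluate_loso(
    matrix: pd.DataFrame,
    context: DecodingContext = DecodingContext(),
    spec: SearchSpec = SearchSpec(search_rounds=0),
    label_column: str = "stage",
    **decoder_kwargs,
) -> dict[str, pd.DataFrame]:
    """Leave-one-subject-out evaluation across a decoding context.

    For every evaluation group of the context's grouping and every
    held-out subject, a decoder is trained on all remaining subjects'
    epochs (all channels pooled) and evaluated on each channel of the
    held-out subject. Returns ``per_channel`` (one metrics row per
    subject x channel) and ``best_channel`` (the max-accuracy channel
    per subject, ties broken by channel order).

    In ``individualized`` mode each subject-channel is evaluated by
    stratified ``spec.outer_folds``-fold cross-validation within its own
    night, with no cross-subject data involved.
    """
    feat_cols = [c for c in matrix.columns if c not in METADATA_COLUMNS]
    rows = []

    if context.mode == "individualized":
        for (subj, chan), g in matrix.groupby(["subject", "channel"], sort=False):
            y = g[label_column].to_numpy()
            X = g[feat_cols].to_numpy(dtype=float)
            skf = StratifiedKFold(
                spec.outer_folds, shuffle=True, random_state=spec.seed
            )
            y_pred = np.empty_like(y)
            for tr, te in skf.split(X, y):
                dec = SleepStageDecoder(
                    search_rounds=spec.search_rounds,
                    inner_folds=spec.inner_folds,
                    random_state=spec.seed,
                    **decoder_kwargs,
                ).fit(X[tr], y[tr])
                y_pred[te] = dec.predict(X[te])
            m = compute_metrics(y, y_pred)
            rows.append(_metrics_row(subj, chan, m))
        per_channel = pd.DataFrame(rows)
        return {"per_channel": per_channel, "best_channel": _best(per_channel)}

    for group in _context_groups(matrix[METADATA_COLUMNS], context.grouping):
        group = list(group)
        if len(group) < 3:
            raise ValueError(
                f"grouping leaves {len(group)} subjects; need >= 3"
            )
        gm = matrix[matrix["subject"].isin(group)]
        for subj in group:
            train = gm[gm["subject"] != subj]
            test = gm[gm["subject"] == subj]
            assert not set(train["subject"]) & set(test["subject"])
            dec = SleepStageDecoder(
                search_rounds=spec.search_rounds,
                inner_folds=spec.inner_folds,
                random_state=spec.seed,
                **decoder_kwargs,
            ).fit(train[feat_cols], train[label_column].to_numpy())
            for chan, g in test.groupby("channel", sort=False):
                y_pred = dec.predict(g[feat_cols])
                m = compute_metrics(g[label_column].to_numpy(), y_pred)
                rows.append(_metrics_row(subj, chan, m))
    per_channel = pd.DataFrame(rows)
    return {"per_channel": per_channel, "best_channel": _best(per_channel)}


def _metrics_row(subject, channel, m: DecodingMetrics) -> dict:
    row = {
        "subject": subject,
        "channel": channel,
        "accuracy": m.accuracy,
        "balanced_accuracy": m.balanced_accuracy,
        "weighted_f1": m.weighted_f1,
        "mislabeling_rate": m.mislabeling_rate,
        "n_epochs": m.n_epochs,
    }
    row.update({f"recall_{k}": v for k, v in m.per_class_recall.items()})
    return row


def _best(per_channel: pd.DataFrame) -> pd.DataFrame:
    # stable idxmax keeps the first-listed (deepest) channel on ties
    idx = per_channel.groupby("subject", sort=False)["accuracy"].idxmax()
    return per_channel.loc[idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# attribution


def feature_importance(
    decoder: SleepStageDecoder, matrix: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Additive (TreeSHAP) per-feature attribution.

    Returns a table indexed by feature name with one column of mean
    |attribution| per class and a ``global`` column (mean over rows and
    classes), sorted descending by global importance. Attributions plus
    the per-class base value reproduce the model's raw margin row by
    row.
    """
    check_is_fitted(decoder, "classes_")
    if decoder.booster_ is None:
        raise ValueError("attribution requires the boosted-tree backend")
    if isinstance(matrix, pd.DataFrame):
        feat_cols = [c for c in matrix.columns if c not in METADATA_COLUMNS]
        X = matrix[feat_cols].to_numpy(dtype=float)
        names = feat_cols
    else:
        X = np.asarray(matrix, dtype=float)
        names = list(getattr(decoder, "feature_names_in_", range(X.shape[1])))
    contrib = decoder.booster_.predict(X, pred_contrib=True)
    n_class = len(decoder.classes_)
    n_feat = X.shape[1]
    if n_class == 2 and contrib.shape[1] == n_feat + 1:
        contrib = np.stack([-contrib, contrib], axis=1)
    else:
        contrib = contrib.reshape(X.shape[0], n_class, n_feat + 1)
    abs_mean = np.abs(contrib[:, :, :n_feat]).mean(axis=0)
    table = pd.DataFrame(
        abs_mean.T, index=[str(n) for n in names],
        columns=[str(c) for c in decoder.classes_],
    )
    table["global"] = abs_mean.mean(axis=0)
    return table.sort_values("global", ascending=False)


# ---------------------------------------------------------------------------
# persistence


def save_decoder(decoder: SleepStageDecoder, path: str | Path) -> None:
    """Write a self-describing JSON bundle (boosted-tree backend only)."""
    check_is_fitted(decoder, "classes_")
    if decoder.booster_ is None:
        raise ValueError("persistence supports the boosted-tree backend only")
    params = decoder.get_params()
    params.pop("base_estimator", None)
    payload = {
        "model": decoder.booster_.model_to_string(),
        "classes": [str(c) for c in decoder.classes_],
        "feature_names": [
            str(c) for c in getattr(decoder, "feature_names_in_", [])
        ],
        "n_features": int(decoder.n_features_in_),
        "params": params,
        "best_params": decoder.best_params_,
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(
            {k: v for k, v in payload.items() if k != "model"}, sort_keys=True
        ).encode()
    ).hexdigest()
    Path(path).write_text(json.dumps(payload))


def load_decoder(path: str | Path) -> SleepStageDecoder:
    """Reload a saved decoder; predictions are bit-identical."""
    payload = json.loads(Path(path).read_text())
    dec = SleepStageDecoder(**payload["params"])
    dec.classes_ = np.asarray(payload["classes"], dtype=object)
    dec.n_features_in_ = payload["n_features"]
    if payload["feature_names"]:
        dec.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
    dec.best_params_ = payload["best_params"]
    dec.booster_ = lgb.Booster(model_str=payload["model"])
    dec._estimator = None
    return dec
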