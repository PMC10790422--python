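"""Single-modality and stacked multimodal classification.

The evaluation protocol is leakage-free leave-one-out cross-validation
(LOOCV). In every outer iteration the held-out sample plays no part in NA
filtering, variance filtering, Boruta selection, base-model fitting or
meta-model fitting. Base models are random forests fit per modality; their
*out-of-fold* probabilities from a stratified 10-fold inner CV on the
training samples form the design matrix of a meta-classifier (stacking).
The held-out sample's final probability comes from the meta-classifier
applied to base probabilities produced by per-modality models refit on the
full training set.

Metrics follow the liquid-biopsy reporting conventions: ROC AUC on the
aggregated held-out probabilities, sensitivity at the smallest threshold
reaching 90% specificity, and F1/confusion at a fixed probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import DataError, UsageError, ValidationError
from .features import FeatureMatrix, boruta_select


def derive_seed(seed: int, *parts: int) -> int:
    """Deterministic child seed (< 2**31) from a base seed and indices."""
    out = seed & 0x7FFFFFFF
    for p in parts:
        out = (out * 1000003 + p + 1) & 0x7FFFFFFF
    return out


@dataclass(frozen=True)
class ModelConfig:
    """Tunable model parameters; defaults follow the training protocol."""

    trees: int = 500                 # base random-forest size
    max_depth: int | None = None
    top_k: int = 100                 # features kept per modality
    inner_k: int = 10                # inner stratified CV folds for stacking
    meta: str = "logistic"           # or "forest"
    var_threshold: float = 1e-8
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.05
    boruta_trees: int | None = None  # default: same as `trees`
    boruta_depth: int | None = 5
    always_boruta: bool = False      # run Boruta even when features <= top_k
    threshold: float = 0.5           # probability cut for F1 / confusion
    spec_target: float = 0.90
    pos_label: str = "cancer"
    # pre-fixed feature list (redesigned-panel mode): bypasses per-iteration
    # selection and uses exactly these features (intersected with the matrix)
    fixed_features: tuple[str, ...] | None = None

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass
class ModalityModel:
    """A fitted per-modality base model plus everything predict needs."""

    features: list[str]
    medians: pd.Series
    classes: np.ndarray
    forest: RandomForestClassifier

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Xs = X.reindex(columns=self.features).fillna(self.medians)
        return self.forest.predict_proba(Xs.to_numpy(dtype=float))


@dataclass
class EvalReport:
    """Aggregated held-out performance of one model."""

    n: int
    auc: float
    sensitivity_at_spec: float
    spec_target: float
    f1: float
    threshold: float
    confusion: pd.DataFrame
    accuracy: float | None = None    # multiclass mode only

    def to_dict(self) -> dict:
        out = {
            "n": self.n, "auc": self.auc,
            "sensitivity_at_spec": self.sensitivity_at_spec,
            "spec_target": self.spec_target, "f1": self.f1,
            "threshold": self.threshold,
            "confusion": self.confusion.to_dict(),
        }
        if self.accuracy is not None:
            out["accuracy"] = self.accuracy
        return out


class _Modality:
    """Numpy view of one modality's matrix for the cross-validation loops.

    The repeated per-iteration selection + fit work is pure numpy; the
    pandas :class:`FeatureMatrix` API stays the user-facing surface. The
    semantics are identical to :func:`features.drop_na_features` /
    :func:`features.drop_low_variance` followed by Boruta when the surviving
    space exceeds ``top_k``.
    """

    def __init__(self, fm: FeatureMatrix):
        self.values = fm.values.to_numpy(dtype=float)
        self.features = np.asarray(fm.feature_ids, dtype=object)
        self.ids = fm.sample_ids
        self.labels = fm.labels.to_numpy()

    def select(self, tr: np.ndarray, cfg: ModelConfig, seed: int) -> np.ndarray:
        """Training-only feature selection; returns column indices.

        Boruta exists to cut an over-complete space down to ``top_k``; when
        the NA/variance-filtered space is already within ``top_k`` it cannot
        discard anything, so its fit is skipped unless ``always_boruta``.
        With ``fixed_features`` set, selection is bypassed entirely.
        """
        if cfg.fixed_features is not None:
            wanted = set(cfg.fixed_features)
            idx = np.flatnonzero(np.isin(self.features, list(wanted)))
            if len(idx) == 0:
                raise DataError("none of the fixed features are present")
            return idx
        sub = self.values[tr]
        ok = ~np.isnan(sub).any(axis=0)
        ok &= np.where(ok, np.var(np.nan_to_num(sub), axis=0), 0) > cfg.var_threshold
        idx = np.flatnonzero(ok)
        if len(idx) > cfg.top_k or cfg.always_boruta:
            frame = pd.DataFrame(sub[:, idx], columns=self.features[idx])
            res = boruta_select(
                frame, self.labels[tr], k=cfg.top_k,
                max_iter=cfg.boruta_max_iter, alpha=cfg.boruta_alpha,
                seed=seed, n_estimators=cfg.boruta_trees or cfg.trees,
                max_depth=cfg.boruta_depth)
            pos = {f: i for f, i in zip(self.features[idx], idx)}
            idx = np.array([pos[f] for f in res.selected], dtype=int)
        return idx

    def fit(self, tr: np.ndarray, cfg: ModelConfig, seed: int):
        y = self.labels[tr]
        if len(np.unique(y)) < 2:
            raise ValidationError("training set lost all but one class")
        fidx = self.select(tr, cfg, derive_seed(seed, 1))
        if len(fidx) == 0:
            raise DataError("no features survived NA/variance filtering")
        X = self.values[np.ix_(tr, fidx)]
        medians = np.nanmedian(X, axis=0)
        nan = np.isnan(X)
        if nan.any():  # only reachable in fixed-feature mode
            X = np.where(nan, np.broadcast_to(medians, X.shape), X)
        forest = RandomForestClassifier(
            n_estimators=cfg.trees, max_depth=cfg.max_depth,
            random_state=derive_seed(seed, 2))
        forest.fit(X, y)
        return fidx, medians, forest

    def predict(self, fitted, rows: np.ndarray) -> np.ndarray:
        fidx, medians, forest = fitted
        X = self.values[np.ix_(rows, fidx)]
        nan = np.isnan(X)
        if nan.any():
            X = np.where(nan, np.broadcast_to(medians, X.shape), X)
        return forest.predict_proba(X)


def fit_modality_model(fm: FeatureMatrix, train_ids: Sequence[str],
                       cfg: ModelConfig, seed: int) -> ModalityModel:
    """Run the selection pipeline and fit the base forest on training rows."""
    data = _Modality(fm)
    pos = {sid: i for i, sid in enumerate(data.ids)}
    tr = np.array([pos[s] for s in train_ids], dtype=int)
    fidx, medians, forest = data.fit(tr, cfg, seed)
    feats = list(data.features[fidx])
    return ModalityModel(feats, pd.Series(medians, index=feats),
                         forest.classes_, forest)


def _positive_index(classes: np.ndarray, pos_label: str) -> int:
    if pos_label in classes:
        return int(np.where(classes == pos_label)[0][0])
    if len(classes) != 2:
        raise UsageError(f"pos_label {pos_label!r} not among classes {classes}")
    return 1


# ---------------------------------------------------------------------------
# LOOCV protocols
# ---------------------------------------------------------------------------

def loocv_single_modality(fm: FeatureMatrix, cfg: ModelConfig,
                          seed: int) -> tuple[pd.Series, EvalReport]:
    """Outer LOOCV of one modality; returns held-out probabilities + report."""
    ids = fm.sample_ids
    if len(ids) < 10:
        raise UsageError(f"LOOCV needs >= 10 samples, got {len(ids)}")
    data = _Modality(fm)
    probs = {}
    for i, sid in enumerate(ids):
        tr = np.array([j for j in range(len(ids)) if j != i], dtype=int)
        try:
            fitted = data.fit(tr, cfg, derive_seed(seed, i))
        except ValidationError as err:
            raise ValidationError(f"LOOCV iteration {i} ({sid}): {err}") from err
        p = data.predict(fitted, np.array([i]))
        probs[sid] = float(p[0, _positive_index(fitted[2].classes_,
                                                cfg.pos_label)])
    probs = pd.Series(probs).loc[ids]
    return probs, evaluate(probs, fm.labels, pos_label=cfg.pos_label,
                           threshold=cfg.threshold, spec_target=cfg.spec_target)


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds whose training parts all retain every class."""
    n_classes = len(np.unique(y))
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=derive_seed(seed, attempt))
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == n_classes for tr, _ in folds):
            return folds
    raise ValidationError(f"could not build {k} stratified folds keeping "
                          "all classes in every training part")


def _inner_oof(datas: dict[str, _Modality], tr_rows: np.ndarray,
               cfg: ModelConfig, seed: int) -> tuple[list[str], np.ndarray]:
    """Out-of-fold base probabilities for the training rows of every modality.

    The full selection pipeline is re-run on each fold's training part, so a
    sample's out-of-fold probability never sees that sample. Column order is
    ``<modality>|<class>`` over sorted modalities and sorted classes, which
    serves two-class and multi-class stacking alike.
    """
    names = sorted(datas)
    y = datas[names[0]].labels[tr_rows]
    classes = sorted(np.unique(y))
    counts = min(np.bincount(pd.factorize(y)[0]))
    k = min(cfg.inner_k, int(counts), len(tr_rows))
    if k < 2:
        raise ValidationError("too few samples per class for inner CV")
    folds = _stratified_folds(y, k, seed)
    colnames = [f"{n}|{c}" for n in names for c in classes]
    out = np.zeros((len(tr_rows), len(names) * len(classes)))
    for m, name in enumerate(names):
        data = datas[name]
        for f, (tr, te) in enumerate(folds):
            fitted = data.fit(tr_rows[tr], cfg, derive_seed(seed, m, f))
            proba = data.predict(fitted, tr_rows[te])
            # fold forests see every class, so classes_ == classes
            out[np.ix_(te, m * len(classes) + np.arange(len(classes)))] = proba
    return colnames, out


def inner_cv_base_predictions(fms: Mapping[str, FeatureMatrix],
                              cfg: ModelConfig, seed: int) -> pd.DataFrame:
    """Out-of-fold base probabilities for every sample and modality.

    Every sample's probability comes from a model whose fold excluded that
    sample; see :func:`_inner_oof` for the column convention.
    """
    names = sorted(fms)
    ids = fms[names[0]].sample_ids
    for name in names:
        if fms[name].sample_ids != ids:
            raise ValidationError(f"modality {name!r} has mismatched samples")
    datas = {n: _Modality(fms[n]) for n in names}
    cols, oof = _inner_oof(datas, np.arange(len(ids)), cfg, seed)
    return pd.DataFrame(oof, index=ids, columns=cols)


def fit_stacked(oof: pd.DataFrame, labels: pd.Series, cfg: ModelConfig,
                seed: int):
    """Fit the meta-classifier on the out-of-fold base probability matrix."""
    if oof.isna().any().any():
        raise DataError("incomplete base-probability table")
    y = labels.loc[oof.index].to_numpy()
    if cfg.meta == "logistic":
        meta = LogisticRegression(max_iter=1000, random_state=derive_seed(seed, 7))
    elif cfg.meta == "forest":
        meta = RandomForestClassifier(n_estimators=cfg.trees,
                                      random_state=derive_seed(seed, 7))
    else:
        raise UsageError(f"unknown meta-classifier {cfg.meta!r}")
    meta.fit(oof.to_numpy(dtype=float), y)
    return meta


@dataclass
class MultimodalResult:
    """Held-out final and per-modality base probabilities plus the report."""

    final_probs: pd.Series                 # positive-class (binary mode)
    final_prob_vectors: pd.DataFrame       # all classes
    base_probs: pd.DataFrame               # per modality, positive class
    labels: pd.Series
    report: EvalReport
    base_reports: dict[str, EvalReport] = field(default_factory=dict)


def loocv_multimodal(fms: Mapping[str, FeatureMatrix], cfg: ModelConfig,
                     seed: int) -> MultimodalResult:
    """Outer LOOCV with inner 10-fold stacking across modalities.

    Per outer iteration: the n−1 training samples produce out-of-fold base
    probabilities (inner CV), the meta-classifier is fit on them, the
    per-modality models are refit on all n−1 samples, and the held-out
    sample's base probabilities feed the meta-classifier. Because the refit
    base models are exactly single-modality LOOCV models, their held-out
    probabilities also yield per-modality reports for free.
    """
    names = sorted(fms)
    first = fms[names[0]]
    ids = first.sample_ids
    labels = first.labels
    classes = np.array(sorted(labels.unique()))
    datas = {n: _Modality(fms[n]) for n in names}
    final_rows = []
    base_rows = {name: {} for name in names}
    all_rows = np.arange(len(ids))
    for i, sid in enumerate(ids):
        tr_rows = np.delete(all_rows, i)
        it_seed = seed ^ i
        cols, oof = _inner_oof(datas, tr_rows, cfg, it_seed)
        meta = fit_stacked(pd.DataFrame(oof, index=[ids[j] for j in tr_rows],
                                        columns=cols),
                           labels, cfg, it_seed)
        held = np.zeros((1, len(cols)))
        n_cls = len(classes)
        for m, name in enumerate(names):
            fitted = datas[name].fit(tr_rows, cfg, derive_seed(it_seed, 99, m))
            proba = datas[name].predict(fitted, np.array([i]))
            held[0, m * n_cls:(m + 1) * n_cls] = proba[0]
            if n_cls == 2:
                base_rows[name][sid] = proba[0, _positive_index(
                    fitted[2].classes_, cfg.pos_label)]
            else:
                # multiclass: track the top class probability per modality
                base_rows[name][sid] = proba[0].max()
        pvec = meta.predict_proba(held)[0]
        final_rows.append(pd.Series(pvec, index=meta.classes_, name=sid))
    final = pd.DataFrame(final_rows).reindex(columns=classes).fillna(0.0)
    base_probs = pd.DataFrame({n: pd.Series(base_rows[n]) for n in names}).loc[ids]
    if len(classes) == 2:
        pos = cfg.pos_label if cfg.pos_label in classes else classes[1]
        final_pos = final[pos]
        report = evaluate(final_pos, labels, pos_label=str(pos),
                          threshold=cfg.threshold, spec_target=cfg.spec_target)
        base_reports = {
            n: evaluate(base_probs[n], labels, pos_label=str(pos),
                        threshold=cfg.threshold, spec_target=cfg.spec_target)
            for n in names}
    else:
        report = evaluate_multiclass(final, labels)
        final_pos = final.max(axis=1)
        base_reports = {}
    return MultimodalResult(final_pos, final, base_probs, labels, report,
                            base_reports)


def cross_cohort(fms_train: Mapping[str, FeatureMatrix],
                 fms_test: Mapping[str, FeatureMatrix], cfg: ModelConfig,
                 seed: int) -> tuple[pd.Series, EvalReport]:
    """Train the stacked model once on one cohort, evaluate on another.

    Per modality the feature universe is intersected between cohorts before
    anything else; selection, stacking and the meta fit use the training
    cohort only, and the fitted pipeline is applied unchanged to the test
    cohort.
    """
    names = sorted(fms_train)
    if sorted(fms_test) != names:
        raise UsageError("train and test cohorts expose different modalities")
    inter: dict[str, FeatureMatrix] = {}
    test_al: dict[str, FeatureMatrix] = {}
    for name in names:
        shared = [f for f in fms_train[name].feature_ids
                  if f in set(fms_test[name].feature_ids)]
        if not shared:
            raise DataError(f"no shared features for modality {name!r}")
        inter[name] = fms_train[name].subset_features(shared)
        test_al[name] = fms_test[name].subset_features(shared)
    labels_tr = inter[names[0]].labels
    oof = inner_cv_base_predictions(inter, cfg, seed)
    meta = fit_stacked(oof, labels_tr, cfg, seed)
    test_ids = test_al[names[0]].sample_ids
    cols = {}
    for m, name in enumerate(names):
        model = fit_modality_model(inter[name], inter[name].sample_ids, cfg,
                                   derive_seed(seed, 99, m))
        proba = model.predict_proba(test_al[name].values)
        for j, cls in enumerate(model.classes):
            cols[f"{name}|{cls}"] = pd.Series(proba[:, j], index=test_ids)
    held = pd.DataFrame(cols).reindex(columns=oof.columns).fillna(0.0)
    pvec = meta.predict_proba(held.to_numpy(dtype=float))
    classes = meta.classes_
    labels_te = test_al[names[0]].labels
    if len(classes) == 2:
        pos = cfg.pos_label if cfg.pos_label in classes else classes[1]
        probs = pd.Series(pvec[:, list(classes).index(pos)], index=test_ids)
        return probs, evaluate(probs, labels_te, pos_label=str(pos),
                               threshold=cfg.threshold,
                               spec_target=cfg.spec_target)
    frame = pd.DataFrame(pvec, index=test_ids, columns=classes)
    return frame.max(axis=1), evaluate_multiclass(frame, labels_te)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_mann_whitney(probs: pd.Series, labels: pd.Series,
                     pos_label: str) -> float:
    """ROC AUC by the rank formulation; ties count half."""
    y = (labels.loc[probs.index] == pos_label).to_numpy()
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC undefined: one class absent")
    ranks = stats.rankdata(probs.to_numpy())
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def sensitivity_at_specificity(probs: pd.Series, labels: pd.Series,
                               pos_label: str,
                               spec_target: float = 0.90) -> float:
    """Sensitivity at the smallest threshold reaching the target specificity.

    A sample is called positive when its probability is >= the threshold;
    candidate thresholds are the observed probabilities (plus one above the
    maximum, where sensitivity is 0).
    """
    y = (labels.loc[probs.index] == pos_label).to_numpy()
    p = probs.to_numpy()
    controls = p[~y]
    cases = p[y]
    if len(controls) == 0 or len(cases) == 0:
        raise ValidationError("sensitivity/specificity undefined: one class absent")
    for t in np.concatenate([np.unique(p), [np.inf]]):
        spec = float((controls < t).mean())
        if spec >= spec_target:
            return float((cases >= t).mean())
    return 0.0


def evaluate(probs: pd.Series, labels: pd.Series, pos_label: str = "cancer",
             threshold: float = 0.5, spec_target: float = 0.90) -> EvalReport:
    """Binary evaluation on aggregated held-out probabilities."""
    labels = labels.loc[probs.index]
    auc = auc_mann_whitney(probs, labels, pos_label)
    sens = sensitivity_at_specificity(probs, labels, pos_label, spec_target)
    pred = probs >= threshold
    truth = labels == pos_label
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    confusion = pd.DataFrame(
        [[tp, fn], [fp, tn]],
        index=pd.Index([pos_label, f"not_{pos_label}"], name="truth"),
        columns=pd.Index([pos_label, f"not_{pos_label}"], name="predicted"))
    return EvalReport(n=len(probs), auc=auc, sensitivity_at_spec=sens,
                      spec_target=spec_target, f1=float(f1),
                      threshold=threshold, confusion=confusion)


def evaluate_multiclass(prob_vectors: pd.DataFrame,
                        labels: pd.Series) -> EvalReport:
    """Argmax evaluation for >= 3 classes: overall accuracy + confusion.

    Probability ties resolve to the lexicographically first class (columns
    are sorted before argmax).
    """
    labels = labels.loc[prob_vectors.index]
    classes = sorted(prob_vectors.columns)
    unknown = set(labels.unique()) - set(map(str, classes)) - set(classes)
    if unknown:
        raise ValidationError(f"labels outside declared class set: {sorted(unknown)}")
    ordered = prob_vectors[classes]
    pred = ordered.idxmax(axis=1)
    acc = float((pred == labels).mean())
    confusion = pd.crosstab(labels, pred).reindex(
        index=classes, columns=classes, fill_value=0)
    confusion.index.name = "truth"
    confusion.columns.name = "predicted"
    return EvalReport(n=len(labels), auc=float("nan"),
                      sensitivity_at_spec=float("nan"), spec_target=float("nan"),
                      f1=float("nan"), threshold=float("nan"),
                      confusion=confusion, accuracy=acc)


def probability_correlations(per_modality: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations of per-modality probabilities.

    Diagonal is 1; pairs involving a constant probability vector are NaN.
    """
    cols = list(per_modality.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            x = per_modality[a].to_numpy()
            yv = per_modality[b].to_numpy()
            if np.all(x == x[0]) or np.all(yv == yv[0]):
                rho = float("nan")
            else:
                rho = float(stats.spearmanr(x, yv).statistic)
            out.loc[a, b] = out.loc[b, a] = rho
    return out
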