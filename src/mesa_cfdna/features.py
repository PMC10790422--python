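"""Feature-matrix assembly and training-side feature selection.

All filters here operate on *training* samples only: inside each
cross-validation iteration, features with any missing training value are
dropped, near-constant features are removed, and — when more features remain
than the model should see — the Boruta all-relevant procedure ranks them
against permuted "shadow" copies and the top ``k`` are kept. Held-out
samples never influence any of these decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .errors import DataError, UsageError, ValidationError

MODALITIES = ("methylation", "occupancy", "fuzziness", "wps")

_STATUS_ORDER = {"confirmed": 0, "tentative": 1, "rejected": 2}


@dataclass
class FeatureMatrix:
    """Samples × features with per-feature modality tags and sample labels."""

    values: pd.DataFrame            # index: sample_ids, columns: feature_ids
    modality: pd.Series             # index: feature_ids
    labels: pd.Series               # index: sample_ids

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate feature ids")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate sample ids")
        self.modality = self.modality.reindex(self.values.columns)
        if self.modality.isna().any():
            missing = list(self.modality.index[self.modality.isna()])[:5]
            raise ValidationError(f"features without modality tag: {missing}")
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])[:5]
            raise ValidationError(f"samples without label: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, features: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[:, list(features)],
                             self.modality.loc[list(features)],
                             self.labels.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        ids = list(sample_ids)
        return FeatureMatrix(self.values.loc[ids], self.modality.copy(),
                             self.labels.loc[ids])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"{m}|{f}" for f, m in self.modality.items()]
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        raw = pd.read_csv(path, sep="\t", index_col="sample_id")
        labels = raw.pop("label")
        feats, mods = [], []
        for col in raw.columns:
            mod, _, feat = col.partition("|")
            if not feat:
                raise DataError(f"feature column {col!r} lacks 'modality|id' tag")
            feats.append(feat)
            mods.append(mod)
        raw.columns = feats
        return cls(raw.astype(float), pd.Series(mods, index=feats), labels)


def assemble(per_sample: Mapping[str, pd.Series], sample_sheet: pd.DataFrame,
             modality: pd.Series | Mapping[str, str] | str) -> FeatureMatrix:
    """Align per-sample feature tables into one matrix.

    ``per_sample`` maps sample_id to a Series of feature values; the feature
    universe is the union, with absent entries left missing. Rows follow the
    sample sheet order and columns are sorted, so input order never matters.
    """
    missing = [s for s in sample_sheet["sample_id"] if s not in per_sample]
    if missing:
        raise DataError(f"samples in sheet without feature data: {missing}")
    ids = list(sample_sheet["sample_id"])
    values = pd.DataFrame({s: per_sample[s] for s in ids}).T
    values = values.loc[ids, sorted(values.columns)].astype(float)
    if isinstance(modality, str):
        modality = pd.Series(modality, index=values.columns)
    else:
        modality = pd.Series(dict(modality))
    labels = sample_sheet.set_index("sample_id")["label"].loc[ids]
    return FeatureMatrix(values, modality, labels)


def drop_na_features(fm: FeatureMatrix, train_ids: Sequence[str]) -> FeatureMatrix:
    """Drop every feature missing in >= 1 *training* sample.

    Features missing only in held-out samples are retained; their held-out
    values are imputed with the training median at predict time.
    """
    train = fm.values.loc[list(train_ids)]
    keep = train.columns[train.notna().all(axis=0)]
    return fm.subset_features(keep)


def drop_low_variance(fm: FeatureMatrix, train_ids: Sequence[str],
                      threshold: float = 1e-8) -> FeatureMatrix:
    """Drop features whose training variance is <= ``threshold``.

    The default threshold only removes (numerically) constant features;
    stricter cuts are a configuration choice.
    """
    if threshold < 0:
        raise UsageError("variance threshold must be >= 0")
    train = fm.values.loc[list(train_ids)]
    var = train.var(axis=0, ddof=0)
    keep = train.columns[var.to_numpy() > threshold]
    return fm.subset_features(keep)


def taps_occupancy_filter(fm: FeatureMatrix) -> FeatureMatrix:
    """Low-coverage occupancy filter for shallow whole-genome data.

    Keeps a feature only if, in every sample, its value is at least that
    sample's mean over all features — i.e. drops regions that fall below
    average coverage in at least one sample, where occupancy estimates are
    unreliable at low depth.
    """
    sample_means = fm.values.mean(axis=1)
    ok = fm.values.ge(sample_means, axis=0).all(axis=0)
    return fm.subset_features(fm.values.columns[ok])


# ---------------------------------------------------------------------------
# Boruta shadow-feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of a Boruta run: full ranking, statuses, and the top-k list."""

    ranking: list[str]
    status: dict[str, str]          # feature -> confirmed / tentative / rejected
    selected: list[str]
    seed: int
    n_iter: int
    mean_importance: pd.Series = field(repr=False)
    hits: pd.Series = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.ranking,
            "rank": np.arange(1, len(self.ranking) + 1),
            "status": [self.status[f] for f in self.ranking],
            "mean_importance": [self.mean_importance[f] for f in self.ranking],
            "hits": [self.hits[f] for f in self.ranking],
            "selected": [f in set(self.selected) for f in self.ranking],
        })


def boruta_select(X: pd.DataFrame, y: Sequence, k: int = 100,
                  max_iter: int = 100, alpha: float = 0.05,
                  seed: int = 0, n_estimators: int = 500,
                  max_depth: int | None = 5,
                  importance: str = "zscore") -> SelectionResult:
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends a permuted shadow copy of every initial feature,
    fits a random forest on ``[candidates | shadows]``, and scores a *hit*
    for every candidate whose importance exceeds the best shadow importance.
    Importance defaults to the Z-score formulation (mean over trees divided
    by the SD over trees), which demotes features whose apparent importance
    is unstable; ``importance="gini"`` uses the raw ensemble importance. The
    shadow pool keeps its initial width even as candidates are rejected, so
    the max-shadow bar does not soften over time. Hit counts are tested against Binomial(iter, 1/2)
    two-sidedly with a Bonferroni correction over the initial feature count:
    significantly many hits confirms a feature, significantly few rejects it
    (rejected features leave the candidate pool). The run stops when nothing
    is left undecided or after ``max_iter`` iterations.

    Features are ranked confirmed > tentative > rejected, by mean importance
    within a status (ties broken by feature id), and the first ``k`` are
    selected.
    """
    if X.isna().any().any():
        raise ValidationError("boruta_select requires a complete matrix; "
                              "apply drop_na_features first")
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("boruta_select needs >= 2 classes in labels")
    rng = np.random.default_rng(seed)
    feats = list(X.columns)
    n0 = len(feats)
    status = {f: "tentative" for f in feats}
    hits = pd.Series(0, index=feats, dtype=int)
    tested = pd.Series(0, index=feats, dtype=int)
    imp_sum = pd.Series(0.0, index=feats)
    Xv = X.to_numpy(dtype=float)
    active = np.ones(n0, dtype=bool)      # candidate pool (not yet rejected)
    undecided = np.ones(n0, dtype=bool)
    two_sided = alpha / (2.0 * n0)
    it = 0
    while it < max_iter and undecided.any():
        it += 1
        Xa = Xv[:, active]
        m_act = Xa.shape[1]
        # shadows permute every *initial* column, not just the survivors:
        # a shrinking shadow pool would lower the max-shadow bar exactly when
        # the surviving candidates are the luckiest ones, inflating false
        # confirmations on pure-noise inputs
        shadow = Xv.copy()
        for j in range(shadow.shape[1]):
            shadow[:, j] = shadow[rng.permutation(shadow.shape[0]), j]
        Z = np.hstack([Xa, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)))
        rf.fit(Z, y)
        if importance == "zscore":
            per_tree = np.array([t.feature_importances_
                                 for t in rf.estimators_])
            imp = per_tree.mean(axis=0) / (per_tree.std(axis=0) + 1e-12)
        elif importance == "gini":
            imp = rf.feature_importances_
        else:
            raise UsageError(f"unknown importance measure {importance!r}")
        m = Xa.shape[1]
        shadow_max = imp[m:].max()
        active_idx = np.flatnonzero(active)
        hit_now = imp[:m] > shadow_max
        hits.iloc[active_idx[hit_now]] += 1
        tested.iloc[active_idx] += 1
        imp_sum.iloc[active_idx] += imp[:m]
        # binomial decisions for the still-undecided candidates
        for i in np.flatnonzero(undecided):
            h, t = int(hits.iloc[i]), int(tested.iloc[i])
            if stats.binom.sf(h - 1, t, 0.5) < two_sided:
                status[feats[i]] = "confirmed"
                undecided[i] = False
            elif stats.binom.cdf(h, t, 0.5) < two_sided:
                status[feats[i]] = "rejected"
                undecided[i] = False
                active[i] = False
    mean_imp = imp_sum / tested.replace(0, 1)
    order = sorted(
        feats,
        key=lambda f: (_STATUS_ORDER[status[f]], -float(mean_imp[f]), f))
    return SelectionResult(
        ranking=order, status=status, selected=order[:min(k, n0)],
        seed=seed, n_iter=it, mean_importance=mean_imp, hits=hits)
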