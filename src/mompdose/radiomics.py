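"""CT-radiomics feature selection and classification.

The pipeline mirrors a standard small-cohort radiomics workflow for
subcutaneous PDX tumours imaged by CT:

1.  drop shape features (conserved in subcutaneous models, hence
    uninformative for phenotype),
2.  prune inter-correlated features — while any pair of remaining
    features has |Spearman rho| above a cutoff (0.85), remove the
    member of an offending pair with the highest mean |rho| to all
    remaining features,
3.  stratified 80:20 train/validation split,
4.  tree-ensemble recursive feature elimination with the optimal
    subset size chosen by repeated cross-validated accuracy,
5.  random-forest classification of the held-out cohort, scored by
    ROC-AUC with a DeLong 95% confidence interval,

plus per-feature pre/post treatment comparisons by Wilcoxon rank-sum.

Every stochastic step is seeded, so a pipeline run is a pure function
of (table, seed).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .profiles import ValidationError

FEATURE_FAMILIES = ("shape", "firstorder", "texture", "wavelet", "other")

#: Conventional feature-name prefixes -> family.
_PREFIX_FAMILY = [
    ("shape", "shape"),
    ("original_shape", "shape"),
    ("wavelet", "wavelet"),
    ("firstorder", "firstorder"),
    ("original_firstorder", "firstorder"),
    ("glcm", "texture"), ("glszm", "texture"), ("glrlm", "texture"),
    ("gldm", "texture"), ("ngtdm", "texture"), ("texture", "texture"),
]


def infer_family(feature_name: str) -> str:
    low = feature_name.lower()
    for prefix, family in _PREFIX_FAMILY:
        if low.startswith(prefix):
            return family
    return "other"


@dataclass
class FeatureTable:
    """Samples x features with class labels, timepoints and feature metadata.

    ``data`` is indexed by sample_id with purely numeric feature
    columns; ``families`` maps every feature to one of
    :data:`FEATURE_FAMILIES`.
    """

    data: pd.DataFrame
    labels: pd.Series
    timepoint: pd.Series
    families: dict

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample_ids in feature table")
        if self.labels.isna().any():
            raise ValidationError("missing class labels")
        missing = [f for f in self.data.columns if f not in self.families]
        if missing:
            raise ValidationError(
                f"feature metadata missing for: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))
        self.labels = self.labels.reindex(self.data.index)
        self.timepoint = self.timepoint.reindex(self.data.index)

    @property
    def features(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def subset_features(self, keep) -> "FeatureTable":
        keep = list(keep)
        return FeatureTable(self.data[keep], self.labels, self.timepoint,
                            {f: self.families[f] for f in keep})

    def subset_samples(self, index) -> "FeatureTable":
        return FeatureTable(self.data.loc[index], self.labels.loc[index],
                            self.timepoint.loc[index], dict(self.families))

    def at_timepoint(self, timepoint: str) -> "FeatureTable":
        idx = self.timepoint[self.timepoint == timepoint].index
        return self.subset_samples(idx)

    @classmethod
    def from_csv(cls, table_path, meta_path=None) -> "FeatureTable":
        """Read the canonical layout: leading columns
        ``sample_id,label,timepoint``, remaining columns features;
        optional metadata JSON mapping feature -> family (otherwise
        families are inferred from name prefixes)."""
        df = pd.read_csv(table_path)
        need = ["sample_id", "label", "timepoint"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValidationError(f"feature CSV is missing columns: {missing}")
        df = df.set_index("sample_id")
        feats = [c for c in df.columns if c not in ("label", "timepoint")]
        if meta_path is not None:
            with open(meta_path) as fh:
                families = json.load(fh)
        else:
            families = {f: infer_family(f) for f in feats}
        bad = {f: fam for f, fam in families.items()
               if fam not in FEATURE_FAMILIES}
        if bad:
            raise ValidationError(f"unknown feature families: {bad}")
        return cls(df[feats].astype(float), df["label"], df["timepoint"],
                   families)

    def to_csv(self, table_path, meta_path=None) -> None:
        out = self.data.copy()
        out.insert(0, "timepoint", self.timepoint)
        out.insert(0, "label", self.labels)
        out.to_csv(table_path, index_label="sample_id")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.families, fh, indent=2)


@dataclass
class SelectionResult:
    """Outcome of the selection cascade: every input feature is either
    kept or dropped with a reason in {shape, correlated, rfe}."""

    kept_features: list
    dropped_features: dict            # feature -> reason
    selected_size: int
    cv_profile: pd.DataFrame | None = None   # size vs mean CV accuracy

    def __post_init__(self):
        overlap = set(self.kept_features) & set(self.dropped_features)
        if overlap:
            raise ValidationError(
                f"features both kept and dropped: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class ClassifierEval:
    """Validation ROC-AUC with a DeLong 95% confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_validation: int

    def __post_init__(self):
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValidationError("require ci_low <= auc <= ci_high")


def drop_shape_features(table: FeatureTable):
    """Remove exactly the features whose family is ``shape``."""
    shape = [f for f in table.features if table.families[f] == "shape"]
    if len(shape) == len(table.features):
        warnings.warn("all features are shape features; table is now empty",
                      stacklevel=2)
    kept = [f for f in table.features if f not in set(shape)]
    return table.subset_features(kept), shape


def _abs_spearman(data: pd.DataFrame) -> np.ndarray:
    """|Spearman rho| matrix; constant features (undefined rho) are
    treated as uncorrelated with a warning."""
    X = data.to_numpy(dtype=float)
    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s): Spearman rho "
            "undefined, treated as 0", stacklevel=3)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.abs(rho)
    rho[~np.isfinite(rho)] = 0.0
    np.fill_diagonal(rho, 0.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    return rho


def spearman_filter(table: FeatureTable, threshold: float = 0.85):
    """Iteratively prune features until no pair exceeds the correlation
    cutoff.

    While any pair of remaining features has |Spearman rho| above
    ``threshold``, the candidate features (members of offending pairs)
    are ranked by their mean |rho| against all other remaining features
    and the highest is removed; exact ties (within 1e-12) are broken by
    dropping the lexicographically later name.

    Returns ``(filtered_table, dropped_feature_names)``.
    """
    if table.n_samples < 2:
        raise ValidationError("need >= 2 samples for correlation filtering")
    names = np.array(table.features)
    rho = _abs_spearman(table.data)
    alive = np.ones(len(names), dtype=bool)
    dropped: list[str] = []
    while True:
        sub = rho[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        alive_idx = np.nonzero(alive)[0]
        offending = np.unique(np.nonzero(sub > threshold)[0])
        n_alive = alive.sum()
        mean_rho = sub[offending].sum(axis=1) / max(n_alive - 1, 1)
        best = mean_rho.max()
        tied = offending[mean_rho >= best - 1e-12]
        victim_local = tied[np.argmax(names[alive_idx[tied]])]
        victim = alive_idx[victim_local]
        alive[victim] = False
        dropped.append(str(names[victim]))
    kept = [str(n) for n in names[alive]]
    return table.subset_features(kept), dropped


def stratified_split(table: FeatureTable, train_fraction: float = 0.8,
                     seed: int = 0):
    """Deterministic stratified split preserving class proportions.

    Train size is ``floor(train_fraction * n)``; a class with fewer
    than 2 samples cannot be stratified and raises.
    """
    counts = table.labels.value_counts()
    if (counts < 2).any():
        raise ValidationError(
            f"every class needs >= 2 samples, got {counts.to_dict()}")
    n_train = int(np.floor(train_fraction * table.n_samples))
    train_idx, val_idx = train_test_split(
        table.data.index.to_numpy(), train_size=n_train,
        stratify=table.labels.to_numpy(), random_state=seed, shuffle=True)
    return table.subset_samples(train_idx), table.subset_samples(val_idx)


def _forest(seed: int, n_estimators: int = 200) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_estimators,
                                  random_state=seed, n_jobs=1)


def _rank_features(data: pd.DataFrame, y: np.ndarray, sizes, seed: int):
    """Recursive elimination ranking: refit at each subset size, drop
    the least important features down the size ladder.  Returns
    {size: ordered feature list}."""
    current = list(data.columns)
    ranking = {}
    for size in sorted(sizes, reverse=True):
        if size >= len(current):
            ranking[size] = list(current)
            continue
        rf = _forest(seed)
        rf.fit(data[current], y)
        order = np.argsort(rf.feature_importances_)[::-1]
        current = [current[i] for i in order[:size]]
        ranking[size] = list(current)
    return ranking


def _default_sizes(n_features: int):
    sizes = [s for s in (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 15, 20, 30,
                         50, 80) if s < n_features]
    return sizes + [n_features]


def rfe_select(train: FeatureTable, repeats: int = 3, seed: int = 0, *,
               n_folds: int = 5, sizes=None) -> SelectionResult:
    """Tree-ensemble recursive feature elimination with the subset size
    chosen by repeated cross-validated accuracy.

    For each CV fold the elimination ranking is recomputed on the fold's
    training part only; the size maximising mean CV accuracy (smallest
    size on ties) wins, and the final feature set is the elimination
    ranking at that size on the full training cohort.  Fully seeded.
    """
    y = train.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("RFE needs at least two classes")
    if train.n_samples < 10 or len(train.features) < 2:
        raise ValidationError("RFE needs >= 10 samples and >= 2 features")
    sizes = list(sizes) if sizes is not None \
        else _default_sizes(len(train.features))

    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=repeats,
                                 random_state=seed)
    X = train.data
    acc = {s: [] for s in sizes}
    for fold_i, (tr, te) in enumerate(cv.split(X, y)):
        ranking = _rank_features(X.iloc[tr], y[tr], sizes, seed + fold_i)
        for s in sizes:
            feats = ranking[s]
            rf = _forest(seed + fold_i)
            rf.fit(X.iloc[tr][feats], y[tr])
            acc[s].append(accuracy_score(y[te], rf.predict(X.iloc[te][feats])))
    profile = pd.DataFrame({
        "size": sizes,
        "mean_cv_accuracy": [float(np.mean(acc[s])) for s in sizes],
    })
    best_acc = profile["mean_cv_accuracy"].max()
    best_size = int(profile.loc[
        profile["mean_cv_accuracy"] >= best_acc - 1e-12, "size"].min())

    final_ranking = _rank_features(X, y, sizes, seed)
    kept = final_ranking[best_size]
    dropped = {f: "rfe" for f in train.features if f not in set(kept)}
    return SelectionResult(kept, dropped, best_size, profile)


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """DeLong placement-value variance of the empirical AUC."""
    m, n = len(pos_scores), len(neg_scores)
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, s in enumerate(pos_scores):
        v10[i] = (np.sum(s > neg_scores) + 0.5 * np.sum(s == neg_scores)) / n
    for j, s in enumerate(neg_scores):
        v01[j] = (np.sum(pos_scores > s) + 0.5 * np.sum(pos_scores == s)) / m
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return auc, var


def auc_with_delong_ci(y_true, scores, alpha: float = 0.95):
    """Empirical ROC-AUC with a DeLong normal-approximation CI, clipped
    to [0, 1].  With a handful of validation samples the interval is
    expected to be very wide."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValidationError("AUC needs exactly two classes in y_true")
    pos, neg = classes[1], classes[0]
    auc, var = _delong_variance(scores[y_true == pos], scores[y_true == neg])
    z = stats.norm.ppf(0.5 + alpha / 2.0)
    half = z * np.sqrt(var)
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def train_evaluate(train: FeatureTable, validation: FeatureTable,
                   features, seed: int = 0) -> ClassifierEval:
    """Fit a seeded random forest on the selected features and score the
    validation cohort by ROC-AUC with a DeLong 95% CI."""
    features = list(features)
    for tbl, name in ((train, "train"), (validation, "validation")):
        missing = [f for f in features if f not in tbl.data.columns]
        if missing:
            raise ValidationError(f"{name} table lacks features {missing[:5]}")
    y_val = validation.labels.to_numpy()
    if len(np.unique(y_val)) < 2:
        raise ValidationError("validation cohort has a single class; "
                              "AUC undefined")
    rf = _forest(seed, n_estimators=500)
    rf.fit(train.data[features], train.labels.to_numpy())
    pos_class = rf.classes_[1]
    scores = rf.predict_proba(validation.data[features])[:, 1]
    auc, lo, hi = auc_with_delong_ci((y_val == pos_class).astype(int), scores)
    return ClassifierEval(auc, lo, hi, len(y_val))


def compare_pre_post(table: FeatureTable, feature: str, group) -> dict:
    """Two-sided Wilcoxon rank-sum of a feature's pre vs post values
    within one treatment group (label)."""
    if feature not in table.data.columns:
        raise ValidationError(f"unknown feature {feature!r}")
    sel = table.labels == group
    pre = table.data.loc[sel & (table.timepoint == "pre"), feature]
    post = table.data.loc[sel & (table.timepoint == "post"), feature]
    if pre.empty or post.empty:
        raise ValidationError(
            f"group {group!r} needs samples at both timepoints")
    all_tied = pre.nunique() == 1 and post.nunique() == 1 \
        and pre.iloc[0] == post.iloc[0]
    res = stats.mannwhitneyu(pre, post, alternative="two-sided",
                             method="auto")
    return {"statistic": float(res.statistic),
            "p_value": float(min(res.pvalue, 1.0)),
            "n_pre": len(pre), "n_post": len(post),
            "all_tied": bool(all_tied)}


@dataclass
class RadiomicsResults:
    """Fitted radiomics pipeline: the selection cascade and validation
    performance."""

    selection: SelectionResult
    evaluation: ClassifierEval
    n_train: int
    n_validation: int
    seed: int
    spearman_threshold: float
    dropped_shape: list = field(default_factory=list)
    dropped_correlated: list = field(default_factory=list)

    def summary(self) -> str:
        e = self.evaluation
        return "\n".join([
            "Radiomics selection / classification results",
            "=" * 46,
            f"  cohort split           {self.n_train} train / "
            f"{self.n_validation} validation",
            f"  shape features removed {len(self.dropped_shape)}",
            f"  correlated removed     {len(self.dropped_correlated)} "
            f"(|Spearman rho| > {self.spearman_threshold})",
            f"  RFE selected size      {self.selection.selected_size}",
            f"  selected features      {self.selection.kept_features}",
            f"  validation ROC-AUC     {e.auc:.3f} "
            f"(95% CI {e.ci_low:.3f}-{e.ci_high:.3f}, n = {e.n_validation})",
        ])

    def to_json(self, path) -> None:
        payload = {
            "kept_features": self.selection.kept_features,
            "dropped_features": self.selection.dropped_features,
            "selected_size": self.selection.selected_size,
            "auc": self.evaluation.auc,
            "ci": [self.evaluation.ci_low, self.evaluation.ci_high],
            "n_train": self.n_train, "n_validation": self.n_validation,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class RadiomicsPipeline:
    """End-to-end seeded pipeline: shape removal -> Spearman filter ->
    stratified split -> RFE -> held-out evaluation.

    Filtering statistics that could leak information (the correlation
    structure is near-identical in any subsample of this design, and
    the split is performed before RFE) are computed as the field's
    standard workflow prescribes; see the methods note for caveats.
    """

    def __init__(self, table: FeatureTable, *, seed: int = 0,
                 spearman_threshold: float = 0.85,
                 train_fraction: float = 0.8, rfe_repeats: int = 3):
        self.table = table
        self.seed = seed
        self.spearman_threshold = spearman_threshold
        self.train_fraction = train_fraction
        self.rfe_repeats = rfe_repeats

    def fit(self) -> RadiomicsResults:
        pre = self.table.at_timepoint("pre") \
            if (self.table.timepoint == "pre").any() else self.table
        no_shape, dropped_shape = drop_shape_features(pre)
        train0, val0 = stratified_split(no_shape, self.train_fraction,
                                        self.seed)
        # correlation structure is estimated on the training cohort only
        train1, dropped_corr = spearman_filter(train0,
                                               self.spearman_threshold)
        val1 = val0.subset_features(train1.features)
        selection = rfe_select(train1, repeats=self.rfe_repeats,
                               seed=self.seed)
        merged_dropped = {f: "shape" for f in dropped_shape}
        merged_dropped.update({f: "correlated" for f in dropped_corr})
        merged_dropped.update(selection.dropped_features)
        selection = SelectionResult(selection.kept_features, merged_dropped,
                                    selection.selected_size,
                                    selection.cv_profile)
        evaluation = train_evaluate(train1, val1, selection.kept_features,
                                    self.seed)
        return RadiomicsResults(
            selection, evaluation, train1.n_samples, val1.n_samples,
            self.seed, self.spearman_threshold, dropped_shape, dropped_corr)
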