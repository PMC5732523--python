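"""Diagnostic-model evaluation for methylation marker panels.

Univariate and multi-marker logistic models (maximum likelihood, Wald CIs,
odds ratios per unit change of methylation fraction, reported on both the
natural-log and log10 scales), rank-statistic ROC/AUC, a Youden-J operating
point, an eight-classifier suite under repeated stratified five-fold
cross-validation, and covariate subgroup analyses.

Models treat samples as independent and unadjusted for covariates; tumor
vs adjacent-normal pairing is carried in metadata only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger("methmarker")

_Z95 = 1.959963984540054
_LN10 = np.log(10.0)

#: labels treated as the positive (case) class
_POSITIVE = {"case", "tumor", "1", "true", "yes"}

MODEL_NAMES = {
    "logistic": "logistic regression",
    "random_forest": "random forest",
    "svm": "supporting vector machine",
    "naive_bayes": "Naive Bayes",
    "neural_net": "neural network",
    "lda": "linear discriminant analysis",
    "mda": "mixture discriminant analysis",
    "fda": "flexible discriminant analysis",
}


@dataclass
class ModelConfig:
    """Pinned hyperparameters for the eight-classifier suite."""

    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    rf_trees: int = 100
    nn_hidden: int = 5
    nn_max_iter: int = 200
    mda_subclasses: int = 3
    fda_degree: int = 2
    operating_rule: str = "youden"  # or "fixed_0.5"


def binarize_labels(labels) -> np.ndarray:
    """Map case/tumor-style labels to 1, everything else to 0."""
    arr = np.asarray(labels)
    return np.array([1 if str(v).strip().lower() in _POSITIVE else 0 for v in arr])


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """An ML logistic fit; ``separation=True`` flags non-finite estimates."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    probs: pd.Series
    separation: bool
    n_dropped: int
    feature_names: list[str] = field(default_factory=list)


def fit_logistic(features: pd.DataFrame, labels) -> LogisticFit:
    """Maximum-likelihood logistic regression of case status on features.

    Samples with any missing feature are dropped (count logged).  Complete
    separation is detected and reported as a flag on the returned fit rather
    than silently diverging.
    """
    X = pd.DataFrame(features).astype(float)
    y = pd.Series(binarize_labels(labels), index=X.index)
    ok = ~X.isna().any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("fit_logistic: dropped %d samples with missing features", n_dropped)
        X, y = X.loc[ok], y.loc[ok]
    if y.nunique() < 2:
        raise ValueError("labels contain a single class")
    if len(X) < 5 * X.shape[1]:
        logger.warning("fit_logistic: only %d samples for %d features", len(X), X.shape[1])

    design = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            res = None
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            separation = True

    if res is None:
        nan = pd.Series(np.nan, index=design.columns)
        probs = pd.Series(np.where(y == 1, 1.0, 0.0), index=y.index)
        return LogisticFit(nan, nan, nan, probs, True, n_dropped, list(X.columns))

    if not separation and np.max(np.abs(res.params.values)) > 1e3:
        separation = True  # numerically diverged slope: treat as separated
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        probs=pd.Series(res.predict(design), index=y.index),
        separation=separation,
        n_dropped=n_dropped,
        feature_names=list(X.columns),
    )


# ---------------------------------------------------------------------------
# ROC / operating point
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """AUC = P(score_case > score_control) + half credit for ties (rank statistic)."""
    s = np.asarray(scores, dtype=float)
    y = binarize_labels(labels)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def operating_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sens + spec - 1 over observed scores.

    A sample is called positive when its score >= threshold; J-ties are
    broken toward the higher-specificity (higher-threshold) point.
    """
    s = np.asarray(scores, dtype=float)
    y = binarize_labels(labels)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    best = None
    for t in np.unique(s):
        pred = s >= t
        sens = float(pred[y == 1].sum() / n1)
        spec = float((~pred)[y == 0].sum() / n0)
        key = (sens + spec - 1.0, spec, t)
        if best is None or key > best[0]:
            best = (key, (float(t), sens, spec))
    return best[1]


def roc_points(scores, labels) -> pd.DataFrame:
    """(threshold, sens, spec) at every observed score, descending threshold."""
    s = np.asarray(scores, dtype=float)
    y = binarize_labels(labels)
    rows = []
    for t in sorted(np.unique(s), reverse=True):
        pred = s >= t
        rows.append(
            (float(t), float(pred[y == 1].mean()), float((~pred)[y == 0].mean()))
        )
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


# ---------------------------------------------------------------------------
# univariate and panel models
# ---------------------------------------------------------------------------


def univariate_results(features: pd.DataFrame, labels, config: ModelConfig | None = None) -> pd.DataFrame:
    """Per-feature logistic OR (log10 and natural-log), Wald CI, P, Sens/Spec/AUC.

    Sens/Spec are resubstitution values at the configured operating rule
    (Youden by default) on the fitted probabilities; AUC is the rank AUC.
    """
    cfg = config or ModelConfig()
    rows = []
    for name in features.columns:
        col = features[[name]].dropna()
        y = pd.Series(binarize_labels(labels), index=features.index).loc[col.index]
        fit = fit_logistic(col, y)
        coef = fit.params.get(name, np.nan)
        se = fit.bse.get(name, np.nan)
        if cfg.operating_rule == "fixed_0.5":
            pred = fit.probs >= 0.5
            sens = float(pred[y == 1].mean())
            spec = float((~pred)[y == 0].mean())
        else:
            _, sens, spec = operating_point(fit.probs.values, y.values)
        rows.append(
            {
                "feature_id": name,
                "log_or": coef,
                "log10_or": coef / _LN10,
                "ci95_low": (coef - _Z95 * se) / _LN10,
                "ci95_high": (coef + _Z95 * se) / _LN10,
                "p_value": fit.pvalues.get(name, np.nan),
                "sens": sens,
                "spec": spec,
                "auc": roc_auc(col[name].values, y.values),
                "separation": fit.separation,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def panel_model(features: pd.DataFrame, labels, config: ModelConfig | None = None):
    """Multi-marker logistic model; returns (fit, metrics dict, ROC points)."""
    cfg = config or ModelConfig()
    X = features.dropna()
    y = pd.Series(binarize_labels(labels), index=features.index).loc[X.index]
    fit = fit_logistic(X, y)
    if cfg.operating_rule == "fixed_0.5":
        pred = fit.probs >= 0.5
        thr, sens, spec = 0.5, float(pred[y == 1].mean()), float((~pred)[y == 0].mean())
    else:
        thr, sens, spec = operating_point(fit.probs.values, y.values)
    metrics = {
        "sensitivity": sens,
        "specificity": spec,
        "auc": roc_auc(fit.probs.values, y.values),
        "threshold": thr,
        "n": int(len(y)),
    }
    return fit, metrics, roc_points(fit.probs.values, y.values)


# ---------------------------------------------------------------------------
# the eight-classifier suite
# ---------------------------------------------------------------------------


class MixtureDiscriminantAnalysis:
    """Discriminant classifier with a Gaussian mixture per class.

    Each class density is a mixture of ``n_subclasses`` Gaussians with a
    covariance tied across that class's subclasses; prediction maximises
    log class prior + log mixture density.
    """

    def __init__(self, n_subclasses: int = 3, reg_covar: float = 1e-3, random_state=None):
        self.n_subclasses = n_subclasses
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._mixtures, self._log_priors = [], []
        for k in self.classes_:
            Xk = X[y == k]
            gm = GaussianMixture(
                n_components=min(self.n_subclasses, len(Xk)),
                covariance_type="tied",
                reg_covar=self.reg_covar,
                random_state=self.random_state,
                n_init=1,
            ).fit(Xk)
            self._mixtures.append(gm)
            self._log_priors.append(np.log(len(Xk) / len(X)))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.column_stack(
            [lp + gm.score_samples(X) for gm, lp in zip(self._mixtures, self._log_priors)]
        )
        return self.classes_[np.argmax(scores, axis=1)]


class FlexibleDiscriminantAnalysis:
    """LDA on a standardized polynomial basis expansion (optimal-scoring view).

    With a degree-1 basis this reduces to ordinary LDA; the default degree-2
    expansion gives the flexible, curved class boundary.
    """

    def __init__(self, degree: int = 2):
        self.degree = degree
        self._pipe = make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=degree, include_bias=False),
            LinearDiscriminantAnalysis(solver="svd"),
        )

    def fit(self, X, y):
        self._pipe.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X):
        return self._pipe.predict(np.asarray(X, dtype=float))


def _make_model(name: str, cfg: ModelConfig, random_state: int):
    if name == "logistic":
        return LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=random_state)
    if name == "svm":
        return SVC(kernel=cfg.svm_kernel, C=cfg.svm_c, gamma="scale")
    if name == "naive_bayes":
        return GaussianNB()
    if name == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=(cfg.nn_hidden,),
            max_iter=cfg.nn_max_iter,
            random_state=random_state,
        )
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "mda":
        return MixtureDiscriminantAnalysis(
            n_subclasses=cfg.mda_subclasses, random_state=random_state
        )
    if name == "fda":
        return FlexibleDiscriminantAnalysis(degree=cfg.fda_degree)
    raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_NAMES)}")


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random stratified fold ids in [0, folds); class counts balanced per fold."""
    fold_id = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_id[idx] = np.arange(len(idx)) % folds
    return fold_id


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    pos, neg = y_true == 1, y_true == 0
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else np.nan
    return sens, spec, float((y_pred == y_true).mean())


def cv_suite(
    features,
    labels,
    models: list[str] | None = None,
    folds: int = 5,
    reps: int = 1000,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV over the named model families.

    Fold assignments are drawn once per replication and shared by every
    model; metrics (sens/spec/accuracy on train and held-out test, at each
    model's default decision cut) are averaged over folds x reps.  Fully
    seeded: the same seed reproduces identical summaries.
    """
    cfg = config or ModelConfig()
    names = models or list(MODEL_NAMES)
    unknown = set(names) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown model(s) {sorted(unknown)}")
    X = np.asarray(features, dtype=float)
    y = binarize_labels(labels)
    if min(np.bincount(y, minlength=2)) < folds:
        raise ValueError(f"need >= {folds} samples per class")

    rng = np.random.default_rng(seed)
    acc = {n: np.zeros((2, 3)) for n in names}  # (train/test) x (sens, spec, acc)
    n_folds_total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from MLP/GMM on small folds
        for rep in range(reps):
            fold_id = _stratified_folds(y, folds, rng)
            model_seed = int(rng.integers(2**31 - 1))
            for f in range(folds):
                test = fold_id == f
                train = ~test
                n_folds_total += 1
                for mi, name in enumerate(names):
                    est = _make_model(name, cfg, model_seed + mi)
                    est.fit(X[train], y[train])
                    acc[name][0] += _fold_metrics(y[train], est.predict(X[train]))
                    acc[name][1] += _fold_metrics(y[test], est.predict(X[test]))

    rows = []
    for name in names:
        tr, te = acc[name] / n_folds_total
        rows.append(
            {
                "model": MODEL_NAMES[name],
                "train_sensitivity": tr[0], "train_specificity": tr[1], "train_accuracy": tr[2],
                "test_sensitivity": te[0], "test_specificity": te[1], "test_accuracy": te[2],
                "folds": folds, "replications": reps,
            }
        )
    return pd.DataFrame(rows).set_index("model")


# ---------------------------------------------------------------------------
# subgroup analyses
# ---------------------------------------------------------------------------

STRATIFIERS = ("age-median", "sex", "smoking", "alcohol")


def _subgroup_assignment(covariates: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "age-median":
        if "age" not in covariates.columns:
            raise ValueError("stratifier age-median needs an 'age' column")
        age = covariates["age"].astype(float)
        med = float(np.median(age))
        return pd.Series(np.where(age < med, "young", "old"), index=covariates.index)
    if stratifier == "sex":
        if "sex" not in covariates.columns:
            raise ValueError("stratifier sex needs a 'sex' column")
        return covariates["sex"].astype(str)
    if stratifier in ("smoking", "alcohol"):
        if stratifier not in covariates.columns:
            raise ValueError(f"stratifier {stratifier} needs a {stratifier!r} column")
        flag = covariates[stratifier].astype(bool)
        return pd.Series(
            np.where(flag, stratifier, f"non-{stratifier}"), index=covariates.index
        )
    raise ValueError(f"unknown stratifier {stratifier!r}; choose from {STRATIFIERS}")


@dataclass
class SubgroupResult:
    stratifier: str
    groups: dict  # name -> {"samples", "evaluable", "univariate", "combined"}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, g in self.groups.items():
            if not g["evaluable"]:
                rows.append({"subgroup": name, "feature_id": "(all)", "n": len(g["samples"]),
                             "evaluable": False})
                continue
            for fid, r in g["univariate"].iterrows():
                rows.append({"subgroup": name, "feature_id": fid, "n": len(g["samples"]),
                             "evaluable": True, **r.to_dict()})
            rows.append({"subgroup": name, "feature_id": "(combined)", "n": len(g["samples"]),
                         "evaluable": True, **g["combined"]})
        return pd.DataFrame(rows)


def subgroup_eval(
    features: pd.DataFrame,
    labels,
    covariates: pd.DataFrame,
    stratifier: str,
    restrict: "pd.Series | None" = None,
    config: ModelConfig | None = None,
) -> SubgroupResult:
    """Per-subgroup univariate logistic results plus the combined-panel AUC.

    Subgroups partition the evaluable samples (non-missing features and
    stratifier).  ``restrict`` optionally pre-filters samples (e.g. a
    male-only mask) before stratifying.  A subgroup missing either class is
    reported as not evaluable, with no model output.
    """
    y = pd.Series(binarize_labels(labels), index=features.index)
    evaluable = features.notna().all(axis=1) & features.index.isin(covariates.index)
    if restrict is not None:
        evaluable &= restrict.reindex(features.index).fillna(False).astype(bool)
    idx = features.index[evaluable]
    assign = _subgroup_assignment(covariates.loc[idx], stratifier)

    groups = {}
    for name in sorted(assign.unique()):
        members = assign.index[assign == name]
        sub_y = y.loc[members]
        if sub_y.nunique() < 2:
            groups[name] = {"samples": list(members), "evaluable": False,
                            "univariate": None, "combined": None}
            continue
        uni = univariate_results(features.loc[members], sub_y, config)
        _, metrics, _ = panel_model(features.loc[members], sub_y, config)
        groups[name] = {
            "samples": list(members),
            "evaluable": True,
            "univariate": uni,
            "combined": {
                "sens": metrics["sensitivity"],
                "spec": metrics["specificity"],
                "auc": metrics["auc"],
            },
        }
    return SubgroupResult(stratifier=stratifier, groups=groups)
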