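"""Plumage-color prediction from melanosome summaries.

Two model families, mirroring standard practice in paleocolor work:
quadratic discriminant analysis (class-specific Gaussians over the
quantitative variables; binary flags cannot enter, but can act as a
pre-filter assigning flagged samples to iridescent), and multinomial
logistic regression (softmax-linear; takes the flags as 0/1 covariates and
makes no normality assumption). Variables are chosen by exhaustive AIC
ranking; performance is assessed with repeated stratified k-fold
cross-validation, Cohen's kappa, and an exact binomial test against the
no-information rate. `model_decay` measures robustness to taphonomic
shrinkage: the fraction of predictions that change when melanosome
dimensions are shrunk as in fossil maturation experiments.

QDA parameter estimation is closed-form and authored here; the MLR fit
uses scikit-learn's multinomial logistic regression with a negligible
ridge for numerical stability.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

CLASSES = ("black", "brown", "grey", "iridescent")

# Analysis-variable names -> SampleSummary columns. "diameter" is the
# literature's synonym for mean width.
FEATURE_COLUMNS = {
    "length": "mean_length_um",
    "diameter": "mean_width_um",
    "aspect_ratio": "aspect_ratio",
    "flatness": "flatness",
    "hollowness": "hollowness",
}
QUANTITATIVE_FEATURES = ("length", "diameter", "aspect_ratio")
DEFAULT_MLR_VARIABLES = ("diameter", "aspect_ratio", "flatness", "hollowness")
DEFAULT_QDA_VARIABLES = ("length", "aspect_ratio", "diameter")


def design_matrix(summaries: pd.DataFrame, variables: Sequence[str]) -> np.ndarray:
    cols = []
    for v in variables:
        col = summaries[FEATURE_COLUMNS[v]]
        cols.append(col.astype(float).to_numpy())
    return np.column_stack(cols)


@dataclass
class ColorClassifier:
    model_kind: str  # "qda" | "mlr"
    variables: list
    classes: list
    # QDA parameters
    means: np.ndarray | None = None  # (K, p)
    covariances: np.ndarray | None = None  # (K, p, p)
    priors: np.ndarray | None = None
    # MLR parameters: coef (K, p), intercept (K,) in sklearn convention
    coef: np.ndarray | None = None
    intercept: np.ndarray | None = None
    n_per_class: dict = field(default_factory=dict)
    flag_prefilter: bool = False

    # -- prediction --------------------------------------------------------

    def predict_proba(self, summaries: pd.DataFrame) -> pd.DataFrame:
        missing = [
            v for v in self.variables if FEATURE_COLUMNS[v] not in summaries.columns
        ]
        if missing:
            raise KeyError(f"missing classifier variable(s): {missing}")
        X = design_matrix(summaries, self.variables)
        if self.model_kind == "qda":
            log_post = np.empty((len(X), len(self.classes)))
            for k in range(len(self.classes)):
                log_post[:, k] = math.log(self.priors[k]) + _mvn_logpdf(
                    X, self.means[k], self.covariances[k]
                )
        else:
            scores = X @ self.coef.T + self.intercept
            log_post = scores
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        out = pd.DataFrame(post, columns=self.classes, index=summaries.index)
        if self.flag_prefilter and {"flatness", "hollowness"} <= set(summaries.columns):
            flagged = (
                summaries["flatness"].astype(bool)
                | summaries["hollowness"].astype(bool)
            ).to_numpy()
            if flagged.any() and "iridescent" in self.classes:
                out.loc[flagged, :] = 0.0
                out.loc[flagged, "iridescent"] = 1.0
        return out

    def predict(self, summaries: pd.DataFrame) -> np.ndarray:
        post = self.predict_proba(summaries)
        return post.columns.to_numpy()[np.argmax(post.to_numpy(), axis=1)]

    # -- persistence -------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = dict(
            model_kind=self.model_kind,
            variables=self.variables,
            classes=self.classes,
            n_per_class=self.n_per_class,
            flag_prefilter=self.flag_prefilter,
        )
        for name in ("means", "covariances", "priors", "coef", "intercept"):
            arr = getattr(self, name)
            payload[name] = None if arr is None else np.asarray(arr).tolist()
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ColorClassifier":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        for name in ("means", "covariances", "priors", "coef", "intercept"):
            if payload[name] is not None:
                payload[name] = np.array(payload[name])
        return cls(**payload)


def _mvn_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    p = len(mean)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("class covariance not positive definite")
    diff = X - mean
    maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    return -0.5 * (p * math.log(2 * math.pi) + logdet + maha)


def fit(
    summaries: pd.DataFrame,
    model_kind: str,
    variables: Sequence[str] | None = None,
    label_col: str = "color_category",
    flag_prefilter: bool = False,
) -> ColorClassifier:
    """Fit a QDA or MLR color classifier.

    QDA: per-class mean and covariance with priors equal to class
    frequencies (quantitative variables only). MLR: maximum-likelihood
    multinomial logit via scikit-learn (ridge 1e-8 scale for stability).
    """
    if model_kind not in ("qda", "mlr"):
        raise ValueError("model_kind must be 'qda' or 'mlr'")
    if variables is None:
        variables = (
            DEFAULT_QDA_VARIABLES if model_kind == "qda" else DEFAULT_MLR_VARIABLES
        )
    variables = list(variables)
    if model_kind == "qda":
        bad = [v for v in variables if v not in QUANTITATIVE_FEATURES]
        if bad:
            raise ValueError(f"qualitative variables cannot enter a QDA: {bad}")
    y = summaries[label_col].to_numpy()
    classes = [c for c in CLASSES if c in set(y)] or sorted(set(y))
    X = design_matrix(summaries, variables)
    n_per_class = {c: int((y == c).sum()) for c in classes}
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    if model_kind == "qda":
        p = X.shape[1]
        means = np.empty((len(classes), p))
        covs = np.empty((len(classes), p, p))
        priors = np.empty(len(classes))
        for k, c in enumerate(classes):
            Xk = X[y == c]
            if len(Xk) <= p:
                raise ValueError(
                    f"class {c!r} has n={len(Xk)} <= {p} variables; "
                    "reduce the variable set"
                )
            means[k] = Xk.mean(axis=0)
            covs[k] = np.cov(Xk, rowvar=False)
            if np.linalg.matrix_rank(covs[k]) < p:
                raise np.linalg.LinAlgError(
                    f"singular covariance for class {c!r}; reduce variables"
                )
            priors[k] = len(Xk) / len(X)
        return ColorClassifier(
            "qda", variables, classes, means=means, covariances=covs,
            priors=priors, n_per_class=n_per_class, flag_prefilter=flag_prefilter,
        )

    model = LogisticRegression(C=1e8, max_iter=5000, tol=1e-8)
    model.fit(X, y)
    coef, intercept = model.coef_, model.intercept_
    if coef.shape[0] == 1:  # binary fit: expand to per-class score rows
        coef = np.vstack([np.zeros_like(coef[0]), coef[0]])
        intercept = np.array([0.0, intercept[0]])
    order = [list(model.classes_).index(c) for c in classes]
    return ColorClassifier(
        "mlr", variables, classes,
        coef=coef[order], intercept=intercept[order],
        n_per_class=n_per_class,
    )


# ---------------------------------------------------------------------------
# AIC variable selection
# ---------------------------------------------------------------------------


def _aic(clf: ColorClassifier, summaries: pd.DataFrame, label_col: str) -> float:
    y = summaries[label_col].to_numpy()
    K, p = len(clf.classes), len(clf.variables)
    if clf.model_kind == "mlr":
        post = clf.predict_proba(summaries)
        ll = float(np.log(np.maximum(post.to_numpy()[
            np.arange(len(y)), [clf.classes.index(c) for c in y]
        ], 1e-300)).sum())
        n_params = (K - 1) * (p + 1)
    else:
        X = design_matrix(summaries, clf.variables)
        ll = 0.0
        for k, c in enumerate(clf.classes):
            Xk = X[y == c]
            ll += float(
                (_mvn_logpdf(Xk, clf.means[k], clf.covariances[k])
                 + math.log(clf.priors[k])).sum()
            )
        n_params = (K - 1) + K * p + K * p * (p + 1) // 2
    return 2 * n_params - 2 * ll


def select_variables(
    summaries: pd.DataFrame,
    model_kind: str,
    candidates: Sequence[str] = tuple(FEATURE_COLUMNS),
    label_col: str = "color_category",
) -> pd.DataFrame:
    """Enumerate all nonempty candidate subsets and rank them by AIC.

    For QDA, qualitative candidates are dropped before enumeration (with a
    note column); subsets with singular class likelihoods are marked
    infeasible and ranked last.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    note = ""
    if model_kind == "qda":
        dropped = [c for c in candidates if c not in QUANTITATIVE_FEATURES]
        if dropped:
            note = f"qualitative candidates skipped for QDA: {dropped}"
            candidates = [c for c in candidates if c in QUANTITATIVE_FEATURES]
    rows = []
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf = fit(summaries, model_kind, subset, label_col=label_col)
                    aic = _aic(clf, summaries, label_col)
                feasible = math.isfinite(aic)
            except (ValueError, np.linalg.LinAlgError):
                aic, feasible = math.inf, False
            rows.append(
                dict(variables=subset, n_vars=r, aic=aic, feasible=feasible,
                     note=note)
            )
    out = pd.DataFrame.from_records(rows).sort_values(
        ["aic", "n_vars"], kind="mergesort"
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a (true x predicted) confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / n**2
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1 - p_e))


@dataclass
class CVResult:
    accuracy: float
    kappa: float
    exact_p: float
    no_information_rate: float
    confusion: pd.DataFrame
    k: int
    repeats: int


def cross_validate(
    summaries: pd.DataFrame,
    model_kind: str,
    variables: Sequence[str] | None = None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    label_col: str = "color_category",
    flag_prefilter: bool = False,
) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    Accuracy is the mean held-out correct fraction; kappa comes from the
    confusion matrix pooled over all folds and repeats; the exact test is a
    one-sided binomial test of the pooled correct count against the
    no-information rate (largest class frequency). Folds shrink with a
    warning if the smallest class has fewer than k members.
    """
    y = summaries[label_col].to_numpy()
    classes = [c for c in CLASSES if c in set(y)] or sorted(set(y))
    min_class = min((y == c).sum() for c in classes)
    if min_class < k:
        warnings.warn(f"smallest class has {min_class} < k={k}; reducing folds")
        k = max(2, int(min_class))
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    idx_of = {c: i for i, c in enumerate(classes)}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            train = summaries.iloc[train_idx]
            test = summaries.iloc[test_idx]
            clf = fit(train, model_kind, variables, label_col=label_col,
                      flag_prefilter=flag_prefilter)
            pred = clf.predict(test)
            truth = y[test_idx]
            fold_acc.append(float(np.mean(pred == truth)))
            for t, pr in zip(truth, pred):
                cm[idx_of[t], idx_of[pr]] += 1
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    nir = max((y == c).mean() for c in classes)
    n_total = int(cm.sum())
    n_correct = int(np.trace(cm))
    exact_p = binomtest(n_correct, n_total, nir, alternative="greater").pvalue
    return CVResult(
        accuracy=float(np.mean(fold_acc)),
        kappa=cohens_kappa(cm),
        exact_p=float(exact_p),
        no_information_rate=float(nir),
        confusion=confusion,
        k=k,
        repeats=repeats,
    )


# ---------------------------------------------------------------------------
# Shrinkage robustness and fossil prediction
# ---------------------------------------------------------------------------


def _shrink_summaries(summaries: pd.DataFrame, fraction: float) -> pd.DataFrame:
    out = summaries.copy()
    out["mean_length_um"] = out["mean_length_um"] * (1 - fraction)
    out["mean_width_um"] = out["mean_width_um"] * (1 - fraction)
    # aspect ratio and flags are unaffected by uniform linear shrinkage
    return out


def model_decay(
    classifier: ColorClassifier,
    summaries: pd.DataFrame,
    fractions: Sequence[float] = (0.10, 0.20, 0.30),
) -> tuple[float, pd.DataFrame]:
    """Percent of predictions changed under dimensional shrinkage.

    The fitted model is re-applied (not retrained) to data whose length and
    width are shrunk by each fraction. Returns the decay percentage at the
    largest fraction and a per-fraction table of predictions.
    """
    base = classifier.predict(summaries)
    rows = []
    tables = {0.0: base}
    for f in sorted(fractions):
        pred = classifier.predict(_shrink_summaries(summaries, f))
        tables[f] = pred
        rows.append(
            dict(fraction=f, pct_changed=100.0 * float(np.mean(pred != base)))
        )
    table = pd.DataFrame.from_records(rows)
    decay = float(table["pct_changed"].iloc[-1]) if len(table) else 0.0
    preds = pd.DataFrame(tables, index=summaries.index)
    preds.columns = [f"shrink_{c}" for c in preds.columns]
    table.attrs["predictions"] = preds
    return decay, table


def predict_fossil(
    classifier: ColorClassifier,
    fossil_summaries: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Posterior color probabilities and threshold calls for fossil samples.

    A sample is called only when its maximum posterior reaches ``threshold``
    (paleocolor practice: >= 50%); otherwise "inconclusive".
    """
    post = classifier.predict_proba(fossil_summaries)
    best = post.to_numpy().argmax(axis=1)
    maxp = post.to_numpy().max(axis=1)
    calls = [
        post.columns[b] if mp >= threshold else "inconclusive"
        for b, mp in zip(best, maxp)
    ]
    out = post.copy()
    if "sample_id" in fossil_summaries.columns:
        out.insert(0, "sample_id", fossil_summaries["sample_id"].to_numpy())
    out["call"] = calls
    out["max_posterior"] = maxp
    out["threshold"] = threshold
    return out
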