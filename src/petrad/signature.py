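"""Radiomic signature construction and honest cross-validated evaluation.

A signature is built in two stages: L1-penalized (LASSO) logistic regression
selects a sparse feature subset, then an AdaBoost ensemble of depth-limited
decision trees turns the selected features into a continuous class score.
Performance is estimated by stratified 10-fold cross-validation repeated 10
times; standardization, LASSO selection and classifier fitting are all redone
inside every training fold so no test information leaks into the model.
Per repeat, the pooled out-of-fold scores give the AUC and the
Youden-optimal sensitivity/specificity/accuracy; means across repeats are
reported, accuracy as a percent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .stats import _binary_labels, _youden_operating_point, mann_whitney_auc

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSpec",
    "SignatureResult",
    "lasso_select",
    "fit_boosting",
    "make_cv_splits",
    "evaluate_signature",
    "combine_with_clinical",
    "CLINICAL_COLUMNS",
]

# age + gender + smoking + stage + 3 lobe dummies (upper lobe is reference)
CLINICAL_COLUMNS = [
    "age",
    "gender_female",
    "smoking_yes",
    "stage_34",
    "loc_middle",
    "loc_lower",
    "loc_overlapping",
]

LASSO_CS = np.logspace(-2.5, 2.0, 12)


@dataclass
class SignatureSpec:
    """Configuration of one signature evaluation."""

    feature_scope: str = "petct"  # "pet" | "ct" | "petct" | "clinical"
    include_clinical: bool = False
    lasso: bool = True
    lasso_cv: int = 10
    n_rounds: int = 100
    max_depth: int = 1
    folds: int = 10
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class SignatureResult:
    auc: float
    accuracy_pct: float
    sensitivity: float
    specificity: float
    per_repeat: pd.DataFrame
    selection_frequency: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def summary_row(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    constant = X.columns[X.nunique() <= 1]
    if len(constant):
        logger.warning("dropping constant feature columns: %s", list(constant))
        X = X.drop(columns=constant)
    return X


def lasso_select(
    features: pd.DataFrame,
    labels,
    cs=LASSO_CS,
    cv: int = 10,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """L1-penalized logistic selection along a penalty path.

    The penalty is chosen by inner stratified ``cv``-fold deviance
    (log-loss) minimization; the selected set is the features with nonzero
    coefficients at that penalty.  Inputs are standardized internally.
    Returns ``(selected_names, coefficients)``.
    """
    y = _binary_labels(labels)
    X = _drop_constant(features)
    if X.shape[1] == 0:
        raise ValueError("no non-constant feature columns")
    Z = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    cv_folds = min(cv, int(np.bincount(y).min()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegressionCV(
            Cs=np.asarray(cs),
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
            max_iter=500,
            refit=True,
            random_state=seed,
        ).fit(Z, y)
    coef = pd.Series(model.coef_.ravel(), index=X.columns)
    selected = list(coef.index[coef != 0])
    return selected, coef


def fit_boosting(
    features: np.ndarray,
    labels,
    n_rounds: int = 100,
    max_depth: int = 1,
    seed: int = 0,
) -> AdaBoostClassifier:
    """Adaptive boosting of depth-limited trees emitting a continuous score."""
    y = _binary_labels(labels)
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=seed),
        n_estimators=n_rounds,
        random_state=seed,
    )
    return model.fit(np.asarray(features, dtype=float), y)


def make_cv_splits(labels, folds: int, repeats: int, seed: int):
    """Deterministic stratified splits: ``repeats`` lists of (train, test) pairs."""
    y = _binary_labels(labels)
    all_repeats = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1000 * r)
        all_repeats.append(list(skf.split(np.zeros(len(y)), y)))
    return all_repeats


def _fallback_feature(X: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Single most discriminative column, used when LASSO selects nothing."""
    aucs = {
        c: abs(mann_whitney_auc(X[c].to_numpy(dtype=float), y) - 0.5)
        for c in X.columns
    }
    return [max(aucs, key=aucs.get)]


def evaluate_signature(
    features: pd.DataFrame, labels, spec: SignatureSpec
) -> SignatureResult:
    """Repeated stratified k-fold evaluation of one signature definition.

    Within each training fold only: constant-column removal, z-score
    standardization, LASSO selection and boosting fit.  Out-of-fold scores
    are pooled per repeat; AUC and Youden-point metrics are averaged across
    repeats.
    """
    y = _binary_labels(labels)
    if len(y) < spec.folds:
        raise ValueError("fewer samples than folds")
    features = features.reset_index(drop=True)
    splits = make_cv_splits(y, spec.folds, spec.repeats, spec.seed)

    selection_counts: dict[str, int] = {}
    n_fits = 0
    repeat_rows = []
    for r, folds in enumerate(splits):
        scores = np.empty(len(y))
        for k, (train, test) in enumerate(folds):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                raise ValueError("a fold lost one of the classes; reduce folds")
            X_train = _drop_constant(features.iloc[train])
            X_test = features.iloc[test][X_train.columns]
            fit_seed = spec.seed + 1000 * r + k
            if spec.lasso:
                selected, _ = lasso_select(
                    X_train, y[train], cv=spec.lasso_cv, seed=fit_seed
                )
                if not selected:
                    selected = _fallback_feature(X_train, y[train])
                    logger.info("empty LASSO selection; falling back to %s", selected)
            else:
                selected = list(X_train.columns)
            for name in selected:
                selection_counts[name] = selection_counts.get(name, 0) + 1
            n_fits += 1

            scaler = StandardScaler().fit(X_train[selected].to_numpy(dtype=float))
            Z_train = scaler.transform(X_train[selected].to_numpy(dtype=float))
            Z_test = scaler.transform(X_test[selected].to_numpy(dtype=float))
            model = fit_boosting(
                Z_train, y[train], spec.n_rounds, spec.max_depth, seed=fit_seed
            )
            scores[test] = model.predict_proba(Z_test)[:, 1]

        auc = mann_whitney_auc(scores, y)
        _, sens, sp, acc = _youden_operating_point(scores, y)
        repeat_rows.append(
            {"repeat": r, "auc": auc, "accuracy_pct": 100.0 * acc,
             "sensitivity": sens, "specificity": sp}
        )

    per_repeat = pd.DataFrame(repeat_rows)
    freq = pd.Series(selection_counts, dtype=float).sort_values(ascending=False) / n_fits
    return SignatureResult(
        auc=float(per_repeat["auc"].mean()),
        accuracy_pct=float(per_repeat["accuracy_pct"].mean()),
        sensitivity=float(per_repeat["sensitivity"].mean()),
        specificity=float(per_repeat["specificity"].mean()),
        per_repeat=per_repeat,
        selection_frequency=freq,
    )


def clinical_design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the clinical covariates (7 columns)."""
    out = pd.DataFrame(index=cohort.index)
    out["age"] = cohort["age"].astype(float)
    out["gender_female"] = (cohort["gender"] == "female").astype(float)
    out["smoking_yes"] = (cohort["smoking"] == "yes").astype(float)
    out["stage_34"] = (cohort["stage"] == "III-IV").astype(float)
    for lobe in ("middle", "lower", "overlapping"):
        out[f"loc_{lobe}"] = (cohort["location"] == lobe).astype(float)
    missing = [
        c for c in ("age", "gender", "smoking", "stage", "location")
        if cohort[c].isna().any()
    ]
    if missing:
        raise ValueError(f"missing clinical covariates: {missing}")
    return out


def combine_with_clinical(
    features: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Append the 7 encoded clinical columns to a radiomic feature matrix.

    Rows are aligned on patient_id; any mismatch is an error rather than a
    silent reorder.
    """
    cohort = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    if list(features.index) != list(cohort.index):
        raise ValueError("feature rows and cohort rows do not align on patient_id")
    clin = clinical_design_matrix(cohort)
    return pd.concat([features, clin], axis=1)
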