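"""Risk models, labels, and evaluation metrics.

The oligogenic score for sample i is the additive gene part of a
logistic model fitted on a task's case/control labels:

    adORS_i = sum_{j in G} beta_j * v_ij

with v_ij the direction-corrected burden of gene j and beta_j its
logistic weight, the model being adjusted for age and sex (and
optionally an APOE allele score).  Two tasks are supported: CN-vs-AD
classification (``CNAD``) and MCI conversion prediction (``MCI_CP``).
Models are developed with a stratified 80:20 train/test split and
stratified 10-fold cross-validation inside the training split.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .burden import BurdenMatrix
from .io_formats import COGNITIVE_SCORES
from .selection import ConstantInputError, pearson_r

__all__ = [
    "APOEWeights",
    "RiskModel",
    "EvalReport",
    "assign_labels",
    "task_labels",
    "parse_apoe",
    "apoe_score",
    "stratified_split",
    "fit_risk_model",
    "adors_score",
    "auroc",
    "auprc",
    "phenotype_association",
    "SingleClassError",
]

TASKS = ("CNAD", "MCI_CP")
LABEL_POLICIES = ("text", "table1")


class SingleClassError(ValueError):
    """A classification metric was requested with only one class present."""


@dataclass(frozen=True)
class APOEWeights:
    """Log-odds weights for the APOE isoform alleles (external GWAS).

    The e3 allele is the reference; e2 is protective and e4 risk
    increasing.  The APOE score of a genotype is
    beta_e2 * (#e2 alleles) + beta_e4 * (#e4 alleles).
    """

    beta_e2: float = -0.47
    beta_e4: float = 1.12


def assign_labels(visits, policy: str = "text") -> str:
    """Collapse a longitudinal diagnosis sequence into a single label.

    Visits are diagnoses in {CN, EMCI, LMCI, AD}, in time order.  Under
    both policies an AD diagnosis must be maintained once reached (a
    relapse excludes the sample), and:

    * MCI_c  — first visit EMCI/LMCI, last visit AD;
    * MCI_nc — every visit EMCI/LMCI;
    * CN     — every visit CN;
    * AD     — policy ``text``: every visit AD;
               policy ``table1``: first visit CN or AD, last visit AD
               (so CN-first converters count as AD);
    * excluded — anything else.
    """
    if policy not in LABEL_POLICIES:
        raise ValueError(f"unknown label policy {policy!r}")
    visits = tuple(visits)
    if not visits:
        raise ValueError("empty visit sequence")
    for v in visits:
        if v not in ("CN", "EMCI", "LMCI", "AD"):
            raise ValueError(f"unknown diagnosis token {v!r}")
    if all(v == "CN" for v in visits):
        return "CN"
    if all(v in ("EMCI", "LMCI") for v in visits):
        return "MCI_nc"
    if visits[-1] == "AD":
        first_ad = visits.index("AD")
        if all(v == "AD" for v in visits[first_ad:]):  # AD maintained
            if visits[0] in ("EMCI", "LMCI"):
                return "MCI_c"
            if visits[0] == "AD":
                return "AD"
            # CN-first converter
            return "AD" if policy == "table1" else "excluded"
    return "excluded"


def task_labels(labels: pd.Series, task: str, policy: str = "text") -> pd.Series:
    """Binary case(1)/control(0) labels for a task; other samples dropped.

    CNAD: controls are CN; cases are AD, plus MCI converters under the
    ``text`` policy (which defines AD as consistently-AD *or* MCI_c).
    MCI_CP: controls MCI_nc, cases MCI_c (policy-independent).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if task == "CNAD":
        cases = {"AD", "MCI_c"} if policy == "text" else {"AD"}
        controls = {"CN"}
    else:
        cases, controls = {"MCI_c"}, {"MCI_nc"}
    out = pd.Series(
        np.where(labels.isin(list(cases)), 1, np.where(labels.isin(list(controls)), 0, -1)),
        index=labels.index,
    )
    return out[out >= 0]


_APOE_RE = re.compile(r"(?:ε|e|E)?([234])")


def parse_apoe(genotype: str) -> tuple[int, int]:
    """Parse an APOE genotype string to allele numbers, e.g. 'e3e4' -> (3, 4)."""
    alleles = _APOE_RE.findall(str(genotype))
    if len(alleles) != 2:
        raise ValueError(f"APOE genotype {genotype!r} does not parse to two alleles")
    return int(alleles[0]), int(alleles[1])


def apoe_score(genotype: str, weights: APOEWeights | None = None) -> float:
    """Weighted APOE allele score: beta_e2 * #e2 + beta_e4 * #e4."""
    w = weights or APOEWeights()
    a, b = parse_apoe(genotype)
    n2 = (a == 2) + (b == 2)
    n4 = (a == 4) + (b == 4)
    return w.beta_e2 * n2 + w.beta_e4 * n4


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic; ties get half credit)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("AUPRC needs both classes present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def stratified_split(
    labels: pd.Series, test_size: float = 0.2, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Label-stratified train/test sample-ID split (reproducible by seed)."""
    ids = np.asarray(labels.index.astype(str))
    train, test = train_test_split(
        ids, test_size=test_size, stratify=labels.to_numpy(), random_state=seed
    )
    return list(train), list(test)


@dataclass
class EvalReport:
    """Cross-validated and held-out performance of one risk model."""

    cv_auroc: list[float]
    cv_auprc: list[float]
    test_auroc: float
    test_auprc: float
    test_auroc_score_only: float | None = None

    @property
    def cv_auroc_mean(self) -> float:
        return float(np.mean(self.cv_auroc))

    @property
    def cv_auroc_sd(self) -> float:
        return float(np.std(self.cv_auroc, ddof=1))

    @property
    def cv_auprc_mean(self) -> float:
        return float(np.mean(self.cv_auprc))

    @property
    def cv_auprc_sd(self) -> float:
        return float(np.std(self.cv_auprc, ddof=1))

    def to_dict(self) -> dict:
        return {
            "cv_auroc_mean": self.cv_auroc_mean,
            "cv_auroc_sd": self.cv_auroc_sd,
            "cv_auprc_mean": self.cv_auprc_mean,
            "cv_auprc_sd": self.cv_auprc_sd,
            "cv_auroc": self.cv_auroc,
            "cv_auprc": self.cv_auprc,
            "test_auroc": self.test_auroc,
            "test_auprc": self.test_auprc,
            "test_auroc_score_only": self.test_auroc_score_only,
        }


@dataclass
class RiskModel:
    """A fitted additive (logistic) risk model.

    ``gene_weights`` carries the weights of the score features (gene
    burdens for the oligogenic score, or e.g. a PRS column for the
    comparator models); ``covariate_weights`` the nuisance adjustments
    (age, sex, optionally apoe).
    """

    task: str
    intercept: float
    gene_weights: dict[str, float]
    covariate_weights: dict[str, float]
    seed: int = 0
    ridge_used: bool = False
    train_samples: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)
    fold_assignments: dict[str, int] = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        weights = {**self.gene_weights, **self.covariate_weights}
        lp = np.full(len(X), self.intercept)
        for name, w in weights.items():
            lp += w * X[name].to_numpy(dtype=float)
        return lp


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge_strength: float) -> tuple[np.ndarray, float, bool]:
    """Unpenalized ML logistic fit with a ridge fallback on separation.

    Returns (coef, intercept, ridge_used).  Separation is flagged when
    the ML fit fails to converge or produces coefficients that are
    numerically unbounded on the standardized scale; the fallback
    refits with an L2 penalty on standardized features and maps the
    coefficients back to the raw scale.
    """
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ml = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
        ml.fit(X, y)
        unconverged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    sd = X.std(axis=0, ddof=0)
    scaled_coef = np.abs(ml.coef_[0]) * np.where(sd > 0, sd, 1.0)
    if not unconverged and scaled_coef.max(initial=0.0) < 50.0:
        return ml.coef_[0].copy(), float(ml.intercept_[0]), False
    warnings.warn("separation suspected; refitting with ridge penalty")
    mu = X.mean(axis=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / safe_sd
    ridge = LogisticRegression(
        C=1.0 / ridge_strength, solver="lbfgs", max_iter=5000, tol=1e-10
    )
    ridge.fit(Z, y)
    coef = ridge.coef_[0] / safe_sd
    intercept = float(ridge.intercept_[0] - np.dot(coef, mu))
    return coef, intercept, True


def fit_risk_model(
    features: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    task: str = "CNAD",
    seed: int = 0,
    n_folds: int = 10,
    test_size: float = 0.2,
    ridge_strength: float = 1.0,
    standardize: bool = False,
    split: tuple[list[str], list[str]] | None = None,
) -> tuple[RiskModel, EvalReport]:
    """Fit the task's logistic model and evaluate it.

    ``features`` (indexed by sample) are the score features — gene
    burdens restricted to the selected set G for the oligogenic score;
    ``covariates`` (age, sex, optionally apoe) are concatenated for
    fitting but reported separately.  The data are split 80:20
    stratified by label; stratified ``n_folds``-fold CV inside the
    training split yields per-fold AUROC/AUPRC, and the final model is
    fitted on the full training split and evaluated on the untouched
    test split.  Features are used raw unless ``standardize``.
    """
    if not features.index.equals(labels.index):
        features = features.loc[labels.index]
    if covariates is not None and not covariates.index.equals(labels.index):
        covariates = covariates.loc[labels.index]
    X_df = features if covariates is None else pd.concat([features, covariates], axis=1)
    feature_names = list(X_df.columns)
    score_names = list(features.columns)
    covariate_names = [] if covariates is None else list(covariates.columns)
    y = labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("need both classes to fit a risk model")

    X = X_df.to_numpy(dtype=float)
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)

    idx = np.arange(len(y))
    if split is None:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_size, stratify=y, random_state=seed
        )
    else:  # split fixed upstream (selection/imputation are train-scoped)
        pos = {str(s): i for i, s in enumerate(X_df.index)}
        train_idx = np.array([pos[str(s)] for s in split[0]])
        test_idx = np.array([pos[str(s)] for s in split[1]])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_auroc, cv_auprc, fold_of = [], [], {}
    for fold, (tr, va) in enumerate(skf.split(X[train_idx], y[train_idx])):
        tr_i, va_i = train_idx[tr], train_idx[va]
        coef, icpt, _ = _fit_logistic(X[tr_i], y[tr_i], ridge_strength)
        lp = X[va_i] @ coef + icpt
        cv_auroc.append(auroc(lp, y[va_i]))
        cv_auprc.append(auprc(lp, y[va_i]))
        for i in va_i:
            fold_of[str(X_df.index[i])] = fold

    coef, intercept, ridge_used = _fit_logistic(X[train_idx], y[train_idx], ridge_strength)
    if standardize:  # map back to raw scale so Eq. 3 uses raw burdens
        coef = coef / np.where(sd > 0, sd, 1.0)
        intercept = intercept - float(np.dot(coef, mu))
    lp_test = X_df.to_numpy(dtype=float)[test_idx] @ coef + intercept

    weights = dict(zip(feature_names, (float(c) for c in coef)))
    model = RiskModel(
        task=task,
        intercept=float(intercept),
        gene_weights={n: weights[n] for n in score_names},
        covariate_weights={n: weights[n] for n in covariate_names},
        seed=seed,
        ridge_used=ridge_used,
        train_samples=[str(s) for s in X_df.index[train_idx]],
        test_samples=[str(s) for s in X_df.index[test_idx]],
        fold_assignments=fold_of,
    )
    score_only = features.to_numpy(dtype=float)[test_idx] @ np.array(
        [model.gene_weights[n] for n in score_names]
    )
    try:
        score_only_auroc = auroc(score_only, y[test_idx])
    except SingleClassError:  # pragma: no cover
        score_only_auroc = None
    report = EvalReport(
        cv_auroc=cv_auroc,
        cv_auprc=cv_auprc,
        test_auroc=auroc(lp_test, y[test_idx]),
        test_auprc=auprc(lp_test, y[test_idx]),
        test_auroc_score_only=score_only_auroc,
    )
    return model, report


def adors_score(
    model: RiskModel,
    burdens: BurdenMatrix | pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    model_name: str = "adORS",
) -> pd.DataFrame:
    """Gene-only oligogenic score per sample, plus the full linear predictor.

    The score is sum_j beta_j v_ij over the model's gene weights only —
    no intercept, no covariate terms.  The companion column
    ``linear_predictor`` adds intercept and covariate terms (covariate
    terms require ``covariates``; otherwise they are omitted from it).
    """
    bdf = burdens.to_frame() if isinstance(burdens, BurdenMatrix) else burdens
    missing = [g for g in model.gene_weights if g not in bdf.columns]
    if missing:
        raise KeyError(f"burden matrix lacks model genes: {missing}")
    genes = list(model.gene_weights)
    beta = np.array([model.gene_weights[g] for g in genes])
    score = bdf[genes].to_numpy(dtype=float) @ beta
    lp = score + model.intercept
    if covariates is not None:
        cov = covariates.loc[bdf.index]
        for name, w in model.covariate_weights.items():
            lp = lp + w * cov[name].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "sample": list(bdf.index),
            "score": score,
            "linear_predictor": lp,
            "model_name": model_name,
            "task": model.task,
        }
    )


def phenotype_association(
    scores: pd.Series,
    phenotypes: pd.DataFrame,
    tests: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of a risk score with cognitive assessments.

    ``scores`` is indexed by sample; ``phenotypes`` carries the
    cognitive score columns.  Samples missing *all* tested scores are
    excluded; each correlation uses pairwise-complete samples.  Returns
    a frame with columns (test, r, n).
    """
    tests = list(tests or COGNITIVE_SCORES)
    common = scores.index.intersection(phenotypes.index)
    scores = scores.loc[common]
    ph = phenotypes.loc[common, tests]
    keep = ~ph.isna().all(axis=1)
    scores, ph = scores[keep], ph[keep]
    rows = []
    for test in tests:
        x = scores.to_numpy(dtype=float)
        y = ph[test].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete pairs for {test}")
        r = pearson_r(x[ok], y[ok])
        rows.append({"test": test, "r": r, "n": int(ok.sum())})
    return pd.DataFrame(rows)
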