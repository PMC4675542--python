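"""Composite logistic risk model over binary carriage markers, with ROC/AUC.

Significant single variants and minimal combinations are recoded as subject
level 0/1 markers (a combination marker is 1 iff the subject carries every
constituent element) and entered jointly into a maximum-likelihood logistic
regression of case status.  Discrimination is summarized by the ROC curve and
its area; a trained model can be transferred verbatim to a replication cohort
(no refitting) to check whether the discrimination survives out of sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.metrics import roc_curve

from .epistasis import (
    EpistasisVerdict,
    flint_exact_test,
    sf_flint_decision,
    synergy_factor,
    table_from_indicators,
)
from .io import CarriagePattern, GenotypeDataset, PatternElement, pattern_carriage


class SeparationError(RuntimeError):
    """Raised when the logistic MLE does not exist (perfect separation)."""


@dataclass
class MarkerSet:
    """Named binary markers, each a carriage pattern recoded to 0/1."""

    markers: list[tuple[str, CarriagePattern]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.markers]

    def design_matrix(self, dataset: GenotypeDataset) -> np.ndarray:
        """(n_samples, n_markers) 0/1 matrix with NaN for missing carriage."""
        cols = []
        for name, pattern in self.markers:
            for e in pattern.elements:
                if e.locus_id not in {l.id for l in dataset.loci}:
                    raise KeyError(f"marker {name}: locus {e.locus_id} absent from dataset")
            cols.append(pattern_carriage(dataset, pattern))
        return np.column_stack(cols)


@dataclass
class CompositeModel:
    marker_names: list[str]
    intercept: float
    beta: np.ndarray
    wald_p: np.ndarray  # per marker coefficient
    train_auc: float
    ridged: bool = False

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.beta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "markers": self.marker_names,
                "intercept": self.intercept,
                "beta": list(map(float, self.beta)),
                "wald_p": list(map(float, self.wald_p)),
                "train_auc": self.train_auc,
                "ridged": self.ridged,
            },
            indent=2,
        )


@dataclass
class RocCurve:
    points: np.ndarray  # ordered (FPR, TPR) pairs, (0,0) .. (1,1)
    auc: float


def _complete_cases(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ~np.isnan(X).any(axis=1)
    return X[ok], np.asarray(y)[ok]


def fit_composite_logistic(
    dataset: GenotypeDataset,
    marker_set: MarkerSet,
    on_separation: str = "error",
) -> CompositeModel:
    """ML logistic fit of case status on the binary marker matrix.

    Complete separation raises :class:`SeparationError` by default;
    ``on_separation='ridge'`` falls back to a weakly L2-penalized fit
    (lambda = 1e-4), flagged in the result.
    """
    X, y = _complete_cases(marker_set.design_matrix(dataset), dataset.phenotype)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
            separated = not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 25
        except Exception:
            res, separated = None, True
    if separated:
        if on_separation == "error":
            raise SeparationError(
                "perfect separation: logistic MLE does not exist "
                "(use on_separation='ridge' for a penalized fallback)"
            )
        from sklearn.linear_model import LogisticRegression

        lam = 1e-4
        clf = LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=1000)
        clf.fit(X, y)
        beta = clf.coef_.ravel()
        intercept = float(clf.intercept_[0])
        wald_p = np.full(X.shape[1], np.nan)
        ridged = True
    else:
        beta = res.params[1:]
        intercept = float(res.params[0])
        wald_p = res.pvalues[1:]
        ridged = False
    scores = 1.0 / (1.0 + np.exp(-(intercept + X @ beta)))
    roc = roc_auc(scores, y)
    return CompositeModel(
        marker_names=marker_set.names,
        intercept=intercept,
        beta=np.asarray(beta, dtype=float),
        wald_p=np.asarray(wald_p, dtype=float),
        train_auc=roc.auc,
        ridged=ridged,
    )


def apply_model(
    model: CompositeModel, dataset: GenotypeDataset, marker_set: MarkerSet
) -> np.ndarray:
    """Per-subject fitted probabilities using the trained coefficients, no refit.

    Subjects with missing carriage for any marker get NaN scores.
    """
    if marker_set.names != model.marker_names:
        raise ValueError("marker set does not match the trained model")
    X = marker_set.design_matrix(dataset)
    scores = np.full(len(X), np.nan)
    ok = ~np.isnan(X).any(axis=1)
    scores[ok] = model.predict_proba(X[ok])
    return scores


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve by threshold sweep; trapezoidal AUC (= Mann-Whitney U/(n1*n0)).

    NaN scores are dropped pairwise with their labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    if len(np.unique(labels)) < 2:
        raise ValueError("need both labels present to build a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=np.column_stack([fpr, tpr]), auc=auc)


@dataclass
class GenderModerationReport:
    marker_name: str
    beta_marker: float
    beta_sex: float
    beta_interaction: float
    interaction_p: float
    sf_flint: EpistasisVerdict

    @property
    def moderated(self) -> bool:
        return self.interaction_p < 0.05 or self.sf_flint.call != "none"


def gender_moderation_test(
    dataset: GenotypeDataset,
    marker: tuple[str, CarriagePattern] | PatternElement | CarriagePattern,
) -> GenderModerationReport:
    """Test whether a marker's effect differs between the sexes.

    Fits outcome ~ marker + male + marker:male and reports the Wald p of the
    interaction term; additionally runs SF+FLINT on the (marker, male,
    outcome) 2x2x2 table, since the procedure accepts any pair of binary
    indicators.  Samples with missing sex or carriage are excluded.
    """
    if isinstance(marker, PatternElement):
        marker = (marker.label, CarriagePattern.of(marker))
    elif isinstance(marker, CarriagePattern):
        marker = (marker.label, marker)
    name, pattern = marker
    carriage = pattern_carriage(dataset, pattern)
    sex = np.array([{"M": 1.0, "F": 0.0}.get(s, np.nan) for s in dataset.sex])
    ok = ~np.isnan(carriage) & ~np.isnan(sex)
    if len(np.unique(sex[ok])) < 2:
        raise ValueError("both sexes must be present")
    x, m, y = carriage[ok], sex[ok], dataset.phenotype[ok]
    X = sm.add_constant(np.column_stack([x, m, x * m]), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=False, maxiter=200)
    verdict = sf_flint_decision(
        synergy_factor(tab := table_from_indicators(x, m, y)),
        flint_exact_test(tab),
    )
    return GenderModerationReport(
        marker_name=name,
        beta_marker=float(res.params[1]),
        beta_sex=float(res.params[2]),
        beta_interaction=float(res.params[3]),
        interaction_p=float(res.pvalues[3]),
        sf_flint=verdict,
    )
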