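"""Ligand/decoy screening with logistic regression and ROC analysis.

The screening stage summarizes a posed small molecule by two features:

* ``pm_per_mass`` — the total probability mass of its direct contacts
  (excluding designated anchor fragments, e.g. metal-coordinating oxygens)
  divided by the molecular mass in hydrogen-mass units. It is intensive:
  molecule size does not directly change it.
* ``phob_phil`` — the ratio of hydrophobic to hydrophilic fragment counts, a
  desolvation surrogate.

A two-feature logistic regression with intercept separates ligands from
decoys; a small ridge penalty on the slopes (never the intercept) keeps the
fit convergent under the quasi-separation present in the packaged data. The
packaged 27-molecule feature table (8 COMT ligands, 19 DUD decoys in two
subgroups) ships with the package; rotatable-bond counts are carried but
never fitted by default, as no predictive role was identified for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RocPoint",
    "LigandDecoyClassifier",
    "load_screening_table",
    "compute_features",
    "fit_logistic",
    "roc",
    "bootstrap_logistic",
    "ROC_THRESHOLDS",
]

#: the 12 discrimination thresholds of the screening ROC curve
ROC_THRESHOLDS = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5, 0.65, 0.75, 0.8, 0.9)

#: default ridge penalty on the logistic slopes
RIDGE_DEFAULT = 1e-4

FEATURES = ("pm_per_mass", "phob_phil")


@dataclass(frozen=True)
class RocPoint:
    """One operating point of the ROC curve at a fixed probability threshold."""

    threshold: float
    tpr: float
    fpr: float
    acc: float


def load_screening_table() -> pd.DataFrame:
    """The packaged 27-molecule feature table.

    Columns: index (1..27 ordering), zinc (ZINC identifier), pm_per_mass,
    rot_bonds, phob_phil, label ('ligand' rows 1-8, 'decoy' rows 9-27) and
    subgroup (0 ligands; 1 and 2 the two decoy subsets).
    """
    path = resources.files("contactprefs.data").joinpath("screening_table.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    return df


def compute_features(contact_masses, molecular_mass: float, n_phob: int, n_phil: int,
                     anchor_indices=()) -> tuple:
    """Per-molecule screening features from posed contact masses.

    ``contact_masses`` are the direct-contact probability masses of the
    molecule's fragments in the chosen pose; entries at ``anchor_indices``
    (e.g. metal-coordinating oxygens) are excluded from the sum.
    ``molecular_mass`` is in hydrogen-mass units. Returns
    ``(pm_per_mass, phob_phil)``; a zero hydrophilic count is an error since
    the ratio is undefined.
    """
    if molecular_mass <= 0:
        raise ValueError("molecular mass must be positive")
    if n_phil <= 0:
        raise ValueError("phob/phil ratio undefined with no hydrophilic fragments")
    masses = np.asarray(contact_masses, dtype=float)
    keep = np.ones(len(masses), dtype=bool)
    keep[list(anchor_indices)] = False
    return float(masses[keep].sum() / molecular_mass), float(n_phob / n_phil)


class LigandDecoyClassifier(BaseEstimator, ClassifierMixin):
    """Two-feature logistic regression for ligand/decoy separation.

    Parameters
    ----------
    ridge : float
        L2 penalty on the slopes only (the intercept is unpenalized),
        default 1e-4; keeps the optimizer convergent under quasi-separation.

    Attributes
    ----------
    coef_, intercept_ : fitted slopes and intercept.
    classes_ : the two class labels, decoy-first.
    """

    def __init__(self, ridge: float = RIDGE_DEFAULT):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_samples, n_features)")
        if np.any(np.ptp(X, axis=0) == 0):
            raise ValueError("constant feature column; the fit is unidentified")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("need exactly two classes")
        if np.any(counts < 2):
            raise ValueError("need at least two rows per class")
        self._lr = LogisticRegression(C=1.0 / self.ridge, max_iter=100_000, tol=1e-12)
        self._lr.fit(X, y)
        self.classes_ = self._lr.classes_
        self.coef_ = self._lr.coef_
        self.intercept_ = self._lr.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        return self._lr.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X, threshold: float = 0.5):
        """Predict the positive (second) class iff its probability >= threshold."""
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= threshold, self.classes_[1], self.classes_[0])


def _xy(table: pd.DataFrame):
    X = table[list(FEATURES)].to_numpy(dtype=float)
    y = (table["label"] == "ligand").astype(int).to_numpy()
    return X, y


def fit_logistic(table: pd.DataFrame, ridge: float = RIDGE_DEFAULT) -> np.ndarray:
    """Fit the two-feature model to a screening table and return the in-sample
    probability of being a ligand for every row."""
    X, y = _xy(table)
    clf = LigandDecoyClassifier(ridge=ridge).fit(X, y)
    return clf.predict_proba(X)[:, 1]


def roc(probabilities, labels, thresholds=ROC_THRESHOLDS) -> list:
    """ROC operating points: predict ligand iff probability >= threshold.

    ``labels`` may be the strings 'ligand'/'decoy' or binary 0/1. Raises when
    either class is absent.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = (y == "ligand").astype(int)
    if len(p) != len(y):
        raise ValueError("probabilities and labels are not aligned")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positives and negatives")
    points = []
    for t in thresholds:
        pred = p >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        tn = n_neg - fp
        points.append(
            RocPoint(threshold=float(t), tpr=tp / n_pos, fpr=fp / n_neg,
                     acc=(tp + tn) / len(y))
        )
    return points


def bootstrap_logistic(table: pd.DataFrame, n_boot: int = 200, seed: int | None = None,
                       ridge: float = RIDGE_DEFAULT) -> pd.DataFrame:
    """Bootstrap the fit over the two decoy subgroups.

    Each replicate resamples every decoy subgroup with replacement (ligand
    rows are kept fixed), refits, and records the probability of every
    original row under the replicate model. Returns a DataFrame indexed like
    ``table`` with ``mean``/``se`` columns plus the replicate count used;
    replicates whose resample collapses to a single class are skipped and
    counted in ``df.attrs['skipped']``.
    """
    rng = np.random.default_rng(seed)
    X_all, _ = _xy(table)
    ligands = table[table["label"] == "ligand"]
    groups = [g for _, g in table[table["label"] == "decoy"].groupby("subgroup")]
    if not groups:
        raise ValueError("no decoy subgroups to resample")
    probs, skipped = [], 0
    for _ in range(n_boot):
        parts = [ligands]
        for g in groups:
            idx = rng.integers(0, len(g), size=len(g))
            parts.append(g.iloc[idx])
        boot = pd.concat(parts, ignore_index=True)
        if boot["label"].nunique() < 2:
            skipped += 1
            continue
        Xb, yb = _xy(boot)
        try:
            clf = LigandDecoyClassifier(ridge=ridge).fit(Xb, yb)
        except ValueError:
            skipped += 1
            continue
        probs.append(clf.predict_proba(X_all)[:, 1])
    arr = np.asarray(probs)
    out = pd.DataFrame(
        {
            "mean": arr.mean(axis=0),
            "se": arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1]),
        },
        index=table.index,
    )
    out.attrs["n_replicates"] = len(arr)
    out.attrs["skipped"] = skipped
    return out
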