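"""Binary air-printability classification from rheological features.

A bath is "printable" (holds air channels) when its yield stress can
balance the capillary pressure at the printed radius and the bath still
recovers after nozzle passage (it is not so viscous/elastic that it
tears). The classifier bank predicts that label from three features --
yield stress (Pa), reference viscosity at 0.01 1/s (Pa*s) and nozzle
diameter (um) -- with nozzle type, speed and air flow rate held constant,
using seven model families: random forest, XGBoost, a feed-forward neural
network, k-nearest neighbors, logistic regression, a support vector
machine and naive Bayes.

Because the features span decades, models operate on standardized log10
features. A physics-informed synthetic generator emulates the
(yield stress, viscosity, nozzle diameter, label) schema: the ground-truth
label is printable iff the plastocapillary number at the nozzle radius
exceeds ``y_crit`` and the reference viscosity stays below a tearing
threshold; in log space that boundary is piecewise linear, so a clean
dataset is (almost) linearly separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .rheology import DEFAULT_Y_CRIT

__all__ = [
    "PrintabilityRecord",
    "ClassifierReport",
    "LoadReport",
    "FAMILY_NAMES",
    "generate_synthetic_dataset",
    "train_classifiers",
    "predict_printability",
    "load_printability_csv",
    "write_printability_csv",
    "records_to_dataframe",
]

LABEL_PRINTABLE = "printable"
LABEL_NOT = "not-printable"
FAMILY_NAMES = ("rf", "xgboost", "mlp", "knn", "logreg", "svm", "nb")

DEFAULT_TEAR_VISCOSITY = 3.0e5  # Pa*s at 0.01 1/s, above this the gel tears
DEFAULT_SIGMA = 0.025  # N/m, gel-air surface tension used by the generator
# log-uniform feature ranges bracketing soft-matter baths and print nozzles
DEFAULT_RANGES = {
    "yield_stress": (1.0, 1.0e3),  # Pa
    "viscosity_ref": (10.0, 1.0e6),  # Pa*s
    "nozzle_diameter": (100.0, 2000.0),  # um
}


@dataclass(frozen=True)
class PrintabilityRecord:
    """One (features, label) row of the classifier bank."""

    yield_stress: float  # Pa
    viscosity_ref: float  # Pa*s at shear rate 0.01 1/s
    nozzle_diameter: float  # um
    printable: bool

    def __post_init__(self) -> None:
        feats = (self.yield_stress, self.viscosity_ref, self.nozzle_diameter)
        if not all(np.isfinite(f) and f > 0 for f in feats):
            raise ValueError("features must be positive and finite")

    @property
    def label(self) -> str:
        return LABEL_PRINTABLE if self.printable else LABEL_NOT


def printable_rule(
    yield_stress: np.ndarray,
    viscosity_ref: np.ndarray,
    nozzle_diameter_um: np.ndarray,
    y_crit: float = DEFAULT_Y_CRIT,
    tear_viscosity: float = DEFAULT_TEAR_VISCOSITY,
    sigma: float = DEFAULT_SIGMA,
) -> np.ndarray:
    """Ground-truth generating rule: stable channel and no tearing.

    Printable iff the plastocapillary number Y = tau_y * R / sigma at the
    nozzle radius R = d/2 satisfies Y >= y_crit AND the reference viscosity
    is below the tearing threshold.
    """
    R = np.asarray(nozzle_diameter_um, dtype=float) * 1e-6 / 2.0
    y = np.asarray(yield_stress, dtype=float) * R / sigma
    return (y >= y_crit) & (np.asarray(viscosity_ref) < tear_viscosity)


def generate_synthetic_dataset(
    n: int,
    seed: int,
    y_crit: float = DEFAULT_Y_CRIT,
    tear_viscosity: float = DEFAULT_TEAR_VISCOSITY,
    label_noise: float = 0.0,
    ranges: dict[str, tuple[float, float]] | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> list[PrintabilityRecord]:
    """Sample feature rows log-uniformly and label them by the physics rule.

    ``label_noise`` flips each label independently with that probability.
    """
    if n < 20:
        raise ValueError("need n >= 20 records")
    if not 0.0 <= label_noise < 0.5:
        raise ValueError("label_noise must be in [0, 0.5)")
    ranges = dict(DEFAULT_RANGES, **(ranges or {}))
    for key, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise ValueError(f"degenerate range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)

    def sample(key: str) -> np.ndarray:
        lo, hi = ranges[key]
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    tau_y = sample("yield_stress")
    mu = sample("viscosity_ref")
    d = sample("nozzle_diameter")
    labels = printable_rule(tau_y, mu, d, y_crit, tear_viscosity, sigma)
    if label_noise > 0:
        flips = rng.random(n) < label_noise
        labels = labels ^ flips
    return [
        PrintabilityRecord(
            yield_stress=float(tau_y[i]),
            viscosity_ref=float(mu[i]),
            nozzle_diameter=float(d[i]),
            printable=bool(labels[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    """Cross-validated metrics and the refitted model of one family."""

    family: str
    cv_folds: int
    fold_accuracy: np.ndarray
    fold_precision: np.ndarray
    fold_recall: np.ndarray
    fold_f1: np.ndarray
    confusion: np.ndarray  # 2x2 summed over folds, rows = truth
    model: Pipeline
    feature_ranges: np.ndarray  # (2, 3) min/max of raw features seen in training
    boundary_summary: dict | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))


def _feature_matrix(records: Sequence[PrintabilityRecord]) -> np.ndarray:
    raw = np.array(
        [[r.yield_stress, r.viscosity_ref, r.nozzle_diameter] for r in records]
    )
    return raw


def _make_estimator(family: str, seed: int):
    if family == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if family == "xgboost":
        return XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.2,
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )
    if family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(32, 16), max_iter=3000, random_state=seed
        )
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=7)
    if family == "logreg":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "svm":
        return SVC(probability=True, random_state=seed)
    if family == "nb":
        return GaussianNB()
    raise ValueError(f"unknown model family {family!r}")


def train_classifiers(
    records: Sequence[PrintabilityRecord],
    families: Sequence[str] | str = "all",
    cv_folds: int = 5,
    seed: int = 0,
) -> list[ClassifierReport]:
    """Stratified k-fold evaluation + full refit for each model family.

    Features are log10-transformed and standardized inside the pipeline, so
    scaling is learned on training folds only. Raises on single-class data;
    every fold is checked to contain both classes.
    """
    if isinstance(families, str):
        families = FAMILY_NAMES if families == "all" else (families,)
    unknown = set(families) - set(FAMILY_NAMES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    raw = _feature_matrix(records)
    y = np.array([r.printable for r in records], dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 10:
        import warnings

        warnings.warn(
            f"minority class has only {counts.min()} records; "
            "cross-validated metrics will be noisy"
        )
    X = np.log10(raw)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    reports = []
    for family in families:
        accs, precs, recs, f1s = [], [], [], []
        conf = np.zeros((2, 2), dtype=int)
        for train_idx, test_idx in skf.split(X, y):
            if np.unique(y[train_idx]).size < 2 or np.unique(y[test_idx]).size < 2:
                raise ValueError("a fold lost one of the classes; reduce cv_folds")
            pipe = Pipeline(
                [("scale", StandardScaler()), ("clf", _make_estimator(family, seed))]
            )
            pipe.fit(X[train_idx], y[train_idx])
            pred = pipe.predict(X[test_idx])
            accs.append(accuracy_score(y[test_idx], pred))
            precs.append(precision_score(y[test_idx], pred, zero_division=0))
            recs.append(recall_score(y[test_idx], pred, zero_division=0))
            f1s.append(f1_score(y[test_idx], pred, zero_division=0))
            conf += confusion_matrix(y[test_idx], pred, labels=[0, 1])
        final = Pipeline(
            [("scale", StandardScaler()), ("clf", _make_estimator(family, seed))]
        )
        final.fit(X, y)
        boundary = None
        if family == "logreg":
            clf = final.named_steps["clf"]
            boundary = {
                "coef_log10_yield_stress": float(clf.coef_[0][0]),
                "coef_log10_viscosity": float(clf.coef_[0][1]),
                "coef_log10_nozzle_diameter": float(clf.coef_[0][2]),
                "intercept": float(clf.intercept_[0]),
            }
        reports.append(
            ClassifierReport(
                family=family,
                cv_folds=cv_folds,
                fold_accuracy=np.array(accs),
                fold_precision=np.array(precs),
                fold_recall=np.array(recs),
                fold_f1=np.array(f1s),
                confusion=conf,
                model=final,
                feature_ranges=np.vstack([raw.min(axis=0), raw.max(axis=0)]),
                boundary_summary=boundary,
            )
        )
    return reports


def predict_printability(
    report: ClassifierReport, record: PrintabilityRecord
) -> tuple[str, float]:
    """Predict the label of one record; returns (label, printable-score).

    Warns when a feature lies more than a factor of 10 outside the training
    range (extrapolation).
    """
    raw = np.array(
        [[record.yield_stress, record.viscosity_ref, record.nozzle_diameter]]
    )
    lo, hi = report.feature_ranges
    if (raw[0] < lo / 10).any() or (raw[0] > hi * 10).any():
        import warnings

        warnings.warn("features lie >10x outside the training range")
    score = float(report.model.predict_proba(np.log10(raw))[0, 1])
    return (LABEL_PRINTABLE if score >= 0.5 else LABEL_NOT), score


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("yield_stress_Pa", "viscosity_Pa_s", "nozzle_diameter_um", "label")


@dataclass
class LoadReport:
    records: list[PrintabilityRecord]
    n_rows: int
    rejections: list[tuple[int, str]] = field(default_factory=list)


def records_to_dataframe(records: Sequence[PrintabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "yield_stress_Pa": [r.yield_stress for r in records],
            "viscosity_Pa_s": [r.viscosity_ref for r in records],
            "nozzle_diameter_um": [r.nozzle_diameter for r in records],
            "label": [r.label for r in records],
        }
    )


def write_printability_csv(
    records: Sequence[PrintabilityRecord], path: str | Path
) -> None:
    records_to_dataframe(records).to_csv(path, index=False, float_format="%.17g")


def load_printability_csv(path: str | Path) -> LoadReport:
    """Read and validate a printability CSV; malformed rows are rejected
    individually with reasons rather than failing the whole file."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[PrintabilityRecord] = []
    rejections: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            feats = [
                float(row["yield_stress_Pa"]),
                float(row["viscosity_Pa_s"]),
                float(row["nozzle_diameter_um"]),
            ]
        except (TypeError, ValueError):
            rejections.append((int(i), "non-numeric feature"))
            continue
        label = str(row["label"]).strip().lower()
        if label not in (LABEL_PRINTABLE, LABEL_NOT):
            rejections.append((int(i), f"unknown label {row['label']!r}"))
            continue
        try:
            records.append(
                PrintabilityRecord(
                    yield_stress=feats[0],
                    viscosity_ref=feats[1],
                    nozzle_diameter=feats[2],
                    printable=label == LABEL_PRINTABLE,
                )
            )
        except ValueError as exc:
            rejections.append((int(i), str(exc)))
    return LoadReport(records=records, n_rows=int(df.shape[0]), rejections=rejections)
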