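"""Patient-disjoint evaluation protocol: splits, SVM, metrics, trials.

Images are never split directly: patients are partitioned 70/30
(stratified by class) so that no patient contributes images to both the
training and the test set.  An RBF-kernel SVM (penalty c = 2, kernel
parameter g = 1) is trained on min-max-scaled features, the scaling
statistics fit on the training rows only.  Performance is reported per
magnification as mean +/- sample standard deviation over five trials,
each trial redrawing the patient split, at both the image level
(fraction of test images correct) and the patient level (mean over test
patients of each patient's per-image correct fraction), together with
sensitivity, precision and F1 with malignant as the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from histo3c.fusion_registry import feature_columns
from histo3c.image_channels import SampleMeta

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "malignant"
DEFAULT_C = 2.0
DEFAULT_G = 1.0
DEFAULT_TRAIN_FRACTION = 0.7
DEFAULT_N_TRIALS = 5

METRIC_NAMES = ("image_accuracy", "patient_accuracy", "sensitivity", "precision", "f1")


@dataclass(frozen=True)
class SplitPlan:
    """A patient-disjoint train/test partition."""

    train_patients: frozenset
    test_patients: frozenset
    seed: int
    train_fraction: float = DEFAULT_TRAIN_FRACTION

    def __post_init__(self) -> None:
        if self.train_patients & self.test_patients:
            raise ValueError("train and test patient sets overlap")


@dataclass
class ConfusionCounts:
    """Binary confusion counts with malignant as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def n_correct(self) -> int:
        return self.TP + self.TN

    @classmethod
    def from_labels(cls, y_true: Sequence[str], y_pred: Sequence[str]) -> "ConfusionCounts":
        t = np.asarray(y_true) == POSITIVE_CLASS
        p = np.asarray(y_pred) == POSITIVE_CLASS
        return cls(
            TP=int((t & p).sum()),
            TN=int((~t & ~p).sum()),
            FP=int((~t & p).sum()),
            FN=int((t & ~p).sum()),
        )


def split_patients(
    metas: Iterable[SampleMeta],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> SplitPlan:
    """Random patient-level split, stratified by class.

    Each class's patients are independently split at train_fraction
    (rounded to nearest, keeping at least one patient on each side).
    """
    by_class: dict[str, set] = {}
    for m in metas:
        by_class.setdefault(m.class_label, set()).add(m.patient_id)
    for label, patients in by_class.items():
        if len(patients) < 2:
            raise ValueError(f"class {label!r} has {len(patients)} patient(s); need >= 2 to split")
    rng = np.random.default_rng(seed)
    train: set = set()
    test: set = set()
    for label in sorted(by_class):
        patients = sorted(by_class[label])
        n_train = int(round(train_fraction * len(patients)))
        n_train = min(max(n_train, 1), len(patients) - 1)
        perm = rng.permutation(len(patients))
        train.update(patients[i] for i in perm[:n_train])
        test.update(patients[i] for i in perm[n_train:])
    return SplitPlan(frozenset(train), frozenset(test), seed, train_fraction)


def train_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    c: float = DEFAULT_C,
    g: float = DEFAULT_G,
    scale: bool = True,
) -> Pipeline:
    """RBF-kernel SVM on (optionally) min-max-scaled features.

    Scaling statistics come from the training rows only, so the fitted
    model is independent of anything in the test set.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set contains a single class")
    X = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    steps = []
    if scale:
        steps.append(("scale", MinMaxScaler()))
    steps.append(("svm", SVC(kernel="rbf", C=c, gamma=g)))
    model = Pipeline(steps)
    model.fit(X, labels)
    return model


def image_accuracy(counts: ConfusionCounts) -> float:
    """Fraction of test images classified correctly."""
    if counts.N == 0:
        raise ValueError("no test images")
    return counts.n_correct / counts.N


def patient_scores(
    patient_ids: Sequence[str], y_true: Sequence[str], y_pred: Sequence[str]
) -> dict[str, float]:
    """Per-patient fraction of that patient's test images correct."""
    pid = np.asarray(patient_ids)
    correct = np.asarray(y_true) == np.asarray(y_pred)
    return {
        p: float(correct[pid == p].mean())
        for p in sorted(set(pid.tolist()))
    }


def patient_accuracy(scores: Mapping[str, float]) -> float:
    """Mean of per-patient scores over the test patients."""
    if not scores:
        raise ValueError("no test patients")
    return float(np.mean(list(scores.values())))


def se_pr_f1(counts: ConfusionCounts) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Sensitivity, precision, F1 (malignant positive).

    A metric whose denominator is zero is returned as None (missing),
    never as 0.
    """
    se = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN > 0 else None
    pr = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP > 0 else None
    denom = 2 * counts.TP + counts.FP + counts.FN
    f1 = 2 * counts.TP / denom if denom > 0 else None
    return se, pr, f1


def format_mean_std(mean: float, std: float) -> str:
    """Render a metric on the percent scale as ``94.12 ± 2.19``."""
    return f"{100 * mean:.2f} ± {100 * std:.2f}"


def run_trial(
    table: pd.DataFrame,
    seed: int,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    c: float = DEFAULT_C,
    g: float = DEFAULT_G,
    scale: bool = True,
) -> dict[str, float]:
    """One split/train/test cycle on a single-magnification feature table."""
    metas = [
        SampleMeta(r.image_id, r.patient_id, r.class_label, r.magnification)
        for r in table.itertuples()
    ]
    plan = split_patients(metas, train_fraction, seed)
    fcols = feature_columns(table)
    in_train = table["patient_id"].isin(plan.train_patients)
    train_df = table[in_train]
    test_df = table[~in_train]
    model = train_classifier(train_df[fcols].to_numpy(), train_df["class_label"], c, g, scale)
    y_pred = model.predict(test_df[fcols].to_numpy())
    y_true = test_df["class_label"].to_numpy()
    counts = ConfusionCounts.from_labels(y_true, y_pred)
    se, pr, f1 = se_pr_f1(counts)
    scores = patient_scores(test_df["patient_id"].to_numpy(), y_true, y_pred)
    return {
        "image_accuracy": image_accuracy(counts),
        "patient_accuracy": patient_accuracy(scores),
        "sensitivity": np.nan if se is None else se,
        "precision": np.nan if pr is None else pr,
        "f1": np.nan if f1 is None else f1,
    }


def run_experiment(
    table: pd.DataFrame,
    n_trials: int = DEFAULT_N_TRIALS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    c: float = DEFAULT_C,
    g: float = DEFAULT_G,
    seed: int = 0,
    scale: bool = True,
) -> pd.DataFrame:
    """Five-trial protocol over each magnification in a feature table.

    Trial t uses seed ``seed + t`` and redraws the patient split.  Returns
    a tidy frame with columns magnification, metric, mean, std, formatted,
    n_trials.  A magnification whose table cannot be split (fewer than two
    patients in some class) is skipped with a warning.
    """
    results = []
    for mag in sorted(table["magnification"].unique()):
        sub = table[table["magnification"] == mag].reset_index(drop=True)
        trials = []
        try:
            for t in range(n_trials):
                trials.append(run_trial(sub, seed + t, train_fraction, c, g, scale))
        except ValueError as exc:
            logger.warning("skipping magnification %s: %s", mag, exc)
            continue
        for metric in METRIC_NAMES:
            vals = np.array([tr[metric] for tr in trials], dtype=np.float64)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            results.append(
                {
                    "magnification": mag,
                    "metric": metric,
                    "mean": mean,
                    "std": std,
                    "formatted": format_mean_std(mean, std),
                    "n_trials": int(vals.size),
                }
            )
    return pd.DataFrame(results)


def report_markdown(report: pd.DataFrame, descriptor: str = "", mode: str = "") -> str:
    """Render a run_experiment frame as a compact markdown table."""
    header = f"### {descriptor} ({mode})\n\n" if descriptor else ""
    lines = ["| Magnification | " + " | ".join(METRIC_NAMES) + " |",
             "|" + "---|" * (len(METRIC_NAMES) + 1)]
    for mag in sorted(report["magnification"].unique()):
        row = [str(mag)]
        sub = report[report["magnification"] == mag].set_index("metric")
        for metric in METRIC_NAMES:
            row.append(sub.loc[metric, "formatted"] if metric in sub.index else "—")
        lines.append("| " + " | ".join(row) + " |")
    return header + "\n".join(lines) + "\n"
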