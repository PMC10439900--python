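"""Cancer-signal-origin (CSO) cascade.

Two classifiers run in sequence under plain stratified 5-fold
cross-validation (80% train / 20% test per fold): the Cancer Classifier
(both cancer types vs healthy controls) gates which test samples are called
cancer-positive, and the Cancer Type Classifier (colorectal vs lung, trained
on the cancer samples of the same training split) assigns each positive call
the type with the highest probability.  Results aggregate into a confusion
matrix of truth class against called type, with a "not_detected" column for
gated-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .nn import CancerScoreNet, DNNConfig
from .simulate import CONTROL

NOT_DETECTED = "not_detected"


@dataclass
class CSOReport:
    calls: pd.DataFrame  # sample_id, truth, cancer_call, type_call, cancer_prob
    confusion: pd.DataFrame  # truth class x (type calls + not_detected)

    def __post_init__(self) -> None:
        gated = self.calls.loc[~self.calls["cancer_call"], "type_call"]
        if gated.notna().any():
            raise ValueError("type_call present for a sample without a cancer call")
        if int(self.confusion.to_numpy().sum()) != len(self.calls):
            raise ValueError("confusion matrix counts do not sum to cohort size")


def cso_crossval(
    X: np.ndarray,
    labels: np.ndarray,
    dnn_config: DNNConfig,
    folds: int = 5,
    seed: int = 0,
    cancer_threshold: float = 0.5,
    sample_ids: list[str] | None = None,
) -> CSOReport:
    """Run the two-stage cascade under stratified k-fold cross-validation.

    ``labels`` are class names with healthy controls labelled "control";
    the remaining classes are the cancer types.  ``cancer_threshold`` is the
    cancer-probability gate (0.5 by default; an anchored threshold can be
    passed instead).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes, counts = np.unique(labels, return_counts=True)
    if CONTROL not in classes:
        raise ValueError(f"labels must include {CONTROL!r}")
    cancer_types = sorted(c for c in classes if c != CONTROL)
    if len(cancer_types) != 2:
        raise ValueError(f"cascade expects exactly two cancer types, got {cancer_types}")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= folds ({folds})"
        )
    n = len(labels)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]

    cancer_call = np.zeros(n, dtype=bool)
    cancer_prob = np.full(n, np.nan)
    type_call = np.array([None] * n, dtype=object)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(2 * folds) % (2**31)
    for f, (train, test) in enumerate(skf.split(X, labels)):
        y_cancer = (labels[train] != CONTROL).astype(int)
        gate = CancerScoreNet(replace(dnn_config, seed=int(fold_seeds[2 * f]))).fit(
            X[train], y_cancer
        )
        tr_cancer = train[labels[train] != CONTROL]
        y_type = (labels[tr_cancer] == cancer_types[1]).astype(int)
        typer = CancerScoreNet(
            replace(dnn_config, seed=int(fold_seeds[2 * f + 1]))
        ).fit(X[tr_cancer], y_type)
        p = gate.cancer_score(X[test])
        cancer_prob[test] = p
        pos = test[p > cancer_threshold]
        cancer_call[pos] = True
        if pos.size:
            p_type = typer.cancer_score(X[pos])
            type_call[pos] = np.where(
                p_type > 0.5, cancer_types[1], cancer_types[0]
            )

    calls = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "truth": labels,
            "cancer_call": cancer_call,
            "type_call": type_call,
            "cancer_prob": cancer_prob,
        }
    )
    confusion = confusion_from_calls(calls, cancer_types)
    return CSOReport(calls, confusion)


def confusion_from_calls(calls: pd.DataFrame, cancer_types: list[str]) -> pd.DataFrame:
    truth_classes = [CONTROL] + list(cancer_types)
    cols = list(cancer_types) + [NOT_DETECTED]
    mat = pd.DataFrame(0, index=truth_classes, columns=cols)
    for _, row in calls.iterrows():
        called = row["type_call"] if row["cancer_call"] else NOT_DETECTED
        mat.loc[row["truth"], called] += 1
    mat.index.name = "truth"
    return mat


@dataclass
class CSOSummary:
    cascade_sensitivity_pct: float
    n_cancer: int
    n_detected: int
    per_type_tpr_pct: dict[str, float]


def cso_summary(report: CSOReport) -> CSOSummary:
    """Cascade sensitivity and per-type true-positive rates.

    Cascade sensitivity = cancer-positive cancer samples / all cancer
    samples.  The per-type TPR is computed among the forwarded true
    positives of that type: typed correctly / forwarded.  With nothing
    forwarded the TPR is reported missing (NaN).
    """
    calls = report.calls
    cancers = calls.loc[calls["truth"] != CONTROL]
    n_cancer = len(cancers)
    detected = cancers.loc[cancers["cancer_call"]]
    sens = len(detected) / n_cancer * 100 if n_cancer else float("nan")
    tpr: dict[str, float] = {}
    for t in sorted(cancers["truth"].unique()):
        fwd = detected.loc[detected["truth"] == t]
        tpr[t] = (
            float((fwd["type_call"] == t).mean() * 100) if len(fwd) else float("nan")
        )
    return CSOSummary(float(sens), n_cancer, len(detected), tpr)
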