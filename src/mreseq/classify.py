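"""Repeated nested cross-validated cancer scoring.

Protocol: for each of 20 repetitions, samples are split into 5 stratified
outer folds.  Within each outer-training set, 5 stratified inner folds each
train one network (the held-back inner part serves as a validation split
whose loss is logged).  Every outer-fold test sample is then scored by each
of the 5 inner models, giving 5 out-of-training scores per repetition and
100 over 20 repetitions.  No score ever comes from a model whose training
set contained the scored sample; :meth:`CancerScoreSet.audit_leakage`
re-checks this exhaustively from the recorded fold assignments.

A sample's cancer score is the mean of its out-of-training scores; the IQR
(Q3 - Q1) of the same scores measures stability across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .nn import CancerScoreNet, DNNConfig


@dataclass(frozen=True)
class CVConfig:
    n_repetitions: int = 20
    outer_folds: int = 5
    inner_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    @property
    def scores_per_sample(self) -> int:
        return self.n_repetitions * self.inner_folds


@dataclass
class FoldRecord:
    repetition: int
    outer_fold: int
    inner_fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    val_loss: float


@dataclass
class CancerScoreSet:
    """Out-of-training scores: (n_samples, n_repetitions * inner_folds)."""

    sample_ids: list[str]
    labels: np.ndarray
    scores: np.ndarray
    fold_log: list[FoldRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must be in [0,1]")

    @property
    def n_scores_per_sample(self) -> int:
        return self.scores.shape[1]

    def mean_scores(self) -> np.ndarray:
        return self.scores.mean(axis=1)

    def iqrs(self) -> np.ndarray:
        q1, q3 = np.percentile(self.scores, [25, 75], axis=1)
        return q3 - q1

    def audit_leakage(self) -> int:
        """Number of (sample, scoring model) pairs where the sample was in
        that model's training set.  Must be zero."""
        violations = 0
        for rec in self.fold_log:
            train = set(rec.train_idx.tolist())
            violations += sum(1 for i in rec.test_idx if i in train)
        return violations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "truth": self.labels,
                "mean_score": self.mean_scores(),
                "iqr": self.iqrs(),
                "n_scores": self.n_scores_per_sample,
            }
        ).set_index("sample_id")


def train_model(X: np.ndarray, y: np.ndarray, config: DNNConfig) -> CancerScoreNet:
    """Fit the cancer-score network; deterministic given ``config.seed``."""
    return CancerScoreNet(config).fit(X, y)


def score_samples(model: CancerScoreNet, X: np.ndarray) -> np.ndarray:
    """Cancer-class softmax probability for each row of ``X``."""
    return model.cancer_score(X)


def repeated_nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    dnn_config: DNNConfig,
    cv_config: CVConfig,
    sample_ids: list[str] | None = None,
) -> CancerScoreSet:
    """Run the repeated nested cross-validation protocol."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("degenerate training set: only one class present")
    if counts.min() < cv_config.outer_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; "
            f"needs >= outer_folds ({cv_config.outer_folds})"
        )
    ss = np.random.SeedSequence(cv_config.seed)
    rep_seeds = ss.generate_state(3 * cv_config.n_repetitions) % (2**31)
    scores = np.full((n, cv_config.scores_per_sample), np.nan)
    log: list[FoldRecord] = []
    for rep in range(cv_config.n_repetitions):
        outer = StratifiedKFold(
            n_splits=cv_config.outer_folds,
            shuffle=True,
            random_state=int(rep_seeds[3 * rep]),
        )
        for ofold, (otrain, otest) in enumerate(outer.split(X, y)):
            inner = StratifiedKFold(
                n_splits=cv_config.inner_folds,
                shuffle=True,
                random_state=int(rep_seeds[3 * rep + 1]) + ofold,
            )
            for ifold, (itrain, ival) in enumerate(outer_inner_split(inner, X, y, otrain)):
                model_seed = int(
                    (rep_seeds[3 * rep + 2] + 1000 * ofold + ifold) % (2**31)
                )
                model = CancerScoreNet(replace(dnn_config, seed=model_seed)).fit(
                    X[itrain], y[itrain]
                )
                val_p = model.predict_proba(X[ival])
                val_loss = float(
                    -np.mean(np.log(val_p[np.arange(len(ival)), y[ival]] + 1e-12))
                )
                col = rep * cv_config.inner_folds + ifold
                scores[otest, col] = model.cancer_score(X[otest])
                log.append(
                    FoldRecord(rep, ofold, ifold, itrain, ival, otest, val_loss)
                )
    assert not np.isnan(scores).any()
    return CancerScoreSet(list(sample_ids), y, scores, log)


def outer_inner_split(inner, X, y, otrain):
    """Inner folds expressed in global sample indices."""
    for itrain_rel, ival_rel in inner.split(X[otrain], y[otrain]):
        yield otrain[itrain_rel], otrain[ival_rel]


def score_summary(score_set: CancerScoreSet) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample (mean, IQR) table and class-average IQR."""
    table = score_set.to_frame()
    by_class = table.groupby("truth")["iqr"].mean()
    by_class.name = "mean_iqr"
    return table, by_class


def sample_size_sweep(
    X: np.ndarray,
    y: np.ndarray,
    ratios: list[float],
    dnn_config: DNNConfig,
    cv_config: CVConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC and average IQR of the mean scores at reduced cohort sizes.

    Each ratio subsamples the cohort without replacement (stratified) and
    reruns the nested CV; a ratio leaving fewer than 2*outer_folds samples
    is skipped with a warning.
    """
    from sklearn.metrics import roc_auc_score
    import warnings as _warnings

    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    rows = []
    for ratio in ratios:
        if not 0 < ratio <= 1:
            raise ValueError("ratios must lie in (0, 1]")
        keep: list[int] = []
        for cls in np.unique(y):
            idx = np.where(y == cls)[0]
            k = max(1, int(round(ratio * idx.size)))
            keep.extend(rng.choice(idx, size=k, replace=False).tolist())
        keep_arr = np.sort(np.array(keep))
        if ratio == 1.0:
            keep_arr = np.arange(len(y))
        if keep_arr.size < 2 * cv_config.outer_folds:
            _warnings.warn(f"ratio {ratio}: too few samples, skipped")
            continue
        # CV seed kept fixed across ratios so ratio=1.0 equals the full run
        score_set = repeated_nested_cv(X[keep_arr], y[keep_arr], dnn_config, cv_config)
        auc = roc_auc_score(y[keep_arr], score_set.mean_scores())
        rows.append(
            {
                "ratio": ratio,
                "n_samples": int(keep_arr.size),
                "auc": float(auc),
                "mean_iqr": float(score_set.iqrs().mean()),
            }
        )
    return pd.DataFrame(rows)
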