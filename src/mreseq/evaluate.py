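"""ROC/AUC, anchored-specificity thresholding, and stratified sensitivity.

The clinical operating point is anchored on specificity rather than chosen
from the ROC curve: the decision threshold is set so that a fixed number of
healthy controls (k, typically 1 of 126 -> 99.2% specificity) score above
it, and sensitivity is then reported per stratum (overall, by stage, by
subtype) with Wilson 95% confidence intervals on the per-sample mean
cross-validation scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint


@dataclass
class ROCResult:
    points: pd.DataFrame  # threshold, fpr, tpr
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and AUC (ties counted 1/2, i.e. the Mann-Whitney statistic
    normalized by n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return ROCResult(pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr}), auc)


def threshold_at_k_false_positives(
    control_scores: np.ndarray, k: int
) -> tuple[float, float]:
    """Decision threshold allowing exactly ``k`` control false positives.

    The threshold sits midway between the k-th and (k+1)-th largest control
    scores (for k=0, midway between the maximum control score and 1).  If
    tied control scores straddle the cut, the threshold is raised onto the
    tie so that false positives stay <= k, with a warning.  Specificity is
    (n - k) / n; calls are positive when score > threshold (strict).
    """
    s = np.sort(np.asarray(control_scores, dtype=float))[::-1]
    n = s.size
    if n < 1:
        raise ValueError("need at least one control score")
    if not 0 <= k < n:
        raise ValueError(f"k must be in [0, {n})")
    if k > 0 and s[k - 1] == s[k]:
        warnings.warn(
            "tied control scores straddle the anchored cut; "
            "threshold placed on the tie keeps false positives <= k but the "
            "realized count may fall below k"
        )
        threshold = float(s[k])
    else:
        upper = 1.0 if k == 0 else s[k - 1]
        threshold = (upper + s[k]) / 2.0
    fp = int((s > threshold).sum())
    specificity = (n - fp) / n
    return float(threshold), float(specificity)


def wilson_ci(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, as proportions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    alpha = 1.0 - confidence
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


# statsmodels is the implementation; keep the closed form documented and
# available for cross-checking
def wilson_ci_closed_form(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    z = norm.ppf((1 + confidence) / 2)
    p = successes / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return float(max(center - half, 0.0)), float(min(center + half, 1.0))


@dataclass
class SensitivityReport:
    threshold: float
    specificity_pct: float
    specificity_ci_pct: tuple[float, float]
    strata: pd.DataFrame  # stratum, n, n_positive, sensitivity_pct, ci_lo_pct, ci_hi_pct


def sensitivity_report(
    scores: np.ndarray,
    labels: np.ndarray,
    strata: pd.Series | None,
    threshold: float,
    control_scores: np.ndarray | None = None,
) -> SensitivityReport:
    """Sensitivity (score > threshold) per stratum with Wilson 95% CIs.

    ``scores``/``labels`` cover the evaluation cohort (1 = case); ``strata``
    labels the cases (stage, subtype, ...).  An "all" row is always included;
    empty strata are reported with n=0 and missing sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    case_mask = labels == 1
    case_scores = scores[case_mask]
    if control_scores is None:
        control_scores = scores[~case_mask]
    control_scores = np.asarray(control_scores, dtype=float)
    n_ctrl = control_scores.size
    fp = int((control_scores > threshold).sum())
    spec_lo, spec_hi = wilson_ci(n_ctrl - fp, n_ctrl) if n_ctrl else (np.nan, np.nan)
    spec = (n_ctrl - fp) / n_ctrl * 100 if n_ctrl else np.nan

    def _row(name: str, mask: np.ndarray) -> dict:
        n = int(mask.sum())
        if n == 0:
            return {
                "stratum": name, "n": 0, "n_positive": 0,
                "sensitivity_pct": np.nan, "ci_lo_pct": np.nan, "ci_hi_pct": np.nan,
            }
        pos = int((case_scores[mask] > threshold).sum())
        lo, hi = wilson_ci(pos, n)
        return {
            "stratum": name, "n": n, "n_positive": pos,
            "sensitivity_pct": pos / n * 100,
            "ci_lo_pct": lo * 100, "ci_hi_pct": hi * 100,
        }

    rows = [_row("all", np.ones(case_scores.size, dtype=bool))]
    if strata is not None:
        svals = pd.Series(strata).reset_index(drop=True)
        if len(svals) != case_scores.size:
            raise ValueError("strata must label exactly the case samples")
        for name in svals.dropna().unique():
            rows.append(_row(str(name), (svals == name).to_numpy()))
        # combined early-stage row when stages I and II are both present
        if {"I", "II"} <= set(svals.dropna().unique()):
            rows.append(_row("I-II", svals.isin(["I", "II"]).to_numpy()))
    return SensitivityReport(
        threshold=float(threshold),
        specificity_pct=float(spec),
        specificity_ci_pct=(spec_lo * 100, spec_hi * 100),
        strata=pd.DataFrame(rows),
    )
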