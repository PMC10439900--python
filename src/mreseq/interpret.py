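"""Marker discovery, model interpretation, and confounder diagnostics.

Per-site two-sample t-tests rank markers that separate cancer from control
depth profiles; feature importance of the trained network is estimated
either by sampling-based Shapley values or by AUC-drop permutation
importance; sites are annotated to genomic region classes (promoter, 5'UTR,
exon, intron, intergenic) from a GFF3; PCA screens for batch structure and
depth outliers; and per-sample mean cancer scores are screened against
age, sex and other covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .nn import CancerScoreNet
from .sites import SacIISiteTable

REGION_CLASSES = ["promoter", "five_prime_utr", "exon", "intron", "intergenic"]
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


# ---------------------------------------------------------------------------
# marker t-tests


def marker_ttests(
    X: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    threshold: float = 1e-7,
    equal_var: bool = True,
    site_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-site two-sample Student t-test (pooled variance by default).

    Returns a table with group means, t, two-sided P, rank (ascending P)
    and a ``selected`` flag at the P threshold.  Sites with zero variance in
    both groups get P = 1 by convention.
    """
    if isinstance(X, pd.DataFrame):
        if site_ids is None:
            site_ids = list(X.columns)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if site_ids is None:
        site_ids = [f"site{j}" for j in range(X.shape[1])]
    a, b = X[labels == 1], X[labels == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    degenerate = np.isnan(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance sites assigned P = 1"
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    table = pd.DataFrame(
        {
            "site_id": site_ids,
            "mean_case": a.mean(axis=0),
            "mean_control": b.mean(axis=0),
            "t": t,
            "p": p,
        }
    )
    order = np.lexsort((-np.abs(table["t"].to_numpy()), table["p"].to_numpy()))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    table["selected"] = table["p"] < threshold
    return table


def top_markers(table: pd.DataFrame, k: int = 1000) -> pd.DataFrame:
    return table.sort_values("rank").head(k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature importance

IMPORTANCE_METHODS = ("shapley", "permutation")


def feature_importance(
    model: CancerScoreNet,
    X: np.ndarray,
    y: np.ndarray | None = None,
    method: str = "permutation",
    n_repeats: int = 5,
    n_permutations: int = 30,
    seed: int = 0,
    site_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature importance of a trained network.

    "shapley" estimates Shapley values of the cancer score by sampling
    feature orderings (marginal contributions against the column-mean
    background, averaged over instances; importance is the mean absolute
    value).  "permutation" is AUC-drop importance and needs labels: the
    decrease in ROC AUC when one feature column is permuted, averaged over
    ``n_repeats`` shuffles; it can be negative and centers on zero for an
    uninformative model.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if site_ids is None:
        site_ids = [f"site{j}" for j in range(d)]
    rng = np.random.default_rng(seed)
    if method == "shapley":
        background = X.mean(axis=0)
        phi = np.zeros((n, d))
        for _ in range(n_permutations):
            order = rng.permutation(d)
            z = np.tile(background, (n, 1))
            prev = model.cancer_score(z)
            for j in order:
                z[:, j] = X[:, j]
                cur = model.cancer_score(z)
                phi[:, j] += cur - prev
                prev = cur
        phi /= n_permutations
        importance = np.abs(phi).mean(axis=0)
    elif method == "permutation":
        if y is None:
            raise ValueError("permutation importance requires labels y")
        y = np.asarray(y, dtype=int)
        base = roc_auc_score(y, model.cancer_score(X))
        importance = np.zeros(d)
        for j in range(d):
            drops = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(n), j]
                drops.append(base - roc_auc_score(y, model.cancer_score(Xp)))
            importance[j] = float(np.mean(drops))
    else:
        raise ValueError(
            f"unknown importance method {method!r}; choose from {IMPORTANCE_METHODS}"
        )
    table = pd.DataFrame({"site_id": site_ids, "importance": importance})
    order = np.argsort(-importance, kind="stable")
    ranks = np.empty(d, dtype=int)
    ranks[order] = np.arange(1, d + 1)
    table["rank"] = ranks
    return table


# ---------------------------------------------------------------------------
# region annotation


def annotate_regions(
    sites: SacIISiteTable,
    gff3: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each site into a genomic region class from a GFF3 annotation.

    Precedence: promoter > 5'UTR > exon > intron > intergenic.  The promoter
    window is [TSS - 2000, TSS + 500) on the annotated strand; intron means
    inside a transcript span but not in any exon.  Sites on contigs absent
    from the annotation are intergenic (with a warning).  Returns (per-site
    table, distribution table with counts and percentages).
    """
    import gffutils
    from intervaltree import IntervalTree

    db = gffutils.create_db(
        str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    trees: dict[str, dict[str, IntervalTree]] = {}

    def _tree(chrom: str, cls: str) -> IntervalTree:
        return trees.setdefault(chrom, {}).setdefault(cls, IntervalTree())

    tx_types = [ft for ft in db.featuretypes() if ft in ("mRNA", "transcript")]
    for ft in tx_types:
        for tx in db.features_of_type(ft):
            start0, end0 = tx.start - 1, tx.end
            _tree(tx.seqid, "transcript").addi(start0, end0)
            if tx.strand == "-":
                tss = end0 - 1
                lo = tss - PROMOTER_DOWNSTREAM + 1
                hi = tss + PROMOTER_UPSTREAM + 1
            else:
                tss = start0
                lo = tss - PROMOTER_UPSTREAM
                hi = tss + PROMOTER_DOWNSTREAM
            _tree(tx.seqid, "promoter").addi(max(lo, 0), hi)
    for ft, cls in [("exon", "exon"), ("five_prime_UTR", "five_prime_utr")]:
        if ft in set(db.featuretypes()):
            for feat in db.features_of_type(ft):
                _tree(feat.seqid, cls).addi(feat.start - 1, feat.end)

    missing_contigs = set()
    classes = []
    for s in sites:
        chrom_trees = trees.get(s.chrom)
        if chrom_trees is None:
            missing_contigs.add(s.chrom)
            classes.append("intergenic")
            continue
        pos = s.motif_start

        def _in(cls: str) -> bool:
            t = chrom_trees.get(cls)
            return bool(t is not None and t.overlaps(pos))

        if _in("promoter"):
            classes.append("promoter")
        elif _in("five_prime_utr"):
            classes.append("five_prime_utr")
        elif _in("exon"):
            classes.append("exon")
        elif _in("transcript"):
            classes.append("intron")
        else:
            classes.append("intergenic")
    if missing_contigs:
        warnings.warn(
            f"sites on contigs absent from annotation treated as intergenic: "
            f"{sorted(missing_contigs)}"
        )
    per_site = pd.DataFrame({"site_id": sites.site_ids, "region": classes})
    counts = per_site["region"].value_counts().reindex(REGION_CLASSES, fill_value=0)
    dist = pd.DataFrame(
        {"count": counts, "percent": counts / counts.sum() * 100}
    )
    dist.index.name = "region"
    return per_site, dist


# ---------------------------------------------------------------------------
# confounder diagnostics


@dataclass
class PCACheck:
    coords: pd.DataFrame  # samples x PC1..PCk
    outlier: pd.Series  # PC1 > threshold
    batch_anova_p: pd.Series  # per PC


def pca_batch_check(
    X: pd.DataFrame,
    batches: pd.Series | np.ndarray,
    pc1_outlier_threshold: float = np.inf,
    n_components: int = 3,
) -> PCACheck:
    """Top principal components of the normalized matrix, PC1 outlier flags,
    and a one-way ANOVA of each PC against sequencing batch."""
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    arr = np.asarray(X, dtype=float)
    k = min(n_components, min(arr.shape) - 1) or 1
    pca = PCA(n_components=k, random_state=0)
    coords = pca.fit_transform(arr - arr.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(k)]
    coords_df = pd.DataFrame(coords, index=index, columns=cols)
    outlier = pd.Series(coords[:, 0] > pc1_outlier_threshold, index=index, name="pc1_outlier")
    batches = pd.Series(np.asarray(batches), index=index)
    pvals = {}
    for c in cols:
        groups = [g.to_numpy() for _, g in coords_df[c].groupby(batches) if len(g) > 0]
        if len(groups) < 2:
            pvals[c] = np.nan
        else:
            pvals[c] = float(stats.f_oneway(*groups).pvalue)
    return PCACheck(coords_df, outlier, pd.Series(pvals, name="batch_anova_p"))


def confounder_screen(
    scores: pd.Series,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
    multivariable: bool = False,
) -> pd.DataFrame:
    """Screen per-sample mean scores against covariates.

    Numeric covariates: Pearson correlation with two-sided P.  Two-level
    categorical covariates: two-sided Student t-test of the score between
    levels.  Constant covariates are reported with missing statistics.  With
    ``multivariable=True`` an OLS fit of score on all screened covariates is
    appended (one row per coefficient, kind "ols").
    """
    meta = metadata.loc[scores.index]
    if covariates is None:
        covariates = [c for c in meta.columns if c not in ("truth_class",)]
    rows = []
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique(dropna=True) < 2:
                rows.append({"covariate": cov, "kind": "pearson",
                             "statistic": np.nan, "p": np.nan})
                continue
            mask = col.notna()
            r, p = stats.pearsonr(scores[mask], col[mask])
            rows.append({"covariate": cov, "kind": "pearson",
                         "statistic": float(r), "p": float(p)})
        else:
            levels = col.dropna().unique()
            if len(levels) != 2:
                rows.append({"covariate": cov, "kind": "ttest",
                             "statistic": np.nan, "p": np.nan})
                continue
            a = scores[col == levels[0]]
            b = scores[col == levels[1]]
            t, p = stats.ttest_ind(a, b)
            rows.append({"covariate": cov, "kind": "ttest",
                         "statistic": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if multivariable:
        import statsmodels.api as sm

        design = pd.get_dummies(meta[covariates], drop_first=True).astype(float)
        design = sm.add_constant(design)
        fit = sm.OLS(scores.astype(float), design, missing="drop").fit()
        ols_rows = pd.DataFrame(
            {
                "covariate": fit.params.index,
                "kind": "ols",
                "statistic": fit.params.to_numpy(),
                "p": fit.pvalues.to_numpy(),
            }
        )
        out = pd.concat([out, ols_rows], ignore_index=True)
    return out
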