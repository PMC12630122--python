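"""Multi-criteria quality ranking and grading of material batches.

Three complementary devices operate on a batches x analytes content
matrix (mg/g):

* **Entropy-weighted TOPSIS.**  Contents are min-max normalized per
  criterion, converted to a column-stochastic proportion matrix, and
  each criterion is weighted by its information divergence
  w_j = (1 - e_j) / sum(1 - e_k), where e_j is the Shannon entropy of
  the proportion column scaled by 1/ln(n).  Alternatives are ranked by
  the closeness coefficient C = d- / (d+ + d-), the relative Euclidean
  proximity to the per-criterion ideal (column maximum of the weighted
  matrix) versus the anti-ideal (column minimum).

* **PCA composite score.**  Contents are z-scored, the first principal
  component of the correlation matrix gives the score
  Y = sum_j v_j X_j (v = unit eigenvector), and the composite score is
  F = (lambda_1 / p) * Y, the PC score weighted by its variance
  proportion.  Both Y and the eigenvector are recomputed from the data,
  never hard-coded.

* **Hierarchical grading.**  Agglomerative clustering (Euclidean
  distance on z-scored contents plus total) cut into k = 3 grades,
  ordered so grade 1 has the best batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr

from . import chemometrics


@dataclass
class EntropyWeights:
    proportions: pd.DataFrame   # column-stochastic p_ij
    entropy: pd.Series          # e_j in [0, 1]
    divergence: pd.Series       # d_j = 1 - e_j
    weights: pd.Series          # w_j = d_j / sum(d)


@dataclass
class TopsisResult:
    weighted: pd.DataFrame      # v_ij = w_j * xn_ij
    ideal: pd.Series
    anti_ideal: pd.Series
    d_plus: pd.Series
    d_minus: pd.Series
    closeness: pd.Series        # C_i in [0, 1]
    rank: pd.Series             # 1 = best


@dataclass
class CompositeScore:
    pc_score: pd.Series         # Y, first-PC score (mean 0)
    score: pd.Series            # F = (lambda_1 / p) * Y
    rank: pd.Series
    eigenvector: pd.Series
    variance_proportion: float  # lambda_1 / p


@dataclass
class GradeResult:
    linkage: np.ndarray
    labels: pd.Series           # grade 1..k, 1 = best
    sizes: pd.Series
    method: str


def minmax_normalize(dm: pd.DataFrame, cost_columns: tuple = ()) -> pd.DataFrame:
    """(x - min) / (max - min) per column; cost-type columns (where
    smaller is better) are flipped to (max - x) / (max - min)."""
    dm = pd.DataFrame(dm).astype(float)
    if len(dm) < 2:
        raise ValueError("need at least two batches")
    span = dm.max() - dm.min()
    constant = span[span == 0]
    if len(constant):
        raise ValueError(f"constant column(s): {list(constant.index)}")
    xn = (dm - dm.min()) / span
    for c in cost_columns:
        xn[c] = 1.0 - xn[c]
    return xn


def proportion_matrix(nm: pd.DataFrame) -> pd.DataFrame:
    """p_ij = xn_ij / sum_i xn_ij (column-stochastic)."""
    sums = nm.sum()
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero column(s): {list(zero.index)}")
    return nm / sums


def entropy_weights(p: pd.DataFrame) -> EntropyWeights:
    """Shannon-entropy criterion weights with the 0*ln(0) := 0 convention.

    e_j = -(1/ln n) sum_i p_ij ln p_ij ; d_j = 1 - e_j ; w_j = d_j / sum d.
    """
    n = len(p)
    arr = p.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(arr > 0, arr * np.log(arr), 0.0)
    e = pd.Series(-plogp.sum(axis=0) / np.log(n), index=p.columns)
    d = 1.0 - e
    if np.allclose(d, 0):
        raise ValueError("every criterion is uniform; weights undefined")
    return EntropyWeights(
        proportions=p, entropy=e, divergence=d, weights=d / d.sum()
    )


def topsis(
    nm: pd.DataFrame, weights: pd.Series, variant: str = "normalized"
) -> TopsisResult:
    """Closeness to the ideal solution under entropy (or any) weights.

    ``variant='normalized'`` (default, the calibrated choice) applies
    weights to the min-max normalized matrix; ``variant='proportion'``
    applies them to the proportion matrix instead.
    """
    if len(nm) < 2:
        raise ValueError("TOPSIS needs at least two alternatives")
    w = pd.Series(weights).reindex(nm.columns)
    if w.isna().any():
        raise KeyError("weights missing for some criteria")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"weights must sum to 1, got {w.sum():.6g}")
    base = proportion_matrix(nm) if variant == "proportion" else nm
    if variant not in ("normalized", "proportion"):
        raise ValueError(f"unknown variant {variant!r}")
    v = base * w
    ideal = v.max()
    anti = v.min()
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    if (denom == 0).any():
        raise ValueError("degenerate alternative with d+ + d- = 0")
    closeness = d_minus / denom
    rank = _dense_rank_desc(closeness)
    return TopsisResult(
        weighted=v,
        ideal=ideal,
        anti_ideal=anti,
        d_plus=d_plus.rename("d_plus"),
        d_minus=d_minus.rename("d_minus"),
        closeness=closeness.rename("closeness"),
        rank=rank,
    )


def evaluate_topsis(
    contents: pd.DataFrame, variant: str = "normalized"
) -> TopsisResult:
    """Full entropy-weighted TOPSIS from a raw content table."""
    nm = minmax_normalize(contents)
    ew = entropy_weights(proportion_matrix(nm))
    return topsis(nm, ew.weights, variant=variant)


def composite_score(contents: pd.DataFrame) -> CompositeScore:
    """First-PC composite quality score of the standardized contents."""
    std = chemometrics.standardize(contents)
    res = chemometrics.pca(std)
    p = contents.shape[1]
    y = res.scores["PC1"].rename("pc_score")
    vprop = float(res.eigenvalues[0]) / p
    f = (vprop * y).rename("score")
    return CompositeScore(
        pc_score=y,
        score=f,
        rank=_dense_rank_desc(f),
        eigenvector=res.eigenvectors["PC1"],
        variance_proportion=vprop,
    )


def hca_grade(
    contents: pd.DataFrame,
    k: int = 3,
    method: str = "average",
    add_total: bool = True,
    order_by: pd.Series | None = None,
) -> GradeResult:
    """Cut an agglomerative tree into k quality grades.

    Clustering runs on z-scored contents (plus their total by default)
    with Euclidean distance.  Grades are renumbered so grade 1 holds the
    best batches: by descending mean of ``order_by`` (e.g. TOPSIS
    closeness or composite score) when given, else by descending mean
    total content.
    """
    if k >= len(contents):
        raise ValueError("k must be smaller than the number of batches")
    X = contents.copy().astype(float)
    if add_total:
        X["total"] = X.sum(axis=1)
    Z = chemometrics.standardize(X).values
    lk = linkage(Z.to_numpy(), method=method, metric="euclidean")
    raw = fcluster(lk, k, criterion="maxclust")
    score = (
        pd.Series(order_by).reindex(contents.index)
        if order_by is not None
        else X.sum(axis=1)
    )
    means = score.groupby(raw).mean().sort_values(ascending=False)
    remap = {old: new for new, old in enumerate(means.index, start=1)}
    labels = pd.Series([remap[c] for c in raw], index=contents.index,
                       name="grade")
    return GradeResult(
        linkage=lk,
        labels=labels,
        sizes=labels.value_counts().sort_index().rename("n_batches"),
        method=method,
    )


def quality_report(
    topsis_result: TopsisResult,
    composite: CompositeScore,
    grades: GradeResult,
) -> pd.DataFrame:
    """Merged per-batch report with rank concordance in ``attrs``."""
    idx = topsis_result.closeness.index
    if not (idx.equals(composite.score.index) and idx.equals(grades.labels.index)):
        raise ValueError("batch ids differ between ranking stages")
    df = pd.DataFrame(
        {
            "closeness": topsis_result.closeness,
            "topsis_rank": topsis_result.rank,
            "composite_score": composite.score,
            "composite_rank": composite.rank,
            "grade": grades.labels,
        }
    )
    rho = spearmanr(df["topsis_rank"], df["composite_rank"]).statistic
    df.attrs["spearman_rho"] = float(rho)
    return df


def _dense_rank_desc(s: pd.Series) -> pd.Series:
    """1 = largest; ties get the first-occurrence order for reporting."""
    order = s.sort_values(ascending=False, kind="stable").index
    return pd.Series(
        np.arange(1, len(s) + 1), index=order, name="rank"
    ).reindex(s.index)
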