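"""Multivariate pattern recognition for fingerprint and content matrices.

Two screens are provided.  Correlation-matrix PCA gives eigenvalues,
variance contributions, loadings (eigenvector * sqrt(eigenvalue)) and
sample scores; with standardized inputs the eigenvalues sum to the
number of variables, so variance percentages are eigenvalue / p * 100.
OPLS-DA separates the between-class variation from variation orthogonal
to the class labels and ranks variables by VIP (Variable Importance in
Projection); variables with VIP > 1 are taken as discriminating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StandardizedMatrix:
    """Column-wise z-scored data with the statistics needed to invert."""

    values: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series

    def inverse(self) -> pd.DataFrame:
        return self.values * self.column_sds + self.column_means


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending
    variance_pct: np.ndarray         # eigenvalue / p * 100
    cumulative_pct: np.ndarray
    eigenvectors: pd.DataFrame       # variables x components
    loadings: pd.DataFrame           # eigenvector * sqrt(eigenvalue)
    scores: pd.DataFrame             # samples x components


@dataclass
class OPLSDAResult:
    t_pred: np.ndarray               # predictive scores
    w_pred: np.ndarray               # predictive weights (unit norm)
    p_pred: np.ndarray               # predictive loadings
    t_orth: np.ndarray               # samples x k orthogonal scores
    p_orth: np.ndarray
    w_orth: np.ndarray
    y: np.ndarray                    # centred +/- class code
    variables: list = field(default_factory=list)
    r2y: float = np.nan
    q2: float = np.nan


def standardize(table: pd.DataFrame) -> StandardizedMatrix:
    """Z-score each column with the sample (n-1) standard deviation."""
    df = pd.DataFrame(table).astype(float)
    if len(df) < 2:
        raise ValueError("standardization needs at least two samples")
    sds = df.std(ddof=1)
    constant = sds[sds == 0]
    if len(constant):
        raise ValueError(f"constant column(s): {list(constant.index)}")
    means = df.mean()
    return StandardizedMatrix((df - means) / sds, means, sds)


def pca(matrix: StandardizedMatrix | pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the correlation matrix.

    Raw (unstandardized) input is standardized first, so this is always
    correlation PCA.  Eigenvector signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    if not isinstance(matrix, StandardizedMatrix):
        matrix = standardize(matrix)
    Z = matrix.values
    if not np.isfinite(Z.to_numpy()).all():
        raise ValueError("non-finite values in input")
    n, p = Z.shape
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: eigenvalues may be unstable", stacklevel=2)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    lam, V = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    V = V[:, order]
    load = V * np.sqrt(lam)
    for k in range(p):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            V[:, k] = -V[:, k]
            load[:, k] = -load[:, k]
    comp = [f"PC{k + 1}" for k in range(p)]
    scores = Z.to_numpy() @ V
    return PCAResult(
        eigenvalues=lam,
        variance_pct=lam / p * 100.0,
        cumulative_pct=np.cumsum(lam / p * 100.0),
        eigenvectors=pd.DataFrame(V, index=Z.columns, columns=comp),
        loadings=pd.DataFrame(load, index=Z.columns, columns=comp),
        scores=pd.DataFrame(scores, index=Z.index, columns=comp),
    )


def _code_labels(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {len(classes)}")
    for c in classes:
        if (labels == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
    y = np.where(labels == classes[1], 1.0, -1.0)
    return y - y.mean(), classes


def _opls_fit(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Core NIPALS-style OPLS: strip y-orthogonal components, then fit
    one predictive PLS component on the deflated X."""
    Xd = X.copy()
    t_o, p_o, w_o = [], [], []
    for _ in range(n_orthogonal):
        w = Xd.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        wo = p - (w @ p) * w          # loading part orthogonal to w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            break
        wo /= norm
        to = Xd @ wo
        po = Xd.T @ to / (to @ to)
        Xd = Xd - np.outer(to, po)
        t_o.append(to)
        p_o.append(po)
        w_o.append(wo)
    w = Xd.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    return Xd, t, w, p, t_o, p_o, w_o


def opls_da(
    matrix: StandardizedMatrix | pd.DataFrame,
    labels,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
) -> OPLSDAResult:
    """OPLS discriminant analysis of a two-class standardized matrix.

    Deterministic: weights are initialized from the class-code vector y,
    so no random start enters the fit.  R2Y is the fraction of y variance
    explained by the predictive component; Q2 is its ``cv_folds``-fold
    cross-validated counterpart (sample-wise, contiguous folds).
    """
    if not isinstance(matrix, StandardizedMatrix):
        matrix = standardize(matrix)
    X = matrix.values.to_numpy()
    y, _ = _code_labels(labels)
    _, t, w, p, t_o, p_o, w_o = _opls_fit(X, y, n_orthogonal)
    c = (y @ t) / (t @ t)
    r2y = 1.0 - float(((y - c * t) ** 2).sum() / (y ** 2).sum())
    q2 = _q2(X, y, n_orthogonal, cv_folds)
    k = len(t_o)
    return OPLSDAResult(
        t_pred=t,
        w_pred=w,
        p_pred=p,
        t_orth=np.column_stack(t_o) if k else np.empty((len(y), 0)),
        p_orth=np.column_stack(p_o) if k else np.empty((X.shape[1], 0)),
        w_orth=np.column_stack(w_o) if k else np.empty((X.shape[1], 0)),
        y=y,
        variables=list(matrix.values.columns),
        r2y=r2y,
        q2=q2,
    )


def _q2(X: np.ndarray, y: np.ndarray, n_orthogonal: int, folds: int) -> float:
    n = len(y)
    folds = min(folds, n)
    idx = np.arange(n)
    press = 0.0
    for f in range(folds):
        test = idx[f::folds]
        train = np.setdiff1d(idx, test)
        if len(set(np.sign(y[train]))) < 2:
            continue
        Xd, t, w, p, t_o, p_o, w_o = _opls_fit(X[train], y[train], n_orthogonal)
        c = (y[train] @ t) / (t @ t)
        Xt = X[test].copy()
        for wo, po in zip(
            (w_o[k] for k in range(len(w_o))), (p_o[k] for k in range(len(p_o)))
        ):
            to = Xt @ wo
            Xt = Xt - np.outer(to, po)
        yhat = c * (Xt @ w)
        press += float(((y[test] - yhat) ** 2).sum())
    return 1.0 - press / float((y ** 2).sum())


def vip(result: OPLSDAResult) -> pd.Series:
    """VIP on the predictive component: VIP_j = sqrt(p) * |w_j| for a
    single component with unit-norm weights, hence mean(VIP^2) = 1."""
    w = result.w_pred
    p = len(w)
    scores = np.sqrt(p * w ** 2)
    index = result.variables if result.variables else range(1, p + 1)
    return pd.Series(scores, index=index, name="vip")


def select_markers(vip_scores: pd.Series, threshold: float = 1.0) -> list:
    """Variables with VIP strictly above the threshold, ordered by
    descending VIP (ties keep input order)."""
    s = pd.Series(vip_scores)
    hits = s[s > threshold]
    return list(hits.sort_values(ascending=False, kind="stable").index)
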