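"""Q+K mixed linear model for single-marker association.

The model is y = Xβ + u + e with X = [1, Q (one column dropped), marker],
Var(u) = σ²_a·K and Var(e) = σ²_e·I.  Following the single-eigendecomposition
approach, K = U·diag(s)·Uᵀ is decomposed once; the variance structure is
parameterised by the heritability ratio h = σ²_a/(σ²_a+σ²_e), giving rotated
observation weights w_i = h·s_i + (1−h).  REML profiles the total variance, a
1-D search over h finds the optimum, and the marker coefficient is tested
with a Wald F statistic on 1 and n−p denominator degrees of freedom.  At the
h = 0 boundary the fit reduces exactly to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class MLMError(ValueError):
    pass


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix."""

    values: np.ndarray   # eigenvalues, clipped at 0
    vectors: np.ndarray  # columns are eigenvectors

    @classmethod
    def from_kinship(cls, K: np.ndarray) -> "KinshipEigen":
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-10):
            raise MLMError("kinship matrix is not symmetric")
        s, U = np.linalg.eigh(K)
        if s.min() < -1e-8 * max(1.0, s.max()):
            raise MLMError(
                f"kinship matrix is not PSD (min eigenvalue {s.min():.3e})"
            )
        return cls(np.clip(s, 0.0, None), U)


@dataclass(frozen=True)
class MLMFit:
    """Result of a single-marker mixed-model fit."""

    beta_marker: float
    se_marker: float
    f_statistic: float
    p_value: float
    r2_explained: float   # percent of phenotypic variance
    h2: float             # REML estimate of σ²_a/(σ²_a+σ²_e)
    sigma2_total: float
    n_used: int
    df_denominator: int


def design_matrix(n: int, Q: np.ndarray | None) -> np.ndarray:
    """Fixed-effect design [1, Q with last column dropped]."""
    cols = [np.ones(n)]
    if Q is not None:
        Q = np.asarray(Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != n:
            raise MLMError("Q matrix shape mismatch")
        if Q.shape[1] > 1:
            cols.append(Q[:, :-1])  # drop one column: rows sum to 1
    return np.column_stack(cols)


def _reml_neg_loglik(h: float, ystar: np.ndarray, Xstar: np.ndarray,
                     s: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Profiled REML criterion at heritability ratio h; returns
    (criterion, beta_hat, weighted RSS)."""
    n, p = Xstar.shape
    w = h * s + (1.0 - h)
    w = np.maximum(w, 1e-12)
    sw = 1.0 / np.sqrt(w)
    Xw = Xstar * sw[:, None]
    yw = ystar * sw
    XtX = Xw.T @ Xw
    try:
        beta = np.linalg.solve(XtX, Xw.T @ yw)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(p), np.inf
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    if sign <= 0 or rss <= 0:
        return np.inf, beta, rss
    crit = (n - p) * np.log(rss) + float(np.sum(np.log(w))) + logdet_xtx
    return crit, beta, rss


def mlm_single_marker(
    y: np.ndarray,
    marker: np.ndarray,
    Q: np.ndarray | None = None,
    K: np.ndarray | None = None,
    eig: KinshipEigen | None = None,
    n_grid: int = 64,
) -> MLMFit:
    """REML Q+K mixed-model test of one marker.

    Individuals with missing trait or marker are dropped; when that changes
    the sample, the kinship eigendecomposition is redone on the subset.
    """
    y = np.asarray(y, dtype=float)
    marker = np.asarray(marker, dtype=float)
    mask = np.isfinite(y) & np.isfinite(marker)
    n_used = int(mask.sum())
    if n_used < 30:
        raise MLMError(f"only {n_used} complete cases (need ≥ 30)")
    yv, mv = y[mask], marker[mask]
    Qv = None if Q is None else np.asarray(Q, dtype=float)[mask]
    X = np.column_stack([design_matrix(n_used, Qv), mv])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise MLMError("marker collinear with covariates")

    if eig is None:
        if K is None:
            s = np.ones(n_used)
            U = None
        else:
            eig = KinshipEigen.from_kinship(np.asarray(K, dtype=float)[np.ix_(mask, mask)])
            s, U = eig.values, eig.vectors
    else:
        if eig.values.shape[0] != y.shape[0]:
            raise MLMError("cached eigendecomposition size mismatch")
        if not mask.all():
            sub = np.asarray(
                eig.vectors * eig.values @ eig.vectors.T, dtype=float
            )[np.ix_(mask, mask)]
            eig = KinshipEigen.from_kinship(sub)
        s, U = eig.values, eig.vectors

    if U is None:
        ystar, Xstar = yv, X
    else:
        ystar, Xstar = U.T @ yv, U.T @ X

    # 1-D REML search over h on a coarse grid with local refinement
    grid = np.linspace(0.0, 0.999, n_grid)
    crits = np.array([_reml_neg_loglik(h, ystar, Xstar, s)[0] for h in grid])
    k = int(np.argmin(crits))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda h: _reml_neg_loglik(h, ystar, Xstar, s)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        h_hat = float(res.x)
        if _reml_neg_loglik(grid[k], ystar, Xstar, s)[0] < res.fun:
            h_hat = float(grid[k])
    else:
        h_hat = float(grid[k])

    n, p = Xstar.shape
    w = np.maximum(h_hat * s + (1.0 - h_hat), 1e-12)
    sw = 1.0 / np.sqrt(w)
    Xw = Xstar * sw[:, None]
    yw = ystar * sw
    XtX = Xw.T @ Xw
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    sigma2 = float(resid @ resid) / (n - p)
    se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
    b = float(beta[-1])
    F = (b / se) ** 2 if se > 0 else np.inf
    p_value = float(stats.f.sf(F, 1, n - p))
    var_y = float(np.var(yv))
    r2 = 100.0 * float(np.var(mv * b)) / var_y if var_y > 0 else 0.0
    return MLMFit(
        beta_marker=b, se_marker=se, f_statistic=float(F), p_value=p_value,
        r2_explained=r2, h2=h_hat, sigma2_total=sigma2, n_used=n_used,
        df_denominator=n - p,
    )
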