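"""Regularized partial-correlation network estimation.

The network is a Gaussian graphical model: node pairs are connected iff they
are conditionally dependent given all other variables, with edge weights
equal to partial correlations computed from the estimated precision matrix

    W(i, j) = -K(i, j) / sqrt(K(i, i) * K(j, j)).

Estimation maximizes the L1-penalized Gaussian log-likelihood

    log det K - trace(S K) - lambda * sum_{i != j} |K(i, j)|

by block coordinate descent (graphical lasso: one lasso regression per
column subproblem), over a log-spaced lambda path, selecting the model that
minimizes the extended Bayesian information criterion

    EBIC = -2 l(K) + E log n + 4 gamma E log p,    l = (n/2)(log det K - tr(SK)),

where E is the number of edges. The penalty shrinks small partial
correlations to exactly zero, yielding a sparse, stable network.

`GaussianGraphicalModel` is the scikit-learn style estimator; the
module-level functions (`correlate`, `glasso_fit`, `ebic`,
`estimate_network`, `partial_from_precision`) are thin functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy import optimize, stats
from scipy.special import owens_t
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "NetworkModel",
    "GaussianGraphicalModel",
    "correlate",
    "partial_from_precision",
    "glasso_fit",
    "ebic",
    "estimate_network",
]

#: convergence tolerance on the working covariance between sweeps
GLASSO_TOL = 1e-5
#: maximum block-coordinate-descent sweeps
GLASSO_MAX_SWEEPS = 500


# ---------------------------------------------------------------------------
# containers


@dataclass
class CorrelationMatrix:
    """Marginal correlation matrix S feeding the graphical model."""

    values: np.ndarray
    method: str
    n_effective: int
    psd_repaired: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        self.values = v

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class NetworkModel:
    """A fitted sparse partial-correlation network."""

    precision: np.ndarray  # K
    weights: np.ndarray  # W, partial correlations, zero diagonal
    lam: float
    gamma: float
    ebic: float
    n_edges: int
    node_ids: list[str] | None = None
    communities: dict[str, str] | None = None
    method: str | None = None
    n: int | None = None
    path: list[dict] | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> list[tuple[str, str, float]]:
        ids = self.node_ids or [str(i) for i in range(self.p)]
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0.0:
                    out.append((ids[i], ids[j], float(self.weights[i, j])))
        return out

    def to_graph(self):
        """Weighted networkx graph (attribute ``weight`` = partial correlation)."""
        import networkx as nx

        ids = self.node_ids or [str(i) for i in range(self.p)]
        g = nx.Graph()
        g.add_nodes_from(ids)
        for a, b, w in self.edge_list():
            g.add_edge(a, b, weight=w)
        return g


# ---------------------------------------------------------------------------
# correlation input


def _score_matrix(table) -> tuple[np.ndarray, list[str] | None, dict | None]:
    """Accept a CohortTable, DataFrame or ndarray; return floats + metadata."""
    from .instruments import CohortTable

    if isinstance(table, CohortTable):
        return (
            table.scores.astype(float),
            table.schema.ids,
            dict(table.schema.communities),
        )
    import pandas as pd

    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), [str(c) for c in table.columns], None
    return np.asarray(table, dtype=float), None, None


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T."""
    if np.isinf(h) or np.isinf(k):
        if h == -np.inf or k == -np.inf:
            return 0.0
        if h == np.inf:
            return float(stats.norm.cdf(k))
        return float(stats.norm.cdf(h))
    # avoid the removable singularities at h = 0 or k = 0
    if h == 0.0:
        h = 1e-12
    if k == 0.0:
        k = 1e-12
    rho = min(max(rho, -0.999999), 0.999999)
    denom = np.sqrt(1.0 - rho * rho)
    a1 = (k - rho * h) / (h * denom)
    a2 = (h - rho * k) / (k * denom)
    beta = 0.0 if h * k > 0 or (h * k == 0 and h + k >= 0) else 0.5
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - owens_t(h, a1)
        - owens_t(k, a2)
        - beta
    )
    return float(min(max(val, 0.0), 1.0))


def _polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step maximum-likelihood polychoric correlation of two ordinal vectors.

    Step 1 estimates thresholds from the marginal category proportions
    (normal quantiles); step 2 maximizes the bivariate-normal contingency
    likelihood over rho with thresholds fixed.
    """
    xv, xc = np.unique(x, return_inverse=True)
    yv, yc = np.unique(y, return_inverse=True)
    if len(xv) < 2 or len(yv) < 2:
        raise ValueError("polychoric requires >= 2 observed categories")
    counts = np.zeros((len(xv), len(yv)))
    np.add.at(counts, (xc, yc), 1.0)
    n = counts.sum()
    tx = np.concatenate(([-np.inf], stats.norm.ppf(np.cumsum(counts.sum(1))[:-1] / n), [np.inf]))
    ty = np.concatenate(([-np.inf], stats.norm.ppf(np.cumsum(counts.sum(0))[:-1] / n), [np.inf]))

    def neg_loglik(rho: float) -> float:
        ll = 0.0
        for i in range(len(xv)):
            for j in range(len(yv)):
                if counts[i, j] == 0:
                    continue
                pij = (
                    _bvn_cdf(tx[i + 1], ty[j + 1], rho)
                    - _bvn_cdf(tx[i], ty[j + 1], rho)
                    - _bvn_cdf(tx[i + 1], ty[j], rho)
                    + _bvn_cdf(tx[i], ty[j], rho)
                )
                ll += counts[i, j] * np.log(max(pij, 1e-300))
        return -ll

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError("polychoric likelihood maximization failed")
    return float(res.x)


def correlate(table, method: str = "pearson") -> CorrelationMatrix:
    """Marginal correlation matrix of a cohort by the requested method.

    ``pearson`` and ``spearman`` are computed on the raw item scores;
    ``polychoric`` fits a latent bivariate-normal model per item pair
    (falling back to Spearman for a pair whose likelihood maximization
    fails, with a logged warning).  A matrix that is not positive
    semidefinite is repaired by clipping eigenvalues at 1e-8 and
    renormalizing the diagonal; the repair is flagged on the result.
    """
    x, _, _ = _score_matrix(table)
    n, p = x.shape
    if p < 2:
        raise ValueError("need at least two variables")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        from .instruments import CohortTable

        names = (
            table.schema.ids
            if isinstance(table, CohortTable)
            else [str(i) for i in range(p)]
        )
        zero = [names[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance item(s): {zero}")

    if method == "pearson":
        s = np.corrcoef(x, rowvar=False)
    elif method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 0, x)
        s = np.corrcoef(ranks, rowvar=False)
    elif method == "polychoric":
        s = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                try:
                    r = _polychoric_pair(x[:, i], x[:, j])
                except Exception:  # non-convergence -> rank fallback
                    logger.warning(
                        "polychoric failed for pair (%d, %d); using Spearman", i, j
                    )
                    r = float(stats.spearmanr(x[:, i], x[:, j]).statistic)
                s[i, j] = s[j, i] = r
    else:
        raise ValueError(f"unknown correlation method: {method}")

    s = (s + s.T) / 2.0
    repaired = False
    evals, evecs = np.linalg.eigh(s)
    if evals.min() < -1e-8:
        evals = np.clip(evals, 1e-8, None)
        s = evecs @ np.diag(evals) @ evecs.T
        d = np.sqrt(np.diag(s))
        s = s / np.outer(d, d)
        s = (s + s.T) / 2.0
        repaired = True
        logger.warning("correlation matrix repaired to near-PSD (%s)", method)
    np.fill_diagonal(s, 1.0)
    return CorrelationMatrix(values=s, method=method, n_effective=n, psd_repaired=repaired)


# ---------------------------------------------------------------------------
# graphical lasso


def partial_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix from a positive-definite precision matrix.

    ``W(i, j) = -K(i, j) / sqrt(K(i, i) K(j, j))`` with a zero diagonal.
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("precision matrix must be positive definite")
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return W


@njit(cache=True)
def _lasso_cd(Q, s, lam, beta, tol, max_iter):  # pragma: no cover - numba
    """Coordinate descent for min 0.5 b'Qb - s'b + sum lam_i |b_i|."""
    m = s.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for i in range(m):
            qii = Q[i, i]
            g = s[i] - np.dot(Q[i], beta) + qii * beta[i]
            if g > lam[i]:
                b_new = (g - lam[i]) / qii
            elif g < -lam[i]:
                b_new = (g + lam[i]) / qii
            else:
                b_new = 0.0
            d = abs(b_new - beta[i])
            if d > dmax:
                dmax = d
            beta[i] = b_new
        if dmax < tol:
            break


@njit(cache=True)
def _glasso_cd(S, Lam, tol, max_sweeps, W, B):  # pragma: no cover - numba
    """Block coordinate descent graphical lasso with elementwise penalties.

    Operates in place on the working covariance W and regression
    coefficients B (both warm-startable).  Returns (K, sweeps, converged).
    """
    p = S.shape[0]
    Q = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    lam12 = np.empty(p - 1)
    beta = np.empty(p - 1)
    sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        max_delta = 0.0
        for j in range(p):
            # assemble the column subproblem excluding j
            r = 0
            for a in range(p):
                if a == j:
                    continue
                s12[r] = S[a, j]
                lam12[r] = Lam[a, j]
                beta[r] = B[a, j]
                c = 0
                for b in range(p):
                    if b == j:
                        continue
                    Q[r, c] = W[a, b]
                    c += 1
                r += 1
            _lasso_cd(Q, s12, lam12, beta, tol * 0.1, 1000)
            # w12 = Q beta; record max change
            r = 0
            for a in range(p):
                if a == j:
                    continue
                w_new = np.dot(Q[r], beta)
                d = abs(w_new - W[a, j])
                if d > max_delta:
                    max_delta = d
                W[a, j] = w_new
                W[j, a] = w_new
                B[a, j] = beta[r]
                r += 1
        if max_delta < tol:
            converged = True
            break
    # recover the precision matrix from the stored regressions
    K = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for a in range(p):
            if a != j:
                dot += W[a, j] * B[a, j]
        k22 = 1.0 / (W[j, j] - dot)
        K[j, j] = k22
        for a in range(p):
            if a != j:
                K[a, j] = -B[a, j] * k22
    # symmetrize, preserving exact zeros where both regressions agree
    for i in range(p):
        for j in range(i + 1, p):
            if B[i, j] == 0.0 and B[j, i] == 0.0:
                K[i, j] = 0.0
                K[j, i] = 0.0
            else:
                avg = 0.5 * (K[i, j] + K[j, i])
                K[i, j] = avg
                K[j, i] = avg
    return K, sweeps, converged


def _glasso(
    S: np.ndarray,
    lam,
    tol: float = GLASSO_TOL,
    max_sweeps: int = GLASSO_MAX_SWEEPS,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Solve the graphical lasso; returns (K, W_partials, warm-start state)."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    Lam = np.asarray(lam, dtype=float)
    if Lam.ndim == 0:
        Lam = np.full((p, p), float(Lam))
    if np.all(Lam[~np.eye(p, dtype=bool)] == 0.0):
        if np.linalg.eigvalsh(S).min() <= 1e-12:
            raise ValueError(
                "unpenalized fit requires a positive-definite correlation "
                "matrix; use lambda > 0 or PSD repair"
            )
    if warm is not None:
        W = warm[0].copy()
        B = warm[1].copy()
        np.fill_diagonal(W, np.diag(S))
    else:
        W = S.copy()
        B = np.zeros((p, p))
    K, sweeps, converged = _glasso_cd(S, Lam, tol, max_sweeps, W, B)
    if not converged:
        logger.warning("glasso did not converge in %d sweeps", max_sweeps)
    return K, partial_from_precision(K), (W, B)


def glasso_objective(K: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Penalized log-likelihood log det K - tr(SK) - lam * sum_{i!=j} |K_ij|."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    off = np.abs(K).sum() - np.abs(np.diag(K)).sum()
    return float(logdet - np.trace(S @ K) - lam * off)


def glasso_fit(S, lam: float, *, tol: float = GLASSO_TOL,
               max_sweeps: int = GLASSO_MAX_SWEEPS) -> NetworkModel:
    """Fit the graphical lasso at a single penalty value.

    ``S`` may be a `CorrelationMatrix` or a plain symmetric matrix.  The
    returned model has no EBIC attached (NaN) since no selection happened.
    """
    if isinstance(S, CorrelationMatrix):
        values, n, method = S.values, S.n_effective, S.method
    else:
        values, n, method = np.asarray(S, dtype=float), None, None
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    K, W, _ = _glasso(values, lam, tol=tol, max_sweeps=max_sweeps)
    E = int(np.count_nonzero(np.triu(W, 1)))
    return NetworkModel(
        precision=K, weights=W, lam=float(lam), gamma=np.nan, ebic=np.nan,
        n_edges=E, method=method, n=n,
    )


def _gaussian_loglik(K: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(K)
    return 0.5 * n * (logdet - float(np.trace(S @ K)))


def ebic(model: NetworkModel, S, n: int, gamma: float) -> float:
    """Extended BIC of a fitted model: ``-2 l + E log n + 4 gamma E log p``."""
    values = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    ll = _gaussian_loglik(model.precision, values, n)
    E = model.n_edges
    p = model.p
    return float(-2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p))


# ---------------------------------------------------------------------------
# estimator


class GaussianGraphicalModel(BaseEstimator):
    """Sparse partial-correlation network with EBIC-selected lasso penalty.

    Parameters
    ----------
    method : {"pearson", "spearman", "polychoric"}, default "pearson"
        Marginal correlation computed from the item scores.
    gamma : float, default 0.5
        EBIC hyperparameter; 0 reduces the criterion to BIC, larger values
        prefer sparser networks.
    n_lambda : int, default 100
        Number of penalty values on the log-spaced path.
    lambda_min_ratio : float, default 0.01
        Smallest penalty as a fraction of lambda_max = max off-diagonal |S|.
    adaptive : bool, default False
        Two-stage adaptive variant: per-edge penalty factors
        ``1 / |W_ridge(i, j)|**adaptive_power`` from a ridge pre-fit.
    adaptive_power : float, default 0.5
    tol, max_sweeps
        Block-coordinate-descent convergence controls.

    Attributes
    ----------
    correlation_ : CorrelationMatrix
    precision_ : ndarray, selected K
    weights_ : ndarray, selected partial-correlation matrix
    lambda_ : float, selected penalty
    ebic_ : float, criterion at the selected penalty
    n_edges_ : int
    path_ : list of dict with keys (lam, n_edges, ebic) along the path
    node_ids_ : list of str (schema ids / column names when available)
    """

    def __init__(
        self,
        method: str = "pearson",
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        adaptive: bool = False,
        adaptive_power: float = 0.5,
        tol: float = GLASSO_TOL,
        max_sweeps: int = GLASSO_MAX_SWEEPS,
    ) -> None:
        self.method = method
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.adaptive = adaptive
        self.adaptive_power = adaptive_power
        self.tol = tol
        self.max_sweeps = max_sweeps

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "GaussianGraphicalModel":
        """Estimate the network from a cohort (CohortTable, DataFrame or array)."""
        _, node_ids, communities = _score_matrix(X)
        S = correlate(X, method=self.method)
        n = S.n_effective
        p = S.p

        penalty_factors = np.ones((p, p))
        if self.adaptive:
            ridge_K = np.linalg.inv(S.values + 0.1 * np.eye(p))
            ridge_W = partial_from_precision(ridge_K)
            mags = np.abs(ridge_W)
            np.fill_diagonal(mags, 1.0)
            penalty_factors = 1.0 / np.maximum(mags, 1e-4) ** self.adaptive_power
            off = ~np.eye(p, dtype=bool)
            penalty_factors[off] /= penalty_factors[off].mean()
            np.fill_diagonal(penalty_factors, 0.0)

        off_abs = np.abs(S.values[~np.eye(p, dtype=bool)])
        if self.adaptive:
            offmask = ~np.eye(p, dtype=bool)
            lam_max = float(
                np.max(np.abs(S.values)[offmask] / penalty_factors[offmask])
            )
        else:
            lam_max = float(off_abs.max())
        if lam_max <= 0:
            lam_max = 1e-3
        grid = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambda)

        best = None
        warm = None
        path: list[dict] = []
        for lam in grid:
            Lam = lam * penalty_factors if self.adaptive else lam
            try:
                K, W, warm = _glasso(
                    S.values, Lam, tol=self.tol, max_sweeps=self.max_sweeps, warm=warm
                )
            except np.linalg.LinAlgError:
                logger.warning("glasso failed at lambda=%g; stopping path", lam)
                break
            E = int(np.count_nonzero(np.triu(W, 1)))
            ll = _gaussian_loglik(K, S.values, n)
            crit = float(-2.0 * ll + E * np.log(n) + 4.0 * self.gamma * E * np.log(p))
            path.append({"lam": float(lam), "n_edges": E, "ebic": crit})
            # strict improvement by >1e-9 so ties keep the sparser (larger) lambda
            if best is None or crit < best["ebic"] - 1e-9:
                best = {"lam": float(lam), "K": K, "W": W, "E": E, "ebic": crit}

        if best is None:
            raise RuntimeError("no model could be fitted along the lambda path")

        self.correlation_ = S
        self.precision_ = best["K"]
        self.weights_ = best["W"]
        self.lambda_ = best["lam"]
        self.ebic_ = best["ebic"]
        self.n_edges_ = best["E"]
        self.path_ = path
        self.n_samples_ = n
        self.node_ids_ = node_ids
        self.communities_ = communities
        self.n_features_in_ = p
        return self

    def to_network_model(self) -> NetworkModel:
        """Package the fitted state as an immutable NetworkModel."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "weights_")
        return NetworkModel(
            precision=self.precision_,
            weights=self.weights_,
            lam=self.lambda_,
            gamma=self.gamma,
            ebic=self.ebic_,
            n_edges=self.n_edges_,
            node_ids=self.node_ids_,
            communities=self.communities_,
            method=self.method,
            n=self.n_samples_,
            path=self.path_,
        )


def estimate_network(
    table,
    method: str = "pearson",
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    **kwargs,
) -> NetworkModel:
    """End-to-end network estimation: correlation -> lasso path -> EBIC pick."""
    est = GaussianGraphicalModel(
        method=method,
        gamma=gamma,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        **kwargs,
    ).fit(table)
    return est.to_network_model()
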