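"""Binomial mixed-logit (GLMM) engine.

Maximum-likelihood estimation of

    y_i ~ Binomial(n_i, logistic(x_i' beta + z_i' b_{g(i)})),
    b_g ~ N(0, Sigma),

with one grouping factor (participant).  The marginal likelihood integrates
the random effects out per group with adaptive Gauss-Hermite quadrature:
the integrand is recentred at its mode and rescaled by the curvature there,
which with a single node is exactly the Laplace approximation and with more
nodes converges to the true integral.  Quadrature with a tensor-product grid
is used up to ``MAX_AGQ_DIM`` random-effect dimensions; above that the
Laplace approximation (one node) is used.

Sigma is parameterized through its Cholesky factor with log-diagonal, either
diagonal (independent random effects) or full.  Optimization is quasi-Newton
(BFGS) over the joint (beta, theta) vector; per-group modes are found by a
batched, step-halved Newton iteration and warm-started across objective
evaluations.

The log-likelihood includes the binomial normalizing constant, so deviances
are comparable with any correctly normalized external computation of the
same integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, gammaln, log_expit, logsumexp

__all__ = ["MixedLogitData", "MixedLogitResult", "fit_mixed_logit_ml",
           "marginal_loglik"]

MAX_AGQ_DIM = 2       # tensor-product quadrature up to this many dimensions
DEFAULT_NODES = 7
SD_FLOOR = 1e-4       # random-effect SD below this counts as singular
CORR_CEIL = 0.99


class MixedLogitData:
    """Sorted-by-group view of one mixed-logit dataset."""

    def __init__(self, y, n, X, Z, groups):
        y = np.asarray(y, float)
        n = np.asarray(n, float)
        X = np.atleast_2d(np.asarray(X, float))
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        self.y, self.n, self.X = y[order], n[order], X[order]
        self.groups = groups[order]
        if Z is None or (hasattr(Z, "size") and np.size(Z) == 0):
            self.Z = np.zeros((len(self.y), 0))
        else:
            self.Z = np.atleast_2d(np.asarray(Z, float))[order]
        _, self.group_index = np.unique(self.groups, return_inverse=True)
        self.n_groups = int(self.group_index.max()) + 1 if len(y) else 0
        # reduceat boundaries (data sorted by group)
        self.starts = np.searchsorted(self.group_index,
                                      np.arange(self.n_groups))
        self.log_binom = (gammaln(self.n + 1) - gammaln(self.y + 1)
                          - gammaln(self.n - self.y + 1))

    @property
    def q(self):
        return self.Z.shape[1]

    def group_sum(self, values):
        return np.add.reduceat(values, self.starts, axis=0)


def _n_theta(q: int, corr: bool) -> int:
    return q * (q + 1) // 2 if corr else q


def _chol_from_theta(theta: np.ndarray, q: int, corr: bool) -> np.ndarray:
    L = np.zeros((q, q))
    if corr:
        idx = 0
        for i in range(q):
            for j in range(i + 1):
                if i == j:
                    L[i, j] = np.exp(theta[idx])
                else:
                    L[i, j] = theta[idx]
                idx += 1
    else:
        L[np.diag_indices(q)] = np.exp(theta)
    return L


def _bernoulli_loglik_terms(eta, y, n):
    # y*log p + (n-y)*log(1-p), numerically safe
    return y * log_expit(eta) + (n - y) * log_expit(-eta)


def _find_modes(data: MixedLogitData, xb, Sigma_inv, b0, max_iter=50,
                tol=1e-9):
    """Batched Newton for the per-group posterior modes of b."""
    G, q = data.n_groups, data.q
    b = b0.copy()
    Zb = np.einsum("nq,nq->n", data.Z, b[data.group_index])
    eta = xb + Zb

    def neg_obj(eta_vec, b_mat):  # per-group objective (to minimize)
        ll = _bernoulli_loglik_terms(eta_vec, data.y, data.n)
        pen = 0.5 * np.einsum("gi,ij,gj->g", b_mat, Sigma_inv, b_mat)
        return -data.group_sum(ll) + pen

    f = neg_obj(eta, b)
    for _ in range(max_iter):
        p = expit(eta)
        r = data.y - data.n * p
        grad = data.group_sum(data.Z * r[:, None]) - b @ Sigma_inv
        w = data.n * p * (1 - p)
        ZwZ = data.group_sum(np.einsum("ni,nj->nij",
                                       data.Z, data.Z * w[:, None]))
        H = ZwZ + Sigma_inv
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        if np.max(np.abs(grad)) < tol:
            break
        # step halving per group
        scale = np.ones(G)
        for _ in range(25):
            b_new = b + scale[:, None] * step
            Zb = np.einsum("nq,nq->n", data.Z, b_new[data.group_index])
            f_new = neg_obj(xb + Zb, b_new)
            bad = f_new > f + 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        b = b + scale[:, None] * step
        Zb = np.einsum("nq,nq->n", data.Z, b[data.group_index])
        eta = xb + Zb
        f_prev, f = f, neg_obj(eta, b)
        if np.max(np.abs(f_prev - f)) < tol:
            break
    p = expit(eta)
    w = data.n * p * (1 - p)
    H = data.group_sum(np.einsum("ni,nj->nij",
                                 data.Z, data.Z * w[:, None])) + Sigma_inv
    return b, H


def _quad_grid(q: int, n_nodes: int):
    x, w = hermgauss(n_nodes)
    if q == 1:
        nodes = x[:, None]
        logw = np.log(w)
    else:
        grids = np.meshgrid(*([x] * q), indexing="ij")
        nodes = np.stack([g.ravel() for g in grids], axis=1)
        wg = np.meshgrid(*([w] * q), indexing="ij")
        logw = np.sum([np.log(g.ravel()) for g in wg], axis=0)
    return nodes, logw


def marginal_loglik(data: MixedLogitData, beta, Sigma, n_quad=DEFAULT_NODES,
                    modes=None):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    ``n_quad`` is the number of nodes per random-effect dimension; one node
    gives the Laplace approximation.  Returns ``(loglik, modes)`` so callers
    can warm-start the next evaluation.
    """
    beta = np.asarray(beta, float)
    xb = data.X @ beta
    q = data.q
    if q == 0:
        ll = _bernoulli_loglik_terms(xb, data.y, data.n)
        return float(ll.sum() + data.log_binom.sum()), None

    Sigma = np.asarray(Sigma, float)
    Sigma_inv = np.linalg.inv(Sigma)
    sign, logdet_Sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf, modes
    b0 = modes if modes is not None else np.zeros((data.n_groups, q))
    m, H = _find_modes(data, xb, Sigma_inv, b0)

    # curvature scaling: C C' = H^{-1}
    Hc = np.linalg.cholesky(H)                     # H = Hc Hc'
    sign_h, logdet_H = np.linalg.slogdet(H)

    nodes, logw = _quad_grid(q, n_quad)            # (K, q), (K,)
    K = nodes.shape[0]
    # b_gk = m_g + sqrt(2) * C_g x_k with C_g = inv(Hc_g)'
    scaled = np.sqrt(2.0) * np.linalg.solve(
        np.swapaxes(Hc, 1, 2)[:, None, :, :],
        np.broadcast_to(nodes[None, :, :, None],
                        (data.n_groups, K, q, 1)).copy()
    )[..., 0]
    b_nodes = m[:, None, :] + scaled               # (G, K, q)

    # log integrand at each node: sum_i bernoulli + gaussian prior density
    Zb = np.einsum("nq,nkq->nk", data.Z, b_nodes[data.group_index])
    ll_obs = _bernoulli_loglik_terms(xb[:, None] + Zb,
                                     data.y[:, None], data.n[:, None])
    ll_group = data.group_sum(ll_obs)              # (G, K)
    quad_pen = 0.5 * np.einsum("gki,ij,gkj->gk", b_nodes, Sigma_inv, b_nodes)
    log_prior = -0.5 * q * np.log(2 * np.pi) - 0.5 * logdet_Sigma - quad_pen
    log_f = ll_group + log_prior

    # adaptive GH: log of |sqrt(2) C| sum_k w_k exp(x_k^2) f(b_gk)
    log_jac = 0.5 * q * np.log(2.0) - 0.5 * logdet_H
    contrib = logsumexp(log_f + logw[None, :]
                        + np.sum(nodes**2, axis=1)[None, :], axis=1)
    ll = float(np.sum(contrib + log_jac) + data.log_binom.sum())
    return ll, m


@dataclass
class MixedLogitResult:
    beta: np.ndarray
    se: np.ndarray
    Sigma: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    corr: bool
    n_quad: int

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2 * self.loglik

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def random_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.Sigma))


def _fd_hessian(fun, x, eps=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) \
                / (4 * eps * eps)
    return H


def fit_mixed_logit_ml(data: MixedLogitData, corr: bool = False,
                       n_quad: int | None = None,
                       start_beta: np.ndarray | None = None,
                       maxiter: int = 400) -> MixedLogitResult:
    """Maximize the marginal likelihood for one random-effects structure."""
    p = data.X.shape[1]
    q = data.q
    if n_quad is None:
        n_quad = DEFAULT_NODES if q <= MAX_AGQ_DIM else 1
    nt = _n_theta(q, corr)

    state = {"modes": None}

    def unpack(params):
        beta = params[:p]
        if q == 0:
            return beta, None
        L = _chol_from_theta(params[p:], q, corr)
        return beta, L @ L.T

    def nll(params):
        beta, Sigma = unpack(params)
        if q == 0:
            ll, _ = marginal_loglik(data, beta, None)
            return -ll
        try:
            ll, m = marginal_loglik(data, beta, Sigma, n_quad=n_quad,
                                    modes=state["modes"])
        except np.linalg.LinAlgError:
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        state["modes"] = m
        return -ll

    if start_beta is None:
        # crude empirical-logit start for the intercept
        prop = (data.y.sum() + 0.5) / (data.n.sum() + 1.0)
        start_beta = np.zeros(p)
        if np.allclose(data.X[:, 0], 1.0):
            start_beta[0] = np.log(prop / (1 - prop))
    theta0 = np.full(nt, 0.0)
    if corr and q > 0:
        theta0 = np.zeros(nt)
        idx = 0
        for i in range(q):
            for j in range(i + 1):
                theta0[idx] = -0.5 if i == j else 0.0
                idx += 1
    elif q > 0:
        theta0 = np.full(q, -0.5)
    x0 = np.concatenate([start_beta, theta0])

    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"maxiter": maxiter, "gtol": 1e-6})
    beta_hat, Sigma_hat = unpack(res.x)
    if q == 0:
        Sigma_hat = np.zeros((0, 0))

    # Wald SEs from the observed information (finite differences)
    H = _fd_hessian(nll, res.x)
    se = np.full(p + nt, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        ok = d > 0
        se[ok] = np.sqrt(d[ok])
    except np.linalg.LinAlgError:
        pass

    singular = False
    if q > 0:
        sds = np.sqrt(np.diag(Sigma_hat))
        singular = bool(np.any(sds < SD_FLOOR))
        if corr and q > 1 and not singular:
            denom = np.outer(sds, sds)
            corr_mat = Sigma_hat / denom
            off = corr_mat[~np.eye(q, dtype=bool)]
            singular = bool(np.any(np.abs(off) > CORR_CEIL))

    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
    # quasi-separation: the optimizer wanders to the boundary of the logit
    # scale and Wald inference is meaningless — never report this silently
    if np.any(np.abs(beta_hat) > 15) or not np.all(np.isfinite(beta_hat)):
        converged = False
    return MixedLogitResult(
        beta=beta_hat, se=se[:p], Sigma=Sigma_hat, loglik=-res.fun,
        n_params=p + nt, n_obs=data.X.shape[0], n_groups=data.n_groups,
        converged=converged, singular=singular, corr=corr, n_quad=n_quad,
    )
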