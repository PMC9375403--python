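"""Marginal maximum likelihood estimation of the random-effect PCM.

Model: responses follow the Partial Credit Model with person trait

    theta_i = mu0 + g_i * gamma + theta_res_i,   theta_res_i ~ N(0, sigma^2),

where ``g_i`` is a 0/1 treatment indicator (``gamma`` absent for
single-population fits).  The marginal likelihood integrates theta_res out by
Gauss-Hermite quadrature, and is maximized with L-BFGS-B using analytic
gradients (the PCM score identities: d log P / d theta = k - E[K|theta], and
d log P / d delta_jl = -1[k >= l] + P(K >= l | theta)).

Identification.  Adding a constant c to every threshold is equivalent to
shifting the latent location by -c, so exactly one location constraint is
active per fit:

* free items with ``fix_latent_mean=True`` (calibration fits): mu0 == 0 and
  thresholds are reported as estimated;
* free items otherwise: thresholds are grand-mean centered and mu0 picks up
  the location.  Internally the optimizer always fixes mu0 = 0 when items are
  free (an exact reparameterization that avoids a flat direction) and the fit
  is re-expressed afterwards;
* anchored fits (``fixed_items`` given): thresholds carry the scale, and
  (mu0, gamma, sigma^2) are all free.

Person measures are expected-a-posteriori (EAP) means under a normal prior,
by default the fitted marginal latent distribution of the supplied
(typically pooled, no-covariate) fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data_sim import ResponseDataset
from .item_model import ItemBank

__all__ = [
    "FitOptions",
    "FitResult",
    "EAPResult",
    "fit_random_pcm",
    "marginal_loglik",
    "eap_latent",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class FitOptions:
    """Numerical knobs for the MML fit."""

    n_quadrature_nodes: int = 21
    max_iter: int = 500
    gtol: float = 1e-7
    delta_bound: float = 15.0  # |delta_jl| cap; binds only for unobserved categories

    def __post_init__(self) -> None:
        if self.n_quadrature_nodes < 15:
            raise ValueError("n_quadrature_nodes must be >= 15")
        if self.gtol <= 0:
            raise ValueError("gtol must be > 0")


@dataclass
class FitResult:
    """Estimates from one random-effect PCM fit."""

    thresholds_hat: np.ndarray
    mu0_hat: float
    gamma_hat: float | None
    se_gamma: float | None
    sigma2_hat: float
    loglik: float
    converged: bool
    fixed_items: bool
    M: int
    flagged: bool = False  # e.g. unobserved category while items were free
    n_unobserved_categories: int = 0

    @property
    def bank(self) -> ItemBank:
        """Estimated thresholds as an ItemBank (anchor for later fits)."""
        return ItemBank(self.thresholds_hat)

    def to_report(self) -> str:
        lines = [
            f"converged: {self.converged}",
            f"fixed_items: {self.fixed_items}",
            f"loglik: {self.loglik:.6f}",
            f"mu0_hat: {self.mu0_hat:.6f}",
            f"sigma2_hat: {self.sigma2_hat:.6f}",
        ]
        if self.gamma_hat is not None:
            lines.append(f"gamma_hat: {self.gamma_hat:.6f}")
            if self.se_gamma is not None:
                lines.append(f"se_gamma: {self.se_gamma:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class EAPResult:
    """Posterior means and SDs of the person latent traits."""

    theta_hat: np.ndarray
    psd: np.ndarray


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


class _Patterns:
    """Responses collapsed to unique (group, pattern) rows with counts."""

    def __init__(self, data: ResponseDataset, use_group: bool):
        X = data.responses
        g = (
            data.group
            if (use_group and data.group is not None)
            else np.zeros(data.N, dtype=np.int64)
        )
        key = np.column_stack([g, X])
        uniq, inverse, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        self.group = uniq[:, 0]
        self.X = uniq[:, 1:]
        self.counts = counts.astype(float)
        self.inverse = inverse  # maps subjects -> unique rows
        self.S = self.X.sum(axis=1)
        self.M = data.M
        self.J = data.J


def _gh(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, np.log(w) - 0.5 * np.log(np.pi)


def _item_logprobs(thresholds: np.ndarray, theta: np.ndarray, M: int) -> np.ndarray:
    """log P(K=k | theta) for every (theta, item, category): (T, J, M)."""
    cum = np.concatenate(
        [np.zeros((thresholds.shape[0], 1)), np.cumsum(thresholds, axis=1)], axis=1
    )
    k = np.arange(M)
    logits = k[None, None, :] * theta[:, None, None] - cum[None, :, :]
    return logits - logsumexp(logits, axis=2, keepdims=True)


class _Layout:
    """Free-parameter packing: [delta.ravel()?] [mu0?] [gamma?] [log_sigma]."""

    def __init__(self, J: int, M: int, free_delta: bool, free_mu0: bool, free_gamma: bool):
        self.J, self.M = J, M
        self.P = J * (M - 1)
        self.free_delta = free_delta
        self.free_mu0 = free_mu0
        self.free_gamma = free_gamma
        n = (self.P if free_delta else 0) + int(free_mu0) + int(free_gamma) + 1
        self.n = n
        self.i_mu0 = self.P if free_delta else 0
        self.i_gamma = self.i_mu0 + int(free_mu0)
        self.i_logsig = self.i_gamma + int(free_gamma)

    def unpack(self, x: np.ndarray, fixed_delta: np.ndarray | None):
        if self.free_delta:
            delta = x[: self.P].reshape(self.J, self.M - 1)
        else:
            delta = fixed_delta
        mu0 = x[self.i_mu0] if self.free_mu0 else 0.0
        gamma = x[self.i_gamma] if self.free_gamma else 0.0
        return delta, mu0, gamma, x[self.i_logsig]


def _neg_loglik_grad(
    x: np.ndarray,
    pat: _Patterns,
    layout: _Layout,
    nodes: np.ndarray,
    log_w: np.ndarray,
    fixed_delta: np.ndarray | None,
):
    delta, mu0, gamma, log_sig = layout.unpack(x, fixed_delta)
    sigma = np.exp(log_sig)
    M, J = pat.M, pat.J
    k = np.arange(M)
    jj = np.arange(J)

    loglik = 0.0
    g_delta = np.zeros((J, M - 1)) if layout.free_delta else None
    g_mu0 = 0.0
    g_gamma = 0.0
    g_logsig = 0.0

    for g in np.unique(pat.group):
        sel = pat.group == g
        Xg, c, S = pat.X[sel], pat.counts[sel], pat.S[sel]
        t = mu0 + gamma * g + _SQRT2 * sigma * nodes  # (Q,)
        logP = _item_logprobs(delta, t, M)  # (Q, J, M)
        LPr = logP[:, jj[None, :], Xg].sum(axis=2)  # (Q, U)
        A = log_w[:, None] + LPr
        Lu = logsumexp(A, axis=0)  # (U,)
        loglik += float(c @ Lu)

        h = np.exp(A - Lu[None, :])  # posterior node weights, (Q, U)
        hc = h * c[None, :]
        P = np.exp(logP)
        E = np.einsum("qjm,m->q", P, k)  # expected total score per node
        resid = S[None, :] - E[:, None]  # (Q, U)
        B = float((hc * resid).sum())
        g_mu0 += B
        if g == 1:
            g_gamma += B
        g_logsig += float((hc * resid * (_SQRT2 * sigma * nodes)[:, None]).sum())
        if layout.free_delta:
            tail = np.cumsum(P[:, :, ::-1], axis=2)[:, :, ::-1][:, :, 1:]  # P(K>=l)
            W = hc.sum(axis=1)  # (Q,)
            term2 = np.einsum("q,qjl->jl", W, tail)
            ge = Xg[:, :, None] >= np.arange(1, M)[None, None, :]
            term1 = np.einsum("u,ujl->jl", c, ge)
            g_delta += term2 - term1

    grad = np.empty(layout.n)
    if layout.free_delta:
        grad[: layout.P] = g_delta.ravel()
    if layout.free_mu0:
        grad[layout.i_mu0] = g_mu0
    if layout.free_gamma:
        grad[layout.i_gamma] = g_gamma
    grad[layout.i_logsig] = g_logsig
    return -loglik, -grad


def _observed_information(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of the negative log-likelihood."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        h = 1e-4 * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        gp = fun(xp)[1]
        gm = fun(xm)[1]
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def fit_random_pcm(
    data: ResponseDataset,
    include_group: bool = False,
    fixed_items: ItemBank | None = None,
    fix_latent_mean: bool = False,
    options: FitOptions | None = None,
    compute_se: bool | None = None,
) -> FitResult:
    """Fit the random-effect PCM by marginal maximum likelihood.

    Parameters
    ----------
    data
        Responses (with ``group`` labels when ``include_group``).
    include_group
        Add the treatment covariate ``gamma`` (Wald-test pathway).
    fixed_items
        Anchor: hold all thresholds at this bank's values (calibrated
        analysis); only (mu0[, gamma], sigma^2) are estimated.
    fix_latent_mean
        Constrain mu0 = 0 with free items (calibration-sample fits).
    compute_se
        Compute SE(gamma_hat) from the observed information (inverted over
        all free parameters).  Defaults to ``include_group``.
    """
    opts = options or FitOptions()
    if include_group:
        if data.group is None:
            raise ValueError("include_group requires group labels")
        if len(np.unique(data.group)) != 2:
            raise ValueError("both arms must be non-empty")
        if fix_latent_mean:
            raise ValueError("cannot both fix the latent mean and estimate a group model")
    if fixed_items is not None and fix_latent_mean:
        raise ValueError("fixed_items already identifies the location; cannot fix mu0 too")
    if fixed_items is not None and (
        fixed_items.J != data.J or fixed_items.M != data.M
    ):
        raise ValueError("anchor bank dimensions do not match the data")
    if compute_se is None:
        compute_se = include_group

    free_delta = fixed_items is None
    # free items: location absorbed by thresholds, so mu0 is fixed at 0
    # internally; re-expressed after the fit unless fix_latent_mean.
    layout = _Layout(data.J, data.M, free_delta, free_mu0=not free_delta, free_gamma=include_group)
    fixed_delta = None if free_delta else fixed_items.thresholds

    pat = _Patterns(data, use_group=include_group)
    nodes, log_w = _gh(opts.n_quadrature_nodes)

    n_unobserved = 0
    if free_delta:
        for kcat in range(data.M):
            n_unobserved += int(np.sum((data.responses == kcat).sum(axis=0) == 0))

    x0 = np.zeros(layout.n)
    bounds: list[tuple[float, float]] = []
    if free_delta:
        bounds += [(-opts.delta_bound, opts.delta_bound)] * layout.P
    if layout.free_mu0:
        bounds.append((-20.0, 20.0))
    if layout.free_gamma:
        bounds.append((-20.0, 20.0))
    bounds.append((np.log(0.05), np.log(8.0)))  # log sigma

    fun = lambda x: _neg_loglik_grad(x, pat, layout, nodes, log_w, fixed_delta)
    minimize_opts = {"maxiter": opts.max_iter, "ftol": 1e-13, "gtol": opts.gtol, "maxcor": 30}
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds, options=minimize_opts)
    # line searches can abort at machine precision near the optimum; a small
    # final gradient (relative to the loglik scale) still counts as converged
    grad_ok = np.max(np.abs(res.jac)) <= 1e-3
    if not res.success and not grad_ok:
        res = minimize(fun, res.x, jac=True, method="L-BFGS-B", bounds=bounds, options=minimize_opts)
        grad_ok = np.max(np.abs(res.jac)) <= 1e-3

    delta_hat, mu0_hat, gamma_hat, log_sig = layout.unpack(res.x, fixed_delta)
    delta_hat = np.array(delta_hat, dtype=float)
    sigma2_hat = float(np.exp(log_sig)) ** 2

    se_gamma = None
    if include_group and compute_se:
        try:
            H = _observed_information(fun, res.x)
            cov = np.linalg.inv(H)
            v = cov[layout.i_gamma, layout.i_gamma]
            se_gamma = float(np.sqrt(v)) if v > 0 else None
        except np.linalg.LinAlgError:
            se_gamma = None

    converged = bool(res.success or grad_ok)
    if include_group and compute_se and se_gamma is None:
        converged = False

    if free_delta and not fix_latent_mean:
        shift = float(delta_hat.mean())
        delta_hat = delta_hat - shift
        mu0_hat = -shift

    return FitResult(
        thresholds_hat=delta_hat,
        mu0_hat=float(mu0_hat),
        gamma_hat=float(gamma_hat) if include_group else None,
        se_gamma=se_gamma,
        sigma2_hat=sigma2_hat,
        loglik=float(-res.fun),
        converged=converged,
        fixed_items=not free_delta,
        M=data.M,
        flagged=n_unobserved > 0,
        n_unobserved_categories=n_unobserved,
    )


def marginal_loglik(
    data: ResponseDataset,
    thresholds: np.ndarray | ItemBank,
    mu0: float = 0.0,
    gamma: float = 0.0,
    sigma2: float = 1.0,
    n_nodes: int = 21,
) -> float:
    """Marginal log-likelihood at given parameters (the MML objective).

    Deterministic given the node count; ``sigma2 = 0`` degenerates to
    evaluating the PCM likelihood at theta = mu0 + g*gamma exactly.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    thr = thresholds.thresholds if isinstance(thresholds, ItemBank) else np.asarray(thresholds, float)
    pat = _Patterns(data, use_group=True)
    jj = np.arange(pat.J)
    total = 0.0
    for g in np.unique(pat.group):
        sel = pat.group == g
        Xg, c = pat.X[sel], pat.counts[sel]
        if sigma2 == 0.0:
            t = np.array([mu0 + gamma * g])
            logP = _item_logprobs(thr, t, pat.M)
            total += float(c @ logP[0, jj[None, :], Xg].sum(axis=1))
        else:
            nodes, log_w = _gh(n_nodes)
            t = mu0 + gamma * g + _SQRT2 * np.sqrt(sigma2) * nodes
            logP = _item_logprobs(thr, t, pat.M)
            LPr = logP[:, jj[None, :], Xg].sum(axis=2)
            total += float(c @ logsumexp(log_w[:, None] + LPr, axis=0))
    return total


def eap_latent(
    data: ResponseDataset,
    fit: FitResult,
    prior: tuple[float, float] | None = None,
    group_conditional: bool = False,
    n_nodes: int | None = None,
) -> EAPResult:
    """Expected-a-posteriori latent trait estimates.

    ``prior`` is (mean, variance) of the normal prior; by default the fitted
    marginal latent distribution ``N(mu0_hat, sigma2_hat)`` of ``fit`` (a
    pooled prior -- the source of the familiar shrinkage of group contrasts).
    ``group_conditional`` instead centers each subject's prior at
    ``mu0_hat + g_i * gamma_hat`` (requires a group-covariate fit).

    Person posteriors are much narrower than the prior when J*M is large, so
    EAP uses a finer default rule (121 nodes) than the fit; per-pattern cost
    is negligible.
    """
    if not fit.converged:
        raise ValueError("EAP requires a converged fit")
    thr = fit.thresholds_hat
    Q = n_nodes or 121
    nodes, log_w = _gh(Q)

    if group_conditional:
        if fit.gamma_hat is None or data.group is None:
            raise ValueError("group_conditional needs a group-covariate fit and labels")
        means = fit.mu0_hat + data.group * fit.gamma_hat
        var = fit.sigma2_hat
    else:
        mean, var = prior if prior is not None else (fit.mu0_hat, fit.sigma2_hat)
        means = np.full(data.N, float(mean))
    if var <= 0:
        raise ValueError("prior variance must be > 0")
    sd = np.sqrt(var)

    theta_hat = np.empty(data.N)
    psd = np.empty(data.N)
    jj = np.arange(data.J)
    for m in np.unique(means):
        sel = means == m
        sub = data.responses[sel]
        uniq, inv = np.unique(sub, axis=0, return_inverse=True)
        t = m + _SQRT2 * sd * nodes  # (Q,)
        logP = _item_logprobs(thr, t, data.M)
        LPr = logP[:, jj[None, :], uniq].sum(axis=2)  # (Q, U)
        A = log_w[:, None] + LPr
        h = np.exp(A - logsumexp(A, axis=0, keepdims=True))
        mean_u = t @ h
        var_u = (t**2) @ h - mean_u**2
        theta_hat[sel] = mean_u[inv]
        psd[sel] = np.sqrt(np.maximum(var_u, 1e-300))[inv]
    return EAPResult(theta_hat=theta_hat, psd=psd)
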