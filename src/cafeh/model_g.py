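"""Generative model and closed-form CAVI updates (individual-level mode).

The model: for trait t, ``y_t = X b_t + eps``, ``eps ~ N(0, tau_t^{-1} I)``,
with the sparse effect decomposed into K single-variant components

    b_t = sum_k phi_k * s_tk * w_tk,
    w_tk ~ N(0, alpha_tk^{-1}),   s_tk ~ Bernoulli(p0_k),
    phi_k ~ Categorical(pi0),     alpha_tk ~ Gamma(a0, b0),
    tau_t ~ Gamma(c0, d0).

Each component phi_k points at one causal variant shared across traits; the
Bernoulli switch s_tk decides whether that variant has any effect in trait t
(the spike of the spike-and-slab prior), and w_tk is the slab effect size.

Inference is coordinate-ascent variational inference over the mean-field
family q(w|phi,s) q(s) q(phi) q(alpha) q(tau). Every update below is the
exact maximizer of the ELBO in its coordinate, so the ELBO is non-decreasing
across sweeps — the main correctness invariant the test suite enforces.

All updates are written in terms of the sufficient statistics
``X'X``, ``X'y``, ``y'y`` and N, which is what makes the summary-statistic
mode (see :mod:`cafeh.model_s`) share this exact code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .data import (
    GenotypePanel,
    Hyperparameters,
    NumericalError,
    TraitMatrix,
    VariationalPosterior,
)

LOGIT_CLIP = 700.0
VAR_FLOOR = 1e-12
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SuffStats:
    """Per-trait sufficient statistics driving every CAVI update.

    In individual-level mode ``xtx`` is the shared Gram matrix X'X and
    ``xty[t] = X'y_t``; in summary mode they are the RSS-implied analogues
    (see :func:`cafeh.model_s.suffstats_from_summary`). ``infer_tau`` is False
    in summary mode, where the residual precision is absorbed into the scale
    matrix and fixed at 1.
    """

    xtx: list  # length-T list of (G, G); may alias one shared array
    xty: np.ndarray  # (T, G)
    yty: np.ndarray | None  # (T,) individual-level mode only
    n: np.ndarray  # (T,)
    diag: np.ndarray  # (T, G) diagonals of xtx
    mode: str  # "g" or "s"
    loglik_const: np.ndarray  # (T,) additive log-likelihood constants
    infer_tau: bool = True

    @property
    def T(self) -> int:
        return self.xty.shape[0]

    @property
    def G(self) -> int:
        return self.xty.shape[1]


def suffstats_from_individual(
    panel: GenotypePanel, traits: TraitMatrix
) -> SuffStats:
    x = panel.genotypes
    y = traits.values
    if y.shape[0] != x.shape[0]:
        raise ValueError("trait rows must match genotype rows")
    n, _ = x.shape
    xtx = x.T @ x
    t_count = y.shape[1]
    return SuffStats(
        xtx=[xtx] * t_count,
        xty=(x.T @ y).T.copy(),
        yty=np.einsum("nt,nt->t", y, y),
        n=np.full(t_count, float(n)),
        diag=np.tile(np.diag(xtx), (t_count, 1)),
        mode="g",
        loglik_const=np.zeros(t_count),
        infer_tau=True,
    )


# ---------------------------------------------------------------------------
# moment helpers


def _tau_moments(post, hyper, stats):
    """E[tau_t] and E[log tau_t] per trait (point mass when not inferred)."""
    if stats.infer_tau and hyper.fixed_tau is None:
        e = post.tau_shape / post.tau_rate
        elog = digamma(post.tau_shape) - np.log(post.tau_rate)
        return e, elog
    val = 1.0 if hyper.fixed_tau is None else float(hyper.fixed_tau)
    e = np.full(stats.T, val)
    return e, np.log(e)


def _alpha_moments(post, hyper):
    if hyper.fixed_alpha is None:
        e = post.alpha_shape / post.alpha_rate
        elog = digamma(post.alpha_shape) - np.log(post.alpha_rate)
        return e, elog
    val = float(hyper.fixed_alpha)
    shape = post.s_prob.shape
    return np.full(shape, val), np.full(shape, np.log(val))


def _logit(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p) - np.log1p(-p)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(x, -LOGIT_CLIP, LOGIT_CLIP)))


# ---------------------------------------------------------------------------
# spec-surface single-coordinate operations


def expected_residual(
    t: int,
    k: int,
    post: VariationalPosterior,
    panel: GenotypePanel,
    traits: TraitMatrix,
) -> np.ndarray:
    """Trait t minus the posterior-mean predictions of all components but k.

    This is the target of the single-effect update for component k: the part
    of the signal the other components do not already explain.
    """
    if not (0 <= t < post.T) or not (0 <= k < post.K):
        raise IndexError("trait or component index out of range")
    eb = post.expected_effects()[t]  # (K, G)
    b_other = eb.sum(axis=0) - eb[k]
    return traits.values[:, t] - panel.genotypes @ b_other


def _slab_update(r_stat, diag_t, e_tau_t, e_alpha_tk):
    lam = e_tau_t * diag_t + e_alpha_tk
    var = np.maximum(1.0 / lam, VAR_FLOOR)
    mean = e_tau_t * r_stat * var
    return mean, var


def update_w(
    t: int,
    k: int,
    post: VariationalPosterior,
    panel: GenotypePanel,
    traits: TraitMatrix,
    hyper: Hyperparameters | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional Gaussian slab update for q(w_tk | phi_k = g, s_tk = 1).

    For each candidate variant g the posterior precision is
    ``E[tau_t] x_g'x_g + E[alpha_tk]`` and the mean is
    ``E[tau_t] x_g'r / precision`` with r the expected residual.
    """
    hyper = hyper or Hyperparameters.default(post.K, post.G)
    r = expected_residual(t, k, post, panel, traits)
    e_alpha, _ = _alpha_moments(post, hyper)
    stats = suffstats_from_individual(panel, traits)
    e_tau, _ = _tau_moments(post, hyper, stats)
    mean, var = _slab_update(
        panel.genotypes.T @ r, stats.diag[t], e_tau[t], e_alpha[t, k]
    )
    if np.any(var <= 0):
        raise NumericalError("non-positive slab variance")
    post.w_mean[t, k] = mean
    post.w_var[t, k] = var
    return mean, var


def _log_evidence_ratio(post, t, k, e_log_alpha_tk):
    """Per-variant slab-vs-spike expected log evidence ratio A_tkg.

    A_g = mu_g^2 / (2 sigma_g^2) + (log sigma_g^2 + E[log alpha_tk]) / 2,
    combining the data likelihood gain of the slab with the KL cost of the
    Gaussian slab factor against its N(0, alpha^{-1}) prior.
    """
    mean, var = post.w_mean[t, k], post.w_var[t, k]
    return 0.5 * mean**2 / var + 0.5 * (np.log(var) + e_log_alpha_tk)


def update_s(
    t: int,
    k: int,
    post: VariationalPosterior,
    hyper: Hyperparameters,
    panel: GenotypePanel,
    traits: TraitMatrix,
) -> float:
    """Bernoulli activity update: sigmoid of prior log-odds plus the
    q(phi_k)-averaged slab-vs-spike evidence ratio."""
    if hyper.p0[k] in (0.0, 1.0):  # prior excludes or forces activity
        post.s_prob[t, k] = float(hyper.p0[k])
        return post.s_prob[t, k]
    _, e_log_alpha = _alpha_moments(post, hyper)
    a = _log_evidence_ratio(post, t, k, e_log_alpha[t, k])
    logit = _logit(hyper.p0[k : k + 1])[0] + post.phi[k] @ a
    post.s_prob[t, k] = float(_sigmoid(np.array([logit]))[0])
    return post.s_prob[t, k]


def update_phi(
    k: int,
    post: VariationalPosterior,
    hyper: Hyperparameters,
    panel: GenotypePanel,
    traits: TraitMatrix,
) -> np.ndarray:
    """Categorical update for component k's causal-variant posterior.

    Aggregates the activity-weighted evidence ratio across traits — the
    cross-trait sharing that distinguishes joint from single-trait
    fine-mapping.
    """
    _, e_log_alpha = _alpha_moments(post, hyper)
    log_phi = np.log(hyper.pi0).copy()
    for t in range(post.T):
        log_phi += post.s_prob[t, k] * _log_evidence_ratio(
            post, t, k, e_log_alpha[t, k]
        )
    log_phi -= logsumexp(log_phi)
    post.phi[k] = np.exp(log_phi)
    post.phi[k] /= post.phi[k].sum()
    return post.phi[k]


def update_alpha(
    t: int,
    k: int,
    post: VariationalPosterior,
    hyper: Hyperparameters,
) -> tuple[float, float]:
    """Conjugate Gamma update of the effect precision alpha_tk.

    Under the spike-and-slab prior only the slab branch carries the effect,
    so the sufficient statistics are weighted by the activity probability:
    the spike contributes zero second moment.
    """
    if hyper.fixed_alpha is not None:
        return float(post.alpha_shape[t, k]), float(post.alpha_rate[t, k])
    s = post.s_prob[t, k]
    m2 = post.phi[k] @ (post.w_mean[t, k] ** 2 + post.w_var[t, k])
    post.alpha_shape[t, k] = hyper.a0 + 0.5 * s
    post.alpha_rate[t, k] = hyper.b0 + 0.5 * s * m2
    return float(post.alpha_shape[t, k]), float(post.alpha_rate[t, k])


def _expected_rss(post, stats, t, comp_pred=None):
    """E||y_t - X b_t||^2 under q (up to mode conventions).

    Returns (erss, quad, lin) where quad = E[b'X'Xb] and lin = Eb . X'y.
    In summary mode ``yty`` is unavailable and erss is None.
    """
    eb = post.expected_effects()[t]  # (K, G)
    if comp_pred is None:
        comp_pred = np.stack([stats.xtx[t] @ eb[k] for k in range(post.K)])
    total_pred = comp_pred.sum(axis=0)
    eb_tot = eb.sum(axis=0)
    cross = eb_tot @ total_pred - np.einsum("kg,kg->", eb, comp_pred)
    m2 = post.w_mean[t] ** 2 + post.w_var[t]  # (K, G)
    own = np.einsum(
        "k,kg,kg->", post.s_prob[t], post.phi, m2 * stats.diag[t][None, :]
    )
    quad = cross + own
    lin = eb_tot @ stats.xty[t]
    erss = None
    if stats.yty is not None:
        erss = stats.yty[t] - 2.0 * lin + quad
    return erss, quad, lin


def update_tau(
    t: int,
    post: VariationalPosterior,
    panel: GenotypePanel,
    traits: TraitMatrix,
    hyper: Hyperparameters | None = None,
) -> tuple[float, float]:
    """Conjugate Gamma update of the residual precision tau_t."""
    hyper = hyper or Hyperparameters.default(post.K, post.G)
    stats = suffstats_from_individual(panel, traits)
    return _update_tau_stats(t, post, stats, hyper)


def _update_tau_stats(t, post, stats, hyper, comp_pred=None):
    if not stats.infer_tau or hyper.fixed_tau is not None:
        return float(post.tau_shape[t]), float(post.tau_rate[t])
    erss, _, _ = _expected_rss(post, stats, t, comp_pred)
    post.tau_shape[t] = hyper.c0 + 0.5 * stats.n[t]
    post.tau_rate[t] = hyper.d0 + 0.5 * max(erss, VAR_FLOOR)
    return float(post.tau_shape[t]), float(post.tau_rate[t])


# ---------------------------------------------------------------------------
# ELBO


def _gamma_kl(a, b, a0, b0):
    """KL( Gamma(a, b) || Gamma(a0, b0) ), rate parameterization."""
    return (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


def _binary_kl(q, p):
    q = np.clip(q, 1e-300, 1 - 1e-16)
    out = q * (np.log(q) - np.log(p)) if p > 0 else np.where(q > 1e-250, np.inf, 0.0)
    if p < 1:
        out = out + (1 - q) * (np.log1p(-q) - np.log1p(-p))
    return out


def compute_elbo_stats(
    post: VariationalPosterior, hyper: Hyperparameters, stats: SuffStats
) -> float:
    """Evidence lower bound under the factorized family.

    Expected log-likelihood minus the KL of every factor from its prior;
    exact in both modes (in summary mode the likelihood is the RSS density
    and its additive constant is folded in).
    """
    e_tau, e_log_tau = _tau_moments(post, hyper, stats)
    e_alpha, e_log_alpha = _alpha_moments(post, hyper)
    elbo = 0.0
    for t in range(stats.T):
        erss, quad, lin = _expected_rss(post, stats, t)
        if stats.mode == "g":
            elbo += 0.5 * stats.n[t] * (e_log_tau[t] - _LOG2PI)
            elbo -= 0.5 * e_tau[t] * erss
        else:
            elbo += stats.loglik_const[t] + lin - 0.5 * quad

    # KL(q(phi) || Categorical(pi0))
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post.phi > 0, post.phi * np.log(post.phi), 0.0)
    elbo -= float(np.sum(plogp - post.phi * np.log(hyper.pi0)[None, :]))

    # KL(q(s) || Bernoulli(p0)) and slab KL weighted by activity
    m2 = post.w_mean**2 + post.w_var  # (T, K, G)
    for k in range(post.K):
        elbo -= float(np.sum(_binary_kl(post.s_prob[:, k], hyper.p0[k])))
    kl_w = 0.5 * (
        e_alpha[:, :, None] * m2
        - 1.0
        - np.log(post.w_var)
        - e_log_alpha[:, :, None]
    )
    elbo -= float(np.einsum("tk,kg,tkg->", post.s_prob, post.phi, kl_w))

    if hyper.fixed_alpha is None:
        elbo -= float(
            np.sum(_gamma_kl(post.alpha_shape, post.alpha_rate, hyper.a0, hyper.b0))
        )
    if stats.infer_tau and hyper.fixed_tau is None:
        elbo -= float(
            np.sum(_gamma_kl(post.tau_shape, post.tau_rate, hyper.c0, hyper.d0))
        )
    return float(elbo)


def compute_elbo(
    post: VariationalPosterior,
    hyper: Hyperparameters,
    panel: GenotypePanel,
    traits: TraitMatrix,
) -> float:
    return compute_elbo_stats(post, hyper, suffstats_from_individual(panel, traits))


# ---------------------------------------------------------------------------
# full sweep on sufficient statistics (used by the fitting engine)


def cavi_sweep(
    post: VariationalPosterior,
    hyper: Hyperparameters,
    stats: SuffStats,
    phi_sampler=None,
) -> None:
    """One full coordinate-ascent sweep, in place.

    Order: for each component k — slab updates for every trait, then the
    shared causal-variant posterior phi_k, then the activity updates — then
    all effect precisions, then the residual precisions. Updating phi before
    s lets the activity decision see the concentrated causal-variant
    posterior rather than its diffuse initialization; each step is an exact
    coordinate maximizer, so the ELBO cannot decrease.

    ``phi_sampler`` optionally supplies Monte-Carlo estimates of the
    q(phi)-expectations appearing in other components' residuals (used for
    very large variant sets).
    """
    T, K, G = post.T, post.K, post.G
    e_tau, _ = _tau_moments(post, hyper, stats)
    e_alpha, e_log_alpha = _alpha_moments(post, hyper)
    log_pi0 = np.log(hyper.pi0)

    eb = post.expected_effects()  # (T, K, G)
    comp_pred = np.empty((T, K, G))
    for t in range(T):
        for k in range(K):
            comp_pred[t, k] = _component_pred(stats, post, t, k, eb, phi_sampler)
    pred = comp_pred.sum(axis=1)  # (T, G)

    logit_p0 = _logit(hyper.p0)

    for k in range(K):
        a_mat = np.empty((T, G))
        for t in range(T):
            r_stat = stats.xty[t] - pred[t] + comp_pred[t, k]
            mean, var = _slab_update(r_stat, stats.diag[t], e_tau[t], e_alpha[t, k])
            post.w_mean[t, k] = mean
            post.w_var[t, k] = var
            a_mat[t] = 0.5 * mean**2 / var + 0.5 * (np.log(var) + e_log_alpha[t, k])
        log_phi = log_pi0 + post.s_prob[:, k] @ a_mat
        log_phi -= logsumexp(log_phi)
        post.phi[k] = np.exp(log_phi)
        post.phi[k] /= post.phi[k].sum()
        if phi_sampler is not None:
            phi_sampler.invalidate(k)
        for t in range(T):
            if hyper.p0[k] in (0.0, 1.0):
                post.s_prob[t, k] = float(hyper.p0[k])
                continue
            if phi_sampler is None:
                evidence = post.phi[k] @ a_mat[t]
            else:
                evidence = phi_sampler(k, a_mat[t])
            post.s_prob[t, k] = float(
                _sigmoid(np.array([logit_p0[k] + evidence]))[0]
            )
        for t in range(T):
            eb[t, k] = post.s_prob[t, k] * post.phi[k] * post.w_mean[t, k]
            new_pred = _component_pred(stats, post, t, k, eb, phi_sampler)
            pred[t] += new_pred - comp_pred[t, k]
            comp_pred[t, k] = new_pred

    if hyper.fixed_alpha is None:
        m2 = np.einsum("kg,tkg->tk", post.phi, post.w_mean**2 + post.w_var)
        post.alpha_shape = hyper.a0 + 0.5 * post.s_prob
        post.alpha_rate = hyper.b0 + 0.5 * post.s_prob * m2

    if stats.infer_tau and hyper.fixed_tau is None:
        for t in range(T):
            _update_tau_stats(t, post, stats, hyper, comp_pred[t])


def _component_pred(stats, post, t, k, eb, phi_sampler):
    """xtx[t] @ E[b_tk], exactly or via Monte-Carlo over q(phi_k)."""
    if phi_sampler is None:
        return stats.xtx[t] @ eb[t, k]
    idx = phi_sampler.indices(k)
    cols = stats.xtx[t][:, idx] * post.w_mean[t, k][idx][None, :]
    return post.s_prob[t, k] * cols.mean(axis=1)
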