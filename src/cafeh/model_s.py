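"""Summary-statistic mode: the same model fit through the RSS likelihood.

Given marginal effect sizes ``beta_t`` and standard errors ``se_t`` from
simple linear regressions plus an LD matrix ``R``, define per-variant scales
``s_i^2 = beta_ti^2 / N + se_ti^2`` and the diagonal matrix ``S``. The RSS
likelihood states

    beta_t ~ N( S R S^{-1} b_t,  S R S ),

so the joint effect vector b_t can be inferred without individual-level
data. Expanding the Gaussian log density in b_t shows the inference needs
only ``S^{-1} R S^{-1}`` (in place of X'X) and ``S^{-2} beta_t`` (in place of
X'y): the coordinate updates in :mod:`cafeh.model_g` therefore run unchanged
on these substituted sufficient statistics, with the residual precision
fixed at 1 because the scale matrix already absorbs the noise level.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

from .data import (
    DomainError,
    EmptyIntersection,
    Hyperparameters,
    LDMatrix,
    NotSymmetric,
    SingularCovariance,
    SummaryStatSet,
    VariationalPosterior,
)
from .model_g import SuffStats, _LOG2PI

logger = logging.getLogger(__name__)

#: default ridge weights by LD source
RIDGE_REFERENCE = 0.01
RIDGE_IN_SAMPLE = 1e-6


def compute_scale(beta_t: np.ndarray, se_t: np.ndarray, n: float) -> np.ndarray:
    """Per-variant scale ``s_i = sqrt(beta_i^2 / N + se_i^2)``.

    These are the diagonal entries of the S matrix of the RSS likelihood;
    as N grows (or the effect vanishes) s_i approaches the standard error.
    """
    beta_t = np.asarray(beta_t, float)
    se_t = np.asarray(se_t, float)
    if n < 2:
        raise DomainError("sample size must be at least 2")
    if np.any(se_t <= 0):
        raise DomainError("standard errors must be strictly positive")
    return np.sqrt(beta_t**2 / n + se_t**2)


def regularize_ld(
    ld: LDMatrix, ridge: float = RIDGE_REFERENCE, method: str = "ridge",
    eig_floor: float = 1e-10,
) -> LDMatrix:
    """Condition an estimated LD matrix so the RSS covariance is invertible.

    ``ridge`` shrinks toward the identity: ``(1 - ridge) R + ridge I``;
    ``clip`` floors negative eigenvalues instead. The diagonal is
    renormalized to exactly 1 afterwards.
    """
    r = ld.r
    asym = np.max(np.abs(r - r.T)) if r.size else 0.0
    if asym > 1e-6:
        raise NotSymmetric(f"asymmetry {asym:.2e} exceeds 1e-6")
    r = 0.5 * (r + r.T)
    if method == "ridge":
        out = (1.0 - ridge) * r + ridge * np.eye(r.shape[0])
    elif method == "clip":
        vals, vecs = np.linalg.eigh(r)
        out = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    else:
        raise ValueError(f"unknown regularization method {method!r}")
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return LDMatrix(r=out, variant_ids=list(ld.variant_ids), source=ld.source)


def rss_loglik(
    beta_t: np.ndarray,
    scale: np.ndarray,
    ld: LDMatrix,
    b_t: np.ndarray,
) -> float:
    """Exact log density of the marginal effects under the RSS model.

    ``beta_t ~ N(S R S^{-1} b_t, S R S)`` with S = diag(scale).
    """
    s = np.asarray(scale, float)
    beta_t = np.asarray(beta_t, float)
    b_t = np.asarray(b_t, float)
    g = s.shape[0]
    mean = s * (ld.r @ (b_t / s))
    resid = (beta_t - mean) / s  # S^{-1}(beta - mean)
    try:
        cho = linalg.cho_factor(ld.r, lower=True)
    except linalg.LinAlgError as exc:
        raise SingularCovariance(str(exc)) from exc
    quad = resid @ linalg.cho_solve(cho, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0]))) + 2.0 * np.sum(np.log(s))
    return float(-0.5 * (quad + logdet + g * _LOG2PI))


def suffstats_from_summary(stats: SummaryStatSet, ld: LDMatrix) -> SuffStats:
    """RSS-implied sufficient statistics, one scale matrix per study.

    Requires a regularized (positive definite) LD matrix.
    """
    if list(ld.variant_ids) != list(stats.variant_ids):
        raise ValueError("LD matrix and summary statistics are not variant-aligned")
    t_count, g = stats.beta.shape
    xtx, xty, diag, const = [], [], [], []
    try:
        cho = linalg.cho_factor(ld.r, lower=True)
    except linalg.LinAlgError as exc:
        raise SingularCovariance(
            "LD matrix is not positive definite; run regularize_ld first"
        ) from exc
    logdet_r = 2.0 * np.sum(np.log(np.diag(cho[0])))
    for t in range(t_count):
        s = compute_scale(stats.beta[t], stats.se[t], stats.n[t])
        inv_s = 1.0 / s
        m = ld.r * np.outer(inv_s, inv_s)  # S^{-1} R S^{-1}
        xtx.append(m)
        xty.append(stats.beta[t] * inv_s**2)  # S^{-2} beta
        diag.append(inv_s**2)
        z = stats.beta[t] * inv_s
        quad = z @ linalg.cho_solve(cho, z)
        logdet = logdet_r + 2.0 * np.sum(np.log(s))
        const.append(-0.5 * (quad + logdet + g * _LOG2PI))
    return SuffStats(
        xtx=xtx,
        xty=np.asarray(xty),
        yty=None,
        n=np.asarray(stats.n, float),
        diag=np.asarray(diag),
        mode="s",
        loglik_const=np.asarray(const),
        infer_tau=False,
    )


def fit_updates_s(
    stats: SummaryStatSet,
    ld: LDMatrix,
    hyper: Hyperparameters | None = None,
    config=None,
) -> VariationalPosterior:
    """Fit the model from harmonized summary statistics and regularized LD."""
    from .infer import FitConfig, fit_stats

    config = config or FitConfig(mode="s")
    hyper = hyper or Hyperparameters.default(config.K, stats.n_variants)
    ss = suffstats_from_summary(stats, ld)
    return fit_stats(ss, hyper, config)


# ---------------------------------------------------------------------------
# Monte-Carlo handling of q(phi) expectations (for very large variant sets)


def mc_phi_expectation(
    post: VariationalPosterior,
    k: int,
    values: np.ndarray,
    n_samples: int,
    seed: int,
) -> np.ndarray:
    """Unbiased Monte-Carlo estimate of ``E_{q(phi_k)}[values[..., g]]``.

    ``values`` may be any array whose last axis indexes variants; the
    estimate averages that axis over ``n_samples`` draws from q(phi_k).
    Identical seeds give identical estimates.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(post.G, size=n_samples, p=post.phi[k])
    return np.asarray(values)[..., idx].mean(axis=-1)


class PhiSampler:
    """Per-sweep cache of q(phi_k) samples for stochastic inference.

    The coordinate updates need expectations over q(phi) in two places: the
    residual contribution of every other component and the evidence term of
    the activity update. Both are estimated from the same cached draws so a
    sweep is internally consistent; caches are refreshed once per sweep and
    invalidated when a component's phi is updated.
    """

    def __init__(self, n_samples: int, seed: int):
        self.n_samples = int(n_samples)
        self.rng = np.random.default_rng(seed)
        self._cache: dict[int, np.ndarray] = {}
        self._post: VariationalPosterior | None = None

    def bind(self, post: VariationalPosterior):
        self._post = post

    def refresh(self):
        self._cache.clear()

    def invalidate(self, k: int):
        self._cache.pop(k, None)

    def indices(self, k: int) -> np.ndarray:
        if k not in self._cache:
            self._cache[k] = self.rng.choice(
                self._post.G, size=self.n_samples, p=self._post.phi[k]
            )
        return self._cache[k]

    def __call__(self, k: int, values: np.ndarray) -> float:
        return float(np.asarray(values)[self.indices(k)].mean())


# ---------------------------------------------------------------------------
# multi-study harmonization

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_studies(
    studies: list[SummaryStatSet],
    ld: LDMatrix | None = None,
    keep_ambiguous: bool = False,
):
    """Stack studies onto one shared, allele-aligned variant set.

    Variants are intersected across studies (and the LD matrix if given);
    betas whose effect/other alleles are swapped relative to the first study
    are sign-flipped; strand-ambiguous (A/T, C/G) variants are dropped by
    default. Returns the stacked set, or ``(stacked, ld_subset)`` when an
    LD matrix is supplied.
    """
    if not studies:
        raise ValueError("at least one study is required")
    ref = studies[0]
    shared = set(ref.variant_ids)
    for st in studies[1:]:
        shared &= set(st.variant_ids)
    if ld is not None:
        shared &= set(ld.variant_ids)

    order_src = ld.variant_ids if ld is not None else ref.variant_ids
    ordered = [v for v in order_src if v in shared]

    ref_idx = {v: i for i, v in enumerate(ref.variant_ids)}
    n_ambiguous = 0
    keep: list[str] = []
    for v in ordered:
        i = ref_idx[v]
        ea, oa = str(ref.effect_allele[i]), str(ref.other_allele[i])
        if not keep_ambiguous and _is_ambiguous(ea, oa):
            n_ambiguous += 1
            continue
        keep.append(v)
    if n_ambiguous:
        logger.info("dropped %d strand-ambiguous variant(s)", n_ambiguous)

    betas, ses, ns, names = [], [], [], []
    kept_final = list(keep)
    for st in studies:
        idx = {v: i for i, v in enumerate(st.variant_ids)}
        flip = np.ones(len(kept_final))
        drop = set()
        for j, v in enumerate(kept_final):
            i, ri = idx[v], ref_idx[v]
            ea, oa = str(st.effect_allele[i]), str(st.other_allele[i])
            rea, roa = str(ref.effect_allele[ri]), str(ref.other_allele[ri])
            if ea == rea and oa == roa:
                continue
            if ea == roa and oa == rea:
                flip[j] = -1.0
            else:
                drop.add(v)
        if drop:
            logger.info("dropped %d allele-incompatible variant(s)", len(drop))
            mask = [v not in drop for v in kept_final]
            kept_final = [v for v, m in zip(kept_final, mask) if m]
    if not kept_final:
        raise EmptyIntersection("no shared variants remain after harmonization")

    for st in studies:
        idx = {v: i for i, v in enumerate(st.variant_ids)}
        cols = np.array([idx[v] for v in kept_final])
        flip = np.ones(len(kept_final))
        for j, v in enumerate(kept_final):
            i, ri = idx[v], ref_idx[v]
            if (
                str(st.effect_allele[i]) == str(ref.other_allele[ri])
                and str(st.other_allele[i]) == str(ref.effect_allele[ri])
            ):
                flip[j] = -1.0
        betas.append(st.beta[:, cols] * flip[None, :])
        ses.append(st.se[:, cols])
        ns.append(st.n)
        names.extend(st.study_names)

    ridx = np.array([ref_idx[v] for v in kept_final])
    stacked = SummaryStatSet(
        beta=np.vstack(betas),
        se=np.vstack(ses),
        n=np.concatenate(ns),
        variant_ids=kept_final,
        study_names=names,
        chrom=np.asarray(ref.chrom)[ridx],
        pos=np.asarray(ref.pos)[ridx],
        effect_allele=np.asarray(ref.effect_allele)[ridx],
        other_allele=np.asarray(ref.other_allele)[ridx],
    )
    if ld is None:
        return stacked
    lidx = {v: i for i, v in enumerate(ld.variant_ids)}
    sel = np.array([lidx[v] for v in kept_final])
    ld_sub = LDMatrix(
        r=ld.r[np.ix_(sel, sel)], variant_ids=kept_final, source=ld.source
    )
    return stacked, ld_sub
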