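"""Fitting engine: initialization, CAVI sweeps, convergence and restarts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    GenotypePanel,
    Hyperparameters,
    LDMatrix,
    NonMonotoneElbo,
    SummaryStatSet,
    TraitMatrix,
    VariationalPosterior,
    standardize_genotypes,
)
from .model_g import (
    SuffStats,
    cavi_sweep,
    compute_elbo_stats,
    suffstats_from_individual,
)

#: variant count above which summary-mode inference switches to Monte-Carlo
MC_AUTO_THRESHOLD = 5000


@dataclass
class FitConfig:
    """Fitting options.

    K is an upper bound on the number of causal variants the model can
    represent; irrelevant components stay inactive with diffuse phi and do
    not perturb the inclusion probabilities, so a generous default (20) is
    safe. Convergence is declared when the ELBO improves by less than
    ``elbo_tol`` over a full sweep.
    """

    K: int = 20
    max_sweeps: int = 1000
    elbo_tol: float = 1e-6
    n_restarts: int = 1
    seed: int = 0
    mode: str = "g"
    p0: float = 0.1
    mc: bool | None = None  # None = automatic (summary mode, large G)
    mc_n_samples: int = 100
    standardize: bool = True

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.elbo_tol <= 0:
            raise ValueError("elbo_tol must be positive")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


def initialize(
    stats: SuffStats, hyper: Hyperparameters, config: FitConfig
) -> VariationalPosterior:
    """Null initialization.

    All posterior effect means start at 0, the residual variance at the
    sample variance of each trait, and the prior effect-size variance at
    ``alpha_init_inv`` (0.1 by default, a sensible scale for standardized
    genotypes and traits). phi rows start at the prior pi0. Activity
    probabilities start at 1: every component is provisionally active, so
    the first sweeps can concentrate each phi on a causal variant before the
    Bernoulli updates (which apply the sparse p0 prior every sweep) switch
    unsupported components off. Starting activity at the sparse prior
    instead starves the causal-variant posteriors of evidence and collapses
    all components on null data and real signals alike.
    """
    t_count, g = stats.T, stats.G
    k = hyper.K
    alpha0 = 1.0 / hyper.alpha_init_inv
    if stats.infer_tau:
        # traits are assumed centered; sample variance = y'y / n
        var = stats.yty / stats.n
        tau_shape = np.full(t_count, hyper.c0 + 0.5 * stats.n)
        tau_rate = tau_shape * var
    else:
        tau_shape = np.ones(t_count)
        tau_rate = np.ones(t_count)
    return VariationalPosterior(
        phi=np.tile(hyper.pi0, (k, 1)),
        s_prob=np.ones((t_count, k)),
        w_mean=np.zeros((t_count, k, g)),
        w_var=np.full((t_count, k, g), hyper.alpha_init_inv),
        alpha_shape=np.full((t_count, k), 1.0),
        alpha_rate=np.full((t_count, k), 1.0 / alpha0),
        tau_shape=tau_shape,
        tau_rate=tau_rate,
        elbo_trace=[],
    )


def fit_stats(
    stats: SuffStats,
    hyper: Hyperparameters,
    config: FitConfig,
    init: VariationalPosterior | None = None,
) -> VariationalPosterior:
    """Run CAVI to convergence on prepared sufficient statistics."""
    post = init.copy() if init is not None else initialize(stats, hyper, config)

    sampler = None
    use_mc = config.mc
    if use_mc is None:
        use_mc = stats.mode == "s" and stats.G > MC_AUTO_THRESHOLD
    if use_mc:
        from .model_s import PhiSampler

        sampler = PhiSampler(config.mc_n_samples, config.seed)
        sampler.bind(post)

    elbo = compute_elbo_stats(post, hyper, stats)
    post.elbo_trace.append(elbo)
    for _ in range(config.max_sweeps):
        if sampler is not None:
            sampler.refresh()
        cavi_sweep(post, hyper, stats, phi_sampler=sampler)
        new_elbo = compute_elbo_stats(post, hyper, stats)
        post.elbo_trace.append(new_elbo)
        if sampler is None and new_elbo < elbo - 1e-4:
            raise NonMonotoneElbo(
                f"ELBO decreased from {elbo:.8f} to {new_elbo:.8f}"
            )
        if abs(new_elbo - elbo) < config.elbo_tol:
            elbo = new_elbo
            break
        elbo = new_elbo
    return post


def _prepare_g(panel, traits, config):
    if config.standardize:
        std = standardize_genotypes(panel) if not panel.standardized else panel
        if std.n_variants != panel.n_variants:
            raise ValueError(
                "constant genotype columns present; run standardize_genotypes "
                "and keep the filtered panel before fitting"
            )
        panel = std
        traits = traits.standardized()
    return panel, traits


def fit_g(
    panel: GenotypePanel,
    traits: TraitMatrix,
    hyper: Hyperparameters | None = None,
    config: FitConfig | None = None,
) -> VariationalPosterior:
    """Fit from individual-level genotypes and traits."""
    config = config or FitConfig(mode="g")
    panel, traits = _prepare_g(panel, traits, config)
    hyper = hyper or Hyperparameters.default(config.K, panel.n_variants, p0=config.p0)
    stats = suffstats_from_individual(panel, traits)
    return fit_stats(stats, hyper, config)


def fit_s(
    sumstats: SummaryStatSet,
    ld: LDMatrix,
    hyper: Hyperparameters | None = None,
    config: FitConfig | None = None,
    regularize: bool = True,
) -> VariationalPosterior:
    """Fit from marginal summary statistics and an LD matrix.

    ``ld`` is ridge-regularized by default (weight depends on whether it is
    in-sample or from a reference panel).
    """
    from .model_s import (
        RIDGE_IN_SAMPLE,
        RIDGE_REFERENCE,
        regularize_ld,
        suffstats_from_summary,
    )

    config = config or FitConfig(mode="s")
    hyper = hyper or Hyperparameters.default(
        config.K, sumstats.n_variants, p0=config.p0
    )
    if regularize:
        ridge = RIDGE_IN_SAMPLE if ld.source == "in-sample" else RIDGE_REFERENCE
        ld = regularize_ld(ld, ridge=ridge)
    stats = suffstats_from_summary(sumstats, ld)
    return fit_stats(stats, hyper, config)


def fit_restarts(
    stats: SuffStats,
    hyper: Hyperparameters,
    config: FitConfig,
) -> VariationalPosterior:
    """Null-initialized fit plus perturbed restarts; keep the best ELBO.

    Restarts draw each component's phi row from a flat Dirichlet — the
    component-to-signal assignment is the only label-switching degree of
    freedom worth exploring — with everything else null-initialized.
    """
    best = fit_stats(stats, hyper, config)
    if config.n_restarts <= 1:
        return best
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts - 1)
    for seq in seeds:
        rng = np.random.default_rng(seq)
        init = initialize(stats, hyper, config)
        init.phi = rng.dirichlet(np.ones(stats.G), size=hyper.K)
        cand = fit_stats(stats, hyper, config, init=init)
        if cand.elbo_trace[-1] > best.elbo_trace[-1]:
            best = cand
    return best


def active_components(
    post: VariationalPosterior, threshold: float = 0.5
) -> list[np.ndarray]:
    """Indices of components active in each trait (p_active >= threshold)."""
    return [np.flatnonzero(post.s_prob[t] >= threshold) for t in range(post.T)]
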