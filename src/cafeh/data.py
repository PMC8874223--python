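"""Core data containers for individual-level and summary-statistic inputs.

The model views a locus as an ``N x G`` genotype matrix ``X`` and an
``N x T`` trait matrix ``Y`` (individual-level mode), or as per-study
marginal effect sizes / standard errors plus an LD matrix (summary mode).
These containers validate and standardize those inputs once, up front, so
the inference code can assume clean numerics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np


class CafehError(Exception):
    """Base class for all package errors."""


class AllColumnsConstant(CafehError):
    """No variant survives standardization (every column constant)."""


class NumericalError(CafehError):
    """A posted variance or precision left the valid domain."""


class DomainError(CafehError):
    """An input value is outside its mathematical domain."""


class NotSymmetric(CafehError):
    """A matrix required to be symmetric is not."""


class SingularCovariance(CafehError):
    """The (regularized) covariance matrix is not invertible."""


class EmptyIntersection(CafehError):
    """No shared variants remain after harmonizing studies."""


class InfeasibleConstraint(CafehError):
    """Rejection sampling could not satisfy a simulation constraint."""


class NoActiveComponent(CafehError):
    """A trait has no component above the activity threshold."""


class DegenerateSD(CafehError):
    """An effect-size standard deviation is zero or negative."""


class SchemaError(CafehError):
    """A tabular input is missing required columns or has invalid values."""


class ParseError(CafehError):
    """A file could not be parsed; message carries the offending line."""


class MissingGenotype(CafehError):
    """A VCF record contains an uncalled genotype."""


class LengthMismatch(CafehError):
    """Two aligned sequences have different lengths."""


class NonMonotoneElbo(CafehError):
    """The ELBO decreased beyond tolerance: an update derivation bug."""


def _as_2d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class GenotypePanel:
    """Genotype dosages for ``N`` individuals at ``G`` variants.

    ``genotypes`` holds dosages (0-2) or standardized values; variant
    metadata follows VCF conventions (1-based positions).
    """

    genotypes: np.ndarray
    variant_ids: list[str]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self):
        self.genotypes = _as_2d(self.genotypes, "genotypes")
        n, g = self.genotypes.shape
        if len(self.variant_ids) != g:
            raise ValueError("variant_ids length does not match genotype columns")
        if self.chrom is None:
            self.chrom = np.array(["1"] * g)
        if self.pos is None:
            self.pos = np.arange(1, g + 1, dtype=int)
        if self.ref is None:
            self.ref = np.array(["A"] * g)
        if self.alt is None:
            self.alt = np.array(["G"] * g)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            genotypes=self.genotypes[:, idx],
            variant_ids=[self.variant_ids[i] for i in idx],
            chrom=np.asarray(self.chrom)[idx],
            pos=np.asarray(self.pos)[idx],
            ref=np.asarray(self.ref)[idx],
            alt=np.asarray(self.alt)[idx],
            standardized=self.standardized,
        )


def standardize_genotypes(panel: GenotypePanel) -> GenotypePanel:
    """Center and scale each variant column to mean 0, unit variance.

    Uses the population (ddof=0) standard deviation. Constant columns carry
    no association information and are dropped with a warning; if nothing
    survives, :class:`AllColumnsConstant` is raised.
    """
    if panel.n_individuals < 2:
        raise ValueError("standardization requires at least 2 individuals")
    x = panel.genotypes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise AllColumnsConstant("every genotype column is constant")
    if not keep.all():
        dropped = [panel.variant_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropped {len(dropped)} constant variant column(s): "
            + ",".join(dropped[:5])
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
    z = (x[:, keep] - mu[keep]) / sd[keep]
    out = panel.subset(np.flatnonzero(keep))
    return replace(out, genotypes=z, standardized=True)


@dataclass
class TraitMatrix:
    """``N x T`` trait measurements, column per trait."""

    values: np.ndarray
    trait_names: list[str]

    def __post_init__(self):
        self.values = _as_2d(self.values, "trait values")
        if len(self.trait_names) != self.values.shape[1]:
            raise ValueError("trait_names length does not match columns")
        if np.any(self.values.std(axis=0) <= 0):
            raise ValueError("every trait must have positive variance")

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "TraitMatrix":
        v = self.values
        z = (v - v.mean(axis=0)) / v.std(axis=0)
        return TraitMatrix(z, list(self.trait_names))


@dataclass
class Hyperparameters:
    """Prior settings of the hierarchical model.

    ``K`` components; ``p0[k]`` is the prior probability that component k is
    active in each trait; ``pi0[g]`` the prior probability that variant g is
    the causal variant of a component; vague Gamma priors on the per-trait,
    per-component effect precision alpha ~ Gamma(a0, b0) and the residual
    precision tau ~ Gamma(c0, d0). ``alpha_init_inv`` is the initial prior
    effect-size variance (0.1 is a sensible default for standardized data).
    """

    K: int
    p0: np.ndarray
    pi0: np.ndarray
    a0: float = 1e-6
    b0: float = 1e-6
    c0: float = 1e-6
    d0: float = 1e-6
    alpha_init_inv: float = 0.1
    # Optional point-mass overrides, mainly for exact-oracle comparisons.
    fixed_alpha: float | None = None
    fixed_tau: float | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        self.p0 = np.broadcast_to(np.asarray(self.p0, float), (self.K,)).copy()
        self.pi0 = np.asarray(self.pi0, dtype=float)
        if np.any((self.p0 < 0) | (self.p0 > 1)):
            raise ValueError("p0 entries must lie in [0, 1]")
        if abs(self.pi0.sum() - 1.0) > 1e-10:
            raise ValueError("pi0 must sum to 1")
        for nm in ("a0", "b0", "c0", "d0"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")

    @classmethod
    def default(cls, K: int, G: int, p0: float = 0.1, **kw) -> "Hyperparameters":
        return cls(K=K, p0=np.full(K, p0), pi0=np.full(G, 1.0 / G), **kw)


@dataclass
class VariationalPosterior:
    """All mean-field factor parameters plus the ELBO trace.

    ``phi[k]`` is the categorical posterior over which variant component k
    points at; ``s_prob[t, k]`` the posterior activity probability;
    ``w_mean/w_var[t, k, g]`` the conditional Gaussian slab moments of the
    effect given component k selects variant g and is active in trait t;
    Gamma factors for the effect precisions and residual precisions.
    """

    phi: np.ndarray
    s_prob: np.ndarray
    w_mean: np.ndarray
    w_var: np.ndarray
    alpha_shape: np.ndarray
    alpha_rate: np.ndarray
    tau_shape: np.ndarray
    tau_rate: np.ndarray
    elbo_trace: list = field(default_factory=list)

    @property
    def T(self) -> int:
        return self.s_prob.shape[0]

    @property
    def K(self) -> int:
        return self.s_prob.shape[1]

    @property
    def G(self) -> int:
        return self.phi.shape[1]

    def expected_alpha(self) -> np.ndarray:
        return self.alpha_shape / self.alpha_rate

    def expected_tau(self) -> np.ndarray:
        return self.tau_shape / self.tau_rate

    def expected_effects(self) -> np.ndarray:
        """Posterior-mean sparse effect vector per trait/component, (T, K, G)."""
        return (
            self.s_prob[:, :, None] * self.phi[None, :, :] * self.w_mean
        )

    def validate(self):
        if np.any(np.abs(self.phi.sum(axis=1) - 1.0) > 1e-8):
            raise NumericalError("phi rows must sum to 1")
        if np.any((self.s_prob < 0) | (self.s_prob > 1)):
            raise NumericalError("s_prob must lie in [0, 1]")
        if np.any(self.w_var <= 0):
            raise NumericalError("w_var must be strictly positive")
        for arr in (self.alpha_shape, self.alpha_rate, self.tau_shape, self.tau_rate):
            if np.any(np.asarray(arr) <= 0):
                raise NumericalError("Gamma parameters must be strictly positive")

    def copy(self) -> "VariationalPosterior":
        return VariationalPosterior(
            phi=self.phi.copy(),
            s_prob=self.s_prob.copy(),
            w_mean=self.w_mean.copy(),
            w_var=self.w_var.copy(),
            alpha_shape=self.alpha_shape.copy(),
            alpha_rate=self.alpha_rate.copy(),
            tau_shape=self.tau_shape.copy(),
            tau_rate=self.tau_rate.copy(),
            elbo_trace=list(self.elbo_trace),
        )


@dataclass
class SummaryStatSet:
    """Marginal association summary statistics for T studies over G variants.

    ``beta[t, g]`` and ``se[t, g]`` are the slope and standard error from the
    simple linear regression of trait t on variant g; ``n[t]`` the study
    sample size. All studies share one harmonized, identically ordered
    variant list; betas are signed to ``effect_allele``.
    """

    beta: np.ndarray
    se: np.ndarray
    n: np.ndarray
    variant_ids: list[str]
    study_names: list[str]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None

    def __post_init__(self):
        self.beta = _as_2d(self.beta, "beta")
        self.se = _as_2d(self.se, "se")
        if self.beta.shape != self.se.shape:
            raise ValueError("beta and se shapes differ")
        if np.any(self.se <= 0):
            raise SchemaError("standard errors must be strictly positive")
        self.n = np.broadcast_to(
            np.asarray(self.n, float), (self.beta.shape[0],)
        ).copy()
        g = self.beta.shape[1]
        if len(self.variant_ids) != g:
            raise ValueError("variant_ids length does not match beta columns")
        if self.chrom is None:
            self.chrom = np.array(["1"] * g)
        if self.pos is None:
            self.pos = np.arange(1, g + 1, dtype=int)
        if self.effect_allele is None:
            self.effect_allele = np.array(["G"] * g)
        if self.other_allele is None:
            self.other_allele = np.array(["A"] * g)

    @property
    def n_studies(self) -> int:
        return self.beta.shape[0]

    @property
    def n_variants(self) -> int:
        return self.beta.shape[1]

    def zscores(self) -> np.ndarray:
        return self.beta / self.se


@dataclass
class LDMatrix:
    """Variant correlation matrix ``R`` with its variant ordering."""

    r: np.ndarray
    variant_ids: list[str]
    source: str = "in-sample"

    def __post_init__(self):
        self.r = _as_2d(self.r, "LD matrix")
        g = self.r.shape[0]
        if self.r.shape[1] != g:
            raise ValueError("LD matrix must be square")
        if len(self.variant_ids) != g:
            raise ValueError("variant_ids length does not match LD dimension")
        asym = np.max(np.abs(self.r - self.r.T)) if g else 0.0
        if asym > 1e-6:
            raise NotSymmetric(f"LD matrix asymmetry {asym:.2e} exceeds 1e-6")

    @property
    def n_variants(self) -> int:
        return self.r.shape[0]


def sample_ld(panel: GenotypePanel) -> LDMatrix:
    """In-sample LD (Pearson correlation across individuals)."""
    x = panel.genotypes
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    # exact symmetry for downstream checks
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(r=r, variant_ids=list(panel.variant_ids), source="in-sample")
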