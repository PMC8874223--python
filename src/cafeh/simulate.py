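"""Synthetic genotype/trait generators and performance scoring.

The generators reproduce the statistical structure of the evaluation
designs: mosaic haplotypes with tunable LD for genotypes; two-group trait
designs where traits in a group share causal variants and groups are
disjoint; a random-sharing design where each of q causal variants is
assigned to each trait independently; an LD-confusion design placing the two
groups' causal variants at a controlled r^2; and an expression model with
per-variant effect variance 0.1/n and residual variance 0.9 (10% cis
heritability split across n causal variants).

Signal strength is parameterized by rho, the fraction of trait variance
explained by genotype: given realized effects b, the residual variance is
solved from rho = Var(Xb) / (tau^{-1} + Var(Xb)), exactly, per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    GenotypePanel,
    InfeasibleConstraint,
    LengthMismatch,
    SummaryStatSet,
    TraitMatrix,
)


@dataclass
class SimDesign:
    """Parameters of a two-group simulation.

    ``q`` causal variants per group, ``rho`` the per-trait variance explained,
    ``rmax2`` the maximum pairwise r^2 allowed between causal variants, and
    ``T`` traits split between ``n_groups`` groups with disjoint causal sets.
    """

    N: int = 500
    G: int = 1000
    T: int = 4
    q: int = 1
    rho: float = 0.1
    rmax2: float = 0.8
    n_groups: int = 2
    share_prob: float = 0.2
    effect_model: str = "freq"
    alpha_inv: tuple = (0.01, 0.05, 0.1, 0.5)
    ld_decay: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if not 0 < self.rmax2 <= 1:
            raise ValueError("rmax2 must lie in (0, 1]")
        if self.q > self.G:
            raise ValueError("q cannot exceed G")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    causal: list  # per-trait arrays of causal variant indices
    effects: np.ndarray  # (T, G) true sparse effect vectors
    groups: np.ndarray  # (T,) group label per trait
    var_genetic: np.ndarray  # (T,) realized Var(Xb)
    resid_var: np.ndarray  # (T,) residual variance tau^{-1}
    causal_pool: np.ndarray = field(default_factory=lambda: np.array([], int))

    def causal_indicator(self, G: int) -> np.ndarray:
        out = np.zeros((len(self.causal), G), dtype=bool)
        for t, idx in enumerate(self.causal):
            out[t, np.asarray(idx, int)] = True
        return out

    def sharing_pairs(self) -> dict:
        """True colocalization (shared causal variant) per trait pair."""
        t_count = len(self.causal)
        out = {}
        for t1 in range(t_count):
            for t2 in range(t1 + 1, t_count):
                shared = set(map(int, self.causal[t1])) & set(
                    map(int, self.causal[t2])
                )
                out[(t1, t2)] = len(shared) > 0
        return out


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    N: int,
    G: int,
    ld_decay: float = 0.9,
    maf_range: tuple = (0.05, 0.5),
    seed: int = 0,
    block_mean_len: int = 50,
) -> GenotypePanel:
    """Diploid dosages from 2N mosaic haplotypes with AR(1) within-block LD.

    Each haplotype is a first-order binary Markov chain: adjacent alleles
    within a block correlate at the block's strength (so adjacent dosage r^2
    is that strength squared, and correlation decays geometrically with
    distance); the chain restarts at geometrically distributed block
    boundaries, giving no between-block LD. ``ld_decay`` sets the maximum
    adjacent-allele correlation; each block draws its own strength between
    0.7 and 1 times that maximum, mimicking the heterogeneous LD of real
    loci (and populating the full range of pairwise r^2 the LD-confusion
    design samples from). Deterministic per seed.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=G)

    # block boundaries shared by all haplotypes (one LD structure per panel)
    new_block = np.zeros(G, dtype=bool)
    new_block[0] = True
    if block_mean_len >= 1:
        new_block |= rng.random(G) < 1.0 / block_mean_len

    rho_max = float(np.clip(ld_decay, 0.0, 0.999999))
    block_rho = np.empty(G)
    cur = 0.0
    for j in range(G):
        if new_block[j]:
            cur = rng.uniform(0.7 * rho_max, rho_max) if rho_max > 0 else 0.0
        block_rho[j] = cur

    h = 2 * N
    hap = np.empty((h, G))
    u = rng.random((h, G))
    hap[:, 0] = u[:, 0] < maf[0]
    for j in range(1, G):
        if new_block[j] or block_rho[j] == 0.0:
            hap[:, j] = u[:, j] < maf[j]
            continue
        # binary chain hitting marginal maf[j] and correlation block_rho[j]
        p, q, rho = maf[j - 1], maf[j], block_rho[j]
        p1 = np.clip(q + rho * np.sqrt(q * (1 - q) * (1 - p) / p), 0.0, 1.0)
        p0 = np.clip(q - rho * np.sqrt(q * (1 - q) * p / (1 - p)), 0.0, 1.0)
        prob = np.where(hap[:, j - 1] == 1.0, p1, p0)
        hap[:, j] = u[:, j] < prob
    dosage = hap[:N] + hap[N:]

    # a finite sample can leave a column constant; redraw those i.i.d.
    for j in np.flatnonzero(dosage.std(axis=0) == 0):
        while dosage[:, j].std() == 0:
            dosage[:, j] = rng.binomial(2, maf[j], size=N).astype(float)

    ids = [f"snp{j}" for j in range(G)]
    return GenotypePanel(
        genotypes=dosage,
        variant_ids=ids,
        chrom=np.array(["1"] * G),
        pos=np.arange(1, G + 1) * 1000,
    )


def _r2_matrix(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = x[:, idx]
    r = np.corrcoef(sub, rowvar=False)
    return np.atleast_2d(r) ** 2


def select_causal_sets(
    panel: GenotypePanel,
    q: int,
    n_groups: int,
    rmax2: float,
    seed: int = 0,
    max_tries: int = 2000,
) -> list[np.ndarray]:
    """Disjoint per-group causal sets with all pairwise r^2 <= rmax2.

    Rejection-sampled; raises :class:`InfeasibleConstraint` when the panel
    cannot satisfy the request within the try budget.
    """
    total = q * n_groups
    if total > panel.n_variants:
        raise InfeasibleConstraint(
            f"need {total} causal variants but only {panel.n_variants} available"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        idx = rng.choice(panel.n_variants, size=total, replace=False)
        if total > 1:
            r2 = _r2_matrix(panel.genotypes, idx)
            off = r2[np.triu_indices(total, k=1)]
            if np.any(off > rmax2):
                continue
        return [np.sort(idx[g * q : (g + 1) * q]) for g in range(n_groups)]
    raise InfeasibleConstraint(
        f"no causal configuration with pairwise r^2 <= {rmax2} "
        f"found in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# traits


def _draw_effects(x_causal, maf_c, model, alpha_inv, rng):
    q = x_causal.shape[1]
    if model == "freq":
        sd = 1.0 / np.sqrt(maf_c * (1.0 - maf_c))
        return rng.normal(0.0, sd)
    if model == "normal-mixture":
        var = rng.choice(alpha_inv, size=q)
        return rng.normal(0.0, np.sqrt(var))
    if model == "point-mass":
        # expected magnitude of a N(0, alpha^{-1}) draw: sqrt(2 alpha^{-1} / pi)
        var = rng.choice(alpha_inv, size=q)
        mag = np.sqrt(2.0 * var / np.pi)
        return mag * rng.choice([-1.0, 1.0], size=q)
    raise ValueError(f"unknown effect model {model!r}")


def simulate_traits(
    panel: GenotypePanel,
    causal_sets: list[np.ndarray],
    rho: float,
    T: int,
    effect_model: str = "freq",
    seed: int = 0,
    alpha_inv: tuple = (0.01, 0.05, 0.1, 0.5),
) -> tuple[TraitMatrix, SimulationTruth]:
    """Group-structured traits over given causal sets.

    Traits are shuffled then assigned to groups round-robin; every trait in a
    group shares the group's causal variants but draws its own effect sizes.
    For the frequency-scaled model the residual variance solves the rho
    identity exactly from the realized genetic variance; the normal-mixture
    and point-mass models use standardized genotypes with residual variance
    fixed at 1.
    """
    rng = np.random.default_rng(seed)
    n_groups = len(causal_sets)
    x = panel.genotypes
    maf = np.clip(x.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    if effect_model != "freq":
        x = (x - x.mean(axis=0)) / x.std(axis=0)

    assign = np.array([i % n_groups for i in range(T)])
    rng.shuffle(assign)

    n = panel.n_individuals
    values = np.empty((n, T))
    effects = np.zeros((T, panel.n_variants))
    causal, var_g, resid_var = [], np.zeros(T), np.zeros(T)
    for t in range(T):
        idx = np.asarray(causal_sets[assign[t]], int)
        causal.append(idx)
        if len(idx):
            b = _draw_effects(x[:, idx], maf[idx], effect_model, alpha_inv, rng)
            genetic = x[:, idx] @ b
            effects[t, idx] = b
        else:
            genetic = np.zeros(n)
        vg = float(np.var(genetic))
        var_g[t] = vg
        if effect_model == "freq":
            rv = vg * (1.0 - rho) / rho if vg > 0 else 1.0
        else:
            rv = 1.0
        resid_var[t] = rv
        values[:, t] = genetic + rng.normal(0.0, np.sqrt(rv), size=n)

    traits = TraitMatrix(values, [f"trait{t}" for t in range(T)])
    truth = SimulationTruth(
        causal=causal,
        effects=effects,
        groups=assign,
        var_genetic=var_g,
        resid_var=resid_var,
        causal_pool=np.sort(np.concatenate([np.asarray(c) for c in causal_sets])),
    )
    return traits, truth


def simulate_two_group(design: SimDesign, panel: GenotypePanel | None = None):
    """Main two-group design: genotypes, traits and truth from one seed."""
    if panel is None:
        panel = simulate_genotypes(
            design.N,
            design.G,
            ld_decay=design.ld_decay,
            maf_range=design.maf_range,
            seed=design.seed,
        )
    causal_sets = select_causal_sets(
        panel, design.q, design.n_groups, design.rmax2, seed=design.seed + 1
    )
    traits, truth = simulate_traits(
        panel,
        causal_sets,
        design.rho,
        design.T,
        effect_model=design.effect_model,
        seed=design.seed + 2,
        alpha_inv=design.alpha_inv,
    )
    return panel, traits, truth


def simulate_random_sharing(
    panel: GenotypePanel,
    T: int = 10,
    q: int = 10,
    share_prob: float = 0.2,
    rho: float = 0.1,
    seed: int = 0,
) -> tuple[TraitMatrix, SimulationTruth]:
    """Random-sharing design: q causal variants assigned to each trait
    independently with probability ``share_prob``.

    With the defaults each trait carries two causal variants on average and
    each variant is causal in two traits.
    """
    rng = np.random.default_rng(seed)
    pool = np.sort(rng.choice(panel.n_variants, size=q, replace=False))
    assign = rng.random((T, q)) < share_prob

    x = panel.genotypes
    maf = np.clip(x.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    n = panel.n_individuals
    values = np.empty((n, T))
    effects = np.zeros((T, panel.n_variants))
    causal, var_g, resid_var = [], np.zeros(T), np.zeros(T)
    for t in range(T):
        idx = pool[assign[t]]
        causal.append(idx)
        if len(idx):
            b = _draw_effects(x[:, idx], maf[idx], "freq", (), rng)
            genetic = x[:, idx] @ b
            effects[t, idx] = b
        else:
            genetic = np.zeros(n)
        vg = float(np.var(genetic))
        var_g[t] = vg
        rv = vg * (1.0 - rho) / rho if vg > 0 else 1.0
        resid_var[t] = rv
        values[:, t] = genetic + rng.normal(0.0, np.sqrt(rv), size=n)

    traits = TraitMatrix(values, [f"trait{t}" for t in range(T)])
    truth = SimulationTruth(
        causal=causal,
        effects=effects,
        groups=np.arange(T),
        var_genetic=var_g,
        resid_var=resid_var,
        causal_pool=pool,
    )
    return traits, truth


def simulate_ld_confusion(
    panel: GenotypePanel,
    r2_band: tuple,
    T: int = 4,
    rho: float = 0.1,
    seed: int = 0,
) -> tuple[TraitMatrix, SimulationTruth]:
    """Two one-causal groups whose causal variants sit at a controlled r^2.

    Used to measure how false-positive colocalization grows with the LD
    between truly distinct causal variants.
    """
    lo, hi = r2_band
    rng = np.random.default_rng(seed)
    r = np.corrcoef(panel.genotypes, rowvar=False) ** 2
    iu = np.triu_indices(panel.n_variants, k=1)
    mask = (r[iu] > lo) & (r[iu] < hi)
    cand = np.flatnonzero(mask)
    if len(cand) == 0:
        raise InfeasibleConstraint(f"no variant pair with r^2 in {r2_band}")
    pick = cand[rng.integers(len(cand))]
    i, j = iu[0][pick], iu[1][pick]
    traits, truth = simulate_traits(
        panel,
        [np.array([i]), np.array([j])],
        rho,
        T,
        effect_model="freq",
        seed=seed + 1,
    )
    return traits, truth


def simulate_expression_coloc(
    panel: GenotypePanel,
    n_causal: int,
    seed: int = 0,
) -> tuple[np.ndarray, SimulationTruth]:
    """Expression simulator: ``Y = sum_i b_i x_i + eps`` on standardized
    genotypes with ``b_i ~ N(0, 0.1/n)`` and ``eps ~ N(0, 0.9)``.

    Total expected heritability is 10% regardless of the number of causal
    variants (0.1/n per variant).
    """
    if n_causal < 1:
        raise ValueError("n_causal must be >= 1")
    rng = np.random.default_rng(seed)
    x = panel.genotypes
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    idx = np.sort(rng.choice(panel.n_variants, size=n_causal, replace=False))
    b = rng.normal(0.0, np.sqrt(0.1 / n_causal), size=n_causal)
    eps = rng.normal(0.0, np.sqrt(0.9), size=panel.n_individuals)
    genetic = x[:, idx] @ b
    y = genetic + eps
    effects = np.zeros((1, panel.n_variants))
    effects[0, idx] = b
    truth = SimulationTruth(
        causal=[idx],
        effects=effects,
        groups=np.zeros(1, int),
        var_genetic=np.array([float(np.var(genetic))]),
        resid_var=np.array([0.9]),
        causal_pool=idx,
    )
    return y, truth


# ---------------------------------------------------------------------------
# summary statistics


def marginal_summary_stats(
    panel: GenotypePanel, traits: TraitMatrix
) -> SummaryStatSet:
    """Per-variant simple linear regression (with intercept) of each trait.

    Returns slopes and standard errors; the z-scores are beta/se.
    """
    x = panel.genotypes
    y = traits.values
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = np.einsum("ng,ng->g", xc, xc)
    if np.any(sxx <= 0):
        raise ValueError("constant genotype column; cannot regress")
    sxy = xc.T @ yc  # (G, T)
    syy = np.einsum("nt,nt->t", yc, yc)
    beta = (sxy / sxx[:, None]).T  # (T, G)
    rss = syy[:, None] - beta * sxy.T  # (T, G)
    dof = max(n - 2, 1)
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(np.maximum(sigma2 / sxx[None, :], 1e-300))
    return SummaryStatSet(
        beta=beta,
        se=se,
        n=np.full(traits.n_traits, float(n)),
        variant_ids=list(panel.variant_ids),
        study_names=list(traits.trait_names),
        chrom=np.asarray(panel.chrom),
        pos=np.asarray(panel.pos),
        effect_allele=np.asarray(panel.alt),
        other_allele=np.asarray(panel.ref),
    )


# ---------------------------------------------------------------------------
# evaluation


def fdp_power(calls: np.ndarray, truth: np.ndarray) -> dict:
    """False-discovery proportion and power of boolean decisions.

    FDP = FP / (FP + TP), defined as 0 when nothing is called positive;
    power = TP / (TP + FN).
    """
    calls = np.asarray(calls, bool).ravel()
    truth = np.asarray(truth, bool).ravel()
    if calls.shape != truth.shape:
        raise LengthMismatch("calls and truth differ in length")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    fdp = fp / (fp + tp) if (fp + tp) > 0 else 0.0
    power = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return {"fdp": fdp, "power": power, "tp": tp, "fp": fp, "fn": fn}


def evaluate_coloc(
    pair_scores: dict,
    truth_pairs: dict,
    thresholds=(0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """FDP/power of pairwise colocalization scores across thresholds."""
    keys = sorted(truth_pairs)
    truth = np.array([truth_pairs[k] for k in keys], bool)
    scores = np.array([pair_scores[k] for k in keys], float)
    rows = []
    for th in thresholds:
        res = fdp_power(scores >= th, truth)
        res["threshold"] = th
        rows.append(res)
    return pd.DataFrame(rows)


def evaluate_pips(
    pips: np.ndarray,
    truth_indicator: np.ndarray,
    thresholds=(0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Variant-level FDP/power of inclusion probabilities across thresholds."""
    pips = np.asarray(pips, float)
    truth = np.asarray(truth_indicator, bool)
    if pips.shape != truth.shape:
        raise LengthMismatch("PIP and truth shapes differ")
    rows = []
    for th in thresholds:
        res = fdp_power(pips >= th, truth)
        res["threshold"] = th
        rows.append(res)
    return pd.DataFrame(rows)


def evaluate_credible_sets(
    post,
    truth: SimulationTruth,
    threshold: float = 0.5,
    level: float = 0.95,
) -> dict:
    """Coverage and size of credible sets of active components.

    A set counts as covered when it contains at least one variant that is
    truly causal in some trait the component is active in.
    """
    from .report import credible_set

    n_sets, covered, sizes = 0, 0, []
    causal_union = {int(i) for idx in truth.causal for i in idx}
    for k in range(post.K):
        if not np.any(post.s_prob[:, k] >= threshold):
            continue
        cs = credible_set(post, k, level)
        n_sets += 1
        sizes.append(len(cs))
        if any(int(g) in causal_union for g in cs):
            covered += 1
    return {
        "n_sets": n_sets,
        "coverage": covered / n_sets if n_sets else float("nan"),
        "median_size": float(np.median(sizes)) if sizes else float("nan"),
    }
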