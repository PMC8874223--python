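"""Fine-mapping and colocalization summaries of a fitted posterior.

Components are single-causal-variant effects shared across traits. A trait
"uses" a component when its activity probability p_active passes a
threshold (0.5 throughout, matching the convention used for calling
components active). Colocalization between two traits is then a statement
about shared active components, for which two definitions are reported:

* any-component — some component is active in both traits with joint
  probability above the threshold;
* top-component — the two traits agree on the component that carries their
  single strongest credible-set variant (largest |p_active * effect / sd|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DegenerateSD, NoActiveComponent, VariationalPosterior


def credible_set(
    post: VariationalPosterior, k: int, level: float = 0.95
) -> np.ndarray:
    """Smallest variant set whose phi mass reaches ``level`` for component k.

    Variants are returned in descending order of mass; ties broken by
    variant order.
    """
    phi = post.phi[k]
    order = np.argsort(-phi, kind="stable")
    csum = np.cumsum(phi[order])
    cut = int(np.searchsorted(csum, level - 1e-12)) + 1
    return order[:cut]


def credible_set_purity(post: VariationalPosterior, k: int, ld, level: float = 0.95) -> float:
    """Minimum pairwise |r| among a component's credible-set variants.

    Low purity flags a set whose variants are not mutually linked and is an
    optional filter (off by default) on reported components.
    """
    cs = credible_set(post, k, level)
    if len(cs) < 2:
        return 1.0
    sub = np.abs(ld.r[np.ix_(cs, cs)])
    return float(sub[np.triu_indices(len(cs), k=1)].min())


def pip(
    post: VariationalPosterior,
    t: int,
    active_only: bool = False,
    threshold: float = 0.5,
) -> np.ndarray:
    """Posterior inclusion probability per variant for trait t.

    ``PIP_g = 1 - prod_k (1 - s_prob[t,k] * phi[k,g])`` — the probability
    that at least one component places its causal variant at g and is active
    in t. With ``active_only`` the product runs over active components only.
    """
    ks = np.arange(post.K)
    if active_only:
        ks = ks[post.s_prob[t] >= threshold]
    inc = post.s_prob[t, ks, None] * post.phi[ks, :]
    return 1.0 - np.prod(1.0 - inc, axis=0) if len(ks) else np.zeros(post.G)


def p_coloc(
    post: VariationalPosterior, t1: int, t2: int
) -> tuple[np.ndarray, float]:
    """Per-component probability that t1 and t2 are both active, and its max.

    Under the mean-field posterior the joint activity probability factorizes
    into the product of the two marginal activity probabilities.
    """
    per_comp = post.s_prob[t1] * post.s_prob[t2]
    return per_comp, float(per_comp.max()) if post.K else 0.0


def variant_weight(post: VariationalPosterior, t: int, k: int, g: int) -> float:
    """Signed variant score ``p_active * effect / sd(effect)``.

    Ranks credible-set variants by how confidently non-zero their effect is;
    comparisons use the absolute value.
    """
    sd = np.sqrt(post.w_var[t, k, g])
    if not sd > 0:
        raise DegenerateSD(f"effect sd at (t={t}, k={k}, g={g}) is not positive")
    return float(post.s_prob[t, k] * post.w_mean[t, k, g] / sd)


def top_component(
    post: VariationalPosterior,
    t: int,
    threshold: float = 0.5,
    level: float = 0.95,
) -> int:
    """Component holding trait t's maximum-|weight| credible-set variant.

    Only components active in t are candidates; ties go to the lower index.
    """
    active = np.flatnonzero(post.s_prob[t] >= threshold)
    if len(active) == 0:
        raise NoActiveComponent(f"trait {t} has no active component")
    best_k, best_w = -1, -1.0
    for k in active:
        cs = credible_set(post, k, level)
        w = max(abs(variant_weight(post, t, k, g)) for g in cs)
        if w > best_w:
            best_k, best_w = int(k), w
    return best_k


@dataclass
class ColocCall:
    """Colocalization decision for one trait pair."""

    t1: int
    t2: int
    per_component: np.ndarray
    any_component: bool
    top_component: bool
    threshold: float


def coloc_calls(
    post: VariationalPosterior,
    t1: int,
    t2: int,
    threshold: float = 0.5,
    rule: str = "product",
) -> ColocCall:
    """Both colocalization definitions for a trait pair.

    ``rule='product'`` scores joint activity as the mean-field product;
    ``rule='min'`` instead requires each trait's marginal activity to pass
    the threshold separately.
    """
    if rule == "product":
        per_comp, _ = p_coloc(post, t1, t2)
    elif rule == "min":
        per_comp = np.minimum(post.s_prob[t1], post.s_prob[t2])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    any_call = bool(np.any(per_comp >= threshold))
    try:
        top_call = top_component(post, t1, threshold) == top_component(
            post, t2, threshold
        )
    except NoActiveComponent:
        top_call = False
    return ColocCall(
        t1=t1,
        t2=t2,
        per_component=per_comp,
        any_component=any_call,
        top_component=top_call,
        threshold=threshold,
    )


def sharing_summary(
    post: VariationalPosterior, threshold: float = 0.5
) -> np.ndarray:
    """Number of traits sharing each component (p_active >= threshold)."""
    return (post.s_prob >= threshold).sum(axis=0)


@dataclass
class ComponentReport:
    """Per-component fine-mapping summary."""

    component_id: int
    p_active: np.ndarray  # (T,)
    credible_set_variants: list[str]
    credible_set_mass: np.ndarray
    effect_mean: np.ndarray  # (T, |cs|)
    effect_sd: np.ndarray  # (T, |cs|)
    top_variant_weight: np.ndarray  # (T,) max |weight| in the credible set


def component_reports(
    post: VariationalPosterior,
    variant_ids: list[str],
    level: float = 0.95,
) -> list[ComponentReport]:
    """Reports for all components, ordered by descending max p_active
    (ties by component index)."""
    order = sorted(
        range(post.K), key=lambda k: (-float(post.s_prob[:, k].max()), k)
    )
    out = []
    for k in order:
        cs = credible_set(post, k, level)
        weights = post.s_prob[:, k, None] * post.w_mean[:, k, cs] / np.sqrt(
            post.w_var[:, k, cs]
        )
        out.append(
            ComponentReport(
                component_id=k,
                p_active=post.s_prob[:, k].copy(),
                credible_set_variants=[variant_ids[g] for g in cs],
                credible_set_mass=post.phi[k, cs].copy(),
                effect_mean=post.w_mean[:, k, cs].copy(),
                effect_sd=np.sqrt(post.w_var[:, k, cs]),
                top_variant_weight=np.abs(weights).max(axis=1),
            )
        )
    return out


def components_table(
    post: VariationalPosterior,
    variant_ids: list[str],
    trait_names: list[str],
    threshold: float = 0.5,
    level: float = 0.95,
) -> pd.DataFrame:
    """Long-form component/trait table (the components.tsv payload)."""
    rows = []
    for rep in component_reports(post, variant_ids, level):
        k = rep.component_id
        for t, name in enumerate(trait_names):
            j = int(np.argmax(np.abs(rep.effect_mean[t] / rep.effect_sd[t])))
            rows.append(
                {
                    "component": k,
                    "trait": name,
                    "p_active": rep.p_active[t],
                    "cs_size": len(rep.credible_set_variants),
                    "top_variant": rep.credible_set_variants[j],
                    "weight": rep.p_active[t]
                    * rep.effect_mean[t, j]
                    / rep.effect_sd[t, j],
                }
            )
    return pd.DataFrame(rows)


def coloc_table(
    post: VariationalPosterior,
    trait_names: list[str],
    threshold: float = 0.5,
    rule: str = "product",
) -> pd.DataFrame:
    """All-pairs colocalization table (the coloc_pairs.tsv payload)."""
    rows = []
    t_count = post.T
    for t1 in range(t_count):
        for t2 in range(t1 + 1, t_count):
            call = coloc_calls(post, t1, t2, threshold, rule)
            k = int(np.argmax(call.per_component))
            rows.append(
                {
                    "t1": trait_names[t1],
                    "t2": trait_names[t2],
                    "k": k,
                    "p": float(call.per_component[k]),
                    "any_call": call.any_component,
                    "top_call": call.top_component,
                }
            )
    return pd.DataFrame(rows)
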