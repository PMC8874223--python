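# cafeh

Colocalization and fine-mapping under allelic heterogeneity: a multi-trait
Bayesian model that jointly fine-maps causal variants and tests whether
studies, tissues or traits share them — in the common situation where a locus
harbors several independent causal variants and linkage disequilibrium (LD)
makes marginal association signals overlap.

It is aimed at statistical geneticists integrating eQTL and GWAS data: given
either individual-level genotypes and traits (CAFEH-G) or marginal summary
statistics plus an LD matrix (CAFEH-S), it reports per-component credible
sets, per-variant posterior inclusion probabilities (PIPs), and
colocalization calls between every pair of traits.

## Model

For trait $t$, $y_t = X b_t + \varepsilon$, $\varepsilon \sim N(0,
\tau_t^{-1} I)$, with the effect vector decomposed into $K$
single-causal-variant components shared across traits:

$$b_t = \sum_{k=1}^{K} \phi_k\, s_{tk}\, w_{tk}$$

* $\phi_k \sim \mathrm{Categorical}(\pi_0)$ — a one-hot vector selecting
  component $k$'s causal variant, **shared by all traits**;
* $s_{tk} \sim \mathrm{Bernoulli}(p_{0k})$ — whether the component is active
  in trait $t$ (the spike);
* $w_{tk} \sim N(0, \alpha_{tk}^{-1})$ — the effect size (the slab), with its
  own precision $\alpha_{tk} \sim \mathrm{Gamma}(a_0, b_0)$ per trait and
  component, so effect magnitudes are free to differ across traits;
* $\tau_t \sim \mathrm{Gamma}(c_0, d_0)$.

Two traits colocalize in component $k$ when $s_{t_1 k} = s_{t_2 k} = 1$; the
posterior probability of joint activity is the colocalization statistic.

The posterior is approximated by coordinate-ascent variational inference over
the mean-field family $\prod_{t,k} q(w_{tk}\mid\phi_k,s_{tk})\,q(s_{tk})\,
q(\alpha_{tk}) \prod_k q(\phi_k) \prod_t q(\tau_t)$; every update is closed
form and the ELBO is non-decreasing by construction (enforced at run time).

With only summary statistics available, the same updates run through the RSS
likelihood: with per-variant scales $s_i^2 = \hat\beta_{ti}^2/N +
\hat\sigma_{ti}^2$ and $S = \mathrm{diag}(s_i)$,

$$\hat\beta_t \sim N(S R S^{-1} b_t,\; S R S),$$

which substitutes $S^{-1} R S^{-1}$ for $X'X$ and $S^{-2}\hat\beta_t$ for
$X'y_t$ in the sufficient statistics.

## Worked example

Simulate a locus with two groups of traits (two traits per group, one causal
variant per group, 20% variance explained), fit, and report:

```python
from cafeh.simulate import SimDesign, simulate_two_group
from cafeh.infer import FitConfig, fit_g
from cafeh.report import components_table, coloc_table

design = SimDesign(N=500, G=200, T=4, q=1, rho=0.2, seed=3)
panel, traits, truth = simulate_two_group(design)
post = fit_g(panel, traits, config=FitConfig(K=10, seed=0))
comp = components_table(post, panel.variant_ids, traits.trait_names)
print(comp[comp.p_active >= 0.5])
print(coloc_table(post, traits.trait_names))
```

Output (true causal variants are snp188 for traits 0/1 and snp144 for
traits 2/3):

```
 component  trait  p_active  cs_size top_variant     weight
         0 trait0       1.0        1      snp188 -12.408293
         0 trait1       1.0        1      snp188 -10.882726
         1 trait2       1.0        1      snp144 -10.266832
         1 trait3       1.0        1      snp144  11.395818
    t1     t2  k   p  any_call  top_call
trait0 trait1  0 1.0      True      True
trait0 trait2  0 0.0     False     False
...
trait2 trait3  1 1.0      True      True
```

Component 0 is a single-variant 95% credible set at the true causal variant
of the first group, active (p_active = 1) in exactly that group's traits;
likewise component 1 for the second group. The `weight` column is
p_active × effect / sd(effect), the score used to pick each trait's top
component. The pair table shows both colocalization definitions — sharing
any active component (`any_call`) and sharing the top component
(`top_call`) — correctly linking traits within groups and separating traits
across groups.

The same analysis runs from the shell:

```bash
cafeh simulate --design main --params params.yaml --seed 3 --out sim/
cafeh fit-g --genotypes sim/genotypes.tsv --traits sim/traits.tsv --out fit/
cafeh fit-s --sumstats sim/summary_stats.tsv --ld sim/ld.tsv \
            --ld-variants sim/ld_variants.txt --out fit_s/
cafeh evaluate --posterior fit/posterior.json --truth sim/truth.json --out eval.json
```

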