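# hostislands

**Plant families as islands: who uses which plants, and why?**

Across insects, pathogens and humans, some plant families are used by
almost every kind of consumer while others are barely touched. Treating
each plant family as an island — its *apparency* (species count, genus
count, or distribution area) as the island's area, and its phylogenetic
distance to the most apparent families as the island's isolation — turns
this into a question island biogeography can answer. `hostislands`
implements that analysis for presence–absence utilization data at the
family level: which families a consumer group or human use category does
and does not use, over a dated family-level phylogeny.

The package is organised as an analysis project: the numbered drivers in
`analysis/` run the study on synthetic data and write tables under
`results/`, while every computation lives in the importable package under
`src/hostislands` (modules `phylo`, `tables`, `glm`, `signal_d`,
`regressions`, `synthetic_data`, `pipeline`, `cli`).

## The models

**Utilization GLM.** For a group with presence indicator $y_f$ over
families with apparency $\mathrm{PA}_f$, a binomial GLM with logit link,

$$\operatorname{logit}(\mathrm{UP}) = a\,\mathrm{PA} + b,$$

is fitted by IRLS. The slope is tested with $G = a^2/\mathrm{VAR}(a)$
against $\chi^2_1$, and each fit yields the apparency thresholds
$\mathrm{PA}_{0.5} = -b/a$ and $\mathrm{PA}_{0.95} = (\ln 19 - b)/a$ and
the zero-apparency probability $\mathrm{UP}_0 = e^b/(1+e^b)$.

**Phylogenetic signal.** Each group's binary host profile gets the
Fritz–Purvis $D$ statistic: the sum of sister-clade differences
$\Sigma d$, standardized between a tip-shuffling null ($D \approx 1$,
no signal) and a Brownian-threshold null ($D \approx 0$, clumping), with
lower-tail `p_random` and upper-tail `p_brownian` from 1,000 draws each.

**Island summaries and regressions.** Per family: the utilizer ratio UR
(share of groups using it) and PD_min (cophenetic distance in Myr to the
nearest top-decile "mainland" family). Per group: host breadth HF. Plain
OLS then relates UR to log₁₀(apparency) and to PD_min across families, and
the fitted thresholds, UP₀ and $D$ to HF across groups, with a randomized
Bernoulli baseline showing what the same fits look like when presence is
independent of apparency.

## Worked example

Simulate a synthetic study and run the full pipeline:

```
hostislands simulate --families 420 --groups 12 --seed 42 --out results/synthetic_study
python analysis/02_fit_utilization_glms.py
python analysis/03_phylogenetic_signal.py
python analysis/04_island_regressions.py
```

(`analysis/01_simulate_study.py` is the script form of the first command.)
The generated study contains three kinds of groups — presence driven
logistically by apparency, presence clumped on the tree, and i.i.d. random
controls. The GLM stage recovers exactly the apparency-driven groups:

```
  groups with a positive, significant apparency slope (p_G < 0.05):
  ['logistic_01', 'logistic_02', 'logistic_03', 'logistic_04']
    logistic_02    a=+2.08e-03  p_G=3.36e-13 (significant);  PA_0.5=1302  UP_0=0.062
    clumped_03     a=+1.48e-04  p_G=0.121 (not significant);  PA_0.5=7613  UP_0=0.245
    random_03      a=-7.66e-06  p_G=0.919 (not significant);  PA_0.5=-1.412e+05  UP_0=0.253
```

Here `a` is the fitted slope per species, `PA_0.5` the species count at
which utilization probability reaches one half, and `UP_0` the probability
for a vanishingly small family. The signal stage separates the mechanisms
on the tree:

```
  clumped   mean D = +0.123  (p_random range 0.000999–0.000999)
  logistic  mean D = +1.033  (p_random range 0.637–0.781)
  random    mean D = +0.949  (p_random range 0.000999–0.901)
  clumped groups rejected by the permutation null (p_random < 0.05): 4/4
```

Clumped groups sit near the Brownian expectation $D = 0$ and are all
rejected against the random null; logistic and random groups sit near
$D = 1$. (One random control happens to land in the far lower tail of its
permutation p-value — with 24 p-values computed, occasional small ones are
chance, and its $D = 0.72$ stays far from Brownian.) The regression stage
then contrasts real fits with the randomized baseline:

```
  UR_vs_log10_apparency: slope=+0.06887 intercept=0.07169 r2=0.17 p=2.98e-18 (n=420)
  p=0.1: mean fitted UP_0 = 0.101 (mean a = -7.63e-05, n_used=200)
  real logistic-mechanism fits: UP_0 range 0.062–0.245 — below the matched
  baseline prevalence, as expected when apparency drives presence
```

The same pipeline runs on real inputs — a Newick family tree with branch
lengths in Myr, a family apparency CSV and a families × groups 0/1 CSV —
via `hostislands run --tree ... --families ... --matrix ... --out ...`.

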