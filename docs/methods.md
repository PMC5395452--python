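# Methods

`hostislands` treats plant families as islands: each family's "area" is its
apparency (species count, genus count, or distribution range), each
consumer or use category ("utilization group") leaves a binary
presence–absence footprint across families, and island-biogeography style
models ask how that footprint depends on apparency and on position in the
family-level phylogeny. This note records the models, the defaults and why,
the numerical choices, and what the synthetic data does and does not show.

## The utilization GLM

For one utilization group with presence indicator $y_f \in \{0,1\}$ over
families $f$ with apparency $\mathrm{PA}_f$, the model is a binomial GLM
with logit link:

$$\operatorname{logit}(\mathrm{UP}_f) = a\,\mathrm{PA}_f + b,$$

where UP is the probability the family is utilized. The predictor enters
untransformed (linear PA in the logit); a log-apparency variant is available
to callers by transforming the input, but the linear form is the default
because it is the form the derived thresholds below are defined on.

Fitting is by iteratively reweighted least squares (Newton steps on the
two-parameter score, with step halving so the deviance never increases),
started at $a=0$, $b=\operatorname{logit}(\bar y)$ and declared converged
when the deviance changes by less than $10^{-8}$. Parameter variances come
from the inverse information at the optimum; for the canonical logit link
the observed and expected information coincide, so the distinction carries
no content here.

Complete separation has no finite MLE. A fit is flagged `separated` when
the standardized slope exceeds 50 in magnitude ($|a|\cdot\mathrm{sd(PA)} >
50$) or the deviance collapses to zero on a non-degenerate response.
Separated fits refuse to produce tests, predictions or thresholds — the
flag exists precisely so diverging estimates cannot leak into cross-group
regressions.

Derived quantities, defined only for converged fits with $a \neq 0$:

* $\mathrm{PA}_{0.5} = -b/a$ — apparency at 50% utilization probability;
* $\mathrm{PA}_{0.95} = (\ln 19 - b)/a$ — apparency at 95%;
* $\mathrm{UP}_0 = e^b/(1+e^b)$ — the fitted probability for a vanishingly
  unapparent family.

The slope test is the Wald form $G = a^2/\mathrm{VAR}(a)$ against
$\chi^2_1$, implemented exactly as that ratio rather than as a likelihood
ratio. The Wald form is what the downstream tables consume; calibration is
discussed under Limitations.

## Phylogenetic signal: the D statistic

For a binary trait on a rooted, dated, binary tree, ancestral values are
estimated post-order by Felsenstein-weighted averages: at each internal
node, $v = (v_L/b_L' + v_R/b_R')/(1/b_L' + 1/b_R')$, with the standard
contrasts branch-length adjustment $b' = b + b_L'b_R'/(b_L'+b_R')$. The raw
signal quantity is

$$\Sigma d = \sum_{\text{internal nodes}} |v_L - v_R|,$$

small when presences clump on the tree. It is standardized between two
null expectations computed with the *identical* estimator:

* **random** — the observed trait shuffled uniformly among tips;
* **Brownian** — a Brownian trait (rate 1; the threshold rank is
  scale-invariant, so the rate is immaterial) simulated on the tree and
  thresholded so that exactly the observed number of tips are 1.

$$D = \frac{\Sigma d_{\mathrm{obs}} - \overline{\Sigma d}_{\mathrm{Brownian}}}
         {\overline{\Sigma d}_{\mathrm{random}} - \overline{\Sigma d}_{\mathrm{Brownian}}}$$

so $D \approx 1$ for phylogenetically random traits, $D \approx 0$ for
Brownian-level clumping, $D > 1$ overdispersion, $D < 0$ extreme
conservatism. `p_random` is the lower tail of the permuted $\Sigma d$
(clumping means a small $\Sigma d$); `p_brownian` is the upper tail of the
Brownian $\Sigma d$; both carry the $(\text{count}+1)/(n_{\mathrm{perm}}+1)$
small-sample correction so no reported p is exactly zero. The default is
1,000 draws per null; shuffles and Brownian simulations consume independent
sub-streams spawned from the caller's seed.

Because observed and both null $\Sigma d$ use the same nodal estimator, the
standardization is internally consistent regardless of estimator details.
That internal-consistency contract — random traits center at 1, Brownian
threshold traits at 0 (checked to ±0.1 over 100 traits on a 200-tip tree) —
is what the package promises; numerical equality with any particular legacy
implementation of the statistic is not, since estimator conventions differ
between implementations.

Implementation note: the tree is flattened once into arrays
(`phylo.TreeIndex`); the Felsenstein weights depend only on branch lengths,
never on the trait, so whole matrices of permuted or simulated traits are
pushed through a single post-order sweep. This is what makes 1,000-draw
nulls for dozens of groups cheap.

### Trees, polytomies, degenerate branches

Input trees are taken as rooted as read; no re-rooting is attempted.
Polytomies are resolved by seeded random pairing with inserted zero-length
branches before any nodal computation — patristic distances are provably
unchanged, and the seed is recorded so runs reproduce. Zero-length branches
are replaced by $\varepsilon = 10^{-9}$ Myr *inside weight computations
only* (a zero-length cherry with values 0 and 1 therefore averages to 0.5);
distances are never touched by the guard. Tips present in the tree but
absent from the data tables are pruned with a logged warning; data families
absent from the tree are a hard error.

## Island summaries

* **Utilizer ratio** UR(f) = share of retained groups using family f. The
  denominator is the number of groups actually in the matrix after
  filtering, never a hard-coded constant.
* **Host-breadth filter**: groups using fewer than 10 families are dropped
  at load time (too few presences destabilize both the GLM and D).
* **Mainland**: families ranked descending by the chosen apparency measure;
  the top $\lceil 0.10 N \rceil$ plus every family tied with the boundary
  value. Including boundary ties makes the selection deterministic and
  order-independent (and is the only rule under which a "top decile" of 420
  can legitimately exceed 42).
* **PD\_min**: a family's minimum cophenetic (patristic) distance in Myr to
  the mainland set. A mainland family's own zero self-distance is included
  by default (the definition is a plain minimum over the set); an
  `exclude_self` switch gives the nearest-other-member variant.
* **Apparency fills**: families with unresolved taxonomy get 0.5 species
  and 0.5 genera; families without a mapped range get a 1,000 km²
  placeholder area. Every fill is counted in the load report.

## Cross-family and cross-group regressions

All relationships are ordinary least squares with $r^2$ and a two-sided
slope t-test ($df = n-2$); p-values are reported unadjusted, and no
phylogenetic correction (PGLS) is applied — these are descriptive
relationships. Cross-family: UR on $\log_{10}$(apparency) and UR on
PD\_min. Cross-group: $\log_{10}(\mathrm{PA}_{0.5})$, $\log_{10}
(\mathrm{PA}_{0.95})$ and $\mathrm{UP}_0$ on host breadth HF; D on
$\log_{10}$(HF); and $\mathrm{UP}_0$ on $\log_{10}(D)$. Groups with
separated, non-converged or non-positive-slope fits are excluded from every
cross-group regression, and log-scale regressions additionally drop groups
whose threshold (or D) is non-positive; every exclusion is recorded with a
reason, so no row disappears silently.

The **randomized baseline** refits the same GLM to presence vectors drawn
i.i.d. Bernoulli($p$) for $p \in \{0.1, 0.3, 0.5, 0.7, 0.9\}$, 1,000
replicates per level (the replicate count is per level, not total — the
flag `n_reps` overrides). Because the truth has zero slope, fitted
$\mathrm{UP}_0$ tracks $p$; real apparency-driven fits show
$\mathrm{UP}_0$ well below their raw prevalence, and that contrast is the
point of the baseline.

## Synthetic data

The generator produces the structure the analysis assumes, with defaults
chosen once:

* **Tree**: pure-birth (Yule), ultrametric, rescaled to a 150 Myr crown
  depth — a crown-angiosperm-like time scale.
* **Apparency**: species counts $\sim$ round(LogNormal($\mu=4.6$,
  $\sigma=1.8$)), i.e. median ≈ 100 species with tails into the tens of
  thousands, matching the shape of real family-size distributions; genus
  counts at a tenth of species counts; areas LogNormal(16.5, 1.5) km²
  floored at 1,000.
* **Groups**: `logistic` (Bernoulli at logistic($a\,\mathrm{PA}+b$);
  default $a = 0.0018$, $b = -2.15$, a realistic weak-slope regime),
  `clumped` (Brownian threshold at fixed prevalence), `random` (i.i.d.
  control).

Apparency and the tree are generated independently: any apparency–phylogeny
correlation in real data is an empirical property, not an assumption. A
coupling knob (`apparency_heritability`) exists for sensitivity analyses
and defaults off.

What the synthetic data does *not* emulate: spatial structure in
distribution areas, correlated group footprints (real consumer guilds
overlap), sampling effort biases in presence records, and the
apparency–phylogeny correlation just mentioned. Passing tests therefore
demonstrate that the estimators recover the generating mechanisms under the
stated model, not that real utilization data satisfies that model.

## Numerical choices and degenerate inputs

* IRLS: start $(0, \operatorname{logit}\bar y)$ with $\bar y$ clipped to
  $[10^{-6}, 1-10^{-6}]$; deviance tolerance $10^{-8}$; at most 200
  iterations; step halving guarantees monotone deviance.
* Constant responses (all 0 / all 1) are a hard error, not a fit.
* `ols`: zero-variance x is an error (no slope exists); zero-variance y
  returns the flat fit with a `degenerate` flag.
* D: the standardization denominator vanishing (random and Brownian null
  means equal, e.g. on a star-like tree) is an error, not a zero division.
* Mainland ties at the boundary are included; `select_mainland` is
  deterministic for any input ordering.
* All Monte Carlo consumers spawn independent sub-streams from a single
  seed (`numpy.random.SeedSequence`), so the pipeline is byte-reproducible
  end to end for a fixed seed and the shuffle/Brownian streams cannot
  alias.

## Problem sizes used in the validation suite

The shipped calibration suite runs at the study's natural scale where that
is cheap (GLM fits at $n = 420$; 1,000-replicate baselines and null
calibrations) and at 200 tips / 500 permutations / 100 traits for the D
calibration, which the flattened-tree implementation completes in seconds.
Hand-verifiable oracles use 3- and 4-tip trees.

## Limitations

* The Wald $G$ statistic is conservative when the predictor is extremely
  heavy-tailed (a handful of mega-families dominating the information):
  null rejection drops to ~2–3% at nominal 5% under the generator's raw
  species counts, while well-behaved designs calibrate at 5–6%. This is a
  property of Wald tests under extreme leverage, shared with any software
  reporting $a^2/\mathrm{VAR}(a)$; slope p-values on raw heavy-tailed
  apparency should be read as conservative.
* D is reported with its internal-consistency calibration, not as
  numerically interchangeable with other implementations (estimator and
  polytomy-handling conventions differ between codebases).
* Presence–absence at the family level carries no abundance information;
  the models quantify incidence, not intensity, of utilization.
* With ~10–50 groups, the cross-group regressions have few points; their
  p-values are exact under OLS assumptions but the leverage of single
  groups is high, and exclusion logs should be read alongside the
  coefficients.
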