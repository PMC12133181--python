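# Methods

## Meiosis model

Four fertile parent karyotypes are modelled.  Euploid parents err at the
primary nondisjunction rate µ and the chromosome-loss rate λ, both per
meiosis:

* XX female ova: X with 1 − µ_f − λ_f, XX with µ_f/2, nullo with
  µ_f/2 + λ_f;
* XY male sperm: X and Y with (1 − µ_m − λ_m)/2 each, XY with µ_m/2,
  nullo with µ_m/2 + λ_m.

Loss is modelled in the transmitting parent (a normal single-chromosome
gamete becomes nullo); a post-zygotic variant (loss of one
parent-derived chromosome after fertilisation) is available behind the
`loss_stage="zygotic"` switch and agrees with the default to first order
in the rates.  Aneuploid parents segregate regularly
(XXY → X : XY = 1 : 1, the free Y assorting with either X at random;
XYY → XY : Y = 1 : 1) except for secondary nondisjunction at rate µ₂
(XXY → XX and Y gametes; XYY → X and YY gametes).  Deviations from 1:1
transmission in XXY females are deliberately not modelled: the data this
package was built around recovered XX and XXY daughters equally.

Zygotes outside the supported ten-karyotype set (e.g. XXXY) require
simultaneous errors in both parents (probability of order µ_f µ_m) and
are routed to a zero-viability "complex" class rather than raising,
because any fit with both µ's free must evaluate such configurations.

Viability defaults: XX, XY, XXY, XYY and X∅ fully viable (X∅ males are
sterile); XXX zero; YY, Y∅ and no-X zygotes embryonic-lethal and not
overridable.  Simulation and equilibrium contexts additionally zero
XXYY and X∅ ("complex karyotypes contribute nothing"); XXYY fertility is
not modelled at all, which is the main reason the simulator's neutral
scenario is only approximately a martingale beyond one generation (see
Limitations).

## Rate inference

Offspring class counts from one or more cross designs are treated as
independent multinomials whose class probabilities follow from the
meiosis model, the design's marker labels (body colour is wild-type iff
any chromosome carries `y+`; eyes are Bar iff any carries `Bar`) and the
viability scheme.  The likelihood is maximised by bounded quasi-Newton
iteration on log10 rates from three fixed starts (10⁻⁴, 10⁻³, 10⁻²),
because boundary (zero-count) cases are common; estimates at the lower
bound are reported as zero and flagged.  Standard errors come from the
observed information (central-difference Hessian on the natural scale);
a profile-likelihood alternative was considered and not implemented, as
Wald intervals are what the reference analysis reports.  Nested models
for likelihood-ratio tests are expressed as equality constraints
(`{"mu_m": "mu_f"}`).

The upper confidence limit for secondary nondisjunction applies the
one-sided Clopper–Pearson bound to the proportion of detectable
exceptional offspring and doubles it (Cooper's correction: the
complementary meiotic products are inviable, so exceptional classes are
recovered at half the event rate).  A two-sided-α/2 variant is a flag.

XYY viability selection is estimated as s = (1 − 2f)/(1 − f) from the
pooled frequency f of XYY among sons, with a nonparametric bootstrap
over rearing blocks for the interval — a deliberate substitution for the
mixed-model Wald interval of the reference analysis, chosen to keep the
estimator self-contained; point estimates pool within block with
weights proportional to block totals.

## Forward simulation

Populations evolve in non-overlapping generations.  Each offspring draws
a fertile mother and father uniformly at random (with replacement), a
zygote from the meiosis model, and survives with its viability; draws
repeat until the census (default 287, the mean adult count of the
experimental populations; founders default to 60 XXY females + 60 XY
males) is filled.  Conditional on the parent counts this is exactly a
multinomial over surviving offspring classes, which is how the batched
simulator draws whole generations at once; the per-replicate API and the
batch API are distributionally identical.  Sex ratio is emergent.  The
frequency-change statistic is the maximum-likelihood logistic slope of
(XXY, XX) female counts on generation (founders excluded), computed by a
vectorised Newton solver and cross-checked against a GLM fit in the test
suite; complete separation returns signed infinity.  Simulation p-values
report the fraction of replicate populations whose slope is at least as
negative as the observed (pooled) slope; extinct replicates are excluded
and counted.

## Standing frequency by ABC

A sampled female is XXY with probability f.  In the test cross she is
detected iff at least one of her k tested sons is fertile
(probability 1 − 0.5^k); k is resampled per family from the empirical
list.  PCR detection is perfect.  Because the k values are i.i.d. draws
from the empirical distribution, the detected count given n XXY families
is exactly Binomial(n, E[1 − 0.5^k]), and the sampler uses this marginal
form.  The posterior is exact-match rejection: f ~ Uniform(0, 0.1) is
retained iff the simulated detection counts equal the observed pair,
until 50 000 draws are kept.  No tolerance kernel is used.
Contamination by non-virgin females and secondary nondisjunction in
tested families are ignored, as in the detection model this emulates.

## Mutation–selection balance

The deterministic recursion tracks XX/XXY among females and XY/XYY among
males under random mating.  Mothers are weighted by frequency times
fecundity — w_XXY enters as a total-fitness multiplier on XXY mothers,
not as viability, since XXY viability was measured as normal (a
documented modelling choice); XYY males sire normally but their
offspring survive with viability w_XYY; XXX, XXYY, YY, Y∅ and complex
products contribute nothing, and X∅ males are excluded from the
reproductive pool and from the male frequency denominator.  Equilibrium
is found by fixed-point iteration to 10⁻¹² (the map contracts at rate
≈ w_XXY (1 + w_XYY)/2 ≈ 0.9, so a few hundred iterations suffice).  In
the weak-mutation, selection-dominated limit the equilibrium satisfies
f\* ≅ µ_eff / s_eff with µ_eff = µ_f/2 + µ_m and
s_eff = 1 − w_XXY (1 + w_XYY)/2 — the classical q\* ≅ µ/s.

The inverse solver bisects w_XXY on [0, 2] (the equilibrium XXY
frequency is monotone increasing there, verified at the bracket ends)
until the equilibrium matches the observed standing frequency, and
reports the companion f_XYY.  Credible intervals propagate paired draws
from the ABC posterior for f_XXY and a posterior for w_XYY (when only a
confidence interval for s_XYY is available, a normal on the s scale with
the CI-implied spread, truncated to w > 0, is the documented
approximation) through a vectorised version of the same bisection;
failed inversions are excluded and counted.

At the reference point inputs (f_XXY = 0.0133, w_XYY = 0.79,
µ_f = 1.49 × 10⁻³, µ_m = 5.79 × 10⁻⁴) the inversion gives
w_XXY = 1.0127 and f_XYY = 0.0053, and w_XXY = 1.0302 with
µ₂ = 0.032 in both aneuploid sexes — within about half a percent of the
values the reference analysis reports (1.009, 0.005, 1.024), the
residual reflecting unpublished details of that analysis's class
accounting.

## Synthetic stand-in fixtures

The raw observations this machinery was built around are not
redistributable, so the package ships small synthetic stand-ins,
constructed by the package's own generators and frozen:

* `synthetic_ndj_counts.tsv` — 38 178 offspring over three assays (a
  female-only survey, a fully scored batch of the same marked-Y cross,
  and the Bar-Y sexed test cross), constructed so the combined ML fit
  returns µ_f = 1.45 × 10⁻³, µ_m = 5.85 × 10⁻⁴, λ_f = 6.32 × 10⁻³ and
  λ_m ≈ 3 × 10⁻⁵ — the published estimates at two significant figures —
  with a loss-rate LRT of 30.2.  The µ-equality LRT of this stand-in is
  3.88 (P = 0.049): significant female bias, but smaller than the
  published 4.22, an irreducible residual of reconstructing counts from
  summary statistics alone (no integer dataset under this package's
  class model reproduces the published estimates and both LRT statistics
  simultaneously).
* `synthetic_trajectories.tsv` — three populations of census 287 founded
  by 60 XXY females + 60 XY males, simulated at w_XYY = 0.79 and chosen
  so the pooled observed slope sits at the 9.4% tail of the
  single-population slope distribution under that selection strength,
  which is the anchoring fact reported for the real trajectories.  Under
  this package's simulator the matching null (w_XYY = 1) tail
  probability is ≈ 0.004 rather than the reported 0.019: the null and
  selection slope distributions separate more sharply here than in the
  reference simulations, and no single observed slope can reproduce both
  published tail probabilities.
* `synthetic_detection.tsv` — 158 test-cross families (sons tested 1–6,
  mean 4.9, 775 total) with one detection, and 75 PCR females with one
  detection.  The exact multiset of k values is unpublished; the frozen
  multiset (80×6, 30×5, 20×4, 14×3, 9×2, 5×1) honours the published
  count, total, mean and range.

Passing tests on these fixtures show that the estimators recover the
published quantities from data with the stated statistical structure;
they cannot show anything about features of the real data the fixtures
lack (block effects, overdispersion between vials, marker artifacts).

## Numerical choices

Equilibrium tolerance 10⁻¹² (change per iteration), bisection tolerance
10⁻¹⁰ on w_XXY; ML optimiser ftol 10⁻¹⁴ on the log-likelihood with
bounds 10⁻¹⁰–0.2 per rate; probability maps validated to 10⁻¹²; the
logistic-slope Newton iteration stops at 10⁻¹⁰ and declares separation
beyond |slope| > 30.  Default problem sizes — 10 000 simulation
replicates, 50 000 ABC acceptances, 2 × 10⁶ offspring for the recovery
test — match the reference analysis where it states them and otherwise
keep the full test suite in the tens of seconds.

## Limitations

* The neutral martingale for supernumerary-Y content holds exactly only
  while XXYY individuals do not reproduce; XXYY fertility is not
  modelled, so multi-generation neutral simulations lose a small amount
  of Y content through XXY × XYY matings.
* The ML information structure of the original rate analysis is not
  fully recoverable from its published summaries; see the fixture notes
  above for the two statistics this affects.
* The equilibrium model is deterministic (no drift) and uses scalar
  fitnesses; fecundity structure, age structure and sperm competition
  are out of scope.
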