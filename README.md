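# karyodyn

Population dynamics of sex-chromosome aneuploidy in *Drosophila
melanogaster*.

Sex-chromosome nondisjunction in a euploid parent produces XX or nullo-X
ova (rate µ_f per meiosis) and XY or nullo sperm (rate µ_m), so XXY
females arise recurrently in any fly population; their sons are half XYY,
and the fate of these "supernumerary Y" karyotypes is a balance between
recurrent input by nondisjunction and removal by selection.  `karyodyn`
implements the quantitative machinery for studying that balance:

* **Karyotype algebra** — gamete and zygote distributions under primary
  nondisjunction (µ), spontaneous chromosome loss (λ) and secondary
  nondisjunction in aneuploid parents (µ₂), viability filtering, and
  marker-based phenotype classing for test-cross designs (`y⁺`-marked and
  `Bar`-marked Y chromosomes).
* **Rate inference** — joint multinomial maximum likelihood for
  sex-specific µ and λ from offspring class counts across several cross
  designs, with Wald intervals and likelihood-ratio tests; Clopper–Pearson
  bounds with Cooper's half-recovery correction for secondary
  nondisjunction; the viability selection coefficient
  s = (1 − 2f)/(1 − f) with block-bootstrap intervals.
* **Forward simulation** — Wright–Fisher-style populations with
  non-overlapping generations and random mating, the logistic slope of
  XXY-among-females on generation as the frequency-change statistic, and
  one-tailed simulation p-values for an observed decline.
* **Rejection ABC** — the standing XXY frequency among females from two
  detection assays (a fertility test cross in which an XXY mother is
  missed with probability 0.5^k when k sons are tested, and a PCR assay
  with perfect detection), with exact-match rejection sampling under a
  Uniform(0, 0.1) prior.
* **Mutation–selection balance** — a deterministic recursion for
  XX/XXY female and XY/XYY male frequencies; at equilibrium the standing
  frequency approaches the classical q\* ≅ µ/s.  Given an observed
  standing frequency, the solver inverts the recursion for the XXY
  fitness w_XXY and reports the companion equilibrium XYY frequency, with
  credible intervals by propagating input posteriors.
* **Synthetic data** — generators for every input the pipeline consumes
  (count tables, trajectories, detection tables), plus packaged synthetic
  stand-in fixtures frozen at the study conditions.

## Worked example

Invert the mutation–selection-balance model for the fitness of XXY
females, given a standing XXY frequency of 0.0133 among females, XYY
viability 0.79, and nondisjunction rates µ_f = 1.49 × 10⁻³ and
µ_m = 5.79 × 10⁻⁴:

```sh
$ karyodyn msb --f-xxy 0.0133 --w-xyy 0.79
{
  "f_xxy": 0.013299999999838136,
  "f_xyy": 0.005334457442632239,
  "w_xxy": 1.0126607162237633,
  ...
}
```

The model says XXY females need fitness w_XXY ≈ 1.01 — essentially equal
to XX females — for the observed standing frequency to be an equilibrium,
and that about 1 in 190 males (f_XYY ≈ 0.0053) carries the XYY karyotype
at that equilibrium.  With a secondary-nondisjunction rate of 0.032 in
aneuploid parents (`--mu2 0.032`) the required fitness rises slightly to
w_XXY ≈ 1.03, because part of the output of XXY mothers is then wasted on
inviable XXX and YY zygotes.

The remaining stages run the same way from the packaged fixtures:

```sh
karyodyn fit-ndj                 # ML nondisjunction/loss rates + LRTs
karyodyn abc --seed 1            # ABC posterior for the standing frequency
karyodyn simulate --seed 1       # simulation p-value for the decline
karyodyn pipeline --seed 1       # all of the above in one JSON report
```

`karyodyn abc --seed 1` reports a posterior mean standing frequency of
0.0133 (95% credible interval 0.0027–0.0320): roughly one female in 75
carries an extra Y.  `karyodyn simulate --seed 1` reports
`p_slope ≈ 0.09`: with viability selection of 0.21 against XYY males,
about 9% of simulated populations decline at least as fast as the
observed trajectories, so that selection alone plausibly explains the
observed loss of XXY females over twelve generations.

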