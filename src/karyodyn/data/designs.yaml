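# Built-in cross designs for nondisjunction and aneuploid-transmission assays.
#
# Chromosomes are written as lists of functional/dominant marker alleles:
# [] is a y1-mutant X or an unmarked Y, ["y+"] carries a functional yellow
# allele (a wild X or the Dp(1;Y)y+ marked Y), ["Bar"] is the dominant
# Bar-marked Y.  Phenotype keys are "{body}-{eye}-{sex}" where body is
# wild/yellow and eye is Bar/normal.

spontaneous_pooled:
  description: >
    Large y/y x y/Dp(1;Y)y+ population from which non-yellow (XXY) females
    are collected; nondisjunction in either parent yields the same
    wild-bodied female phenotype, so parent of origin is not identifiable.
    Yellow (X-null) males reveal nondisjunction or loss in either parent.
  mother: {xs: [[], []], ys: []}
  father: {xs: [[]], ys: [["y+"]]}
  classes:
    yellow-normal-female: regular_female
    wild-normal-female: xxy_female
    wild-normal-male: regular_male
    yellow-normal-male: xnull_male

spontaneous_pooled_females:
  description: >
    Female-only scoring of the spontaneous_pooled cross: virgin females
    collected from the population and classified yellow (XX) versus
    wild-bodied (XXY); males not recorded.
  mother: {xs: [[], []], ys: []}
  father: {xs: [[]], ys: [["y+"]]}
  classes:
    yellow-normal-female: regular_female
    wild-normal-female: xxy_female
    wild-normal-male: regular_male
    yellow-normal-male: xnull_male
  unscored: [regular_male, xnull_male]

spontaneous_sexed:
  description: >
    Test cross of y/y females to y+-X / Bar-Y males in which the products
    of female versus male nondisjunction and chromosome loss carry distinct
    marker combinations.
  mother: {xs: [[], []], ys: []}
  father: {xs: [["y+"]], ys: [["Bar"]]}
  classes:
    wild-normal-female: regular_female
    yellow-Bar-male: regular_male
    yellow-Bar-female: maternal_xxy_female
    wild-Bar-female: paternal_xxy_female
    wild-normal-male: maternal_null_male
    yellow-normal-male: paternal_null_male
    # double-aberration products (one error in each parent; probability of
    # order mu*lambda) carry phenotypes outside the designed classes
    yellow-normal-female: double_aberrant_female
    wild-Bar-male: double_aberrant_male
  unscored: [double_aberrant_female, double_aberrant_male]

xxy_outcross:
  description: >
    XXY females (y/y with a y+-marked Y) crossed to wild-type males.  XY
    and XYY sons are distinguishable (only the maternal Y is marked), so
    son frequencies measure XYY viability; XX and XXY daughters share a
    phenotype.  Yellow daughters reveal secondary nondisjunction.
  mother: {xs: [[], []], ys: [["y+"]]}
  father: {xs: [["y+"]], ys: [[]]}
  classes:
    wild-normal-female: female
    yellow-normal-male: xy_male
    wild-normal-male: xyy_male
    yellow-normal-female: secondary_ndj_female

xyy_sires:
  description: >
    XYY males (two y+-marked Y chromosomes) crossed to y/y females; all
    daughters are XXY and wild-bodied.  Yellow daughters arise only by
    paternal secondary nondisjunction (X sperm).
  mother: {xs: [[], []], ys: []}
  father: {xs: [[]], ys: [["y+"], ["y+"]]}
  classes:
    wild-normal-female: xxy_female
    wild-normal-male: male
    yellow-normal-female: secondary_ndj_female
    yellow-normal-male: null_male
  unscored: [null_male]

marker_control:
  description: >
    Viability control for the yellow marker: y+/y females by y males give
    yellow and non-yellow offspring of both sexes at 1:1 within sex when
    the marker is neutral.
  mother: {xs: [["y+"], []], ys: []}
  father: {xs: [[]], ys: [[]]}
  classes:
    wild-normal-female: wild_female
    yellow-normal-female: yellow_female
    wild-normal-male: wild_male
    yellow-normal-male: yellow_male
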