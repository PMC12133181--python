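"""Sex-chromosome karyotype algebra.

Models meiosis in euploid and aneuploid *Drosophila melanogaster* parents,
including primary nondisjunction (rate ``mu``), spontaneous chromosome loss
(rate ``lambda``) and secondary nondisjunction in XXY/XYY parents (rate
``mu2``), and composes gametes into zygote distributions with viability
filtering and marker-based phenotype classing.

Sex is determined by X count: two or more X chromosomes make a female, one
makes a male.  A zygote with no X is lethal regardless of Y count.  The
supported karyotype set is XX, XY, XXY, XYY, X0, XXX, XXYY, YY, Y0 and 00;
zygotes outside this set can only arise when both parents err in the same
meiosis (probability of order mu_f * mu_m) and are routed to a fixed
zero-viability "complex" class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

__all__ = [
    "Karyotype",
    "RateSet",
    "ViabilityScheme",
    "Genotype",
    "Gamete",
    "CrossDesign",
    "KaryotypeError",
    "SterileParentError",
    "DesignError",
    "COMPLEX",
    "gamete_distribution",
    "zygote_distribution",
    "apply_viability",
    "phenotype_classes",
]

_PROB_TOL = 1e-12

# (n_x, n_y) -> canonical name
_SUPPORTED = {
    (2, 0): "XX",
    (1, 1): "XY",
    (2, 1): "XXY",
    (1, 2): "XYY",
    (1, 0): "X0",
    (3, 0): "XXX",
    (2, 2): "XXYY",
    (0, 2): "YY",
    (0, 1): "Y0",
    (0, 0): "00",
}
_BY_NAME = {v: k for k, v in _SUPPORTED.items()}

#: sentinel for zygotes outside the supported set (always inviable)
COMPLEX = "complex"


class KaryotypeError(ValueError):
    """Unsupported karyotype requested."""


class SterileParentError(ValueError):
    """Meiosis requested for a sterile parent (X0 male)."""


class DesignError(ValueError):
    """A cross design does not cover a surviving offspring phenotype."""


@dataclass(frozen=True, order=True)
class Karyotype:
    """A sex-chromosome complement: ``n_x`` X and ``n_y`` Y chromosomes."""

    n_x: int
    n_y: int

    def __post_init__(self):
        if (self.n_x, self.n_y) not in _SUPPORTED:
            raise KaryotypeError(
                f"unsupported karyotype X{self.n_x}Y{self.n_y}; supported: "
                + ", ".join(sorted(_SUPPORTED.values()))
            )

    @classmethod
    def from_name(cls, name: str) -> "Karyotype":
        try:
            n_x, n_y = _BY_NAME[name.upper().replace("∅", "0")]
        except KeyError:
            raise KaryotypeError(f"unknown karyotype name {name!r}") from None
        return cls(n_x, n_y)

    @property
    def name(self) -> str:
        return _SUPPORTED[(self.n_x, self.n_y)]

    @property
    def sex(self) -> str:
        """'female' (>= 2 X), 'male' (1 X) or 'lethal' (no X)."""
        if self.n_x >= 2:
            return "female"
        if self.n_x == 1:
            return "male"
        return "lethal"

    @property
    def fertile(self) -> bool:
        """X0 males are viable but completely sterile; YY/Y0/00 never hatch."""
        if self.sex == "lethal":
            return False
        return not (self.n_x == 1 and self.n_y == 0)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


XX = Karyotype(2, 0)
XY = Karyotype(1, 1)
XXY = Karyotype(2, 1)
XYY = Karyotype(1, 2)


@dataclass(frozen=True)
class RateSet:
    """Per-meiosis aberration probabilities.

    mu_f / mu_m
        primary nondisjunction in XX females / XY males.
    lambda_f / lambda_m
        spontaneous loss of a normally disjoined chromosome transmitted by
        the mother / father (the gamete becomes nullo).
    mu2_f / mu2_m
        secondary nondisjunction in XXY females (XX and Y gametes) and XYY
        males (X and YY gametes).
    """

    mu_f: float = 0.0
    mu_m: float = 0.0
    lambda_f: float = 0.0
    lambda_m: float = 0.0
    mu2_f: float = 0.0
    mu2_m: float = 0.0

    def __post_init__(self):
        for name in ("mu_f", "mu_m", "lambda_f", "lambda_m", "mu2_f", "mu2_m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.mu_f + self.lambda_f > 1.0 or self.mu_m + self.lambda_m > 1.0:
            raise ValueError("mu + lambda exceeds 1 within a sex")

    def replace(self, **kw) -> "RateSet":
        return replace(self, **kw)


def _markers(chrom) -> frozenset:
    return frozenset(chrom)


@dataclass(frozen=True)
class Genotype:
    """A parent's labelled chromosome complement.

    ``xs`` and ``ys`` are tuples of marker sets, one per chromosome; markers
    are the functional/dominant alleles carried (e.g. ``{"y+"}`` for the
    Dp(1;Y)y+ duplication, ``{"Bar"}`` for the Bar-marked Y).  A plain wild
    X is written ``{"y+"}`` since it carries a functional yellow allele; a
    y1-mutant X is the empty set.
    """

    xs: tuple = ()
    ys: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "xs", tuple(_markers(c) for c in self.xs))
        object.__setattr__(self, "ys", tuple(_markers(c) for c in self.ys))

    @classmethod
    def unlabelled(cls, kt: Karyotype) -> "Genotype":
        return cls(xs=((),) * kt.n_x, ys=((),) * kt.n_y)

    @property
    def karyotype(self) -> Karyotype:
        return Karyotype(len(self.xs), len(self.ys))


@dataclass(frozen=True)
class Gamete:
    """A labelled gamete: tuples of marker sets for X and Y chromosomes."""

    xs: tuple = ()
    ys: tuple = ()

    def __post_init__(self):
        object.__setattr__(
            self, "xs", tuple(sorted((_markers(c) for c in self.xs), key=sorted)))
        object.__setattr__(
            self, "ys", tuple(sorted((_markers(c) for c in self.ys), key=sorted)))

    @property
    def n_x(self) -> int:
        return len(self.xs)

    @property
    def n_y(self) -> int:
        return len(self.ys)


def _accumulate(dist: dict, key, p: float) -> None:
    if p > 0.0:
        dist[key] = dist.get(key, 0.0) + p


def gamete_distribution(parent, parent_sex: str, rates: RateSet) -> dict:
    """Distribution of gametes produced by ``parent``.

    Parameters
    ----------
    parent
        A :class:`Karyotype` (treated as unlabelled) or :class:`Genotype`.
    parent_sex
        'female' or 'male'; must agree with the karyotype's derived sex.
    rates
        Aberration rates.  Only ``mu``/``lambda`` apply to euploid parents
        and only ``mu2`` to XXY/XYY parents.

    Returns
    -------
    dict mapping :class:`Gamete` (when given a Genotype) or plain
    ``(n_x, n_y)`` tuples (when given a Karyotype) to probability.
    """
    labelled = isinstance(parent, Genotype)
    geno = parent if labelled else Genotype.unlabelled(parent)
    kt = geno.karyotype

    if kt.sex != parent_sex:
        raise KaryotypeError(f"{kt.name} is not a {parent_sex}")
    if not kt.fertile:
        raise SterileParentError(f"{kt.name} parent is sterile")

    dist: dict = {}
    xs, ys = geno.xs, geno.ys

    if kt == XX:
        reg = 1.0 - rates.mu_f - rates.lambda_f
        for x in xs:
            _accumulate(dist, Gamete(xs=(x,)), reg / 2.0)
        _accumulate(dist, Gamete(xs=xs), rates.mu_f / 2.0)
        _accumulate(dist, Gamete(), rates.mu_f / 2.0 + rates.lambda_f)
    elif kt == XY:
        reg = 1.0 - rates.mu_m - rates.lambda_m
        _accumulate(dist, Gamete(xs=xs), reg / 2.0)
        _accumulate(dist, Gamete(ys=ys), reg / 2.0)
        _accumulate(dist, Gamete(xs=xs, ys=ys), rates.mu_m / 2.0)
        _accumulate(dist, Gamete(), rates.mu_m / 2.0 + rates.lambda_m)
    elif kt == XXY:
        # X-X bivalent disjoins; the free Y assorts with either X at random.
        reg = 1.0 - rates.mu2_f
        for x in xs:
            _accumulate(dist, Gamete(xs=(x,)), reg / 4.0)
            _accumulate(dist, Gamete(xs=(x,), ys=ys), reg / 4.0)
        _accumulate(dist, Gamete(xs=xs), rates.mu2_f / 2.0)
        _accumulate(dist, Gamete(ys=ys), rates.mu2_f / 2.0)
    elif kt == XYY:
        # X pairs with one Y; the other Y segregates to either pole.
        reg = 1.0 - rates.mu2_m
        for y in ys:
            _accumulate(dist, Gamete(xs=xs, ys=(y,)), reg / 4.0)
            _accumulate(dist, Gamete(ys=(y,)), reg / 4.0)
        _accumulate(dist, Gamete(xs=xs), rates.mu2_m / 2.0)
        _accumulate(dist, Gamete(ys=ys), rates.mu2_m / 2.0)
    else:
        raise KaryotypeError(f"meiosis in {kt.name} parents is not modelled")

    total = sum(dist.values())
    dist = {g: p / total for g, p in dist.items()}
    if not labelled:
        plain: dict = {}
        for g, p in dist.items():
            plain[(g.n_x, g.n_y)] = plain.get((g.n_x, g.n_y), 0.0) + p
        return plain
    return dist


def _zygote_key(n_x: int, n_y: int):
    """Karyotype for a zygote, or the COMPLEX sentinel if out of range."""
    if (n_x, n_y) in _SUPPORTED:
        return Karyotype(n_x, n_y)
    return COMPLEX


def zygote_distribution(
    mother,
    father,
    rates: RateSet,
    *,
    loss_stage: str = "gametic",
    labelled: bool = False,
):
    """Offspring karyotype distribution for a mother x father cross.

    With ``loss_stage='gametic'`` (default) chromosome loss converts a
    normal single-chromosome gamete into a nullo gamete in the transmitting
    parent.  With ``'zygotic'`` the loss instead removes one randomly chosen
    parent-derived chromosome from the zygote after fertilisation.

    When ``labelled`` is true the result maps ``(Karyotype-or-'complex',
    chromosome-marker tuple)`` keys to probabilities and the parents must be
    :class:`Genotype` instances; otherwise keys are :class:`Karyotype` or
    the ``'complex'`` sentinel.
    """
    if loss_stage not in ("gametic", "zygotic"):
        raise ValueError("loss_stage must be 'gametic' or 'zygotic'")

    mg = mother if isinstance(mother, Genotype) else Genotype.unlabelled(mother)
    fg = father if isinstance(father, Genotype) else Genotype.unlabelled(father)

    grates = rates
    if loss_stage == "zygotic":
        grates = rates.replace(lambda_f=0.0, lambda_m=0.0)

    mdist = gamete_distribution(mg, "female", grates)
    fdist = gamete_distribution(fg, "male", grates)

    out: dict = {}
    for (ovum, p_o), (sperm, p_s) in itertools.product(mdist.items(), fdist.items()):
        p = p_o * p_s
        if p <= 0.0:
            continue
        if loss_stage == "zygotic":
            for m_loss, f_loss in itertools.product((False, True), repeat=2):
                lam_m = rates.lambda_f if mg.karyotype in (XX,) else 0.0
                lam_p = rates.lambda_m if fg.karyotype in (XY,) else 0.0
                w = ((lam_m if m_loss else 1.0 - lam_m)
                     * (lam_p if f_loss else 1.0 - lam_p))
                if w <= 0.0:
                    continue
                for ov, pv in _drop_one(ovum, m_loss):
                    for sp, ps in _drop_one(sperm, f_loss):
                        _add_zygote(out, ov, sp, p * w * pv * ps)
        else:
            _add_zygote(out, ovum, sperm, p)

    total = sum(out.values())
    out = {k: v / total for k, v in out.items()}
    if labelled:
        return out
    plain: dict = {}
    for (kt, _chroms), v in out.items():
        plain[kt] = plain.get(kt, 0.0) + v
    return plain


def _drop_one(gamete: Gamete, do_drop: bool):
    """All ways of removing one chromosome from a gamete (uniformly)."""
    if not do_drop:
        yield gamete, 1.0
        return
    n = gamete.n_x + gamete.n_y
    if n == 0:
        yield gamete, 1.0
        return
    for i in range(gamete.n_x):
        xs = gamete.xs[:i] + gamete.xs[i + 1:]
        yield Gamete(xs=xs, ys=gamete.ys), 1.0 / n
    for i in range(gamete.n_y):
        ys = gamete.ys[:i] + gamete.ys[i + 1:]
        yield Gamete(xs=gamete.xs, ys=ys), 1.0 / n


def _add_zygote(out: dict, ovum: Gamete, sperm: Gamete, p: float) -> None:
    n_x = ovum.n_x + sperm.n_x
    n_y = ovum.n_y + sperm.n_y
    kt = _zygote_key(n_x, n_y)
    chroms = (tuple(sorted(ovum.xs + sperm.xs, key=sorted)),
              tuple(sorted(ovum.ys + sperm.ys, key=sorted)))
    key = (kt, chroms)
    out[key] = out.get(key, 0.0) + p


# --------------------------------------------------------------------------
# viability

_EMBRYONIC_LETHAL = ("YY", "Y0", "00")


class ViabilityScheme:
    """Relative viability per karyotype.

    XX and XY default to 1.  YY, Y0 and 00 (and the 'complex' sentinel) are
    embryonic-lethal and cannot be overridden.  XXX defaults to 0 (low
    viability and fertility); XXY and XYY default to 1; XXYY and X0 default
    to 1 but the simulation default (:meth:`simulation_default`) zeroes
    XXX/XXYY, matching the assumption that complex karyotypes contribute
    nothing.
    """

    def __init__(self, w=None):
        self._w = {
            "XX": 1.0, "XY": 1.0, "XXY": 1.0, "XYY": 1.0,
            "X0": 1.0, "XXX": 0.0, "XXYY": 1.0,
        }
        if w:
            for k, v in w.items():
                name = k.name if isinstance(k, Karyotype) else str(k)
                if name in _EMBRYONIC_LETHAL or name == COMPLEX:
                    if v != 0.0:
                        raise ValueError(f"{name} viability is fixed at 0")
                    continue
                if name not in self._w:
                    raise KaryotypeError(f"unknown karyotype {name!r}")
                if not 0.0 <= v:
                    raise ValueError(f"viability for {name} must be >= 0")
                self._w[name] = float(v)

    @classmethod
    def simulation_default(cls, w_xyy: float = 1.0, w_xxy: float = 1.0):
        """Scheme used in forward simulations: XXX/XXYY/X0 contribute zero."""
        return cls({"XXX": 0.0, "XXYY": 0.0, "X0": 0.0,
                    "XYY": w_xyy, "XXY": w_xxy})

    def __getitem__(self, kt) -> float:
        name = kt if isinstance(kt, str) else kt.name
        if name == COMPLEX or name in _EMBRYONIC_LETHAL:
            return 0.0
        return self._w[name]

    @property
    def w_xxy(self) -> float:
        return self._w["XXY"]

    @property
    def w_xyy(self) -> float:
        return self._w["XYY"]

    @property
    def s_xyy(self) -> float:
        return 1.0 - self._w["XYY"]


def apply_viability(zygotes: dict, scheme: ViabilityScheme):
    """Filter a zygote probability map through viability selection.

    Returns ``(survivor_map, survival_fraction)`` where the survivor map is
    renormalised over surviving karyotypes and the survival fraction is the
    pre-normalisation probability mass that survives.
    """
    weighted = {}
    for k, p in zygotes.items():
        kt = k[0] if isinstance(k, tuple) else k
        w = scheme[kt]
        if w > 0.0 and p > 0.0:
            weighted[k] = p * w
    survival = sum(weighted.values())
    if survival <= 0.0:
        raise ValueError("degenerate distribution: no zygote survives")
    return {k: v / survival for k, v in weighted.items()}, survival


# --------------------------------------------------------------------------
# phenotype classing

def phenotype_of(kt: Karyotype, chroms) -> str:
    """Visible phenotype key ``'{body}-{eye}-{sex}'`` of an offspring.

    Body colour is wild-type iff any chromosome (X or Y, including the
    Dp(1;Y)y+ duplication) carries ``y+``; eyes are Bar iff any chromosome
    carries the dominant ``Bar`` marker.
    """
    xs, ys = chroms
    alleles = set().union(*xs, *ys) if (xs or ys) else set()
    body = "wild" if "y+" in alleles else "yellow"
    eye = "Bar" if "Bar" in alleles else "normal"
    return f"{body}-{eye}-{kt.sex}"


@dataclass(frozen=True)
class CrossDesign:
    """A cross with marker-labelled parents and a phenotype -> class map.

    ``class_map`` maps phenotype keys (see :func:`phenotype_of`) to named
    offspring classes; several phenotypes may share a class.  ``unscored``
    lists classes that exist but were not recorded in the assay (class
    probabilities are conditioned on scored classes).
    """

    name: str
    mother: Genotype
    father: Genotype
    class_map: dict
    unscored: tuple = ()
    description: str = ""

    @property
    def scored_classes(self) -> tuple:
        seen = []
        for cls in self.class_map.values():
            if cls not in seen and cls not in self.unscored:
                seen.append(cls)
        return tuple(seen)


def phenotype_classes(
    design: CrossDesign,
    rates: RateSet,
    scheme: ViabilityScheme,
    *,
    loss_stage: str = "gametic",
    condition_on_scored: bool = True,
) -> dict:
    """Probability of each scored phenotype class among surviving offspring.

    Raises :class:`DesignError` if a surviving phenotype has no class.
    """
    zyg = zygote_distribution(design.mother, design.father, rates,
                              loss_stage=loss_stage, labelled=True)
    survivors, _ = apply_viability(zyg, scheme)

    out: dict = {c: 0.0 for c in design.scored_classes}
    unscored_mass = 0.0
    for (kt, chroms), p in survivors.items():
        phe = phenotype_of(kt, chroms)
        if phe not in design.class_map:
            raise DesignError(
                f"design {design.name!r}: surviving karyotype {kt.name} with "
                f"phenotype {phe!r} has no phenotype class")
        cls = design.class_map[phe]
        if cls in design.unscored:
            unscored_mass += p
        else:
            out[cls] += p

    if condition_on_scored:
        scored = sum(out.values())
        if scored <= 0.0:
            raise ValueError("no probability mass on scored classes")
        out = {c: p / scored for c, p in out.items()}
    return out
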