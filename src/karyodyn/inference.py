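"""Maximum-likelihood estimation of nondisjunction and loss rates.

The observable data are multinomial counts of phenotypically scored
offspring classes from one or more cross designs.  The class-probability
vector for a design follows from the gamete model in
:mod:`karyodyn.karyotype`; the likelihood is a product of independent
multinomials across assays and is maximised over the four sex-specific
rates (mu_f, mu_m, lambda_f, lambda_m), optionally with equality
constraints between parameters for likelihood-ratio tests.

Also provides the small-sample estimators used alongside the ML model:
a Clopper-Pearson upper bound on secondary nondisjunction with the Cooper
half-recovery correction, the viability selection coefficient
s = (1 - 2f) / (1 - f), and thin wrappers for the exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .karyotype import CrossDesign, RateSet, ViabilityScheme, phenotype_classes

__all__ = [
    "CountTable",
    "MLEResult",
    "class_probabilities",
    "fit_mle",
    "likelihood_ratio_test",
    "secondary_ndj_upper_bound",
    "selection_coefficient",
    "selection_to_frequency",
    "estimate_xyy_selection",
    "fisher_exact_2x2",
    "binomial_two_sided",
]

_RATE_NAMES = ("mu_f", "mu_m", "lambda_f", "lambda_m")
_LOWER = 1e-10
_UPPER = 0.2
_BOUNDARY = 1e-8

REQUIRED_COLUMNS = ("assay_id", "block", "phenotype_class", "count")


@dataclass
class CountTable:
    """Validated offspring class counts.

    The underlying frame has columns ``assay_id``, ``block``,
    ``phenotype_class`` and ``count`` (non-negative integers).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if len(self.df) == 0:
            raise ValueError("count table is empty")
        counts = self.df["count"]
        if (counts < 0).any():
            raise ValueError("count table contains negative counts")
        if not np.allclose(counts, counts.astype(int)):
            raise ValueError("counts must be integers")
        self.df = self.df.assign(count=counts.astype(int))

    def validate_classes(self, designs: dict) -> None:
        """Check that every phenotype class belongs to its assay's design."""
        for assay, sub in self.df.groupby("assay_id"):
            if assay not in designs:
                raise ValueError(f"no design given for assay {assay!r}")
            valid = set(designs[assay].scored_classes)
            unknown = sorted(set(sub["phenotype_class"]) - valid)
            if unknown:
                raise ValueError(
                    f"assay {assay!r}: unknown phenotype classes {unknown}")

    def class_counts(self, assay_id, classes) -> np.ndarray:
        sub = self.df[self.df["assay_id"] == assay_id]
        agg = sub.groupby("phenotype_class")["count"].sum()
        return np.array([int(agg.get(c, 0)) for c in classes])

    @property
    def total(self) -> int:
        return int(self.df["count"].sum())


@dataclass
class MLEResult:
    """Fitted rates with Wald inference."""

    estimates: dict
    se: dict
    ci: dict
    z: dict
    p: dict
    loglik: float
    converged: bool
    boundary: dict
    n_free: int
    n_obs: int
    constraints: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in _RATE_NAMES:
            rows.append({
                "parameter": name,
                "estimate": self.estimates[name],
                "se": self.se.get(name, np.nan),
                "ci_low": self.ci.get(name, (np.nan, np.nan))[0],
                "ci_high": self.ci.get(name, (np.nan, np.nan))[1],
                "z": self.z.get(name, np.nan),
                "p": self.p.get(name, np.nan),
            })
        return pd.DataFrame(rows)


def class_probabilities(
    design: CrossDesign,
    rates: RateSet,
    scheme: ViabilityScheme | None = None,
) -> dict:
    """Probability vector over the design's scored phenotype classes."""
    scheme = scheme or ViabilityScheme()
    return phenotype_classes(design, rates, scheme)


def _resolve_constraints(constraints: dict | None):
    """Map each rate name to the free parameter that carries it."""
    constraints = dict(constraints or {})
    rep = {}
    for name in _RATE_NAMES:
        target = name
        seen = set()
        while target in constraints:
            if target in seen:
                raise ValueError("circular constraint")
            seen.add(target)
            target = constraints[target]
        if target not in _RATE_NAMES:
            raise ValueError(f"constraint target {target!r} is not a rate")
        rep[name] = target
    free = sorted({rep[n] for n in _RATE_NAMES}, key=_RATE_NAMES.index)
    return rep, free


def _expand(theta_free, rep, free) -> RateSet:
    lookup = dict(zip(free, theta_free))
    return RateSet(**{n: float(lookup[rep[n]]) for n in _RATE_NAMES})


def _neg_loglik(theta_free, rep, free, assays, scheme) -> float:
    try:
        rates = _expand(theta_free, rep, free)
    except ValueError:
        return np.inf
    ll = 0.0
    for design, counts in assays:
        probs = phenotype_classes(design, rates, scheme)
        p = np.array([probs[c] for c in design.scored_classes])
        if np.any((p <= 0) & (counts > 0)):
            return np.inf
        mask = counts > 0
        ll += counts[mask] @ np.log(p[mask])
    return -ll


def fit_mle(
    tables,
    designs: dict,
    *,
    constraints: dict | None = None,
    scheme: ViabilityScheme | None = None,
    starts=(1e-4, 1e-3, 1e-2),
) -> MLEResult:
    """Fit sex-specific rates by combined multinomial maximum likelihood.

    Parameters
    ----------
    tables
        One :class:`CountTable` or a list of them.
    designs
        Mapping assay_id -> :class:`CrossDesign`.
    constraints
        Equality constraints, e.g. ``{"mu_m": "mu_f"}`` forces a shared
        nondisjunction rate; used to build nested models for LRTs.
    scheme
        Viability scheme applied when computing class probabilities
        (default: standard scheme with lethal XXX).

    The likelihood is maximised by bounded quasi-Newton iteration on
    log10-rates from several fixed starting points; estimates at the lower
    bound are reported as 0 and flagged as boundary cases.
    """
    if isinstance(tables, CountTable):
        tables = [tables]
    if not tables:
        raise ValueError("at least one count table required")
    scheme = scheme or ViabilityScheme()
    rep, free = _resolve_constraints(constraints)

    merged = CountTable(pd.concat([t.df for t in tables], ignore_index=True))
    merged.validate_classes(designs)
    if merged.total <= 0:
        raise ValueError("total count is zero")

    assays = []
    for assay in merged.df["assay_id"].unique():
        design = designs[assay]
        counts = merged.class_counts(assay, design.scored_classes)
        assays.append((design, counts))

    lo, hi = np.log10(_LOWER), np.log10(_UPPER)

    def obj(log_theta):
        return _neg_loglik(10.0 ** log_theta, rep, free, assays, scheme)

    best = None
    for start in starts:
        x0 = np.full(len(free), np.log10(start))
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B",
            bounds=[(lo, hi)] * len(free),
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    theta = 10.0 ** best.x
    loglik = -best.fun
    boundary = {f: bool(t <= _BOUNDARY) for f, t in zip(free, theta)}

    se_free, cov = _wald_se(theta, rep, free, assays, scheme, boundary)

    estimates, se, ci, zstat, pval, bflag = {}, {}, {}, {}, {}, {}
    for name in _RATE_NAMES:
        carrier = rep[name]
        i = free.index(carrier)
        est = 0.0 if boundary[carrier] else float(theta[i])
        estimates[name] = est
        bflag[name] = boundary[carrier]
        s = se_free[i]
        se[name] = s
        if np.isfinite(s) and s > 0:
            ci[name] = (max(0.0, est - 1.959963984540054 * s),
                        est + 1.959963984540054 * s)
            z = est / s
            zstat[name] = z
            pval[name] = 2.0 * stats.norm.sf(abs(z))
        else:
            ci[name] = (np.nan, np.nan)
            zstat[name] = np.nan
            pval[name] = np.nan

    return MLEResult(
        estimates=estimates, se=se, ci=ci, z=zstat, p=pval,
        loglik=float(loglik), converged=bool(best.success),
        boundary=bflag, n_free=len(free), n_obs=merged.total,
        constraints=dict(constraints or {}),
    )


def _wald_se(theta, rep, free, assays, scheme, boundary):
    """Standard errors from the observed information (numerical Hessian)."""
    k = len(free)
    H = np.full((k, k), np.nan)
    h = np.array([max(1e-8, 1e-3 * t) for t in theta])

    def f(x):
        return _neg_loglik(x, rep, free, assays, scheme)

    f0 = f(theta)
    if not np.isfinite(f0):
        return np.full(k, np.nan), None
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h[i]
            ej = np.eye(k)[j] * h[j]
            if i == j:
                vals = [f(theta + ei), f(theta - ei)]
                if all(np.isfinite(v) for v in vals):
                    H[i, j] = (vals[0] - 2 * f0 + vals[1]) / h[i] ** 2
            else:
                vals = [f(theta + ei + ej), f(theta + ei - ej),
                        f(theta - ei + ej), f(theta - ei - ej)]
                if all(np.isfinite(v) for v in vals):
                    H[i, j] = H[j, i] = (
                        vals[0] - vals[1] - vals[2] + vals[3]
                    ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan), None
    se = np.where(np.diag(cov) > 0, se, np.nan)
    for i, name in enumerate(free):
        if boundary[name]:
            se[i] = np.nan
    return se, cov


def likelihood_ratio_test(full: MLEResult, constrained: MLEResult):
    """Likelihood-ratio test of a constrained model nested in a full model.

    Returns ``(chi2, df, p)`` with chi2 = 2 * (loglik_full -
    loglik_constrained) and df the difference in free parameters.
    """
    df = full.n_free - constrained.n_free
    if df < 0:
        raise ValueError("constrained model has more free parameters than full")
    chi2 = 2.0 * (full.loglik - constrained.loglik)
    if chi2 < -1e-8:
        raise RuntimeError(
            f"negative LRT statistic ({chi2:.3g}): optimisation failure")
    chi2 = max(0.0, chi2)
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def secondary_ndj_upper_bound(
    exceptional: int,
    total: int,
    level: float = 0.95,
    *,
    two_sided: bool = False,
    recovery_factor: float = 2.0,
) -> float:
    """Upper confidence limit on the secondary nondisjunction rate.

    Applies the Clopper-Pearson exact upper limit to the proportion of
    detectable exceptional offspring, then multiplies by
    ``recovery_factor`` (Cooper's correction: exceptional classes are
    recovered at half the rate at which the events occur, because the
    complementary products are inviable).

    With ``two_sided=True`` the upper limit of the two-sided ``level``
    interval (i.e. tail alpha/2) is used instead of the one-sided limit.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= exceptional <= total:
        raise ValueError("exceptional count outside [0, total]")
    alpha = (1.0 - level) / 2.0 if two_sided else 1.0 - level
    if exceptional == total:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1.0 - alpha, exceptional + 1,
                                     total - exceptional))
    return min(1.0, recovery_factor * upper)


def selection_coefficient(f: float) -> float:
    """Viability selection coefficient from the variant frequency.

    For a cross in which the variant and reference karyotypes are expected
    at 1:1, the selection coefficient is s = (1 - 2f) / (1 - f) where f is
    the observed frequency of the variant among its sex.
    """
    f = float(f)
    if not 0.0 <= f < 1.0:
        raise ValueError("f must be in [0, 1)")
    return (1.0 - 2.0 * f) / (1.0 - f)


def selection_to_frequency(s: float) -> float:
    """Inverse of :func:`selection_coefficient`: f = (1 - s) / (2 - s)."""
    s = float(s)
    if s >= 2.0:
        raise ValueError("s must be < 2")
    return (1.0 - s) / (2.0 - s)


def estimate_xyy_selection(
    table: CountTable,
    *,
    variant_class: str = "xyy_male",
    reference_class: str = "xy_male",
    n_boot: int = 2000,
    seed=None,
    level: float = 0.95,
):
    """Estimate viability selection against XYY males from son counts.

    The variant frequency f is pooled over blocks (weights proportional to
    block totals) and transformed to s = (1 - 2f)/(1 - f).  The confidence
    interval comes from a nonparametric bootstrap over blocks; with a
    single block no interval is available and ``(nan, nan)`` is returned.

    Returns a dict with keys ``f``, ``s``, ``ci_f``, ``ci_s``, ``n_blocks``.
    """
    df = table.df
    df = df[df["phenotype_class"].isin([variant_class, reference_class])]
    if df.empty:
        raise ValueError("no male counts found")
    pivot = (df.groupby(["block", "phenotype_class"])["count"].sum()
               .unstack(fill_value=0)
               .reindex(columns=[reference_class, variant_class], fill_value=0))
    var = pivot[variant_class].to_numpy(float)
    tot = var + pivot[reference_class].to_numpy(float)
    keep = tot > 0
    var, tot = var[keep], tot[keep]
    n_blocks = len(tot)
    if n_blocks == 0:
        raise ValueError("all blocks empty")

    f_hat = var.sum() / tot.sum()
    s_hat = selection_coefficient(f_hat)

    if n_blocks < 2:
        return {"f": f_hat, "s": s_hat, "ci_f": (np.nan, np.nan),
                "ci_s": (np.nan, np.nan), "n_blocks": n_blocks}

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
    f_boot = var[idx].sum(axis=1) / tot[idx].sum(axis=1)
    alpha = (1.0 - level) / 2.0
    f_lo, f_hi = np.quantile(f_boot, [alpha, 1.0 - alpha])
    # s is decreasing in f, so the interval flips
    ci_s = (selection_coefficient(min(f_hi, 1 - 1e-12)),
            selection_coefficient(f_lo))
    return {"f": f_hat, "s": s_hat, "ci_f": (float(f_lo), float(f_hi)),
            "ci_s": (float(ci_s[0]), float(ci_s[1])), "n_blocks": n_blocks}


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Empty margins give p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (small-probability method)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
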