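"""Deterministic mutation-selection balance for sex-chromosome aneuploidy.

Tracks the frequencies of XX and XXY among females and XY and XYY among
males under random mating.  Nondisjunction in euploid parents introduces
XXY at rate ~mu_f/2 + mu_m per generation; XXY females transmit the
supernumerary Y to half their offspring; XYY males arise essentially only
from XXY mothers.  Selection acts through

* ``w_xyy`` — viability of XYY offspring relative to XY, and
* ``w_xxy`` — total fitness (fecundity) multiplier of XXY mothers
  relative to XX mothers; XXY viability is taken as normal, so the
  unknown fitness acts on reproductive output rather than survival.

The complex karyotypes (XXX, XXYY, YY, Y-only) contribute nothing; X-null
offspring are viable but sterile and are excluded from the reproductive
pool.  At equilibrium the standing XXY frequency approximates the
classical q* = mu/s when mutation is weak and selection dominates.

Given an observed standing frequency of XXY among females, the inverse
solver finds the XXY fitness w_xxy whose equilibrium matches it
(bisection; the equilibrium frequency is monotone increasing in w_xxy on
the bracket), and reports the companion equilibrium frequency of XYY
among males.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .karyotype import Karyotype, RateSet, ViabilityScheme, zygote_distribution

__all__ = [
    "MSBParams",
    "MSBSolution",
    "recursion_step",
    "solve_equilibrium",
    "invert_for_fitness",
    "credible_intervals",
]

FEMALE_TYPES = ("XX", "XXY")
MALE_TYPES = ("XY", "XYY")


@dataclass
class MSBParams:
    """Parameters of the deterministic recursion.

    rates
        Nondisjunction rates; ``mu_f``/``mu_m`` act in euploid parents and
        ``mu2_f``/``mu2_m`` in XXY/XYY parents.  Chromosome-loss rates are
        not part of the balance model (loss produces no Y-bearing
        aneuploids).
    w_xyy
        Relative viability of XYY males (1 - s_XYY).
    w_xxy
        Relative total fitness of XXY females, applied as a weight on
        their share of matings.
    """

    rates: RateSet = field(default_factory=RateSet)
    w_xyy: float = 1.0
    w_xxy: float = 1.0

    def __post_init__(self):
        if self.w_xyy < 0 or self.w_xxy < 0:
            raise ValueError("fitnesses must be >= 0")


@dataclass
class MSBSolution:
    """Result of an equilibrium solve or fitness inversion."""

    w_xxy: float
    f_xxy: float
    f_xyy: float
    female_freqs: np.ndarray
    male_freqs: np.ndarray
    iterations: int
    residual: float
    converged: bool


def _pair_tensor(rates: RateSet, w_xyy: float):
    """Survival-weighted offspring distributions per parental pair.

    Returns (F, M): ``F[i, j, k]`` is the probability that a mating of
    female type i with male type j yields a surviving female offspring of
    type k (and likewise M for male offspring).  Probabilities do not sum
    to 1; lethal classes and sterile X-null offspring are excluded from
    the reproductive accounting.
    """
    scheme = ViabilityScheme.simulation_default(w_xyy=w_xyy)
    F = np.zeros((2, 2, 2))
    M = np.zeros((2, 2, 2))
    for i, mname in enumerate(FEMALE_TYPES):
        for j, fname in enumerate(MALE_TYPES):
            zyg = zygote_distribution(Karyotype.from_name(mname),
                                      Karyotype.from_name(fname), rates)
            for kt, p in zyg.items():
                name = kt if isinstance(kt, str) else kt.name
                w = scheme[name]
                if w <= 0.0:
                    continue
                if name in FEMALE_TYPES:
                    F[i, j, FEMALE_TYPES.index(name)] += p * w
                elif name in MALE_TYPES:
                    M[i, j, MALE_TYPES.index(name)] += p * w
    return F, M


def recursion_step(female_freqs, male_freqs, params: MSBParams,
                   _tensors=None):
    """One generation of the deterministic recursion.

    ``female_freqs`` = (f_XX, f_XXY) and ``male_freqs`` = (f_XY, f_XYY),
    each summing to 1 within sex (vectorised over trailing dimensions:
    arrays of shape (2,) or (2, n)).

    Mothers are weighted by frequency times fecundity (w_xxy on XXY);
    fathers by frequency alone (XYY male reproductive success is normal);
    offspring survive per viability; the next generation's frequencies
    are renormalised within each sex.
    """
    ff = np.asarray(female_freqs, dtype=float)
    mf = np.asarray(male_freqs, dtype=float)
    if _tensors is None:
        _tensors = _pair_tensor(params.rates, params.w_xyy)
    F, M = _tensors

    wmat = np.array([1.0, params.w_xxy])
    u = ff * (wmat if ff.ndim == 1 else wmat[:, None])
    u = u / u.sum(axis=0)
    v = mf / mf.sum(axis=0)

    daughters = np.einsum("ijk,i...,j...->k...", F, u, v)
    sons = np.einsum("ijk,i...,j...->k...", M, u, v)
    dtot = daughters.sum(axis=0)
    stot = sons.sum(axis=0)
    if np.any(dtot <= 0) or np.any(stot <= 0):
        raise ValueError("degenerate recursion: a sex has zero survival")
    return daughters / dtot, sons / stot


def solve_equilibrium(params: MSBParams, start=None, tol: float = 1e-12,
                      max_iter: int = 1_000_000) -> MSBSolution:
    """Fixed-point iteration of the recursion to the stated tolerance.

    Convergence is measured as the maximum absolute change of any
    frequency in one step.
    """
    tensors = _pair_tensor(params.rates, params.w_xyy)
    if start is None:
        ff = np.array([1.0 - 1e-3, 1e-3])
        mf = np.array([1.0 - 1e-3, 1e-3])
    else:
        ff = np.asarray(start[0], dtype=float)
        mf = np.asarray(start[1], dtype=float)
    it = 0
    res = np.inf
    while it < max_iter:
        nff, nmf = recursion_step(ff, mf, params, _tensors=tensors)
        res = max(np.max(np.abs(nff - ff)), np.max(np.abs(nmf - mf)))
        ff, mf = nff, nmf
        it += 1
        if res < tol:
            break
    if res >= tol:
        raise RuntimeError(
            f"equilibrium iteration did not converge: residual {res:.3e} "
            f"after {it} iterations")
    return MSBSolution(
        w_xxy=params.w_xxy, f_xxy=float(ff[1]), f_xyy=float(mf[1]),
        female_freqs=ff, male_freqs=mf, iterations=it,
        residual=float(res), converged=True)


def invert_for_fitness(
    f_xxy_obs: float,
    w_xyy: float,
    rates: RateSet,
    *,
    bracket=(0.0, 2.0),
    tol: float = 1e-10,
) -> MSBSolution:
    """Solve for the XXY fitness that reproduces an observed frequency.

    Bisection on w_xxy over ``bracket``; the equilibrium XXY-among-females
    frequency is monotone increasing in w_xxy there, which is verified at
    the bracket ends.
    """
    if not 0.0 < f_xxy_obs < 1.0:
        raise ValueError("observed f_XXY must be in (0, 1)")

    def eq_freq(w):
        return solve_equilibrium(MSBParams(rates=rates, w_xyy=w_xyy, w_xxy=w))

    lo, hi = bracket
    sol_lo, sol_hi = eq_freq(lo), eq_freq(hi)
    if not sol_lo.f_xxy < sol_hi.f_xxy:
        raise RuntimeError("equilibrium frequency not increasing on bracket")
    if not sol_lo.f_xxy <= f_xxy_obs <= sol_hi.f_xxy:
        raise ValueError(
            f"no root in bracket: equilibrium f_XXY spans "
            f"[{sol_lo.f_xxy:.4g}, {sol_hi.f_xxy:.4g}], observed {f_xxy_obs:.4g}")
    sol = sol_lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        sol = eq_freq(mid)
        if sol.f_xxy < f_xxy_obs:
            lo = mid
        else:
            hi = mid
    return MSBSolution(
        w_xxy=0.5 * (lo + hi), f_xxy=sol.f_xxy, f_xyy=sol.f_xyy,
        female_freqs=sol.female_freqs, male_freqs=sol.male_freqs,
        iterations=sol.iterations, residual=sol.residual, converged=True)


def _vector_equilibrium(w_xxy, w_xyy, rates: RateSet, tol=1e-10,
                        max_iter=20000):
    """Equilibrium (f_xxy, f_xyy) vectorised over parameter draws.

    ``w_xxy`` and ``w_xyy`` are arrays of the same shape; the recursion
    runs on all draws simultaneously.  Draws whose fitnesses are invalid
    return NaN.
    """
    w_xxy = np.atleast_1d(np.asarray(w_xxy, dtype=float))
    w_xyy = np.atleast_1d(np.asarray(w_xyy, dtype=float))
    n = len(w_xxy)
    # tensors depend on w_xyy per draw: compose from viability-free parts
    scheme1 = ViabilityScheme.simulation_default(w_xyy=1.0)
    F = np.zeros((2, 2, 2))
    M0 = np.zeros((2, 2, 2))   # XY offspring only
    M1 = np.zeros((2, 2, 2))   # XYY offspring (pre-viability)
    for i, mname in enumerate(FEMALE_TYPES):
        for j, fname in enumerate(MALE_TYPES):
            zyg = zygote_distribution(Karyotype.from_name(mname),
                                      Karyotype.from_name(fname), rates)
            for kt, p in zyg.items():
                name = kt if isinstance(kt, str) else kt.name
                if scheme1[name] <= 0.0:
                    continue
                if name in FEMALE_TYPES:
                    F[i, j, FEMALE_TYPES.index(name)] += p
                elif name == "XY":
                    M0[i, j, 0] += p
                elif name == "XYY":
                    M1[i, j, 1] += p
    ff = np.tile(np.array([[1.0 - 1e-3], [1e-3]]), (1, n))
    mf = np.tile(np.array([[1.0 - 1e-3], [1e-3]]), (1, n))
    wm = np.vstack([np.ones(n), w_xxy])
    for it in range(max_iter):
        u = ff * wm
        u = u / u.sum(axis=0)
        v = mf / mf.sum(axis=0)
        daughters = np.einsum("ijk,in,jn->kn", F, u, v)
        sons = (np.einsum("ijk,in,jn->kn", M0, u, v)
                + np.einsum("ijk,in,jn->kn", M1, u, v) * w_xyy)
        nff = daughters / daughters.sum(axis=0)
        nmf = sons / sons.sum(axis=0)
        res = max(np.max(np.abs(nff - ff)), np.max(np.abs(nmf - mf)))
        ff, mf = nff, nmf
        if res < tol:
            break
    return ff[1], mf[1]


def _vector_invert(f_obs, w_xyy, rates: RateSet, tol=1e-6, n_bisect=40):
    """Vectorised bisection of w_xxy over many (f_obs, w_xyy) draws."""
    f_obs = np.atleast_1d(np.asarray(f_obs, dtype=float))
    w_xyy = np.atleast_1d(np.asarray(w_xyy, dtype=float))
    lo = np.zeros_like(f_obs)
    hi = np.full_like(f_obs, 2.0)
    f_lo, _ = _vector_equilibrium(lo, w_xyy, rates)
    f_hi, _ = _vector_equilibrium(hi, w_xyy, rates)
    ok = (f_lo <= f_obs) & (f_obs <= f_hi)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        f_mid, _ = _vector_equilibrium(mid, w_xyy, rates)
        below = f_mid < f_obs
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    w = 0.5 * (lo + hi)
    f_eq, g_eq = _vector_equilibrium(w, w_xyy, rates)
    w[~ok] = np.nan
    g_eq = np.where(ok, g_eq, np.nan)
    return w, g_eq


def credible_intervals(
    f_xxy_sample,
    w_xyy_sample,
    rates: RateSet,
    n: int = 50000,
    rng=None,
    level: float = 0.95,
) -> dict:
    """Propagate input posteriors through the fitness inversion.

    Pairs ``n`` random draws of the standing frequency (ABC posterior)
    with draws of the XYY viability (e.g. a truncated-normal posterior for
    s_XYY mapped to w = 1 - s), inverts each pair, and reports quantile
    intervals for w_XXY and f_XYY.  Failed inversions (observed frequency
    outside the attainable range) are excluded and counted.
    """
    rng = np.random.default_rng(rng)
    f_draws = rng.choice(np.asarray(f_xxy_sample, float), size=n, replace=True)
    w_draws = rng.choice(np.asarray(w_xyy_sample, float), size=n, replace=True)
    w_draws = np.clip(w_draws, 1e-6, None)
    f_draws = np.clip(f_draws, 1e-9, 1 - 1e-9)
    w_xxy, f_xyy = _vector_invert(f_draws, w_draws, rates)
    valid = np.isfinite(w_xxy)
    a = (1.0 - level) / 2.0
    q = [a, 0.5, 1.0 - a]
    wq = np.quantile(w_xxy[valid], q) if valid.any() else [np.nan] * 3
    gq = np.quantile(f_xyy[valid], q) if valid.any() else [np.nan] * 3
    return {
        "w_xxy": {"low": float(wq[0]), "median": float(wq[1]),
                  "high": float(wq[2])},
        "f_xyy": {"low": float(gq[0]), "median": float(gq[1]),
                  "high": float(gq[2])},
        "n_used": int(valid.sum()),
        "n_failed": int(n - valid.sum()),
    }
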