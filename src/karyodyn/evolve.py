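"""Forward simulation of karyotype frequencies in experimental populations.

Wright-Fisher-like dynamics with non-overlapping generations: each
offspring draws a fertile mother and a fertile father uniformly at random
(with replacement), receives a zygote karyotype from the gamete model, and
survives viability selection; draws repeat until the census size is
filled.  Conditional on the current adult composition, the surviving
offspring are therefore a multinomial sample from the mixture distribution
over parental pairs, which is how the simulator draws them.

The summary statistic for frequency change is the maximum-likelihood
logistic-regression slope of XXY-versus-XX female counts on generation
index, and one-tailed simulation p-values compare an observed slope with
the simulated null distribution ("at least as extreme" = as negative or
more negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .karyotype import (
    Karyotype,
    RateSet,
    ViabilityScheme,
    zygote_distribution,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "simulate_trajectory",
    "simulate_batch",
    "freq_change_stat",
    "logistic_slope",
    "simulation_pvalue",
]

# tracked adult classes (viable, ordered); females first
FEMALE_CLASSES = ("XX", "XXY")
MALE_CLASSES = ("XY", "XYY", "X0")
CLASSES = FEMALE_CLASSES + MALE_CLASSES
_FERTILE_F = np.array([True, True])
_FERTILE_M = np.array([True, True, False])  # X0 males are sterile


@dataclass
class SimConfig:
    """Configuration of one simulated experimental population.

    founder_females / founder_males
        Mapping karyotype name -> count (defaults: 60 XXY females and
        60 XY males, the experimental founding composition).
    census
        Adults per generation after regulation: a constant (default 287,
        the mean census of the experimental populations) or a vector with
        one entry per generation.
    n_generations
        Number of offspring generations (default 12).
    """

    founder_females: dict = field(default_factory=lambda: {"XXY": 60})
    founder_males: dict = field(default_factory=lambda: {"XY": 60})
    census: object = 287
    n_generations: int = 12
    rates: RateSet = field(default_factory=RateSet)
    scheme: ViabilityScheme = field(
        default_factory=lambda: ViabilityScheme.simulation_default())

    def census_at(self, gen: int) -> int:
        if np.isscalar(self.census):
            n = int(self.census)
        else:
            n = int(np.asarray(self.census)[min(gen - 1, len(self.census) - 1)])
        if n < 2:
            raise ValueError("census size must be >= 2")
        return n

    def founder_counts(self) -> np.ndarray:
        counts = np.zeros(len(CLASSES), dtype=np.int64)
        for name, k in self.founder_females.items():
            kt = Karyotype.from_name(name)
            if kt.sex != "female":
                raise ValueError(f"{name} is not a female karyotype")
            counts[CLASSES.index(kt.name)] += int(k)
        for name, k in self.founder_males.items():
            kt = Karyotype.from_name(name)
            if kt.sex != "male":
                raise ValueError(f"{name} is not a male karyotype")
            counts[CLASSES.index(kt.name)] += int(k)
        if counts[:2].sum() == 0 or counts[2:4].sum() == 0:
            raise ValueError("founders must include fertile flies of both sexes")
        return counts


@dataclass
class Trajectory:
    """Per-generation counts for one population (generation 0 = founders)."""

    counts: np.ndarray  # (n_gen+1, len(CLASSES))
    extinct: bool = False

    @property
    def n_xxy_females(self) -> np.ndarray:
        return self.counts[:, CLASSES.index("XXY")]

    @property
    def n_xx_females(self) -> np.ndarray:
        return self.counts[:, CLASSES.index("XX")]

    @property
    def xxy_frequency(self) -> np.ndarray:
        """XXY among females, NaN where no females exist."""
        females = self.counts[:, :2].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(females > 0, self.n_xxy_females / np.maximum(females, 1), np.nan)

    def to_frame(self, population: str = "pop1") -> pd.DataFrame:
        return pd.DataFrame({
            "population": population,
            "generation": np.arange(self.counts.shape[0]),
            "n_xxy_females": self.n_xxy_females,
            "n_xx_females": self.n_xx_females,
            "n_males_total": self.counts[:, 2:].sum(axis=1),
        })


def offspring_tensor(rates: RateSet, scheme: ViabilityScheme) -> np.ndarray:
    """Survival-weighted offspring distribution per fertile parental pair.

    Returns ``Z[i, j, k]`` = P(offspring class k AND survival | mother class
    i, father class j); entries do not sum to 1 over k, the deficit being
    inviable or lethal offspring.
    """
    Z = np.zeros((len(FEMALE_CLASSES), len(MALE_CLASSES), len(CLASSES)))
    for i, mname in enumerate(FEMALE_CLASSES):
        for j, fname in enumerate(MALE_CLASSES):
            if not _FERTILE_M[j]:
                continue
            zyg = zygote_distribution(Karyotype.from_name(mname),
                                      Karyotype.from_name(fname), rates)
            for kt, p in zyg.items():
                name = kt if isinstance(kt, str) else kt.name
                w = scheme[name]
                if w <= 0.0:
                    continue
                if name in CLASSES:
                    Z[i, j, CLASSES.index(name)] += p * w
    return Z


def _offspring_probs(counts: np.ndarray, Z: np.ndarray) -> np.ndarray | None:
    """Normalized surviving-offspring distribution given adult counts.

    ``counts`` may be a single state vector or a batch (reps, n_classes).
    Returns None (or NaN rows) when no fertile pair exists.
    """
    single = counts.ndim == 1
    c = np.atleast_2d(counts).astype(float)
    fem = c[:, :2]
    male = c[:, 2:] * _FERTILE_M
    fem_tot = fem.sum(axis=1, keepdims=True)
    male_tot = male.sum(axis=1, keepdims=True)
    ok = (fem_tot[:, 0] > 0) & (male_tot[:, 0] > 0)
    pf = np.divide(fem, fem_tot, out=np.zeros_like(fem), where=fem_tot > 0)
    pm = np.divide(male, male_tot, out=np.zeros_like(male), where=male_tot > 0)
    mix = np.einsum("ri,rj,ijk->rk", pf, pm, Z)
    tot = mix.sum(axis=1, keepdims=True)
    ok &= tot[:, 0] > 0
    probs = np.divide(mix, tot, out=np.full_like(mix, np.nan), where=tot > 0)
    probs[~ok] = np.nan
    return probs[0] if single else probs


def simulate_trajectory(config: SimConfig, rng=None) -> Trajectory:
    """Simulate one population; returns counts per generation.

    On extinction (no fertile pair) the trajectory is truncated and
    flagged.
    """
    rng = np.random.default_rng(rng)
    Z = offspring_tensor(config.rates, config.scheme)
    state = config.founder_counts()
    out = [state.copy()]
    extinct = False
    for gen in range(1, config.n_generations + 1):
        probs = _offspring_probs(state, Z)
        if np.any(np.isnan(probs)):
            extinct = True
            break
        state = rng.multinomial(config.census_at(gen), probs)
        out.append(state.copy())
    return Trajectory(counts=np.array(out), extinct=extinct)


def simulate_batch(config: SimConfig, n_reps: int, rng=None) -> tuple:
    """Simulate many replicate populations at once.

    Returns ``(counts, alive)`` where counts has shape
    ``(n_reps, n_gen+1, n_classes)`` and ``alive`` flags replicates that
    never went extinct.  Extinct replicates keep zero counts from the
    generation of extinction onward.

    Equivalent in distribution to repeated :func:`simulate_trajectory`
    (all replicates advance through one multinomial draw per generation).
    """
    rng = np.random.default_rng(rng)
    Z = offspring_tensor(config.rates, config.scheme)
    state = np.tile(config.founder_counts(), (n_reps, 1))
    alive = np.ones(n_reps, dtype=bool)
    hist = [state.copy()]
    for gen in range(1, config.n_generations + 1):
        probs = _offspring_probs(state, Z)
        dead = np.isnan(probs).any(axis=1)
        alive &= ~dead
        safe = np.where(alive[:, None], probs, 1.0 / probs.shape[1])
        draws = rng.multinomial(config.census_at(gen), safe)
        state = np.where(alive[:, None], draws, 0)
        hist.append(state.copy())
    return np.stack(hist, axis=1), alive


def logistic_slope(successes, totals, gens, tol=1e-10, max_iter=200):
    """Newton-Raphson ML slope of a binomial logistic regression.

    Supports batched input: ``successes``/``totals`` of shape
    (reps, n_gen).  Returns the slope per replicate (scalar for 1-D
    input); +/-inf under complete separation (detected as divergence).
    """
    y = np.atleast_2d(np.asarray(successes, dtype=float))
    n = np.atleast_2d(np.asarray(totals, dtype=float))
    g = np.asarray(gens, dtype=float)
    single = np.asarray(successes).ndim == 1

    mask = n > 0
    beta0 = np.zeros(y.shape[0])
    beta1 = np.zeros(y.shape[0])
    for _ in range(max_iter):
        eta = beta0[:, None] + beta1[:, None] * g
        eta = np.clip(eta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.where(mask, n * p * (1 - p), 0.0)
        r = np.where(mask, y - n * p, 0.0)
        s0 = r.sum(axis=1)
        s1 = (r * g).sum(axis=1)
        a = w.sum(axis=1)
        b = (w * g).sum(axis=1)
        c = (w * g * g).sum(axis=1)
        det = a * c - b * b
        ok = det > 1e-12
        d0 = np.where(ok, (c * s0 - b * s1) / np.where(ok, det, 1.0), 0.0)
        d1 = np.where(ok, (a * s1 - b * s0) / np.where(ok, det, 1.0), 0.0)
        beta0 += d0
        beta1 += d1
        if np.max(np.abs(d1)) < tol and np.max(np.abs(d0)) < tol:
            break
    # flag separation / divergence as signed infinity
    runaway = np.abs(beta1) > 30
    if runaway.any():
        beta1 = beta1.copy()
        beta1[runaway] = np.sign(beta1[runaway]) * np.inf
    return beta1[0] if single else beta1


def freq_change_stat(traj) -> float:
    """Logistic-regression slope of XXY-vs-XX female counts on generation.

    Accepts a :class:`Trajectory` or a data frame with columns
    ``generation``, ``n_xxy_females``, ``n_xx_females`` (one or more
    populations pooled).  Founder generation 0 is excluded; the
    experimental observations start at the first offspring generation.
    """
    if isinstance(traj, Trajectory):
        df = traj.to_frame()
    else:
        df = traj
    df = df[df["generation"] >= 1]
    if df["generation"].nunique() < 2:
        raise ValueError("need at least two generations with females")
    y = df["n_xxy_females"].to_numpy(float)
    n = y + df["n_xx_females"].to_numpy(float)
    g = df["generation"].to_numpy(float)
    # pool across populations by fitting one shared regression
    mask = n > 0
    if mask.sum() < 2:
        raise ValueError("need at least two generations with females")
    # batched solver expects aligned design; use a single row
    return float(logistic_slope(y[mask][None, :], n[mask][None, :], g[mask])[0])


def batch_slopes(counts: np.ndarray) -> np.ndarray:
    """Slopes for a batch of simulated trajectories (founders excluded)."""
    xxy = counts[:, 1:, CLASSES.index("XXY")]
    xx = counts[:, 1:, CLASSES.index("XX")]
    gens = np.arange(1, counts.shape[1])
    return logistic_slope(xxy, xxy + xx, gens)


def simulation_pvalue(
    observed_stat: float,
    config: SimConfig,
    n_sims: int = 10000,
    rng=None,
    observed_final_freq: float | None = None,
) -> dict:
    """One-tailed simulation p-values for the observed frequency decline.

    Returns a dict with:

    ``p_slope``
        Fraction of simulated populations whose logistic slope is <= the
        observed slope (as negative or more).
    ``p_final_freq``
        Fraction whose final-generation XXY-among-females frequency is <=
        the observed final frequency (when given).
    ``n_extinct``
        Number of replicates excluded because the population went extinct.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(rng)
    counts, alive = simulate_batch(config, n_sims, rng)
    slopes = batch_slopes(counts[alive])
    finite = ~np.isnan(slopes)
    slopes = slopes[finite]
    out = {
        "p_slope": float(np.mean(slopes <= observed_stat)) if len(slopes) else np.nan,
        "n_sims": int(n_sims),
        "n_used": int(len(slopes)),
        "n_extinct": int(n_sims - alive.sum()),
    }
    if observed_final_freq is not None:
        fem = counts[alive][:, -1, :2].sum(axis=1)
        xxy = counts[alive][:, -1, CLASSES.index("XXY")]
        with np.errstate(invalid="ignore"):
            final = np.where(fem > 0, xxy / np.maximum(fem, 1), np.nan)
        final = final[~np.isnan(final)]
        out["p_final_freq"] = float(np.mean(final <= observed_final_freq))
    return out
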