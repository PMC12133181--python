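"""Rejection ABC for the standing XXY frequency among females.

Two detection assays are modelled.  In the test-cross assay a sampled
female is crossed to compound-X-Y males; if she is XX all her sons are
X-null and sterile, while an XXY female produces fertile (XY) sons at
Mendelian frequency 1/2, so testing k sons misses her with probability
0.5^k.  In the PCR assay detection is taken as perfect.

The posterior for the standing frequency f is obtained by exact-match
rejection sampling: draw f from the prior, simulate both assays, and keep
the draw iff the simulated detection counts equal the observed pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DetectionAssay",
    "ABCResult",
    "simulate_detection",
    "abc_posterior",
    "read_detection_table",
    "detection_probability",
]


@dataclass
class DetectionAssay:
    """One detection assay.

    method
        'testcross' (imperfect: per-family miss probability 0.5^k) or
        'pcr' (perfect detection).
    n_females
        Number of females sampled.
    k_tested
        For the test cross: number of sons tested per family (the
        empirical list; resampled with replacement per simulation).
    """

    method: str
    n_females: int
    k_tested: np.ndarray | None = None

    def __post_init__(self):
        if self.method not in ("testcross", "pcr"):
            raise ValueError("method must be 'testcross' or 'pcr'")
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if self.method == "testcross":
            if self.k_tested is None or len(self.k_tested) == 0:
                raise ValueError("testcross assay needs a k_tested list")
            self.k_tested = np.asarray(self.k_tested, dtype=int)
            if (self.k_tested < 1).any():
                raise ValueError("all k_tested must be >= 1")

    @property
    def mean_detection(self) -> float:
        """Mean per-XXY-family detection probability, E[1 - 0.5^k]."""
        if self.method == "pcr":
            return 1.0
        return float(np.mean(1.0 - 0.5 ** self.k_tested))


def detection_probability(k: int) -> float:
    """Probability that a test-cross family with k tested sons is detected."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 1.0 - 0.5 ** k


def simulate_detection(f: float, assay: DetectionAssay, rng=None) -> int:
    """Simulate the number of detected XXY females in one assay.

    Draws the number of XXY females n ~ Binomial(n_females, f); for the
    test cross each XXY family draws k from the empirical list (with
    replacement) and is detected iff at least one of Binomial(k, 1/2)
    sons is fertile.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    rng = np.random.default_rng(rng)
    n = rng.binomial(assay.n_females, f)
    if assay.method == "pcr" or n == 0:
        return int(n)
    ks = rng.choice(assay.k_tested, size=n, replace=True)
    fertile_sons = rng.binomial(ks, 0.5)
    return int(np.count_nonzero(fertile_sons))


@dataclass
class ABCResult:
    """Posterior sample of the standing XXY frequency."""

    sample: np.ndarray
    acceptance_rate: float
    n_proposed: int
    prior_max: float
    observed: tuple
    seed: object = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.sample))

    def credible_interval(self, level: float = 0.95) -> tuple:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.sample, [a, 1.0 - a])
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.credible_interval()
        return {
            "mean": self.mean,
            "ci_low": lo,
            "ci_high": hi,
            "n_accepted": int(len(self.sample)),
            "acceptance_rate": self.acceptance_rate,
        }


def abc_posterior(
    assays,
    observed=(1, 1),
    prior_max: float = 0.1,
    n_accept: int = 50000,
    rng=None,
    batch_size: int = 200000,
    max_proposals: int = 500_000_000,
) -> ABCResult:
    """Exact-match rejection ABC posterior for the standing frequency.

    Draws f ~ Uniform(0, prior_max) and retains draws whose simulated
    detection counts equal ``observed`` in every assay, until ``n_accept``
    draws are retained.

    Because test-cross families draw their k values independently from the
    empirical list, the detected count given n XXY families is exactly
    Binomial(n, E[1 - 0.5^k]); the sampler uses this marginal form, which
    is distributionally identical to simulating each family (see
    :func:`simulate_detection`) and much faster.
    """
    if len(assays) != len(observed):
        raise ValueError("need one observed count per assay")
    if prior_max <= 0:
        raise ValueError("empty prior support")
    rng = np.random.default_rng(rng)
    seed_repr = None

    dprobs = [a.mean_detection for a in assays]
    kept = []
    n_prop = 0
    n_acc = 0
    while n_acc < n_accept:
        if n_prop >= max_proposals:
            rate = n_acc / max(n_prop, 1)
            raise RuntimeError(
                f"ABC acceptance rate {rate:.2e} too low after {n_prop} "
                f"proposals ({n_acc} accepted)")
        f = rng.uniform(0.0, prior_max, size=batch_size)
        ok = np.ones(batch_size, dtype=bool)
        for assay, d, obs in zip(assays, dprobs, observed):
            n_xxy = rng.binomial(assay.n_females, f)
            detected = rng.binomial(n_xxy, d) if d < 1.0 else n_xxy
            ok &= detected == obs
        kept.append(f[ok])
        n_prop += batch_size
        n_acc += int(ok.sum())
    sample = np.concatenate(kept)[:n_accept]
    return ABCResult(
        sample=sample,
        acceptance_rate=n_acc / n_prop,
        n_proposed=n_prop,
        prior_max=prior_max,
        observed=tuple(observed),
        seed=seed_repr,
    )


def read_detection_table(path_or_df) -> tuple:
    """Build assays and observed counts from a detection table.

    Expected columns: ``family_id``, ``method`` in {testcross, pcr},
    ``k_tested`` (sons tested; ignored for pcr) and ``detected`` in
    {0, 1}.  Returns ``(assays, observed)`` ordered testcross first.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(
        path_or_df, sep=None, engine="python")
    required = {"family_id", "method", "detected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    assays, observed = [], []
    for method in ("testcross", "pcr"):
        sub = df[df["method"] == method]
        if sub.empty:
            continue
        if sub["family_id"].duplicated().any():
            raise ValueError(f"duplicate family ids in {method} assay")
        k = sub["k_tested"].to_numpy(int) if method == "testcross" else None
        assays.append(DetectionAssay(method=method, n_females=len(sub),
                                     k_tested=k))
        observed.append(int(sub["detected"].sum()))
    if not assays:
        raise ValueError("no recognized assay rows")
    return assays, tuple(observed)
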