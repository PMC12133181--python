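"""Synthetic-data generators for every input the pipeline consumes.

Each generator draws from the same probability model the corresponding
analysis assumes — multinomial offspring classes from the gamete model,
finite-population trajectories from the forward simulator, detection
outcomes from the binomial detection model — so estimator-recovery and
coverage properties can be tested end to end without any external data.

Defaults mirror the study conditions: nondisjunction/loss rates as in the
combined ML fit, XYY viability 0.79, standing XXY frequency 0.0133,
38178-scale offspring counts, 158 test-cross families (sons tested 1-6,
mean 4.9) plus 75 PCR females, and 3 populations of census 287 founded
with 60 XXY females and 60 XY males.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abc import DetectionAssay
from .evolve import SimConfig, simulate_trajectory
from .inference import CountTable, class_probabilities
from .karyotype import CrossDesign, RateSet, ViabilityScheme

__all__ = [
    "GeneratorSpec",
    "PAPER_RATES",
    "default_k_tested",
    "gen_cross_counts",
    "gen_detection_data",
    "gen_evolution_data",
]

#: rates reproducing the published sex-specific estimates
PAPER_RATES = RateSet(mu_f=1.49e-3, mu_m=5.79e-4,
                      lambda_f=6.30e-3, lambda_m=5.50e-5)


def default_k_tested() -> np.ndarray:
    """Sons-tested-per-family multiset: n = 158, total 775, mean 4.905."""
    return np.repeat([6, 5, 4, 3, 2, 1], [80, 30, 20, 14, 9, 5])


@dataclass
class GeneratorSpec:
    """Scenario definition shared by the generators.

    All truths are recorded so tests can compare estimates against them;
    the seed is mandatory for reproducibility.
    """

    seed: int
    rates: RateSet = field(default_factory=lambda: PAPER_RATES)
    scheme: ViabilityScheme = field(default_factory=ViabilityScheme)
    f_xxy: float = 0.0133
    n_offspring: int = 38178
    n_blocks: int = 1
    n_testcross: int = 158
    n_pcr: int = 75
    k_tested: np.ndarray = field(default_factory=default_k_tested)

    def metadata(self) -> dict:
        return {
            "seed": int(self.seed),
            "rates": {k: getattr(self.rates, k) for k in
                      ("mu_f", "mu_m", "lambda_f", "lambda_m",
                       "mu2_f", "mu2_m")},
            "f_xxy": self.f_xxy,
            "n_offspring": self.n_offspring,
        }


def gen_cross_counts(design: CrossDesign, spec: GeneratorSpec,
                     assay_id: str = "assay1", rng=None) -> CountTable:
    """Multinomial offspring class counts for one cross design.

    ``spec.n_offspring`` flies are drawn from the design's scored-class
    probabilities at the true rates, optionally split evenly over
    ``spec.n_blocks`` blocks.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    probs = class_probabilities(design, spec.rates, spec.scheme)
    classes = list(probs)
    p = np.array([probs[c] for c in classes])
    per_block = np.full(spec.n_blocks, spec.n_offspring // spec.n_blocks)
    per_block[: spec.n_offspring % spec.n_blocks] += 1
    rows = []
    for b, n in enumerate(per_block):
        draw = rng.multinomial(int(n), p)
        for cls, k in zip(classes, draw):
            rows.append(dict(assay_id=assay_id, block=f"b{b + 1}",
                             phenotype_class=cls, count=int(k)))
    return CountTable(pd.DataFrame(rows))


def gen_detection_data(spec: GeneratorSpec, rng=None) -> pd.DataFrame:
    """Detection-assay table at the true standing frequency.

    Families are assigned the XXY karyotype with probability
    ``spec.f_xxy``; test-cross families are detected iff at least one of
    their tested sons (Binomial(k, 1/2)) is fertile, PCR females always.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    ks = np.asarray(spec.k_tested, dtype=int)
    if len(ks) != spec.n_testcross:
        ks = rng.choice(ks, size=spec.n_testcross, replace=True)
    rows = []
    is_xxy = rng.random(spec.n_testcross) < spec.f_xxy
    fertile = rng.binomial(ks, 0.5)
    for i in range(spec.n_testcross):
        rows.append(dict(family_id=f"tc{i + 1:03d}", method="testcross",
                         k_tested=int(ks[i]),
                         detected=int(is_xxy[i] and fertile[i] > 0)))
    pcr_xxy = rng.random(spec.n_pcr) < spec.f_xxy
    for i in range(spec.n_pcr):
        rows.append(dict(family_id=f"pcr{i + 1:03d}", method="pcr",
                         k_tested=0, detected=int(pcr_xxy[i])))
    return pd.DataFrame(rows)


def gen_evolution_data(spec: GeneratorSpec, config: SimConfig | None = None,
                       n_populations: int = 3, rng=None) -> pd.DataFrame:
    """Replicate experimental-evolution trajectories as a tidy table.

    Wraps the forward simulator; founder generation 0 is omitted, as in
    the experimental records (scoring starts with the first offspring
    generation).
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    if config is None:
        config = SimConfig(rates=spec.rates,
                           scheme=ViabilityScheme.simulation_default(
                               w_xyy=spec.scheme.w_xyy,
                               w_xxy=spec.scheme.w_xxy))
    frames = []
    for p in range(n_populations):
        traj = simulate_trajectory(config, rng=rng.spawn(1)[0])
        df = traj.to_frame(population=f"pop{p + 1}")
        frames.append(df[df["generation"] >= 1])
    return pd.concat(frames, ignore_index=True)
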