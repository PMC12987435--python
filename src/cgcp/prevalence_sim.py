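"""Permutation simulator for the prevalence / combination-frequency relationship.

The disease model behind the simulation: three causal genotype combinations
of sizes 4, 5 and 6 with per-genotype population frequencies
a1..a4, b1..b5, c1..c6 (fifteen values in (0,1), genotypes independent), so
the disease prevalence is

    P = a1*a2*a3*a4 + b1*...*b5 + c1*...*c6.

An exhaustive 3-genotype search over these groups would report the 34
within-group triples (C(4,3) + C(5,3) + C(6,3) = 4 + 10 + 20); their mean
product frequency X-bar is the predictor.  Each simulation test draws N
populations, computes (X-bar, P) per population, fits ordinary least squares
of P on X-bar, and records the slope, p-value and R^2; the headline outputs
are the proportions of tests with p < 0.05 and with R^2 > 0.5 over (by
default) 1000 tests.

Four population models:

* ``complete_random`` — every population's 15 frequencies i.i.d. uniform(0,1),
  independent across populations (no shared genetic structure).
* ``constrained`` — population 1 is a uniform(0,1) reference; every other
  population's value j is uniform on [ref_j*(1-fluct), ref_j*(1+fluct)]
  (default fluct = 0.20), clipped to (0,1) — related populations whose
  frequencies float around a common ancestor.
* ``constrained_lost`` — constrained, plus one random subset of
  floor(lost_fraction*34) triples removed from X-bar in *all* populations
  (combinations the search failed to report; Type-II error noise).
* ``constrained_lost_mixed`` — additionally floor(mixed_fraction*34) fake
  triples are appended to X-bar (but never enter P): spurious combinations a
  finite control cohort lets through (Type-I error noise).  Each fake triple
  gets a reference value that is a product of three fresh uniforms and
  fluctuates per population exactly like a real value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as iter_combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

MODELS = ("complete_random", "constrained", "constrained_lost", "constrained_lost_mixed")

#: index groups of the three causal combinations within the 15-vector
GROUP_SLICES = (slice(0, 4), slice(4, 9), slice(9, 15))

#: the 34 within-group 3-subsets, canonical order (group a, b, c; lexicographic)
TRIPLE_INDEX: np.ndarray = np.array(
    [t for sl in GROUP_SLICES for t in iter_combinations(range(sl.start, sl.stop), 3)],
    dtype=int,
)
N_TRIPLES: int = TRIPLE_INDEX.shape[0]  # 34

_EPS = 1e-12  # open-interval clipping bound for constrained draws


@dataclass(frozen=True)
class CausalFrequencySet:
    """The 15 causal genotype frequencies of one population (groups of 4, 5, 6)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 15:
            raise ValueError("a causal frequency set has exactly 15 values")
        if not all(0.0 < v < 1.0 for v in self.values):
            raise ValueError("all frequencies must lie strictly in (0,1)")

    @property
    def a(self) -> tuple[float, ...]:
        return self.values[0:4]

    @property
    def b(self) -> tuple[float, ...]:
        return self.values[4:9]

    @property
    def c(self) -> tuple[float, ...]:
        return self.values[9:15]


def population_prevalence(s: CausalFrequencySet) -> float:
    """P = prod(a) + prod(b) + prod(c): the summed frequencies of the causal combinations."""
    v = np.asarray(s.values)
    return float(sum(v[sl].prod() for sl in GROUP_SLICES))


def triple_frequencies(s: CausalFrequencySet) -> np.ndarray:
    """The 34 within-group 3-genotype product frequencies, canonical order."""
    v = np.asarray(s.values)
    return v[TRIPLE_INDEX].prod(axis=1)


@dataclass
class SimModelConfig:
    """One simulation scenario.

    fluctuation is the relative half-width of the constrained draw (0.20 =
    within +/-20% of the reference value); lost_fraction and mixed_fraction
    are the shares of the 34 triples removed from / appended to X-bar and
    must be zero for models that do not use them.
    """

    model: str
    n_populations: int
    n_tests: int = 1000
    fluctuation: float = 0.20
    lost_fraction: float = 0.0
    mixed_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations per test")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if not 0.0 <= self.fluctuation < 1.0:
            raise ValueError("fluctuation must lie in [0,1)")
        if not 0.0 <= self.lost_fraction < 1.0:
            raise ValueError("lost_fraction must lie in [0,1)")
        if self.mixed_fraction < 0.0:
            raise ValueError("mixed_fraction must be >= 0")
        if self.model in ("complete_random", "constrained") and self.lost_fraction:
            raise ValueError(f"{self.model} does not use lost_fraction")
        if self.model != "constrained_lost_mixed" and self.mixed_fraction:
            raise ValueError(f"{self.model} does not use mixed_fraction")


@dataclass
class PopulationDraw:
    """One test's populations plus loss/mixing bookkeeping."""

    populations: list[CausalFrequencySet]
    lost_triples: np.ndarray          # indices into the 34 removed from X-bar
    fake_frequencies: np.ndarray      # (N, n_fake) appended to X-bar, never in P

    @property
    def n_populations(self) -> int:
        return len(self.populations)


def generate_populations(cfg: SimModelConfig,
                         rng: np.random.Generator | None = None) -> PopulationDraw:
    """Draw one test's N populations under the configured model."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    N = cfg.n_populations
    if cfg.model == "complete_random":
        values = rng.uniform(size=(N, 15))
        lost = np.empty(0, dtype=int)
        fakes = np.empty((N, 0))
    else:
        ref = rng.uniform(size=15)
        values = np.empty((N, 15))
        values[0] = ref
        lo = ref * (1.0 - cfg.fluctuation)
        hi = ref * (1.0 + cfg.fluctuation)
        values[1:] = rng.uniform(lo, hi, size=(N - 1, 15)).clip(_EPS, 1.0 - _EPS)
        n_lost = int(cfg.lost_fraction * N_TRIPLES)
        lost = (np.sort(rng.choice(N_TRIPLES, size=n_lost, replace=False))
                if n_lost else np.empty(0, dtype=int))
        n_fake = int(cfg.mixed_fraction * N_TRIPLES)
        if n_fake:
            fake_ref = rng.uniform(size=(n_fake, 3)).prod(axis=1)
            flo = fake_ref * (1.0 - cfg.fluctuation)
            fhi = fake_ref * (1.0 + cfg.fluctuation)
            fakes = rng.uniform(flo, fhi, size=(N, n_fake)).clip(_EPS, 1.0)
            fakes[0] = fake_ref
        else:
            fakes = np.empty((N, 0))
    values = values.clip(_EPS, 1.0 - _EPS)
    pops = [CausalFrequencySet(tuple(row)) for row in values]
    return PopulationDraw(populations=pops, lost_triples=lost, fake_frequencies=fakes)


def mean_triple_frequency(draw: PopulationDraw) -> np.ndarray:
    """Per-population X-bar: mean over surviving real triples plus fake triples."""
    real = np.stack([triple_frequencies(s) for s in draw.populations])  # (N, 34)
    if draw.lost_triples.size:
        keep = np.setdiff1d(np.arange(N_TRIPLES), draw.lost_triples)
        real = real[:, keep]
    combined = np.concatenate([real, draw.fake_frequencies], axis=1)
    return combined.mean(axis=1)


@dataclass
class SimTestResult:
    """Per-test regression records and the two headline proportions."""

    config: SimModelConfig
    records: pd.DataFrame  # columns: slope, intercept, r_squared, p_value, degenerate
    prop_p_lt_05: float
    prop_r2_gt_05: float
    n_degenerate: int

    @property
    def n_valid(self) -> int:
        return len(self.records) - self.n_degenerate


def run_simulation(cfg: SimModelConfig) -> SimTestResult:
    """Run n_tests independent tests and aggregate significance proportions.

    Each test regresses P on X-bar across the N populations.  A degenerate
    test (zero variance in X-bar, e.g. fluctuation = 0) is recorded with NaN
    statistics and counted as non-significant rather than masked.  Per-test
    RNG streams are spawned deterministically from the top-level seed.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_tests)
    rows = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        draw = generate_populations(cfg, rng)
        x = mean_triple_frequency(draw)
        y = np.array([population_prevalence(s) for s in draw.populations])
        if np.allclose(x, x[0]):
            rows.append((np.nan, np.nan, np.nan, np.nan, True))
            continue
        fit = sps.linregress(x, y)
        rows.append((fit.slope, fit.intercept, fit.rvalue ** 2, fit.pvalue, False))
    records = pd.DataFrame(
        rows, columns=["slope", "intercept", "r_squared", "p_value", "degenerate"]
    )
    n_deg = int(records["degenerate"].sum())
    prop_p = float((records["p_value"] < 0.05).sum() / len(records))
    prop_r2 = float((records["r_squared"] > 0.5).sum() / len(records))
    return SimTestResult(
        config=cfg,
        records=records,
        prop_p_lt_05=prop_p,
        prop_r2_gt_05=prop_r2,
        n_degenerate=n_deg,
    )


def slope_sign_summary(result: SimTestResult | pd.DataFrame) -> float:
    """Fraction of (non-degenerate) per-test slopes that are positive."""
    records = result.records if isinstance(result, SimTestResult) else result
    slopes = records["slope"].to_numpy(dtype=float)
    valid = ~np.isnan(slopes)
    if not valid.any():
        return float("nan")
    return float((slopes[valid] > 0).sum() / valid.sum())
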