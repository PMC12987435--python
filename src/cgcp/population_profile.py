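"""Project combinations onto a multi-population panel and relate frequency to prevalence.

For each discovered combination and each population in a reference panel the
carrier frequency (fraction of samples carrying all r genotypes at once) is
computed; per-population mean and median frequencies are then correlated with
epidemiological disease prevalence via Pearson correlation and ordinary
least-squares regression.  Combinations with variants absent from the panel
are skipped and reported, mirroring the attrition that occurs when projecting
exome discoveries onto an external panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cgcp_core import Combination, GenotypeKey
from .genotype_io import PopulationPanel


@dataclass
class FrequencyProfile:
    """Combination x population carrier-frequency matrix plus attrition record."""

    frequencies: pd.DataFrame  # rows combo_key, columns population codes
    skipped: list[str]         # combo keys dropped for missing panel variants

    def __post_init__(self) -> None:
        vals = self.frequencies.to_numpy(dtype=float)
        if vals.size and ((vals < 0) | (vals > 1)).any():
            raise ValueError("frequencies must lie in [0,1]")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    pearson_r: float
    pearson_p: float
    r_squared: float
    n: int


def combination_frequency(panel: PopulationPanel,
                          combination: Combination | Sequence[GenotypeKey],
                          method: str = "joint") -> dict[str, float]:
    """Per-population frequency of a combination in the panel.

    method="joint" (default): observed co-occurrence — the fraction of
    samples carrying all r genotypes simultaneously (MISSING never matches).
    method="marginal_product": product of the per-variant genotype
    frequencies, an independence approximation.

    Raises KeyError if any variant is absent from the panel; profile-level
    code catches this and records the attrition.
    """
    keys = combination.keys if isinstance(combination, Combination) else tuple(combination)
    if method not in ("joint", "marginal_product"):
        raise ValueError(f"unknown method {method!r}")
    matrix = panel.matrix
    cols = [matrix.variant_index(k.variant_id) for k in keys]  # KeyError if absent
    out: dict[str, float] = {}
    for pop in panel.populations:
        idx = panel.sample_indices(pop)
        sub = matrix.genotypes[np.ix_(idx, cols)]
        if method == "joint":
            carries = np.ones(idx.size, dtype=bool)
            for c, key in enumerate(keys):
                carries &= sub[:, c] == key.genotype_code
            out[pop] = float(carries.sum() / idx.size)
        else:
            freqs = [
                float((sub[:, c] == key.genotype_code).sum() / idx.size)
                for c, key in enumerate(keys)
            ]
            out[pop] = float(np.prod(freqs))
    return out


def frequency_profile(panel: PopulationPanel,
                      combinations: Iterable[Combination],
                      method: str = "joint") -> FrequencyProfile:
    """Frequencies of many combinations; absent-variant combinations are skipped."""
    rows: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    for combo in combinations:
        try:
            rows[combo.combo_key] = combination_frequency(panel, combo, method=method)
        except KeyError:
            skipped.append(combo.combo_key)
    if skipped:
        warnings.warn(
            f"{len(skipped)} combination(s) skipped: variants absent from panel",
            stacklevel=2,
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    if not df.empty:
        df = df[sorted(df.columns)]
    return FrequencyProfile(frequencies=df, skipped=skipped)


def summarize(profile: FrequencyProfile, statistic: str = "median") -> dict[str, float]:
    """Per-population mean or median frequency over combinations."""
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if profile.frequencies.empty:
        return {}
    agg = profile.frequencies.mean(axis=0) if statistic == "mean" \
        else profile.frequencies.median(axis=0)
    return {pop: float(v) for pop, v in agg.items()}


def correlate_and_fit(summary: Mapping[str, float],
                      prevalence: Mapping[str, float],
                      percent_y: bool = True) -> RegressionResult:
    """Pearson correlation and OLS of prevalence (y) on summary frequency (x).

    Populations are matched by code; at least three shared populations are
    required.  Prevalences are proportions; with ``percent_y`` (default) the
    regression is reported with y on the percentage scale, the scale on which
    epidemiological prevalences are usually quoted.  The slope CI is the
    standard 95% t-interval with n - 2 degrees of freedom.
    """
    common = sorted(set(summary) & set(prevalence))
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 populations shared between frequency summary and "
            f"prevalence table, got {len(common)}: {common}"
        )
    x = np.array([summary[p] for p in common], dtype=float)
    y = np.array([prevalence[p] for p in common], dtype=float)
    if percent_y:
        y = y * 100.0
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate input: zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, len(common) - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci95=(float(ci[0]), float(ci[1])),
        pearson_r=float(r),
        pearson_p=float(p),
        r_squared=float(fit.rvalue ** 2),
        n=len(common),
    )
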