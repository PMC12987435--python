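"""Per-variant QC and case/control association screening.

Produces the candidate SNP set handed to the combination search.  The screen
is deliberately conventional: call rate, minor allele frequency, an exact
Hardy-Weinberg test in controls, and an allelic 2x2 chi-square comparing alt
allele counts between cases and controls (genotypic 2x3 test available by
flag).  All thresholds are configurable; the defaults are an explicit
stand-in for an upstream study's unpublished quality-control standards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class VariantStats:
    variant_id: str
    call_rate: float
    maf: float
    hwe_p: float
    assoc_p: float
    odds_ratio: float
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined:
            if not (0.0 <= self.call_rate <= 1.0 and 0.0 <= self.maf <= 1.0):
                raise ValueError("call_rate and maf must lie in [0,1]")
            if not (0.0 < self.hwe_p <= 1.0 and 0.0 < self.assoc_p <= 1.0):
                raise ValueError("p-values must lie in (0,1]")


@dataclass
class AssociationConfig:
    """QC/association thresholds (stand-in defaults, all configurable)."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    max_assoc_p: float = 1e-3
    test: str = "allelic"  # or "genotypic"

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p", "max_assoc_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.test not in ("allelic", "genotypic"):
            raise ValueError(f"unknown association test {self.test!r}")


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value (Wigginton-style enumeration).

    Sums the probabilities of all heterozygote counts compatible with the
    observed allele counts that are no more probable than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # log multinomial probability of each het count compatible with the allele counts
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1) - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:  # inconsistent genotype counts cannot occur from real data
        return 1.0
    return float(min(1.0, p[p <= p[obs[0]] * (1 + 1e-12)].sum()))


def _allele_counts(geno_col: np.ndarray) -> tuple[int, int]:
    """(alt, ref) allele counts among non-missing calls."""
    called = geno_col[geno_col != MISSING]
    alt = int(called.sum())
    return alt, int(2 * called.size - alt)


def _chi2_p(table: np.ndarray) -> float:
    """Pearson chi-square p (no continuity correction); p = 1 on degenerate margins."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(p)


def compute_variant_stats(matrix: GenotypeMatrix,
                          config: AssociationConfig | None = None) -> list[VariantStats]:
    """Per-variant call rate, MAF, control HWE, association p and allelic OR.

    The association test compares alt allele counts between cases and controls
    (2x2 chi-square, no continuity correction); missing calls are excluded per
    variant.  The odds ratio uses a Haldane 0.5 correction when any cell is
    zero.  A variant with no called genotypes at all comes back with
    ``defined=False`` rather than NaN-propagating silently.
    """
    config = config or AssociationConfig()
    if matrix.n_cases == 0 or matrix.n_controls == 0:
        raise ValueError("association screening needs at least one case and one control")
    case = matrix.genotypes[matrix.case_indices]
    ctrl = matrix.genotypes[matrix.control_indices]
    out: list[VariantStats] = []
    for j, vid in enumerate(matrix.variant_ids):
        col = matrix.genotypes[:, j]
        n_called = int((col != MISSING).sum())
        if n_called == 0:
            out.append(VariantStats(vid, np.nan, np.nan, np.nan, np.nan, np.nan,
                                    defined=False))
            continue
        call_rate = n_called / matrix.n_samples
        alt, ref = _allele_counts(col)
        maf = min(alt, ref) / (alt + ref)

        ctrl_col = ctrl[:, j]
        n_het = int((ctrl_col == 1).sum())
        n_hom_ref = int((ctrl_col == 0).sum())
        n_hom_alt = int((ctrl_col == 2).sum())
        hwe = hwe_exact_p(n_het, n_hom_ref, n_hom_alt)

        ca_alt, ca_ref = _allele_counts(case[:, j])
        co_alt, co_ref = _allele_counts(ctrl_col)
        if config.test == "allelic":
            assoc_p = _chi2_p([[ca_alt, ca_ref], [co_alt, co_ref]])
        else:
            tab = [[int((g[:, j] == c).sum()) for c in (0, 1, 2)] for g in (case, ctrl)]
            assoc_p = _chi2_p(tab)
        cells = np.array([ca_alt, ca_ref, co_alt, co_ref], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5  # Haldane correction
        odds_ratio = (cells[0] * cells[3]) / (cells[1] * cells[2])
        out.append(VariantStats(vid, call_rate, maf, hwe, assoc_p, float(odds_ratio)))
    return out


def select_candidates(stats: Sequence[VariantStats],
                      config: AssociationConfig | None = None,
                      region_mask: Sequence[str] | None = None) -> list[str]:
    """Variant ids passing all QC/association filters, in input order.

    ``region_mask``, when given, restricts the result to that variant subset
    (e.g. SNPs inside disease-associated regions, or their complement for a
    background-noise run).  Undefined stats never pass.  An empty result is
    returned as such, not raised.
    """
    config = config or AssociationConfig()
    mask = set(region_mask) if region_mask is not None else None
    out = []
    for s in stats:
        if not s.defined:
            continue
        if mask is not None and s.variant_id not in mask:
            continue
        if (s.call_rate >= config.min_call_rate
                and s.maf >= config.min_maf
                and s.hwe_p >= config.min_hwe_p
                and s.assoc_p <= config.max_assoc_p):
            out.append(s.variant_id)
    return out


def greedy_r2_prune(matrix: GenotypeMatrix, variant_ids: Sequence[str],
                    max_r2: float = 0.8) -> list[str]:
    """Optional greedy LD pruner: drop later variants with genotype r^2 above max_r2.

    Off by default in every pipeline; provided because background-noise SNP
    sets are sometimes pruned before enumeration.
    """
    kept: list[str] = []
    kept_cols: list[np.ndarray] = []
    for vid in variant_ids:
        col = matrix.genotypes[:, matrix.variant_index(vid)].astype(float)
        col[col == MISSING] = np.nan
        ok = True
        for other in kept_cols:
            both = ~np.isnan(col) & ~np.isnan(other)
            if both.sum() < 3:
                continue
            a, b = col[both], other[both]
            if a.std() == 0 or b.std() == 0:
                continue
            if np.corrcoef(a, b)[0, 1] ** 2 > max_r2:
                ok = False
                break
        if ok:
            kept.append(vid)
            kept_cols.append(col)
    return kept
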