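"""Exhaustive search for case-exclusive genotype combinations (CGCP).

The method scans every combination of r variants (default r = 3) and every
assignment of one diploid genotype per variant — 3^r * C(n, r) candidate
patterns over n candidate SNPs — and keeps a combination when

* at least ``min_case_carriers`` cases carry all r genotypes simultaneously,
* no control carries them (case exclusivity), and
* the product of estimated population genotype frequencies falls strictly
  inside the prevalence band ``lower_factor * P < prod F_i < P``.

The population frequency of genotype i is estimated from case and control
frequencies as a prevalence-weighted mixture ``F_i = (alpha_i + lambda *
beta_i) / (1 + lambda)`` with ``lambda = (1 - P) / P``: the population is
modelled as a fraction P of cases and 1 - P of controls, so F interpolates
from beta (rare disease) to alpha (P -> 1).

The production enumerator uses packed carrier bitsets with popcount
intersections; :func:`enumerate_specific_combinations_naive` is an
independent per-sample scan kept for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations as iter_combinations
from itertools import product as iter_product
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

GENOTYPE_CODES = (0, 1, 2)


class GenotypeKey(NamedTuple):
    """One diploid state at one SNP — the atomic unit combined by CGCP."""

    variant_id: str
    genotype_code: int


@dataclass(frozen=True)
class Combination:
    """An r-tuple of genotype keys with carrier counts and frequency estimates.

    ``alpha``/``beta`` are the per-key genotype frequencies among cases and
    controls, ``fhat`` the per-key population estimates; all aligned with
    ``keys`` (canonically sorted by variant id then code).
    """

    keys: tuple[GenotypeKey, ...]
    case_carriers: int
    control_carriers: int
    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    fhat: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "keys", canonical_keys(self.keys))

    @property
    def r(self) -> int:
        return len(self.keys)

    @property
    def combo_key(self) -> str:
        return "|".join(f"{k.variant_id}:{k.genotype_code}" for k in self.keys)

    @property
    def alpha_product(self) -> float:
        return float(np.prod(self.alpha))

    @property
    def fhat_product(self) -> float:
        return float(np.prod(self.fhat))


def canonical_keys(keys: Iterable[GenotypeKey]) -> tuple[GenotypeKey, ...]:
    """Sort keys by (variant_id, genotype_code); rejects repeated variants."""
    out = tuple(sorted((GenotypeKey(*k) for k in keys),
                       key=lambda k: (k.variant_id, k.genotype_code)))
    if len({k.variant_id for k in out}) != len(out):
        raise ValueError("combination keys must be on distinct variants")
    return out


@dataclass
class CgcpConfig:
    """Search parameters.

    prevalence
        Disease prevalence P as a proportion; default 0.0047 (psoriasis in the
        Chinese Han population).
    r
        Combination order; 3 keeps the search tractable, the engine is generic.
    min_case_carriers
        Minimum number of cases carrying the full combination (default 10).
    lower_factor
        Lower edge of the frequency band as a fraction of P (default 0.01).
    missing_policy
        "exclude" (default): a sample missing at a variant is excluded from
        that variant's carrier sets *and* frequency denominators.
        "carrier_only": excluded from carrier sets only; denominators are the
        full cohort sizes.
    """

    r: int = 3
    prevalence: float = 0.0047
    min_case_carriers: int = 10
    lower_factor: float = 0.01
    missing_policy: str = "exclude"

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if self.min_case_carriers < 1:
            raise ValueError("min_case_carriers must be >= 1")
        if not 0.0 <= self.lower_factor < 1.0:
            raise ValueError("lower_factor must be in [0,1)")
        if self.missing_policy not in ("exclude", "carrier_only"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


# ---------------------------------------------------------------------------
# the arithmetic primitives
# ---------------------------------------------------------------------------

def count_total_combinations(n: int, r: int) -> int:
    """Total number of genotype-combination patterns: 3^r * C(n, r), exact."""
    if r < 1 or n < 1:
        raise ValueError("n and r must be >= 1")
    if r > n:
        raise ValueError(f"combination order r={r} exceeds candidate count n={n}")
    return 3 ** r * math.comb(n, r)


def lambda_from_prevalence(prevalence: float) -> float:
    """Mixture weight lambda = (1 - P) / P converting case/control to population scale."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    return (1.0 - prevalence) / prevalence


def estimate_population_frequency(alpha: float, beta: float, prevalence: float) -> float:
    """Population genotype frequency estimate F = (alpha + lambda*beta) / (1 + lambda)."""
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise ValueError("alpha and beta must lie in [0,1]")
    lam = lambda_from_prevalence(prevalence)
    return (alpha + lam * beta) / (1.0 + lam)


def passes_boundary(fhat_product: float, prevalence: float, lower_factor: float = 0.01) -> bool:
    """Strict prevalence band: lower_factor * P < fhat_product < P."""
    if fhat_product < 0:
        raise ValueError("fhat_product must be non-negative")
    return lower_factor * prevalence < fhat_product < prevalence


# ---------------------------------------------------------------------------
# carrier queries
# ---------------------------------------------------------------------------

def carriers_of(matrix: GenotypeMatrix, keys: Iterable[GenotypeKey]
                ) -> tuple[int, int, list[str]]:
    """Exact carriers of all given keys: (case count, control count, sample ids).

    A sample carries a key iff its call equals the key's code; MISSING never
    matches.  The empty key set denotes the trivial combination carried by
    every sample.  Sample ids come back in matrix order.
    """
    keys = tuple(keys)
    mask = np.ones(matrix.n_samples, dtype=bool)
    for key in keys:
        col = matrix.genotypes[:, matrix.variant_index(key.variant_id)]
        mask &= col == key.genotype_code
    idx = np.flatnonzero(mask)
    pheno = matrix.phenotype[idx]
    return (
        int((pheno == "case").sum()),
        int((pheno == "control").sum()),
        [matrix.sample_ids[i] for i in idx],
    )


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _prepare(matrix: GenotypeMatrix, candidates: Sequence[str], cfg: CgcpConfig):
    """Per-(variant, code) carrier bitsets and case/control genotype frequencies."""
    if matrix.n_cases == 0 or matrix.n_controls == 0:
        raise ValueError("matrix must contain both cases and controls")
    cols = [matrix.variant_index(v) for v in candidates]
    geno = matrix.genotypes[:, cols]
    case = geno[matrix.case_indices]      # (n_cases, m)
    ctrl = geno[matrix.control_indices]

    if cfg.missing_policy == "exclude":
        case_den = (case != MISSING).sum(axis=0).astype(float)
        ctrl_den = (ctrl != MISSING).sum(axis=0).astype(float)
    else:  # carrier_only
        case_den = np.full(len(cols), float(matrix.n_cases))
        ctrl_den = np.full(len(cols), float(matrix.n_controls))

    lam = lambda_from_prevalence(cfg.prevalence)
    case_bits, ctrl_bits, alpha, beta, fhat = [], [], [], [], []
    for code in GENOTYPE_CODES:
        cmatch = case == code              # MISSING (-1) never equals a code
        kmatch = ctrl == code
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(case_den > 0, cmatch.sum(axis=0) / case_den, np.nan)
            b = np.where(ctrl_den > 0, kmatch.sum(axis=0) / ctrl_den, np.nan)
        alpha.append(a)
        beta.append(b)
        fhat.append((a + lam * b) / (1.0 + lam))
        case_bits.append(np.packbits(cmatch.T, axis=1))   # (m, ceil(n_cases/8))
        ctrl_bits.append(np.packbits(kmatch.T, axis=1))
    return {
        "case_bits": np.stack(case_bits),   # (3, m, bytes)
        "ctrl_bits": np.stack(ctrl_bits),
        "alpha": np.stack(alpha),           # (3, m)
        "beta": np.stack(beta),
        "fhat": np.stack(fhat),
    }


def enumerate_specific_combinations(
    matrix: GenotypeMatrix,
    candidates: Sequence[str],
    cfg: CgcpConfig | None = None,
    stats_out: dict | None = None,
) -> list[Combination]:
    """Exhaustively enumerate case-exclusive combinations passing the prevalence band.

    Visits all 3^r * C(n, r) candidate patterns over the given candidate
    variants using packed carrier bitsets; returns retained combinations in
    canonical key order.  ``stats_out``, when given a dict, receives the
    number of patterns visited under key "visited".
    """
    cfg = cfg or CgcpConfig()
    if cfg.r > len(candidates):
        raise ValueError(f"r={cfg.r} exceeds number of candidates ({len(candidates)})")
    pre = _prepare(matrix, candidates, cfg)
    case_bits, ctrl_bits = pre["case_bits"], pre["ctrl_bits"]
    alpha, beta, fhat = pre["alpha"], pre["beta"], pre["fhat"]

    lo = cfg.lower_factor * cfg.prevalence
    hi = cfg.prevalence
    assignments = list(iter_product(GENOTYPE_CODES, repeat=cfg.r))
    visited = 0
    out: list[Combination] = []
    for variant_idx in iter_combinations(range(len(candidates)), cfg.r):
        for codes in assignments:
            visited += 1
            acc = ctrl_bits[codes[0], variant_idx[0]].copy()
            for code, j in zip(codes[1:], variant_idx[1:]):
                acc &= ctrl_bits[code, j]
            if acc.any():                      # a control carries it: not exclusive
                continue
            acc = case_bits[codes[0], variant_idx[0]].copy()
            for code, j in zip(codes[1:], variant_idx[1:]):
                acc &= case_bits[code, j]
            n_case = int(np.bitwise_count(acc).sum())
            if n_case < cfg.min_case_carriers:
                continue
            f = [float(fhat[c, j]) for c, j in zip(codes, variant_idx)]
            prod = float(np.prod(f))
            if not (lo < prod < hi) or not np.isfinite(prod):
                continue
            out.append(Combination(
                keys=tuple(GenotypeKey(candidates[j], c)
                           for c, j in zip(codes, variant_idx)),
                case_carriers=n_case,
                control_carriers=0,
                alpha=tuple(float(alpha[c, j]) for c, j in zip(codes, variant_idx)),
                beta=tuple(float(beta[c, j]) for c, j in zip(codes, variant_idx)),
                fhat=tuple(f),
            ))
    if stats_out is not None:
        stats_out["visited"] = visited
    out.sort(key=lambda c: (-c.case_carriers, c.combo_key))
    return out


def enumerate_specific_combinations_naive(
    matrix: GenotypeMatrix,
    candidates: Sequence[str],
    cfg: CgcpConfig | None = None,
) -> list[Combination]:
    """Reference enumerator: per-sample python scan, no bitsets.

    Deliberately independent of the production path; used to cross-check it.
    """
    cfg = cfg or CgcpConfig()
    if cfg.r > len(candidates):
        raise ValueError(f"r={cfg.r} exceeds number of candidates ({len(candidates)})")
    if matrix.n_cases == 0 or matrix.n_controls == 0:
        raise ValueError("matrix must contain both cases and controls")
    case_rows = [matrix.genotypes[i] for i in matrix.case_indices]
    ctrl_rows = [matrix.genotypes[i] for i in matrix.control_indices]
    col_of = {v: matrix.variant_index(v) for v in candidates}

    def freq(rows, col, code, n_total):
        hits = sum(1 for row in rows if row[col] == code)
        if cfg.missing_policy == "exclude":
            denom = sum(1 for row in rows if row[col] != MISSING)
        else:
            denom = n_total
        return hits / denom if denom else float("nan")

    out: list[Combination] = []
    for vids in iter_combinations(list(candidates), cfg.r):
        cols = [col_of[v] for v in vids]
        for codes in iter_product(GENOTYPE_CODES, repeat=cfg.r):
            if any(all(row[c] == g for c, g in zip(cols, codes)) for row in ctrl_rows):
                continue
            n_case = sum(
                1 for row in case_rows
                if all(row[c] == g for c, g in zip(cols, codes))
            )
            if n_case < cfg.min_case_carriers:
                continue
            a = [freq(case_rows, c, g, matrix.n_cases) for c, g in zip(cols, codes)]
            b = [freq(ctrl_rows, c, g, matrix.n_controls) for c, g in zip(cols, codes)]
            f = [estimate_population_frequency(ai, bi, cfg.prevalence)
                 if not (math.isnan(ai) or math.isnan(bi)) else float("nan")
                 for ai, bi in zip(a, b)]
            prod = math.prod(f)
            if math.isnan(prod) or not passes_boundary(prod, cfg.prevalence, cfg.lower_factor):
                continue
            out.append(Combination(
                keys=tuple(GenotypeKey(v, g) for v, g in zip(vids, codes)),
                case_carriers=n_case,
                control_carriers=0,
                alpha=tuple(a), beta=tuple(b), fhat=tuple(f),
            ))
    out.sort(key=lambda c: (-c.case_carriers, c.combo_key))
    return out
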