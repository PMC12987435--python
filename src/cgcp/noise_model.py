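"""Empirical background-noise estimation and the scale-up carrier threshold.

Case-exclusive combinations arise by chance; their carrier counts under two
null scenarios calibrate a specificity cutoff:

* split-half controls — healthy controls are randomly halved, one half
  relabelled "cases", and the full search re-run on disease-associated SNPs;
* off-target SNPs — the true case/control cohorts are searched over SNPs
  outside disease-associated regions.

The highest case-carrier count seen among "specific" combinations in a noise
run is rescaled to the main cohort size (ceiling of (n_main / n_noise) * max)
and used as the minimum carrier count for a combination to be called
disease-specific, at both the genotype-combination and the gene-combination
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cgcp_core import CgcpConfig, Combination, enumerate_specific_combinations
from .gene_collapse import GeneCombination, collapse
from .genotype_io import GenotypeMatrix

NOISE_MODES = ("split_half", "off_target")


@dataclass
class NoiseThreshold:
    """A derived specificity cutoff at one collapsing level."""

    max_noise_carriers: int
    n_case_main: int
    n_case_noise: int
    threshold: int
    level: str  # "genotype" or "gene"
    empty_noise_run: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("genotype", "gene"):
            raise ValueError(f"unknown level {self.level!r}")


@dataclass
class NoiseRunResult:
    """Everything one noise scenario produced."""

    mode: str
    combinations: list[Combination]
    gene_combinations: list[GeneCombination] | None
    max_genotype_carriers: int
    max_gene_carriers: int | None
    empty: bool = False


def split_half_controls(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Randomly halve a controls-only cohort, relabelling one half pseudo-cases.

    Deterministic given the seed; group sizes differ by at most one.  Refuses
    matrices containing true cases to guard against leakage into the null.
    """
    if (matrix.phenotype == "case").any():
        raise ValueError("split_half_controls requires a controls-only matrix")
    ctrl = matrix.control_indices
    if ctrl.size < 2:
        raise ValueError("need at least 2 control samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ctrl)
    half = perm.size // 2
    labels = np.array(["unlabeled"] * matrix.n_samples, dtype=object)
    labels[perm[:half]] = "case"
    labels[perm[half:]] = "control"
    out = matrix.with_phenotype(list(labels))
    return out.select_samples(np.flatnonzero(labels != "unlabeled"))


def run_noise_experiment(
    matrix: GenotypeMatrix,
    candidates: Sequence[str],
    cfg: CgcpConfig,
    mode: str,
    seed: int | None = None,
    gene_map: Mapping[str, Sequence[str] | str] | None = None,
) -> NoiseRunResult:
    """Run the full enumeration under one null scenario and report noise maxima.

    mode="split_half" expects a controls-only matrix and a seed (the split
    happens here); mode="off_target" expects the true case/control matrix with
    ``candidates`` drawn from outside disease-associated regions.  Reports the
    maximum case-carrier count among resulting "specific" combinations at the
    genotype level and, when a gene map is supplied, at the gene level.  Zero
    combinations yield maxima of 0 with ``empty=True``.
    """
    if mode not in NOISE_MODES:
        raise ValueError(f"unknown noise mode {mode!r}; expected one of {NOISE_MODES}")
    if mode == "split_half":
        if seed is None:
            raise ValueError("split_half mode requires a seed")
        matrix = split_half_controls(matrix, seed)
    elif matrix.n_cases == 0 or matrix.n_controls == 0:
        raise ValueError("off_target mode requires a case/control matrix")

    combos = enumerate_specific_combinations(matrix, candidates, cfg)
    max_geno = max((c.case_carriers for c in combos), default=0)
    gene_combos = None
    max_gene = None
    if gene_map is not None:
        gene_combos = collapse(combos, gene_map)
        max_gene = max((g.max_case_carriers for g in gene_combos), default=0)
    return NoiseRunResult(
        mode=mode,
        combinations=combos,
        gene_combinations=gene_combos,
        max_genotype_carriers=max_geno,
        max_gene_carriers=max_gene,
        empty=not combos,
    )


def scale_threshold(n_case_main: int, n_case_noise: int, max_noise_carriers: int) -> int:
    """Scale a noise-run maximum to the main cohort: ceil((n_main/n_noise) * max).

    With equal cohort sizes the maximum passes through unchanged.  The result
    is never below 1 so it can always serve as a carrier-count cutoff.
    """
    if n_case_main <= 0 or n_case_noise <= 0:
        raise ValueError("cohort sizes must be positive")
    if max_noise_carriers < 0:
        raise ValueError("max_noise_carriers must be >= 0")
    return max(1, math.ceil(n_case_main / n_case_noise * max_noise_carriers))


def derive_thresholds(
    split_half_result: NoiseRunResult,
    off_target_result: NoiseRunResult,
    n_case_main: int,
    n_case_split: int,
    n_case_off_target: int | None = None,
) -> dict[str, NoiseThreshold]:
    """Combine the two scenarios into genotype- and gene-level cutoffs.

    Each level takes its governing scenario: the genotype-level cutoff comes
    from the split-half run (rescaled to the main cohort), the gene-level
    cutoff from the off-target run (whose case cohort is already the main
    cohort unless stated otherwise).
    """
    n_off = n_case_off_target if n_case_off_target is not None else n_case_main
    geno = NoiseThreshold(
        max_noise_carriers=split_half_result.max_genotype_carriers,
        n_case_main=n_case_main,
        n_case_noise=n_case_split,
        threshold=scale_threshold(n_case_main, n_case_split,
                                  split_half_result.max_genotype_carriers),
        level="genotype",
        empty_noise_run=split_half_result.empty,
    )
    if off_target_result.max_gene_carriers is None:
        raise ValueError("off-target run needs gene-level maxima (supply a gene map)")
    gene = NoiseThreshold(
        max_noise_carriers=off_target_result.max_gene_carriers,
        n_case_main=n_case_main,
        n_case_noise=n_off,
        threshold=scale_threshold(n_case_main, n_off,
                                  off_target_result.max_gene_carriers),
        level="gene",
        empty_noise_run=off_target_result.empty,
    )
    return {"genotype": geno, "gene": gene}


def apply_noise_threshold(combinations: Iterable[Combination],
                          threshold: int) -> list[Combination]:
    """Keep combinations with case_carriers >= threshold (boundary inclusive)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return [c for c in combinations if c.case_carriers >= threshold]
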