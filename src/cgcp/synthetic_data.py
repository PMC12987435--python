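"""Synthetic genotype data with known ground truth.

Two generators:

* :func:`make_case_control` — a case/control matrix with planted causal
  genotype combinations at exact carrier counts over a background of
  independent binomial SNPs (no linkage structure).
* :func:`make_panels` — a multi-population reference panel whose per-population
  combination carrier frequencies follow a programmed linear relationship
  with an assigned prevalence, for testing the frequency-prevalence fit.

Plants are assigned to contiguous blocks of a seeded sample permutation, so
carrier counts are exact (round(freq * n), not binomial draws) and downstream
outputs are predictable from the truth record alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cgcp_core import GenotypeKey, canonical_keys
from .genotype_io import GenotypeMatrix, PopulationPanel


@dataclass(frozen=True)
class PlantSpec:
    """A combination to plant: r genotype keys plus target carrier frequencies.

    ``background_maf`` is the alt-allele frequency used to draw non-carrier
    genotypes at the planted variants (binomial(2, maf)); with the default
    0.05 a heterozygous key has a background genotype frequency of about
    2*0.05*0.95 = 0.095, which puts a 3-key product inside the default
    prevalence band.
    """

    keys: tuple[GenotypeKey, ...]
    case_carrier_freq: float
    control_carrier_freq: float = 0.0
    background_maf: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "keys", canonical_keys(self.keys))
        for name in ("case_carrier_freq", "control_carrier_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.background_maf < 0.5:
            raise ValueError("background_maf must lie in (0, 0.5)")


@dataclass
class PlantTruth:
    """Exact realized carrier counts for one planted combination."""

    keys: tuple[GenotypeKey, ...]
    case_carriers: int
    control_carriers: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class CaseControlTruth:
    plants: list[PlantTruth]
    seed: int


def _plant_cohort(geno: np.ndarray, rows: np.ndarray, cols: list[int],
                  codes: list[int], n_carriers: int, rng: np.random.Generator) -> None:
    """Make exactly the first n_carriers of a shuffled row block carry all keys."""
    perm = rng.permutation(rows)
    carriers = perm[:n_carriers]
    for c, g in zip(cols, codes):
        geno[carriers, c] = g
    # break accidental full carriers among the rest (flip one variant away)
    rest = perm[n_carriers:]
    full = rest[(geno[np.ix_(rest, cols)] == np.array(codes)).all(axis=1)]
    if full.size:
        geno[full, cols[0]] = (codes[0] + 1) % 3


def make_case_control(
    n_cases: int,
    n_controls: int,
    n_null_snps: int,
    plants: Sequence[PlantSpec],
    seed: int,
    null_maf: float = 0.05,
) -> tuple[GenotypeMatrix, CaseControlTruth]:
    """Case/control matrix with planted combinations at exact carrier counts.

    Planted variants (named by the plant keys, which must be disjoint across
    plants) come first, followed by ``n_null_snps`` independent null SNPs
    ``null_0001`` ... drawn binomial(2, null_maf).  Cases occupy the first
    ``n_cases`` rows.  The truth record carries exact per-plant carrier
    counts; an infeasible plant (zero carriers requested from a nonzero
    frequency) is noted there as a warning, not raised.
    """
    rng = np.random.default_rng(seed)
    plant_vids: list[str] = []
    for p in plants:
        for k in p.keys:
            if k.variant_id in plant_vids:
                raise ValueError(f"plants share variant {k.variant_id!r}")
            plant_vids.append(k.variant_id)
    null_vids = [f"null_{i + 1:04d}" for i in range(n_null_snps)]
    variant_ids = plant_vids + null_vids
    n = n_cases + n_controls

    geno = np.empty((n, len(variant_ids)), dtype=np.int8)
    # background at planted variants, per-plant maf
    col = 0
    for p in plants:
        for _ in p.keys:
            geno[:, col] = rng.binomial(2, p.background_maf, size=n)
            col += 1
    geno[:, col:] = rng.binomial(2, null_maf, size=(n, n_null_snps))

    case_rows = np.arange(n_cases)
    ctrl_rows = np.arange(n_cases, n)
    col_of = {v: j for j, v in enumerate(variant_ids)}
    truths: list[PlantTruth] = []
    for p in plants:
        cols = [col_of[k.variant_id] for k in p.keys]
        codes = [k.genotype_code for k in p.keys]
        n_case_carr = round(p.case_carrier_freq * n_cases)
        n_ctrl_carr = round(p.control_carrier_freq * n_controls)
        _plant_cohort(geno, case_rows, cols, codes, n_case_carr, rng)
        _plant_cohort(geno, ctrl_rows, cols, codes, n_ctrl_carr, rng)
        notes = []
        if p.case_carrier_freq > 0 and n_case_carr == 0:
            notes.append("case carrier frequency rounds to zero carriers")
        truths.append(PlantTruth(
            keys=p.keys, case_carriers=n_case_carr, control_carriers=n_ctrl_carr,
            warnings=notes,
        ))

    sample_ids = [f"case_{i + 1:04d}" for i in range(n_cases)] + \
                 [f"ctrl_{i + 1:04d}" for i in range(n_controls)]
    phenotype = np.array(["case"] * n_cases + ["control"] * n_controls, dtype=object)
    matrix = GenotypeMatrix(
        sample_ids=sample_ids, variant_ids=variant_ids,
        genotypes=geno, phenotype=phenotype,
    )
    return matrix, CaseControlTruth(plants=truths, seed=seed)


def make_gene_map(variant_ids: Sequence[str], n_genes: int, seed: int
                  ) -> dict[str, tuple[str, ...]]:
    """Random variant -> gene assignment over ``GENE_0001``... (one gene each)."""
    rng = np.random.default_rng(seed)
    genes = [f"GENE_{i + 1:04d}" for i in range(n_genes)]
    return {v: (genes[int(rng.integers(n_genes))],) for v in variant_ids}


@dataclass
class PanelTruth:
    """Programmed and realized per-population mean carrier frequencies."""

    slope: float
    intercept: float
    noise_sd: float
    target_x: dict[str, float]          # frequency implied by the linear model
    realized_x: dict[str, float]        # after rounding carriers to integers
    noisy_prevalence: dict[str, float]  # slope*realized_x + intercept + noise
    clipped: list[str]                  # populations whose target left [0,1]
    seed: int


def make_panels(
    populations: Sequence[tuple[str, float]],
    combos: Sequence[PlantSpec],
    slope: float,
    intercept: float,
    noise_sd: float,
    n_per_pop: int,
    seed: int,
) -> tuple[PopulationPanel, PanelTruth]:
    """Multi-population panel with a programmed linear frequency-prevalence link.

    For each population with assigned prevalence y the target mean carrier
    frequency is x = (y - intercept) / slope; every planted combination is
    given carrier count round(x * n_per_pop) in that population (targets
    outside [0,1] are clipped and recorded).  Noise models the uncertainty of
    epidemiological prevalence estimates, not of the panel genotypes: the
    truth record carries a per-population observed prevalence
    slope * realized_x + intercept + Normal(0, noise_sd), so regressing it on
    the measured panel frequency is a textbook fixed-x error-in-y fit.
    Combination variants must be disjoint.  Prevalence, intercept and
    noise_sd share whatever scale the caller chooses; no unit conversion
    happens here.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    rng = np.random.default_rng(seed)
    plant_vids: list[str] = []
    for p in combos:
        for k in p.keys:
            if k.variant_id in plant_vids:
                raise ValueError(f"panel combos share variant {k.variant_id!r}")
            plant_vids.append(k.variant_id)

    target_x: dict[str, float] = {}
    realized_x: dict[str, float] = {}
    noisy_prevalence: dict[str, float] = {}
    clipped: list[str] = []
    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    pop_of: dict[str, str] = {}
    for code, prev in populations:
        x = (prev - intercept) / slope
        if not 0.0 <= x <= 1.0:
            clipped.append(code)
            x = min(1.0, max(0.0, x))
        target_x[code] = x
        n_carr = round(x * n_per_pop)
        realized_x[code] = n_carr / n_per_pop
        e = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        noisy_prevalence[code] = slope * realized_x[code] + intercept + e

        geno = np.empty((n_per_pop, len(plant_vids)), dtype=np.int8)
        col = 0
        for p in combos:
            for _ in p.keys:
                geno[:, col] = rng.binomial(2, p.background_maf, size=n_per_pop)
                col += 1
        rows = np.arange(n_per_pop)
        col_of = {v: j for j, v in enumerate(plant_vids)}
        for p in combos:
            cols = [col_of[k.variant_id] for k in p.keys]
            codes = [k.genotype_code for k in p.keys]
            _plant_cohort(geno, rows, cols, codes, n_carr, rng)
        blocks.append(geno)
        ids = [f"{code}_{i + 1:04d}" for i in range(n_per_pop)]
        sample_ids.extend(ids)
        pop_of.update({s: code for s in ids})

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=plant_vids,
        genotypes=np.concatenate(blocks, axis=0),
        phenotype=np.array(["unlabeled"] * len(sample_ids), dtype=object),
    )
    panel = PopulationPanel(matrix=matrix, population_of=pop_of)
    truth = PanelTruth(
        slope=slope, intercept=intercept, noise_sd=noise_sd,
        target_x=target_x, realized_x=realized_x,
        noisy_prevalence=noisy_prevalence, clipped=clipped, seed=seed,
    )
    return panel, truth
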