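"""Reading and writing genotype data and all tabular side files.

The central container is :class:`GenotypeMatrix`: a samples x variants table of
diploid genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing) with a
case/control/unlabeled phenotype label per sample.  Genotypes are unphased alt
allele dosages; phase separators in VCF input are ignored.  I/O never imputes:
missing-call handling is the enumeration engine's concern.

Supported formats: VCF 4.x (plain or bgzipped, via cyvcf2) and plain TSV for
genotype tables, phenotypes, variant-to-gene maps, sample-to-population maps,
prevalence tables and combination result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: genotype code for a missing or half-missing call
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})
_VALID_LABELS = ("case", "control", "unlabeled")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x variants genotype table with phenotype labels.

    Parameters
    ----------
    sample_ids, variant_ids
        Unique identifiers; row and column order of ``genotypes``.
    genotypes
        int8 array of shape ``(n_samples, n_variants)`` with codes in
        {0, 1, 2, MISSING}.
    phenotype
        Per-sample label in {"case", "control", "unlabeled"}.
    variant_meta
        DataFrame indexed by variant id with columns chrom, pos, ref, alt.
        Positions are 1-based VCF coordinates, preserved verbatim.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    variant_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.variant_ids = list(self.variant_ids)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        if self.genotypes.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"genotype table shape {self.genotypes.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.variant_ids)} variants)"
            )
        if self.phenotype.shape != (len(self.sample_ids),):
            raise ValueError("phenotype length does not match sample count")
        codes = set(np.unique(self.genotypes).tolist())
        if not codes <= _VALID_CODES:
            raise ValueError(f"invalid genotype codes {sorted(codes - _VALID_CODES)}")
        bad = set(self.phenotype) - set(_VALID_LABELS)
        if bad:
            raise ValueError(f"invalid phenotype labels {sorted(bad)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        if self.variant_meta is None:
            self.variant_meta = pd.DataFrame(
                {"chrom": ".", "pos": 0, "ref": "N", "alt": "N"},
                index=pd.Index(self.variant_ids, name="variant_id"),
            )

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def case_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phenotype == "case")

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phenotype == "control")

    @property
    def n_cases(self) -> int:
        return int(self.case_indices.size)

    @property
    def n_controls(self) -> int:
        return int(self.control_indices.size)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None

    # -- subsetting ----------------------------------------------------------
    def select_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variant_ids=self.variant_ids,
            genotypes=self.genotypes[idx],
            phenotype=self.phenotype[idx].copy(),
            variant_meta=self.variant_meta,
        )

    def select_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            variant_ids=list(variant_ids),
            genotypes=self.genotypes[:, cols],
            phenotype=self.phenotype.copy(),
            variant_meta=self.variant_meta.loc[list(variant_ids)],
        )

    def with_phenotype(self, labels: Mapping[str, str] | Sequence[str]) -> "GenotypeMatrix":
        """Return a copy with phenotype labels replaced.

        ``labels`` is either a sequence aligned with ``sample_ids`` or a
        mapping sample id -> label; samples absent from the mapping become
        "unlabeled".  A mapping naming an unknown sample raises KeyError.
        """
        if isinstance(labels, Mapping):
            unknown = set(labels) - set(self.sample_ids)
            if unknown:
                raise KeyError(f"phenotype refers to unknown samples: {sorted(unknown)}")
            pheno = np.array(
                [labels.get(s, "unlabeled") for s in self.sample_ids], dtype=object
            )
        else:
            pheno = np.asarray(list(labels), dtype=object)
        return replace(self, phenotype=pheno, variant_meta=self.variant_meta)


@dataclass
class PopulationPanel:
    """A reference panel: an unlabeled genotype matrix plus a sample->population map."""

    matrix: GenotypeMatrix
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.matrix.sample_ids) - set(self.population_of)
        if missing:
            raise ValueError(f"samples without population assignment: {sorted(missing)[:5]}")
        self.population_of = {s: self.population_of[s] for s in self.matrix.sample_ids}
        if not self.population_of:
            raise ValueError("empty panel")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.population_of.values()))

    def sample_indices(self, population: str) -> np.ndarray:
        codes = np.array([self.population_of[s] for s in self.matrix.sample_ids])
        idx = np.flatnonzero(codes == population)
        if idx.size == 0:
            raise KeyError(f"no samples in population {population!r}")
        return idx


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` with all samples unlabeled.

    Diploid GT fields map to alt-dosage codes {0,1,2}; missing and half calls
    map to MISSING.  Multi-allelic sites are dropped when ``biallelic_only``
    (the default), otherwise split into one pseudo-variant per alt allele with
    ``:altN`` suffixed ids.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} declares zero samples")

    variant_ids: list[str] = []
    meta_rows: list[tuple[str, int, str, str]] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        alts = var.ALT
        if biallelic_only and len(alts) != 1:
            continue
        gts = var.genotypes  # [a1, a2, phased] per sample; -1 == missing allele
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int16)
        any_missing = (alleles < 0).any(axis=1)
        base_id = var.ID if var.ID not in (None, ".") else (
            f"{var.CHROM}:{var.POS}:{var.REF}:{','.join(alts)}"
        )
        for k, alt in enumerate(alts):
            codes = (alleles == k + 1).sum(axis=1).astype(np.int8)
            codes[any_missing] = MISSING
            vid = base_id if len(alts) == 1 else f"{base_id}:alt{k + 1}"
            variant_ids.append(vid)
            meta_rows.append((var.CHROM, var.POS, var.REF, alt))
            columns.append(codes)
    vcf.close()

    genotypes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    meta = pd.DataFrame(
        meta_rows, columns=["chrom", "pos", "ref", "alt"],
        index=pd.Index(variant_ids, name="variant_id"),
    )
    return GenotypeMatrix(
        sample_ids=samples,
        variant_ids=variant_ids,
        genotypes=genotypes,
        phenotype=np.array(["unlabeled"] * len(samples), dtype=object),
        variant_meta=meta,
    )


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal biallelic VCF 4.2 (unphased GT only)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = []
    for vid in matrix.variant_ids:
        c = matrix.variant_meta.loc[vid, "chrom"]
        c = c if c != "." else "1"
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids) + "\n"
        )
        for j, vid in enumerate(matrix.variant_ids):
            m = matrix.variant_meta.loc[vid]
            chrom = m["chrom"] if m["chrom"] != "." else "1"
            pos = int(m["pos"]) if int(m["pos"]) > 0 else j + 1
            ref = m["ref"] if m["ref"] != "N" else "A"
            alt = m["alt"] if m["alt"] != "N" else "G"
            calls = "\t".join(gt_str[int(c)] for c in matrix.genotypes[:, j])
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# tabular genotype matrix
# ---------------------------------------------------------------------------

def write_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the genotype matrix as TSV: rows samples, columns variants, NA missing."""
    df = pd.DataFrame(
        matrix.genotypes, index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=matrix.variant_ids,
    ).astype(object)
    df[df == MISSING] = "NA"
    df.to_csv(path, sep="\t")


def read_table(path: str | Path) -> GenotypeMatrix:
    """Read a TSV genotype matrix (as written by :func:`write_table`)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=object, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty genotype table {path}")
    try:
        geno = df.replace("NA", MISSING).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric genotype entries in {path}: {exc}") from exc
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(v) for v in df.columns],
        genotypes=geno.astype(np.int8),
        phenotype=np.array(["unlabeled"] * df.shape[0], dtype=object),
    )


# ---------------------------------------------------------------------------
# side tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> dict[str, str]:
    """Read a phenotype TSV with columns (sample_id, status in {case, control})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty phenotype file {path}")
    _require_columns(df, ("sample_id", "status"), path)
    bad = set(df["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"invalid status values {sorted(bad)} in {path}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return dict(zip(df["sample_id"], df["status"]))


def read_gene_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a variant->gene TSV (variant_id, gene).

    A variant listed on several rows (overlapping loci) maps to the sorted
    tuple of all its genes; collapsing decides which to use.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("variant_id", "gene"), path)
    out: dict[str, set[str]] = {}
    for vid, gene in zip(df["variant_id"], df["gene"]):
        out.setdefault(vid, set()).add(gene)
    return {v: tuple(sorted(g)) for v, g in out.items()}


def read_panel(path_geno: str | Path, path_pops: str | Path) -> PopulationPanel:
    """Read a reference panel: genotype table/VCF plus (sample_id, population) TSV."""
    p = str(path_geno)
    matrix = read_vcf(p) if p.endswith((".vcf", ".vcf.gz", ".vcf.bgz")) else read_table(p)
    df = pd.read_csv(path_pops, sep="\t", dtype=str)
    _require_columns(df, ("sample_id", "population"), path_pops)
    return PopulationPanel(matrix=matrix, population_of=dict(zip(df["sample_id"], df["population"])))


def read_prevalence(path: str | Path) -> dict[str, float]:
    """Read a prevalence TSV (population, prevalence) with proportions in (0,1)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("population", "prevalence"), path)
    out: dict[str, float] = {}
    for pop, prev in zip(df["population"], df["prevalence"]):
        prev = float(prev)
        if not 0.0 < prev < 1.0:
            raise ValueError(f"prevalence for {pop} is {prev}; must be a proportion in (0,1)")
        out[str(pop)] = prev
    return out


def load_table2_prevalence() -> dict[str, float]:
    """The shipped nine-population psoriasis prevalence fixture (proportions)."""
    with resources.as_file(resources.files("cgcp.data") / "table2_prevalence.tsv") as p:
        return read_prevalence(p)


# ---------------------------------------------------------------------------
# combination tables
# ---------------------------------------------------------------------------

_COMBO_COLUMNS = [
    "combo_key", "variant_ids", "genotype_codes", "case_carriers",
    "control_carriers", "alpha_product", "Fhat_product", "genes",
    "alpha", "beta", "fhat",
]


def write_combinations(combos: Iterable, path: str | Path,
                       gene_map: Mapping[str, tuple[str, ...]] | None = None) -> None:
    """Write combinations as TSV, sorted by descending case carriers then key.

    Per-key alpha/beta/F-hat vectors are carried in extra trailing columns so
    the table round-trips losslessly through :func:`read_combinations`.
    """
    rows = []
    for c in combos:
        genes = ""
        if gene_map is not None:
            genes = ",".join(gene_map.get(k.variant_id, ("?",))[0] for k in c.keys)
        rows.append({
            "combo_key": c.combo_key,
            "variant_ids": ",".join(k.variant_id for k in c.keys),
            "genotype_codes": ",".join(str(k.genotype_code) for k in c.keys),
            "case_carriers": c.case_carriers,
            "control_carriers": c.control_carriers,
            "alpha_product": repr(float(c.alpha_product)),
            "Fhat_product": repr(float(c.fhat_product)),
            "genes": genes,
            "alpha": ",".join(repr(float(x)) for x in c.alpha),
            "beta": ",".join(repr(float(x)) for x in c.beta),
            "fhat": ",".join(repr(float(x)) for x in c.fhat),
        })
    df = pd.DataFrame(rows, columns=_COMBO_COLUMNS)
    df = df.sort_values(
        ["case_carriers", "combo_key"], ascending=[False, True], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False)


def read_combinations(path: str | Path) -> list:
    """Read a combination TSV back into :class:`~cgcp.cgcp_core.Combination` records."""
    from .cgcp_core import Combination, GenotypeKey

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        vids = row["variant_ids"].split(",")
        codes = [int(x) for x in row["genotype_codes"].split(",")]
        keys = tuple(GenotypeKey(v, g) for v, g in zip(vids, codes))
        out.append(Combination(
            keys=keys,
            case_carriers=int(row["case_carriers"]),
            control_carriers=int(row["control_carriers"]),
            alpha=tuple(float(x) for x in row["alpha"].split(",")),
            beta=tuple(float(x) for x in row["beta"].split(",")),
            fhat=tuple(float(x) for x in row["fhat"].split(",")),
        ))
    return out


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns {missing}")
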