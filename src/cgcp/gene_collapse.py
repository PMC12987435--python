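"""Collapse genotype combinations into combinations of variants of genes.

Each SNP in a combination is annotated to its gene; combinations whose SNPs
map to the same multiset of genes merge into one gene-level combination.  The
multiset is deliberate: two SNPs in the same gene yield a repeated symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cgcp_core import Combination


@dataclass
class GeneCombination:
    """A gene-level combination: sorted gene multiset plus its member combinations."""

    genes: tuple[str, ...]
    member_combinations: list[Combination]

    @property
    def n_members(self) -> int:
        return len(self.member_combinations)

    @property
    def max_case_carriers(self) -> int:
        return max(c.case_carriers for c in self.member_combinations)

    @property
    def gene_key(self) -> str:
        return "|".join(self.genes)


def _gene_of(variant_id: str, gene_map: Mapping[str, Sequence[str] | str],
             multi_gene: str) -> tuple[str, ...]:
    genes = gene_map[variant_id]
    if isinstance(genes, str):
        genes = (genes,)
    genes = tuple(sorted(genes))
    if multi_gene == "first":
        return genes[:1]
    return genes


def collapse(combinations: Iterable[Combination],
             gene_map: Mapping[str, Sequence[str] | str],
             on_unmapped: str = "error",
             multi_gene: str = "first") -> list[GeneCombination]:
    """Group combinations by the sorted multiset of genes their variants map to.

    Parameters
    ----------
    gene_map
        variant id -> gene symbol (or sequence of symbols for overlapping loci).
    on_unmapped
        "error" (default): raise listing all unmapped variant ids;
        "drop": silently drop combinations containing unmapped variants.
    multi_gene
        "first" (default): a multi-gene variant contributes its
        lexicographically first gene; "all": it contributes every gene.

    Output is sorted by descending member count, ties by gene key; member
    lists partition the kept input.
    """
    if on_unmapped not in ("error", "drop"):
        raise ValueError(f"unknown on_unmapped mode {on_unmapped!r}")
    combinations = list(combinations)
    unmapped = sorted({
        k.variant_id for c in combinations for k in c.keys
        if k.variant_id not in gene_map
    })
    if unmapped and on_unmapped == "error":
        raise KeyError(f"variants missing from gene map: {unmapped}")

    groups: dict[tuple[str, ...], list[Combination]] = {}
    for combo in combinations:
        if any(k.variant_id not in gene_map for k in combo.keys):
            continue
        genes: list[str] = []
        for k in combo.keys:
            genes.extend(_gene_of(k.variant_id, gene_map, multi_gene))
        key = tuple(sorted(genes))
        groups.setdefault(key, []).append(combo)

    out = [GeneCombination(genes=k, member_combinations=v) for k, v in groups.items()]
    out.sort(key=lambda g: (-g.n_members, g.gene_key))
    return out


def unique_gene_inventory(gene_combinations: Iterable[GeneCombination]
                          ) -> tuple[int, list[str]]:
    """(number of distinct gene multisets, sorted union of genes involved)."""
    seen: set[tuple[str, ...]] = set()
    genes: set[str] = set()
    for gc in gene_combinations:
        seen.add(gc.genes)
        genes.update(gc.genes)
    return len(seen), sorted(genes)
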