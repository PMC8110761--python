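"""Transgressive-gene sets, over/under bias testing and shared-DEG logic."""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import chi2

from .io import ValidationError

__all__ = [
    "GeneSet",
    "BiasTestResult",
    "transgressive_sets",
    "bias_test",
    "shared_sets",
    "read_gene_set",
    "write_gene_set",
    "write_regions",
]


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def transgressive_sets(
    de_hp1: pd.DataFrame, de_hp2: pd.DataFrame, labels: tuple[str, str] = ("over_both", "under_both")
) -> tuple[GeneSet, GeneSet]:
    """Genes called over (resp. under) vs BOTH parents.

    The two input tables are the called hybrid-vs-parent comparisons over
    the same gene universe; the returned sets are disjoint by
    construction and equal the overdominant/underdominant classes of the
    trio classifier on the same inputs.
    """
    for name, tab in (("de_hp1", de_hp1), ("de_hp2", de_hp2)):
        if "call" not in tab.columns:
            raise ValidationError(f"{name} lacks a 'call' column")
    if set(de_hp1.index) != set(de_hp2.index):
        raise ValidationError("DE tables cover different gene universes")
    c1 = de_hp1["call"]
    c2 = de_hp2.loc[de_hp1.index, "call"]
    over = frozenset(de_hp1.index[(c1 == "over") & (c2 == "over")])
    under = frozenset(de_hp1.index[(c1 == "under") & (c2 == "under")])
    return GeneSet(labels[0], over), GeneSet(labels[1], under)


@dataclass(frozen=True)
class BiasTestResult:
    n_over: int
    n_under: int
    statistic: float
    df: int
    pvalue: float


def bias_test(n_over: int, n_under: int, *, correction: bool = True) -> BiasTestResult:
    """Two-sided one-sample test of equal over/under proportions.

    Chi-square goodness of fit against p = 0.5 with Yates continuity
    correction (as in R's ``prop.test``):
    ``X2 = sum((|obs - exp| - 0.5)**2 / exp)`` over the two cells, df 1.
    """
    if n_over < 0 or n_under < 0:
        raise ValidationError("counts must be non-negative")
    n = n_over + n_under
    if n < 1:
        raise ValidationError("bias test needs at least one gene")
    expected = n / 2.0
    c = 0.5 if correction else 0.0
    stat = sum((abs(obs - expected) - c) ** 2 / expected for obs in (n_over, n_under))
    pvalue = float(chi2.sf(stat, df=1))
    return BiasTestResult(int(n_over), int(n_under), float(stat), 1, pvalue)


def shared_sets(sets: Sequence[GeneSet]) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-region counts for 2-5 labelled gene sets.

    Keys are tuples of labels; the region keyed by ``(a, b)`` counts the
    genes in exactly sets ``a`` and ``b`` and no other.  Regions
    partition the union of the sets.
    """
    if not 2 <= len(sets) <= 5:
        raise ValidationError("shared_sets supports between 2 and 5 sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError("set labels must be unique")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            inside = frozenset.intersection(*(sets[i].genes for i in combo))
            outside = frozenset().union(
                *(sets[i].genes for i in range(len(sets)) if i not in combo)
            )
            regions[tuple(labels[i] for i in combo)] = len(inside - outside)
    return regions


def read_gene_set(path: str | Path) -> GeneSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"label", "gene_id"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns (label, gene_id)")
    labels = df["label"].unique()
    if len(labels) > 1:
        raise ValidationError(f"{path}: multiple labels in one gene-set file")
    label = labels[0] if len(labels) else Path(path).stem
    return GeneSet(str(label), frozenset(df["gene_id"]))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    pd.DataFrame(
        {"label": gene_set.label, "gene_id": sorted(gene_set.genes)}
    ).to_csv(path, sep="\t", index=False)


def write_regions(regions: dict[tuple[str, ...], int], path: str | Path) -> None:
    rows = [{"region": "&".join(k), "n_sets": len(k), "count": v} for k, v in regions.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
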