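"""Ortholog-mediated term over-representation analysis.

Focal gene sets are first translated to reference-species orthologs via
a partial single-valued map; terms annotate orthologs.  Enrichment of a
study set against a background uses the upper-tail hypergeometric test
(one-sided Fisher) with Benjamini-Hochberg FDR correction.  Terms whose
background member sets are identical are merged before testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from .de import adjust_fdr
from .io import ValidationError
from .setops import GeneSet

__all__ = [
    "AnnotationTable",
    "map_orthologs",
    "enrich",
    "read_annotation",
    "write_annotation",
    "write_enrichment",
]


@dataclass(frozen=True)
class AnnotationTable:
    """Gene -> ortholog map plus ortholog -> term annotation."""

    ortholog_map: Mapping[str, str]
    term_map: Mapping[str, frozenset[str]]
    term_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for orth, terms in self.term_map.items():
            if not terms:
                raise ValidationError(f"ortholog {orth!r} has an empty term set")


def map_orthologs(genes: GeneSet, table: AnnotationTable) -> tuple[GeneSet, list[str]]:
    """Translate a focal gene set through the ortholog map.

    Returns the image as a gene set of ortholog identifiers plus the
    list of unmapped focal genes.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in sorted(genes.genes):
        if g in table.ortholog_map:
            mapped.add(table.ortholog_map[g])
        else:
            unmapped.append(g)
    return GeneSet(f"{genes.label}_orthologs", frozenset(mapped)), unmapped


def enrich(
    study: GeneSet,
    background: GeneSet,
    table: AnnotationTable,
    alpha: float = 0.05,
    *,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Term over-representation of ``study`` against ``background``.

    Both sets are focal gene sets; they are ortholog-mapped first and
    the study must be a subset of the background after mapping.  For
    each term with background members, ``p = P(X >= k)`` with
    ``X ~ Hypergeom(N, K, n)`` (or two-sided Fisher when requested);
    BH-adjusted q-values are reported alongside fold enrichment
    ``(k/n) / (K/N)``.  Rows are sorted by (padj, pvalue, term).
    """
    study_orth, _ = map_orthologs(study, table)
    bg_orth, _ = map_orthologs(background, table)
    if not study_orth.genes <= bg_orth.genes:
        extra = sorted(study_orth.genes - bg_orth.genes)
        raise ValidationError(
            f"study set is not a subset of the background after mapping "
            f"({len(extra)} extra orthologs, e.g. {extra[:3]})"
        )
    N = len(bg_orth.genes)
    n = len(study_orth.genes)
    if n < 1:
        raise ValidationError("study set has no mapped orthologs")

    # term -> background members, merging terms with identical member sets
    members: dict[str, frozenset[str]] = {}
    for orth in bg_orth.genes:
        for term in table.term_map.get(orth, ()):  # type: ignore[call-overload]
            members.setdefault(term, frozenset())
    for term in members:
        members[term] = frozenset(
            o for o in bg_orth.genes if term in table.term_map.get(o, frozenset())
        )
    merged: dict[frozenset[str], list[str]] = {}
    for term, mem in sorted(members.items()):
        merged.setdefault(mem, []).append(term)

    rows = []
    for mem, terms in merged.items():
        K = len(mem)
        if K == 0:
            continue
        k = len(mem & study_orth.genes)
        if two_sided:
            tab2 = [[k, K - k], [n - k, (N - K) - (n - k)]]
            p = float(fisher_exact(tab2, alternative="two-sided")[1])
        else:
            p = float(hypergeom.sf(k - 1, N, K, n))
        term_id = "|".join(sorted(terms))
        name = " | ".join(
            table.term_names.get(t, t) for t in sorted(terms)
        )
        fold = (k / n) / (K / N) if k else 0.0
        rows.append(
            {"term": term_id, "name": name, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fold, "pvalue": min(p, 1.0)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "n", "K", "N", "fold_enrichment",
                     "pvalue", "padj", "significant"]
        )
    out = pd.DataFrame(rows)
    out["padj"] = adjust_fdr(out["pvalue"].to_numpy())
    out["significant"] = out["padj"] < alpha
    out = out.sort_values(["padj", "pvalue", "term"], kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_annotation(orthologs_path: str | Path, terms_path: str | Path) -> AnnotationTable:
    """Read (gene_id, ortholog_id) and (ortholog_id, term_id, term_name) TSVs."""
    odf = pd.read_csv(orthologs_path, sep="\t", dtype=str)
    if odf.shape[1] < 2:
        raise ValidationError(f"{orthologs_path}: expected (gene_id, ortholog_id)")
    gcol, ocol = odf.columns[0], odf.columns[1]
    if odf[gcol].duplicated().any():
        dups = odf.loc[odf[gcol].duplicated(), gcol].tolist()
        raise ValidationError(f"gene mapped to multiple orthologs: {dups[:5]}")
    ortholog_map = dict(zip(odf[gcol], odf[ocol]))

    tdf = pd.read_csv(terms_path, sep="\t", dtype=str)
    if tdf.shape[1] < 2:
        raise ValidationError(f"{terms_path}: expected (ortholog_id, term_id[, term_name])")
    oc, tc = tdf.columns[0], tdf.columns[1]
    term_map: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for _, row in tdf.iterrows():
        term_map.setdefault(row[oc], set()).add(row[tc])
        if tdf.shape[1] > 2 and pd.notna(row[tdf.columns[2]]):
            term_names[row[tc]] = row[tdf.columns[2]]
    frozen = {o: frozenset(ts) for o, ts in term_map.items()}
    return AnnotationTable(ortholog_map, frozen, term_names)


def write_annotation(table: AnnotationTable, orthologs_path: str | Path, terms_path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.ortholog_map.items()), columns=["gene_id", "ortholog_id"]
    ).to_csv(orthologs_path, sep="\t", index=False)
    rows = [
        {"ortholog_id": o, "term_id": t, "term_name": table.term_names.get(t, t)}
        for o, ts in sorted(table.term_map.items())
        for t in sorted(ts)
    ]
    pd.DataFrame(rows, columns=["ortholog_id", "term_id", "term_name"]).to_csv(
        terms_path, sep="\t", index=False
    )


def write_enrichment(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False)
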