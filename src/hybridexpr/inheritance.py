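"""Six-category inheritance-mode classification of hybrid expression.

Each gene carries three pairwise DE calls made at the same thresholds
(|log2fc| > 1, padj < 0.01): hybrid vs parent 1 (``c1``), hybrid vs
parent 2 (``c2``) and parent 1 vs parent 2 (``cp``).  The call pattern
maps deterministically onto {conserved, additive, P1_dominant,
P2_dominant, overdominant, underdominant}; the 12 residual patterns of
the 27-pattern space (e.g. hybrid above one parent and below the other
with equal parents) are reported as ``ambiguous``, never silently
merged.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import ValidationError

CATEGORIES = (
    "conserved",
    "additive",
    "P1_dominant",
    "P2_dominant",
    "overdominant",
    "underdominant",
)
ALL_CATEGORIES = CATEGORIES + ("ambiguous",)

_CALL_SIGN = {"over": 1, "under": -1, "ns": 0}
_SIGN_SYMBOL = {1: "+", -1: "-", 0: "0"}

__all__ = [
    "CATEGORIES",
    "ALL_CATEGORIES",
    "ProfileTest",
    "classify_trio",
    "classify_all",
    "profile_from_table",
    "compare_profiles",
]


def classify_trio(c1: int, c2: int, cp: int) -> str:
    """Map one call pattern to its inheritance category.

    ``c1`` = call(hybrid vs P1), ``c2`` = call(hybrid vs P2), ``cp`` =
    call(P1 vs P2); each is +1 (over), -1 (under) or 0 (ns).
    """
    for name, c in (("c1", c1), ("c2", c2), ("cp", cp)):
        if c not in (-1, 0, 1):
            raise ValidationError(f"{name} must be one of -1, 0, 1; got {c!r}")
    if c1 == 0 and c2 == 0:
        return "conserved"
    if c1 == 1 and c2 == 1:
        return "overdominant"
    if c1 == -1 and c2 == -1:
        return "underdominant"
    if c1 != 0 and c2 != 0 and c1 == -c2 and cp != 0 and cp == c2:
        return "additive"
    if c1 == 0 and c2 != 0 and cp != 0 and cp == c2:
        return "P1_dominant"
    if c2 == 0 and c1 != 0 and cp != 0 and cp == -c1:
        return "P2_dominant"
    return "ambiguous"


def classify_all(
    de_hp1: pd.DataFrame, de_hp2: pd.DataFrame, de_p1p2: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every gene from its three called DE tables.

    The tables must carry ``call`` and ``log2fc`` columns and cover the
    same (post-filter) gene universe.  Returns the per-gene table
    (calls, fold changes, category) and the category profile.
    """
    for name, tab in (("de_hp1", de_hp1), ("de_hp2", de_hp2), ("de_p1p2", de_p1p2)):
        for col in ("call", "log2fc"):
            if col not in tab.columns:
                raise ValidationError(f"{name} lacks required column {col!r}")
    u1, u2, up = set(de_hp1.index), set(de_hp2.index), set(de_p1p2.index)
    if not (u1 == u2 == up):
        diff = (u1 ^ u2) | (u1 ^ up) | (u2 ^ up)
        raise ValidationError(
            f"gene universes differ between DE tables ({len(diff)} genes in the "
            "symmetric difference)"
        )
    genes = de_hp1.index
    c1 = de_hp1["call"].map(_CALL_SIGN).to_numpy()
    c2 = de_hp2.loc[genes, "call"].map(_CALL_SIGN).to_numpy()
    cp = de_p1p2.loc[genes, "call"].map(_CALL_SIGN).to_numpy()
    if any(np.isnan(v).any() for v in (c1, c2, cp)):
        raise ValidationError("calls must be one of 'over', 'under', 'ns'")
    cats = [classify_trio(int(a), int(b), int(c)) for a, b, c in zip(c1, c2, cp)]
    table = pd.DataFrame(
        {
            "c1": [_SIGN_SYMBOL[int(v)] for v in c1],
            "c2": [_SIGN_SYMBOL[int(v)] for v in c2],
            "cp": [_SIGN_SYMBOL[int(v)] for v in cp],
            "log2fc_HP1": de_hp1["log2fc"].to_numpy(),
            "log2fc_HP2": de_hp2.loc[genes, "log2fc"].to_numpy(),
            "log2fc_P1P2": de_p1p2.loc[genes, "log2fc"].to_numpy(),
            "category": cats,
        },
        index=genes,
    )
    table.index.name = "gene_id"
    return table, profile_from_table(table)


def profile_from_table(table: pd.DataFrame) -> dict[str, int]:
    """Category -> gene count, with every category present (zeros kept)."""
    counts = table["category"].value_counts()
    return {cat: int(counts.get(cat, 0)) for cat in ALL_CATEGORIES}


@dataclass(frozen=True)
class ProfileTest:
    statistic: float
    df: int
    pvalue: float
    dropped: tuple[str, ...] = ()


def compare_profiles(a: Mapping[str, int], b: Mapping[str, int]) -> ProfileTest:
    """Pearson chi-square on the 2 x k table of two category profiles.

    No continuity correction; categories with zero total count are
    dropped symmetrically and reported in ``dropped``.
    """
    cats = [c for c in ALL_CATEGORIES if c in a or c in b]
    cats += [c for c in {**a, **b} if c not in cats]
    row_a = np.array([a.get(c, 0) for c in cats], dtype=float)
    row_b = np.array([b.get(c, 0) for c in cats], dtype=float)
    if (row_a < 0).any() or (row_b < 0).any():
        raise ValidationError("profile counts must be non-negative")
    if row_a.sum() == 0 or row_b.sum() == 0:
        raise ValidationError("cannot compare an all-zero profile")
    keep = (row_a + row_b) > 0
    dropped = tuple(c for c, k in zip(cats, keep) if not k)
    row_a, row_b = row_a[keep], row_b[keep]
    if keep.sum() < 2:
        return ProfileTest(0.0, 0, 1.0, dropped)
    res = chi2_contingency(np.vstack([row_a, row_b]), correction=False)
    return ProfileTest(float(res.statistic), int(res.dof), float(res.pvalue), dropped)
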