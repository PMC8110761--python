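"""Synthetic parent + reciprocal-hybrid count experiments with known truth.

Counts are drawn from a negative binomial with mean
``depth_factor * true_mu`` and dispersion ``alpha`` (variance
``mu + alpha * mu**2``; ``alpha = 0`` falls back to Poisson).  Baseline
expression is log-normal on the log2 scale and expected counts are
floored at one read.  Per gene and tissue an inheritance category is
drawn; condition means follow from it:

* conserved       -- parents equal, hybrid equal
* additive        -- parents diverge by ``parental_divergence_log2``,
                     hybrid at the geometric mean (log-scale midpoint)
* P1/P2_dominant  -- parents diverge, hybrid matches one parent
* overdominant    -- hybrid exceeds both parents by
                     ``transgressive_shift_log2`` (log2)
* underdominant   -- hybrid below both parents by the same shift

``under_bias`` sets the fraction of transgressive genes that are
underdominant per tissue.  Both reciprocal hybrids share the category
draw by default; with ``reciprocal_independent=True`` the reverse-cross
hybrid redraws its category among those compatible with the sampled
parental state, emulating maternal-effect asymmetry.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .inheritance import CATEGORIES
from .io import CountMatrix, SampleDesign
from .enrichment import AnnotationTable

__all__ = [
    "SimConfig",
    "SimConfigError",
    "simulate_experiment",
    "simulate_annotation",
    "truth_summary",
    "write_truth",
    "read_truth",
]

TRANSGRESSIVE = ("overdominant", "underdominant")

DEFAULT_PROPORTIONS: dict[str, dict[str, float]] = {
    "ovary": {
        "conserved": 0.978,
        "additive": 0.001,
        "P1_dominant": 0.012,
        "P2_dominant": 0.003,
        "transgressive": 0.006,
    },
    "testis": {
        "conserved": 0.785,
        "additive": 0.0145,
        "P1_dominant": 0.0950,
        "P2_dominant": 0.0200,
        "transgressive": 0.0855,
    },
}
DEFAULT_UNDER_BIAS = {"ovary": 0.5, "testis": 0.675}


class SimConfigError(ValueError):
    """A simulation parameter is invalid; the message names the field."""


@dataclass
class SimConfig:
    n_genes: int = 11654
    n_replicates: int = 2
    tissues: Sequence[str] = ("ovary", "testis")
    hybrids: Sequence[str] = ("H_fwd", "H_rev")
    category_proportions: Mapping[str, Mapping[str, float]] | None = None
    parental_divergence_log2: float = 2.0
    transgressive_shift_log2: float = 2.0
    under_bias: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_UNDER_BIAS)
    )
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    dispersion: float | Sequence[float] = 0.05
    depth_factors: Mapping[str, float] | Sequence[float] | float | None = None
    reciprocal_independent: bool = False
    seed: int = 0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be a positive integer")
        if self.n_replicates < 1:
            raise SimConfigError("n_replicates must be >= 1")
        if not self.tissues:
            raise SimConfigError("tissues must be non-empty")
        if self.parental_divergence_log2 < 0:
            raise SimConfigError("parental_divergence_log2 must be >= 0")
        if self.transgressive_shift_log2 < 0:
            raise SimConfigError("transgressive_shift_log2 must be >= 0")
        if self.baseline_log2_sd < 0:
            raise SimConfigError("baseline_log2_sd must be >= 0")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp < 0).any() or np.isnan(disp).any():
            raise SimConfigError("dispersion must be >= 0")
        if disp.size not in (1, self.n_genes):
            raise SimConfigError("dispersion must be scalar or one value per gene")
        for tissue in self.tissues:
            props = self.proportions_for(tissue)
            self.resolved_proportions(tissue)  # rejects unknown category keys
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise SimConfigError(
                    f"category_proportions for tissue {tissue!r} sum to {total}, not 1"
                )
            if any(v < 0 for v in props.values()):
                raise SimConfigError(
                    f"category_proportions for tissue {tissue!r} contain negatives"
                )
            bias = self.under_bias_for(tissue)
            if not 0.0 <= bias <= 1.0:
                raise SimConfigError(f"under_bias for tissue {tissue!r} must be in [0, 1]")
        depths = self._depth_array()
        if (depths <= 0).any() or not np.all(np.isfinite(depths)):
            raise SimConfigError("depth_factors must all be positive and finite")

    # -- helpers -----------------------------------------------------------
    @property
    def conditions(self) -> tuple[str, ...]:
        return ("P1", "P2") + tuple(self.hybrids)

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{tissue}_{line}_{rep}"
            for tissue in self.tissues
            for line in self.conditions
            for rep in range(1, self.n_replicates + 1)
        ]

    def proportions_for(self, tissue: str) -> dict[str, float]:
        """Raw per-tissue proportions (may use the 'transgressive' pool)."""
        table = self.category_proportions or DEFAULT_PROPORTIONS
        if tissue in table:
            return dict(table[tissue])
        if self.category_proportions is None:
            # unknown tissue under default config: reuse the ovary-like profile
            return dict(DEFAULT_PROPORTIONS["ovary"])
        raise SimConfigError(f"category_proportions missing tissue {tissue!r}")

    def under_bias_for(self, tissue: str) -> float:
        if isinstance(self.under_bias, Mapping):
            return float(self.under_bias.get(tissue, 0.5))
        return float(self.under_bias)

    def resolved_proportions(self, tissue: str) -> dict[str, float]:
        """Six-category proportions with the transgressive pool split."""
        props = self.proportions_for(tissue)
        extra = {k for k in props if k not in CATEGORIES and k != "transgressive"}
        if extra:
            raise SimConfigError(
                f"category_proportions for tissue {tissue!r} has unknown "
                f"categories: {sorted(extra)}"
            )
        out = {cat: float(props.get(cat, 0.0)) for cat in CATEGORIES}
        if "transgressive" in props:
            bias = self.under_bias_for(tissue)
            out["underdominant"] += props["transgressive"] * bias
            out["overdominant"] += props["transgressive"] * (1.0 - bias)
        return out

    def _depth_array(self) -> np.ndarray:
        samples = self.sample_ids
        d = self.depth_factors
        if d is None:
            return np.ones(len(samples))
        if isinstance(d, Mapping):
            missing = [s for s in samples if s not in d]
            if missing:
                raise SimConfigError(f"depth_factors missing samples: {missing[:5]}")
            return np.array([float(d[s]) for s in samples])
        arr = np.atleast_1d(np.asarray(d, dtype=float))
        if arr.size == 1:
            return np.full(len(samples), float(arr[0]))
        if arr.size != len(samples):
            raise SimConfigError(
                f"depth_factors has {arr.size} values for {len(samples)} samples"
            )
        return arr

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["tissues"] = list(self.tissues)
        data["hybrids"] = list(self.hybrids)
        if isinstance(data.get("dispersion"), np.ndarray):
            data["dispersion"] = data["dispersion"].tolist()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Draw a full parent/hybrid count experiment plus its truth table.

    Deterministic for a fixed config (a single seeded generator drives
    all randomness).  The truth table has one row per gene x tissue with
    the sampled category and the per-condition expected means.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(1, n + 1)]
    disp = np.atleast_1d(np.asarray(config.dispersion, dtype=float))
    alpha = np.full(n, float(disp[0])) if disp.size == 1 else disp.astype(float)
    depths = config._depth_array()
    sample_ids = config.sample_ids
    depth_of = dict(zip(sample_ids, depths))

    design_rows = [
        {"sample_id": f"{tissue}_{line}_{rep}", "line": line, "tissue": tissue,
         "replicate": rep}
        for tissue in config.tissues
        for line in config.conditions
        for rep in range(1, config.n_replicates + 1)
    ]
    design = SampleDesign(pd.DataFrame(design_rows))

    half = config.parental_divergence_log2 / 2.0
    shift = config.transgressive_shift_log2
    blocks: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []

    for tissue in config.tissues:
        props = config.resolved_proportions(tissue)
        pvec = np.array([props[c] for c in CATEGORIES])
        base = np.maximum(2.0 ** rng.normal(config.baseline_log2_mean,
                                            config.baseline_log2_sd, n), 1.0)
        cats = rng.choice(len(CATEGORIES), size=n, p=pvec)
        sign = rng.choice([-1.0, 1.0], size=n)
        cat_names = np.array(CATEGORIES, dtype=object)[cats]

        diverged = np.isin(cat_names, ("additive", "P1_dominant", "P2_dominant"))
        mu_p1 = np.where(diverged, base * 2.0 ** (sign * half), base)
        mu_p2 = np.where(diverged, base * 2.0 ** (-sign * half), base)
        mu_h = _hybrid_mean(cat_names, base, mu_p1, mu_p2, shift)

        if config.reciprocal_independent:
            cat_rev = _redraw_compatible(rng, cat_names, diverged, props)
            mu_h_rev = _hybrid_mean(cat_rev, base, mu_p1, mu_p2, shift)
        else:
            cat_rev = cat_names
            mu_h_rev = mu_h

        mu_by_line = {"P1": mu_p1, "P2": mu_p2}
        if config.hybrids:
            mu_by_line[config.hybrids[0]] = mu_h
        for extra in config.hybrids[1:]:
            mu_by_line[extra] = mu_h_rev

        tissue_samples = [s for s in sample_ids if s.startswith(f"{tissue}_")]
        mu_mat = np.column_stack(
            [np.maximum(mu_by_line[design.condition_of(s)[0]], 1.0) * depth_of[s]
             for s in tissue_samples]
        )
        counts = _draw_counts(rng, mu_mat, alpha)
        blocks.append(pd.DataFrame(counts, index=genes, columns=tissue_samples))

        truth = pd.DataFrame(
            {
                "gene_id": genes,
                "tissue": tissue,
                "true_category": cat_names,
                "mu_P1": np.maximum(mu_p1, 1.0),
                "mu_P2": np.maximum(mu_p2, 1.0),
            }
        )
        if config.hybrids:
            truth[f"mu_{config.hybrids[0]}"] = np.maximum(mu_h, 1.0)
        for extra in config.hybrids[1:]:
            truth[f"mu_{extra}"] = np.maximum(mu_h_rev, 1.0)
        if config.reciprocal_independent:
            truth["true_category_rev"] = cat_rev
        truth_rows.append(truth)

    matrix = CountMatrix(pd.concat(blocks, axis=1))
    truth_table = pd.concat(truth_rows, ignore_index=True)
    return matrix, design, truth_table


def _hybrid_mean(cat_names, base, mu_p1, mu_p2, shift):
    hi = np.maximum(mu_p1, mu_p2)
    lo = np.minimum(mu_p1, mu_p2)
    return np.select(
        [
            cat_names == "conserved",
            cat_names == "additive",
            cat_names == "P1_dominant",
            cat_names == "P2_dominant",
            cat_names == "overdominant",
            cat_names == "underdominant",
        ],
        [base, np.sqrt(mu_p1 * mu_p2), mu_p1, mu_p2,
         hi * 2.0 ** shift, lo * 2.0 ** (-shift)],
    )


def _redraw_compatible(rng, cat_names, diverged, props):
    """Redraw categories for the reverse cross, respecting parental state."""
    equal_pool = ["conserved", "overdominant", "underdominant"]
    div_pool = ["additive", "P1_dominant", "P2_dominant", "overdominant", "underdominant"]
    out = np.array(cat_names, dtype=object)
    for pool, mask in ((equal_pool, ~diverged), (div_pool, diverged)):
        if not mask.any():
            continue
        weights = np.array([max(props[c], 1e-12) for c in pool])
        weights = weights / weights.sum()
        draws = rng.choice(len(pool), size=int(mask.sum()), p=weights)
        out[mask] = np.array(pool, dtype=object)[draws]
    return out


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        a = alpha[nb][:, None]
        m = mean[nb]
        size = 1.0 / a
        p = size / (size + m)
        out[nb] = rng.negative_binomial(size, p)
    return out


# ---------------------------------------------------------------------------
# Annotation simulation and truth helpers
# ---------------------------------------------------------------------------

def simulate_annotation(
    n_genes: int,
    n_terms: int,
    genes_per_term: float = 20.0,
    seed: int = 0,
    *,
    mapping_rate: float = 0.85,
    gene_ids: Sequence[str] | None = None,
) -> AnnotationTable:
    """Random ortholog map and term annotation with a known mapping rate.

    Each gene independently receives a unique ortholog with probability
    ``mapping_rate``; each of the ``n_terms`` terms annotates a random
    subset of mapped orthologs with Poisson(``genes_per_term``) size
    (floored at one, capped at the mapped count).
    """
    if n_genes < 1:
        raise SimConfigError("n_genes must be >= 1")
    if n_terms < 1:
        raise SimConfigError("n_terms must be >= 1")
    if not 0.0 <= mapping_rate <= 1.0:
        raise SimConfigError("mapping_rate must be in [0, 1]")
    if genes_per_term <= 0:
        raise SimConfigError("genes_per_term must be positive")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    elif len(gene_ids) != n_genes:
        raise SimConfigError("gene_ids length must equal n_genes")
    mapped_mask = rng.random(n_genes) < mapping_rate
    ortholog_map = {
        g: f"OG{i:05d}" for i, (g, m) in enumerate(zip(gene_ids, mapped_mask), 1) if m
    }
    orthologs = sorted(ortholog_map.values())
    term_map: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for j in range(1, n_terms + 1):
        term = f"T{j:04d}"
        term_names[term] = f"term {j}"
        if not orthologs:
            continue
        size = min(max(1, int(rng.poisson(genes_per_term))), len(orthologs))
        chosen = rng.choice(len(orthologs), size=size, replace=False)
        for idx in chosen:
            term_map.setdefault(orthologs[idx], set()).add(term)
    frozen = {o: frozenset(ts) for o, ts in term_map.items()}
    return AnnotationTable(ortholog_map, frozen, term_names)


def truth_summary(truth: pd.DataFrame, tissue: str | None = None) -> dict[str, int]:
    """Counts per true category (over all rows, or one tissue)."""
    sub = truth if tissue is None else truth[truth["tissue"] == tissue]
    counts = sub["true_category"].value_counts()
    return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str})
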