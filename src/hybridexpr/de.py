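"""Negative-binomial differential expression between two conditions.

The model is NB with mean ``mu`` and dispersion ``alpha`` (variance
``mu + alpha * mu**2``; ``alpha = 0`` degenerates to Poisson).  Samples
are normalized by median-of-ratios size factors, per-gene dispersions
are method-of-moments estimates shrunk toward a mean-dispersion trend,
and each contrast is tested with a Wald statistic on the log2 fold
change against the standard normal.  Multiple testing uses
Benjamini-Hochberg step-up; the default call rule is padj < 0.01 and
|log2fc| > 1 (a twofold change).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, SampleDesign, ValidationError

__all__ = [
    "Contrast",
    "estimate_size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "adjust_fdr",
    "call_deg",
    "read_de_table",
    "write_de_table",
]

DE_COLUMNS = ("base_mean", "log2fc", "se", "stat", "pvalue")
CALLS = ("over", "under", "ns")


@dataclass(frozen=True)
class Contrast:
    """Numerator and denominator conditions, each a (line, tissue) pair."""

    numerator: tuple[str, str]
    denominator: tuple[str, str]

    def __post_init__(self) -> None:
        if tuple(self.numerator) == tuple(self.denominator):
            raise ValidationError("contrast conditions must be distinct")

    def swapped(self) -> "Contrast":
        return Contrast(self.denominator, self.numerator)

    def label(self) -> str:
        n, d = self.numerator, self.denominator
        return f"{n[0]}_vs_{d[0]}@{n[1]}"


def estimate_size_factors(
    matrix: CountMatrix, *, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, computed
    on genes with all-nonzero counts; ``s_j`` is the median over those
    genes of ``count_gj / reference_g``.  With ``pseudo_reference=True``
    the geometric mean ignores zero entries so that sparse matrices with
    no everywhere-nonzero gene can still be normalized.
    """
    counts = matrix.values.astype(float)
    if counts.size == 0:
        raise ValidationError("empty count matrix")
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    if pseudo_reference:
        pos = counts > 0
        usable = pos.any(axis=1)
        if not usable.any():
            raise ValidationError("all counts are zero")
        ref = np.full(counts.shape[0], -np.inf)
        ref[usable] = np.where(pos[usable], logs[usable], 0.0).sum(axis=1) / pos[
            usable
        ].sum(axis=1)
    else:
        usable = (counts > 0).all(axis=1)
        if not usable.any():
            raise ValidationError(
                "no gene has nonzero counts in every sample; re-run with "
                "pseudo_reference=True"
            )
        ref = logs.mean(axis=1)
    log_ratios = logs[usable] - ref[usable, None]
    factors = np.exp(np.nanmedian(np.where(np.isfinite(log_ratios), log_ratios, np.nan), axis=0))
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValidationError("size factor estimation produced non-positive values")
    return pd.Series(factors, index=matrix.samples, name="size_factor")


def estimate_dispersion(
    matrix: CountMatrix,
    factors: pd.Series,
    design: SampleDesign,
    *,
    trend_weight: float = 0.5,
    min_mean: float = 1.0,
) -> pd.Series:
    """Per-gene NB dispersion (method of moments, trend-shrunk).

    Within each condition with >= 2 replicates the raw estimate is
    ``(v - m * h) / m**2`` where ``m`` and ``v`` are mean and variance of
    normalized counts and ``h = mean(1/s_j)`` accounts for the Poisson
    part of normalized-count variance.  Gene estimates are pooled across
    conditions (weights = residual degrees of freedom), floored at zero
    and averaged with a fitted ``a0 + a1/mu`` trend using
    ``trend_weight`` to stabilize low-replicate designs.
    """
    if not 0.0 <= trend_weight <= 1.0:
        raise ValidationError("trend_weight must be in [0, 1]")
    df = matrix.to_frame()
    s = factors.reindex(df.columns)
    if s.isna().any():
        raise ValidationError("size factors missing for some samples")
    y = df.to_numpy(float) / s.to_numpy()[None, :]
    cond_samples = {
        cond: [x for x in ss if x in df.columns]
        for cond, ss in design.condition_samples().items()
    }
    replicated = {c: ss for c, ss in cond_samples.items() if len(ss) >= 2}
    n_genes = df.shape[0]
    wsum = np.zeros(n_genes)
    wtot = np.zeros(n_genes)
    if not replicated:
        warnings.warn(
            "no condition has >= 2 replicates; dispersion set to 0 (Poisson)",
            stacklevel=2,
        )
        return pd.Series(np.zeros(n_genes), index=df.index, name="dispersion")
    cols = {c: j for j, c in enumerate(df.columns)}
    for cond, ss in replicated.items():
        idx = [cols[x] for x in ss]
        yi = y[:, idx]
        m = yi.mean(axis=1)
        v = yi.var(axis=1, ddof=1)
        h = float(np.mean(1.0 / s.to_numpy()[idx]))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m * h) / np.square(m), np.nan)
        w = len(ss) - 1
        good = np.isfinite(a)
        wsum[good] += w * a[good]
        wtot[good] += w
    with np.errstate(invalid="ignore"):
        alpha_raw = np.where(wtot > 0, wsum / np.maximum(wtot, 1e-300), np.nan)
    mu = y.mean(axis=1)
    trend = _fit_dispersion_trend(alpha_raw, mu, min_mean)
    alpha_gene = np.clip(alpha_raw, 0.0, None)
    alpha_gene = np.where(np.isfinite(alpha_gene), alpha_gene, trend)
    alpha = (1.0 - trend_weight) * alpha_gene + trend_weight * trend
    return pd.Series(np.clip(alpha, 0.0, None), index=df.index, name="dispersion")


def _fit_dispersion_trend(alpha_raw: np.ndarray, mu: np.ndarray, min_mean: float) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu, clipped at zero."""
    ok = np.isfinite(alpha_raw) & (mu >= min_mean)
    fallback = max(float(np.nanmedian(alpha_raw[ok])) if ok.any() else 0.0, 0.0)
    if ok.sum() < 10:
        return np.full(mu.shape, fallback)
    # winsorize raw estimates so a few extreme low-count genes cannot
    # dominate the fit
    a = alpha_raw[ok]
    hi = np.quantile(a, 0.99)
    a = np.clip(a, None, hi)
    X = np.column_stack([np.ones(a.size), 1.0 / mu[ok]])
    try:
        coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fixture
        return np.full(mu.shape, fallback)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(mu, min_mean)
    return np.clip(trend, 0.0, None)


def nb_wald_test(
    matrix: CountMatrix,
    factors: pd.Series,
    dispersion: pd.Series | float,
    design: SampleDesign,
    contrast: Contrast,
    *,
    zero_floor: float = 0.5,
) -> pd.DataFrame:
    """Wald test of the contrast on NB group means with size-factor offsets.

    Group means of normalized counts are the (offset) maximum-likelihood
    estimates ``q = sum(K) / sum(s)``; ``log2fc = log2(q_num / q_den)``
    with ``zero_floor`` substituted for all-zero groups.  The standard
    error follows from the NB Fisher information
    ``w_j = mu_j / (1 + alpha * mu_j)``; the two-sided p-value uses the
    standard normal reference.  Genes that are all-zero in both
    conditions get ``log2fc = 0`` and ``p = 1``.
    """
    if zero_floor <= 0:
        raise ValidationError("zero_floor must be positive")
    groups = design.condition_samples()
    for cond in (contrast.numerator, contrast.denominator):
        if tuple(cond) not in groups:
            raise ValidationError(f"condition {cond} not present in design")
    num_s = [s for s in groups[tuple(contrast.numerator)] if s in set(matrix.samples)]
    den_s = [s for s in groups[tuple(contrast.denominator)] if s in set(matrix.samples)]
    if not num_s or not den_s:
        raise ValidationError("contrast conditions have no samples in the matrix")
    if min(len(num_s), len(den_s)) < 2:
        warnings.warn(
            "a contrast condition has a single replicate; inference relies "
            "entirely on pooled dispersion",
            stacklevel=2,
        )
    df = matrix.to_frame()
    s = factors.reindex(df.columns)
    if s.isna().any() or (s <= 0).any():
        raise ValidationError("invalid size factors for matrix samples")
    if isinstance(dispersion, (int, float)):
        alpha = np.full(df.shape[0], float(dispersion))
    else:
        alpha = dispersion.reindex(df.index).to_numpy(float)
        if np.isnan(alpha).any():
            raise ValidationError("dispersion missing for some genes")
    if (alpha < 0).any():
        raise ValidationError("dispersion must be >= 0")

    Kn = df[num_s].to_numpy(float)
    Kd = df[den_s].to_numpy(float)
    sn = s[num_s].to_numpy()
    sd = s[den_s].to_numpy()
    q_n = Kn.sum(axis=1) / sn.sum()
    q_d = Kd.sum(axis=1) / sd.sum()
    zero_both = (q_n == 0) & (q_d == 0)
    qf_n = np.where(q_n == 0, zero_floor, q_n)
    qf_d = np.where(q_d == 0, zero_floor, q_d)
    log2fc = np.log2(qf_n / qf_d)

    mu_n = qf_n[:, None] * sn[None, :]
    mu_d = qf_d[:, None] * sd[None, :]
    w_n = mu_n / (1.0 + alpha[:, None] * mu_n)
    w_d = mu_d / (1.0 + alpha[:, None] * mu_d)
    var_log = 1.0 / w_n.sum(axis=1) + 1.0 / w_d.sum(axis=1)
    se = np.sqrt(var_log) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    log2fc[zero_both] = 0.0
    stat[zero_both] = 0.0
    pvalue[zero_both] = 1.0
    se[zero_both] = np.nan

    norm_all = np.hstack([Kn / sn[None, :], Kd / sd[None, :]])
    base_mean = norm_all.mean(axis=1)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": np.clip(pvalue, 0.0, 1.0),
        },
        index=df.index,
    )
    out.index.name = "gene_id"
    return out


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    np.minimum(adj, 1.0, out=adj)
    out = np.empty(m)
    out[order] = adj
    return out


def call_deg(
    table: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.01
) -> pd.DataFrame:
    """Attach BH-adjusted p-values (if absent) and over/under/ns calls.

    ``over``: padj < alpha and log2fc > lfc_threshold; ``under``: padj <
    alpha and log2fc < -lfc_threshold; otherwise ``ns``.
    """
    out = table.copy()
    if "padj" not in out.columns:
        out["padj"] = adjust_fdr(out["pvalue"].to_numpy())
    sig = out["padj"].to_numpy() < alpha
    lfc = out["log2fc"].to_numpy()
    call = np.where(sig & (lfc > lfc_threshold), "over",
                    np.where(sig & (lfc < -lfc_threshold), "under", "ns"))
    out["call"] = call
    return out


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="gene_id")
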