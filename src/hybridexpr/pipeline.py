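"""End-to-end orchestration: counts + design (+ annotation) -> report bundle.

For each tissue the pipeline filters weakly covered genes, normalizes,
estimates dispersion, runs the three pairwise contrasts per hybrid trio
(hybrid vs each parent, parent vs parent), classifies inheritance
modes, extracts transgressive sets with their over/under bias test,
compares reciprocal-cross category profiles, counts shared transgressive
genes across hybrids and (when annotation is supplied) runs term
enrichment.  Everything is written as TSV plus a JSON run log; the run
is fully deterministic for a fixed input.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import (
    Contrast,
    call_deg,
    estimate_dispersion,
    estimate_size_factors,
    nb_wald_test,
    write_de_table,
)
from .enrichment import enrich, read_annotation, write_enrichment
from .inheritance import classify_all, compare_profiles
from .io import (
    CountMatrix,
    SampleDesign,
    aggregate_transcripts,
    filter_low_counts,
    read_counts,
    read_design,
    read_tx2gene,
    write_counts,
)
from .setops import GeneSet, shared_sets, transgressive_sets, bias_test, write_gene_set, write_regions

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    counts: str
    design: str
    outdir: str = "results"
    tx2gene: str | None = None
    orthologs: str | None = None
    terms: str | None = None
    alpha: float = 0.01
    lfc_threshold: float = 1.0
    min_reads: int = 10
    per_condition_filter: bool = True
    enrich_alpha: float = 0.05
    trend_weight: float = 0.5
    zero_floor: float = 0.5
    allow_rounding: bool = False
    pseudo_reference: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        extra = {k: v for k, v in data.items() if k not in known}
        kwargs = {k: v for k, v in data.items() if k in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data.pop("extra", None)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _trios(design: SampleDesign, tissue: str) -> list[str]:
    """Hybrid lines analyzable as (P1, P2, hybrid) trios for a tissue."""
    conds = design.for_tissue(tissue).condition_samples()
    lines = {line for line, _ in conds}
    if not {"P1", "P2"} <= lines:
        return []
    return [h for h in ("H_fwd", "H_rev") if h in lines]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the run-log manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "lfc_threshold": config.lfc_threshold,
            "min_reads": config.min_reads,
            "enrich_alpha": config.enrich_alpha,
        },
        "stages": [],
        "tissues": {},
        "files": [],
    }

    def record(path: Path) -> Path:
        log["files"].append(str(path.relative_to(outdir)))
        return path

    def fail(stage: str, exc: Exception) -> "PipelineError":
        log["failed_stage"] = stage
        with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        return PipelineError(stage, str(exc))

    # ---- load ------------------------------------------------------------
    stage = "load"
    try:
        matrix = read_counts(config.counts, allow_rounding=config.allow_rounding)
        design = read_design(config.design)
        design.validate_against(matrix)
        if config.tx2gene:
            matrix = aggregate_transcripts(matrix, read_tx2gene(config.tx2gene))
        annotation = None
        if config.orthologs and config.terms:
            annotation = read_annotation(config.orthologs, config.terms)
        log["stages"].append(stage)
        log["n_genes_input"] = matrix.shape[0]
    except Exception as exc:
        raise fail(stage, exc) from exc

    for tissue in design.tissues:
        tdir = outdir / tissue
        tdir.mkdir(exist_ok=True)
        tlog: dict = {"contrasts": {}, "hybrids": {}}
        log["tissues"][tissue] = tlog

        stage = f"filter[{tissue}]"
        try:
            tdesign = design.for_tissue(tissue)
            tmatrix = matrix.subset_samples(tdesign.samples)
            filtered, removed = filter_low_counts(
                tmatrix, tdesign, config.min_reads,
                per_condition=config.per_condition_filter,
            )
            tlog["n_input"] = tmatrix.shape[0]
            tlog["n_removed"] = len(removed)
            tlog["n_expressed"] = filtered.shape[0]
            write_counts(filtered, record(tdir / "filtered_counts.tsv"))
            pd.Series(removed, name="gene_id").to_csv(
                record(tdir / "removed_genes.tsv"), sep="\t", index=False
            )
        except Exception as exc:
            raise fail(stage, exc) from exc

        stage = f"normalize[{tissue}]"
        try:
            factors = estimate_size_factors(
                filtered, pseudo_reference=config.pseudo_reference
            )
            dispersion = estimate_dispersion(
                filtered, factors, tdesign, trend_weight=config.trend_weight
            )
            factors.rename("size_factor").to_csv(
                record(tdir / "size_factors.tsv"), sep="\t", index_label="sample_id"
            )
            tlog["size_factors"] = {k: float(v) for k, v in factors.items()}
        except Exception as exc:
            raise fail(stage, exc) from exc

        hybrids = _trios(design, tissue)
        n_expr = filtered.shape[0]

        def run_contrast(num: str, den: str) -> pd.DataFrame:
            contrast = Contrast((num, tissue), (den, tissue))
            table = nb_wald_test(
                filtered, factors, dispersion, tdesign, contrast,
                zero_floor=config.zero_floor,
            )
            table = call_deg(table, config.lfc_threshold, config.alpha)
            write_de_table(table, record(tdir / f"de_{num}_vs_{den}.tsv"))
            n_over = int((table["call"] == "over").sum())
            n_under = int((table["call"] == "under").sum())
            tlog["contrasts"][f"{num}_vs_{den}"] = {
                "n_deg": n_over + n_under,
                "n_over": n_over,
                "n_under": n_under,
                "pct_deg": 100.0 * (n_over + n_under) / n_expr if n_expr else 0.0,
            }
            return table

        stage = f"de[{tissue}]"
        try:
            de_p1p2 = run_contrast("P1", "P2")
            de_hybrid: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
            for h in hybrids:
                de_hybrid[h] = (run_contrast(h, "P1"), run_contrast(h, "P2"))
        except Exception as exc:
            raise fail(stage, exc) from exc

        profiles: dict[str, dict[str, int]] = {}
        over_sets: list[GeneSet] = []
        under_sets: list[GeneSet] = []
        for h in hybrids:
            hdir = tdir / h
            hdir.mkdir(exist_ok=True)
            hlog: dict = {}
            tlog["hybrids"][h] = hlog
            de_hp1, de_hp2 = de_hybrid[h]

            stage = f"inherit[{tissue}/{h}]"
            try:
                table, profile = classify_all(de_hp1, de_hp2, de_p1p2)
                table.to_csv(record(hdir / "inheritance.tsv"), sep="\t")
                pd.DataFrame(
                    {"category": list(profile), "count": list(profile.values())}
                ).assign(
                    fraction=lambda d: d["count"] / max(d["count"].sum(), 1)
                ).to_csv(record(hdir / "profile.tsv"), sep="\t", index=False)
                profiles[h] = profile
                hlog["profile"] = profile
            except Exception as exc:
                raise fail(stage, exc) from exc

            stage = f"sets[{tissue}/{h}]"
            try:
                over, under = transgressive_sets(
                    de_hp1, de_hp2, labels=(f"{h}_over", f"{h}_under")
                )
                write_gene_set(over, record(hdir / "transgressive_over.tsv"))
                write_gene_set(under, record(hdir / "transgressive_under.tsv"))
                over_sets.append(over)
                under_sets.append(under)
                hlog["n_transgressive_over"] = len(over)
                hlog["n_transgressive_under"] = len(under)
                if len(over) + len(under) >= 1:
                    bias = bias_test(len(over), len(under))
                    hlog["bias_test"] = {
                        "statistic": bias.statistic,
                        "pvalue": bias.pvalue,
                        "df": bias.df,
                    }
            except Exception as exc:
                raise fail(stage, exc) from exc

            if annotation is not None:
                stage = f"enrich[{tissue}/{h}]"
                try:
                    background = GeneSet("expressed", frozenset(filtered.genes))
                    for gs, tag in ((over, "over"), (under, "under")):
                        if not len(gs):
                            continue
                        res = enrich(gs, background, annotation, config.enrich_alpha)
                        write_enrichment(res, record(hdir / f"enrichment_{tag}.tsv"))
                        hlog[f"n_enriched_{tag}"] = int(res["significant"].sum()) if len(res) else 0
                except Exception as exc:
                    raise fail(stage, exc) from exc

        if len(hybrids) == 2:
            stage = f"reciprocal[{tissue}]"
            try:
                test = compare_profiles(profiles[hybrids[0]], profiles[hybrids[1]])
                tlog["reciprocal_profile_test"] = {
                    "statistic": test.statistic,
                    "df": test.df,
                    "pvalue": test.pvalue,
                    "dropped": list(test.dropped),
                }
            except Exception as exc:
                raise fail(stage, exc) from exc

        if len(hybrids) >= 2:
            stage = f"shared[{tissue}]"
            try:
                write_regions(shared_sets(over_sets), record(tdir / "shared_over.tsv"))
                write_regions(shared_sets(under_sets), record(tdir / "shared_under.tsv"))
            except Exception as exc:
                raise fail(stage, exc) from exc

    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
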