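"""Minimal figures regenerated from the pipeline's TSV outputs.

Layouts follow the usual DE conventions: an MA-style scatter per
contrast (red = over, blue = under) and a category bar chart per hybrid
(conserved omitted, as it dwarfs the rest).  Not bit-specified.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

CALL_COLOURS = {"over": "#d62728", "under": "#1f77b4", "ns": "#bbbbbb"}


def plot_de_scatter(de_table: pd.DataFrame, path: Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    x = np.log10(de_table["base_mean"].to_numpy() + 1.0)
    y = de_table["log2fc"].to_numpy()
    for call, colour in CALL_COLOURS.items():
        mask = de_table["call"] == call
        ax.scatter(x[mask], y[mask], s=4, c=colour, label=call, alpha=0.6, linewidths=0)
    ax.axhline(0, lw=0.5, color="k")
    ax.set_xlabel("log10(mean normalized count + 1)")
    ax.set_ylabel("log2 fold change")
    ax.set_title(title)
    ax.legend(markerscale=3, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile_bars(profile: pd.DataFrame, path: Path, title: str = "") -> None:
    sub = profile[~profile["category"].isin(["conserved"])]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(sub["category"], sub["count"], color="#4c72b0")
    ax.set_ylabel("genes")
    ax.set_title(title)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_run(outdir: Path) -> list[Path]:
    """Render plots for every DE table and profile under a pipeline outdir."""
    outdir = Path(outdir)
    plot_dir = outdir / "plots"
    plot_dir.mkdir(exist_ok=True)
    written: list[Path] = []
    for de_path in sorted(outdir.glob("*/de_*.tsv")):
        table = pd.read_csv(de_path, sep="\t", index_col="gene_id")
        name = f"{de_path.parent.name}_{de_path.stem}.png"
        target = plot_dir / name
        plot_de_scatter(table, target, title=de_path.stem)
        written.append(target)
    for prof_path in sorted(outdir.glob("*/*/profile.tsv")):
        profile = pd.read_csv(prof_path, sep="\t")
        name = f"{prof_path.parent.parent.name}_{prof_path.parent.name}_profile.png"
        target = plot_dir / name
        plot_profile_bars(profile, target, title=prof_path.parent.name)
        written.append(target)
    return written
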