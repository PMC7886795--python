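"""Static figures summarizing a pipeline run directory.

Reads only the tabular stage outputs (never recomputes), so the report
is reproducible from a run directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

log = logging.getLogger("commphen")

__all__ = ["render_report"]


def _read(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def render_report(rundir, outdir=None) -> list[str]:
    """Render the run-report figures; returns the written file paths."""
    rundir = Path(rundir)
    outdir = Path(outdir) if outdir else rundir
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _read(rundir / "metadata.tsv", index_col=0) if (
        rundir / "metadata.tsv").exists() else None
    manifest = json.loads((rundir / "manifest.json").read_text())
    cond_of = None
    if meta is not None:
        cond_of = meta["condition"]
    else:  # fall back to "<condition>_r<k>" sample names
        def cond_of_fn(s):
            return s.rsplit("_r", 1)[0]
    written: list[str] = []

    def condition(sample: str) -> str:
        if cond_of is not None and sample in cond_of.index:
            return cond_of[sample]
        return sample.rsplit("_r", 1)[0]

    # PCoA scatter (first two axes)
    pcoa = _read(rundir / "pcoa.tsv", index_col=0)
    if pcoa.shape[1] >= 2:
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = pcoa.groupby([condition(s) for s in pcoa.index])
        for name, sub in groups:
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=name, s=30)
        props = json.loads((rundir / "pcoa.json").read_text())[
            "proportion_explained"]
        ax.set_xlabel(f"PC1 ({100 * props[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * props[1]:.1f}%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / "pcoa_scatter.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))

    # Shannon boxplot, conditions ordered by decreasing median diversity
    sh = _read(rundir / "shannon.tsv", index_col=0)["shannon"]
    by_cond = sh.groupby([condition(s) for s in sh.index])
    order = by_cond.median().sort_values(ascending=False).index
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot([by_cond.get_group(c).to_numpy() for c in order],
               tick_labels=list(order))
    ax.set_ylabel("Shannon diversity (nats)")
    fig.tight_layout()
    path = outdir / "shannon_box.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    # stacked family bars
    fam = _read(rundir / "abund_family.tsv", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = None
    for taxon, row in fam.iterrows():
        vals = row.to_numpy()
        ax.bar(range(len(vals)), vals, bottom=bottom, label=str(taxon))
        bottom = vals if bottom is None else bottom + vals
    ax.set_xticks(range(fam.shape[1]))
    ax.set_xticklabels(fam.columns, rotation=90, fontsize=6)
    ax.set_ylabel("relative abundance")
    ax.legend(fontsize=5, ncols=2)
    fig.tight_layout()
    path = outdir / "family_bars.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    # CPI bars per panel (mean per condition)
    cpi_path = rundir / "cpi.tsv"
    if cpi_path.exists():
        cpi = _read(cpi_path)
        cpi["condition"] = cpi["sample"].map(condition)
        means = cpi.pivot_table(index="phenotype", columns="condition",
                                values="cpi", aggfunc="mean")
        if means.empty:
            log.info("empty CPI panel; figure skipped")
        else:
            fig, ax = plt.subplots(figsize=(7, 4))
            means.plot.bar(ax=ax)
            ax.set_ylabel("CPI (%)")
            ax.tick_params(axis="x", labelsize=6)
            fig.tight_layout()
            path = outdir / "cpi_panels.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))

    # GH delta heatmap
    gh_path = rundir / "gh_delta.tsv"
    if gh_path.exists():
        gh = _read(gh_path)
        mat = gh.pivot(index="phenotype", columns="condition", values="delta")
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(mat.shape[1]), mat.columns, fontsize=7)
        ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
        fig.colorbar(im, label="delta CPI vs control (%)")
        fig.tight_layout()
        path = outdir / "gh_delta_heatmap.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    else:
        log.info("no GH panel in run; heatmap skipped")
    _ = manifest
    return written
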