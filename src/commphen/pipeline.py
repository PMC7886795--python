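"""End-to-end pipeline: QC -> normalize -> diversity -> aggregation ->
fold screen -> CPI panels -> group statistics, with a JSON run manifest.

Every stage writes its outputs before the next begins, so a failing
stage leaves earlier results on disk and aborts with a stage-named
error. All randomness flows from the single seed in :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from . import __version__
from . import tables as tio
from .diversity import PCoA, midpoint_root, shannon_table, unifrac_matrix
from .phenotypes import (
    BinaryPhenotypeMatrix,
    CommunityPhenotypeProfiler,
    cpi_delta,
    load_panels,
)
from .screen import FoldChangeScreen
from .stats import compare_groups

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger("commphen")

STAGES = ("qc", "normalize", "diversity", "aggregate", "screen", "cpi", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    table: str
    metadata: str
    taxonomy: str
    bpm: str
    tree: str | None = None
    panels: str | None = None
    control: str = "control"
    conditions: list[str] | None = None  # default: all non-control labels
    min_reads: int = 5000
    fold_k: float = 5.0
    normalization: str = "total_sum"
    rarefy_depth: int | None = None
    unifrac_normalized: bool = True
    cpi_renormalize: bool = False
    stats_method: str = "mann_whitney"
    context_by_condition: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name in ("table", "metadata", "taxonomy", "bpm"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.tree is not None and not Path(self.tree).exists():
            raise FileNotFoundError(f"tree path does not exist: {self.tree}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _context_for(config: RunConfig, condition: str) -> str:
    """Media context of a condition; the control medium is sugar-free."""
    if condition in config.context_by_condition:
        return config.context_by_condition[condition]
    return "control" if condition == config.control else "herb"


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "commphen",
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": [],
        "outputs": {},
    }
    t_start = time.time()

    def record(stage: str, **outputs):
        manifest["stages"].append(stage)
        for k, v in outputs.items():
            manifest["outputs"][k] = str(v)
        log.info("stage %s done (%.2fs elapsed)", stage, time.time() - t_start)

    counts = tio.read_table(config.table)
    metadata = tio.read_metadata(config.metadata)
    taxonomy = tio.read_taxonomy(config.taxonomy)
    bpm = BinaryPhenotypeMatrix.read_tsv(config.bpm)
    conditions = config.conditions or sorted(
        c for c in metadata["condition"].unique() if c != config.control
    )

    # -- qc ---------------------------------------------------------------
    try:
        counts_qc, excluded = tio.qc_filter_samples(counts, config.min_reads)
        excluded.to_csv(out / "qc_excluded.tsv", sep="\t")
        tio.write_table(counts_qc, out / "counts_qc.tsv")
        metadata = metadata.loc[[s for s in metadata.index
                                 if s in counts_qc.columns]]
        metadata.to_csv(out / "metadata.tsv", sep="\t")
    except Exception as e:
        raise StageError("qc", e) from e
    record("qc", qc_excluded=out / "qc_excluded.tsv",
           counts_qc=out / "counts_qc.tsv")

    # -- normalize --------------------------------------------------------
    try:
        table = tio.normalize(
            counts_qc,
            method=config.normalization,
            depth=config.rarefy_depth,
            seed=config.seed,
        )
        tio.write_table(table, out / "relabund.tsv")
    except Exception as e:
        raise StageError("normalize", e) from e
    record("normalize", relabund=out / "relabund.tsv")

    # -- diversity --------------------------------------------------------
    try:
        alpha = shannon_table(table)
        alpha.to_frame().to_csv(out / "shannon.tsv", sep="\t",
                                float_format="%.10g")
        if config.tree is None:
            raise FileNotFoundError(
                "UniFrac/PCoA requested but no tree provided"
            )
        tree = TreeNode.read(config.tree)
        rooted = midpoint_root(tree)
        dm = unifrac_matrix(rooted, table,
                            normalized=config.unifrac_normalized)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / "unifrac.tsv", sep="\t", float_format="%.10g"
        )
        ord_model = PCoA().fit(dm)
        ord_model.coordinates_.to_csv(out / "pcoa.tsv", sep="\t",
                                      float_format="%.10g")
        (out / "pcoa.json").write_text(
            json.dumps(
                {
                    "eigvals": list(ord_model.eigvals_),
                    "proportion_explained": list(
                        ord_model.proportion_explained_
                    ),
                    "negative_eigvals": list(ord_model.negative_eigvals_),
                },
                indent=1,
            )
        )
    except Exception as e:
        raise StageError("diversity", e) from e
    record("diversity", shannon=out / "shannon.tsv",
           unifrac=out / "unifrac.tsv", pcoa=out / "pcoa.tsv")

    # -- aggregate --------------------------------------------------------
    try:
        agg_paths = {}
        for rank in tio.RANKS:
            agg = tio.aggregate(table, taxonomy, rank)
            path = out / f"abund_{rank}.tsv"
            tio.write_table(agg, path)
            agg_paths[f"abund_{rank}"] = path
    except Exception as e:
        raise StageError("aggregate", e) from e
    record("aggregate", **agg_paths)

    # -- screen -----------------------------------------------------------
    try:
        screen_paths = {}
        for cond in conditions:
            scr = FoldChangeScreen(
                condition=cond, control=config.control, k=config.fold_k
            ).fit(table, metadata)
            path = out / f"screen_{cond}.tsv"
            scr.results_.to_csv(path, sep="\t", float_format="%.10g")
            (out / f"screen_{cond}.json").write_text(
                json.dumps(scr.summary_, indent=1)
            )
            screen_paths[f"screen_{cond}"] = path
    except Exception as e:
        raise StageError("screen", e) from e
    record("screen", **screen_paths)

    # -- cpi --------------------------------------------------------------
    try:
        panels, psets = load_panels(config.panels)
        profiler = CommunityPhenotypeProfiler(
            bpm, taxonomy, renormalize=config.cpi_renormalize
        ).fit()
        long_cpi = profiler.profile(table)
        long_cpi.to_csv(out / "cpi.tsv", sep="\t", index=False,
                        float_format="%.10g")
        # pathway-set CPI per condition under its media context
        rows = []
        for cond in [config.control, *conditions]:
            samples = [s for s in table.columns
                       if metadata.loc[s, "condition"] == cond]
            sub = table[samples]
            ctx = _context_for(config, cond)
            for pset in psets.values():
                if not set(pset.members) <= set(bpm.phenotypes):
                    continue
                prof = profiler.pathway_set_profile(sub, pset, ctx)
                prof.insert(0, "condition", cond)
                prof.insert(1, "context", ctx)
                rows.append(prof)
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                out / "cpi_pathway_sets.tsv", sep="\t", index=False,
                float_format="%.10g"
            )
        # GH-family delta vs control (any BPM column starting with "GH")
        gh_cols = [c for c in bpm.phenotypes if c.startswith("GH")]
        if gh_cols:
            wide = long_cpi[long_cpi["phenotype"].isin(gh_cols)]
            deltas = []
            ctrl_long = wide[wide["sample"].map(
                lambda s: metadata.loc[s, "condition"] == config.control)]
            for cond in conditions:
                cond_long = wide[wide["sample"].map(
                    lambda s: metadata.loc[s, "condition"] == cond)]
                d, net = cpi_delta(cond_long, ctrl_long)
                d.insert(0, "condition", cond)
                d["net_effect"] = net
                deltas.append(d.reset_index())
            pd.concat(deltas, ignore_index=True).to_csv(
                out / "gh_delta.tsv", sep="\t", index=False,
                float_format="%.10g"
            )
    except Exception as e:
        raise StageError("cpi", e) from e
    record("cpi", cpi=out / "cpi.tsv",
           cpi_pathway_sets=out / "cpi_pathway_sets.tsv")

    # -- stats ------------------------------------------------------------
    try:
        wide_cpi = long_cpi.pivot(index="sample", columns="phenotype",
                                  values="cpi")
        metrics = wide_cpi.join(shannon_table(table))
        res = []
        for cond in conditions:
            res.append(
                compare_groups(metrics, metadata, cond,
                               control=config.control,
                               method=config.stats_method)
            )
        stats_df = pd.concat(res, ignore_index=True)
        stats_df.to_csv(out / "stats.tsv", sep="\t", index=False,
                        float_format="%.10g")
    except Exception as e:
        raise StageError("stats", e) from e
    record("stats", stats=out / "stats.tsv")

    manifest["runtime_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def configure_logging(verbose: bool = True) -> None:
    """Stage logs go to stderr; machine outputs never mix with logs."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
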