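"""Genome-reconstruction phenotype prediction for 16S-profiled communities.

Reference genomes carry curated binary phenotypes (1 iff the genome
encodes a complete metabolic pathway or CAZyme family). Taxa observed in
a community map to reference genomes by species name; averaging the
binary phenotypes over a species' genomes gives a fractional community
phenotype matrix (CPM), and the Community Phenotype Index

    CPI(sample, phenotype) = 100 * sum_taxa CPM[taxon, phenotype] * abundance

estimates the percentage of cells in the community carrying the
capability. Capabilities realizable through several routes (e.g. butyrate
synthesis via sugar- or amino-acid-fermentation pathways) are handled as
pathway sets whose active subset depends on the culture medium.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BinaryPhenotypeMatrix",
    "PathwaySet",
    "load_panels",
    "CommunityPhenotypeProfiler",
    "map_taxa",
    "cpi",
    "pathway_set_cpi",
    "sugar_capability",
    "combine_sugar_bpm",
    "cpi_delta",
]


def _norm_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


class BinaryPhenotypeMatrix:
    """Reference genomes x phenotypes with strictly binary entries.

    Parameters
    ----------
    values : pandas.DataFrame
        Indexed by genome id, one column per phenotype, entries in {0, 1}.
    species : pandas.Series
        Genome id -> species name (required for community mapping).
    panels : dict, optional
        Panel name -> list of member phenotype ids (e.g. vitamins, sugars,
        GH families). Panels must not overlap.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        species: pd.Series,
        panels: dict[str, list[str]] | None = None,
    ):
        if not values.isin([0, 1]).all().all():
            raise ValueError("BPM entries must be 0 or 1")
        values = values.astype(np.int8, copy=True)
        species = species.reindex(values.index)
        if species.isna().any():
            missing = list(values.index[species.isna()])
            raise ValueError(f"genomes without species assignment: {missing[:5]}")
        self.values = values
        self.species = species.astype(str)
        panels = dict(panels or {})
        seen: set[str] = set()
        for name, members in panels.items():
            members = [m for m in members if m in values.columns]
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"phenotype in several panels: {sorted(overlap)}")
            seen |= set(members)
            panels[name] = members
        self.panels = panels

    @property
    def genomes(self) -> list[str]:
        return list(self.values.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path, panels=None) -> "BinaryPhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "species" not in df.columns:
            raise ValueError("BPM TSV requires a 'species' column")
        species = df.pop("species").astype(str)
        return cls(df, species, panels=panels)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "species", self.species)
        out.to_csv(path, sep="\t")


@dataclass
class PathwaySet:
    """A capability with several biosynthetic routes and media contexts.

    ``contexts`` maps a media label to the subset of routes that can run
    in that medium (e.g. in a sugar-free control medium only the
    amino-acid fermentation routes to butyrate are available, while
    substrate-supplemented cultures admit all four routes).
    """

    name: str
    members: list[str]
    contexts: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("pathway set needs at least one member")
        for ctx, subset in self.contexts.items():
            bad = set(subset) - set(self.members)
            if bad:
                raise ValueError(f"context {ctx!r} not a member subset: {bad}")
            if not subset:
                raise ValueError(f"context {ctx!r} has an empty active subset")

    def active(self, context: str) -> list[str]:
        if context not in self.contexts:
            raise ValueError(
                f"no active subset configured for context {context!r}"
            )
        return self.contexts[context]


def load_panels(path=None):
    """Load phenotype panels and pathway sets from JSON.

    Without ``path`` the packaged default panels are used: SCFA routes
    (butyrate and propionate, four routes each, with a control-medium
    butyrate context restricted to amino-acid fermentation routes), 11
    vitamins/cofactors, 20 amino acids, and 10 sugars.

    Returns
    -------
    (panels, pathway_sets) : dict[str, list[str]], dict[str, PathwaySet]
    """
    if path is None:
        text = (
            resources.files("commphen").joinpath("data/panels.json").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    panels = {k: list(v) for k, v in raw.get("panels", {}).items()}
    psets = {
        k: PathwaySet(name=k, members=v["members"], contexts=v.get("contexts", {}))
        for k, v in raw.get("pathway_sets", {}).items()
    }
    return panels, psets


class CommunityPhenotypeProfiler(BaseEstimator, TransformerMixin):
    """Predict community metabolic capacity from a BPM and a taxonomy map.

    ``fit`` builds the community phenotype matrix: each species-assigned
    taxon receives the arithmetic mean (``genome_agg="mean"``) or the
    maximum (``"any"``) of its reference genomes' binary phenotypes. Taxa
    whose species matches no reference genome (or with no species
    assignment) stay unmapped and are reported, not silently dropped.

    ``transform`` converts a relative-abundance table into per-sample CPI
    values on the 0-100% scale. By default unmapped abundance dilutes the
    CPI toward zero; with ``renormalize=True`` abundances are first
    rescaled over mapped taxa only. The mapped fraction per sample is
    always available via :meth:`profile`.
    """

    def __init__(
        self,
        bpm: BinaryPhenotypeMatrix,
        taxonomy: pd.DataFrame,
        genome_agg: str = "mean",
        renormalize: bool = False,
    ):
        self.bpm = bpm
        self.taxonomy = taxonomy
        self.genome_agg = genome_agg
        self.renormalize = renormalize

    # -- fitting -----------------------------------------------------------
    def fit(self, X=None, y=None):
        if self.bpm.values.shape[0] == 0:
            raise ValueError("empty BPM")
        if self.genome_agg not in ("mean", "any"):
            raise ValueError("genome_agg must be 'mean' or 'any'")
        by_species = self._species_profiles(self.bpm.values)
        rows = {}
        counts = {}
        unmapped = []
        species_col = self.taxonomy["species"]
        for taxon in self.taxonomy.index:
            sp = species_col.get(taxon)
            key = _norm_name(sp) if isinstance(sp, str) and sp.strip() else None
            if key is not None and key in by_species.index:
                rows[taxon] = by_species.loc[key]
                counts[taxon] = self._genome_counts[key]
            else:
                unmapped.append(taxon)
        self.cpm_ = pd.DataFrame(rows).T
        if self.cpm_.empty:
            self.cpm_ = pd.DataFrame(columns=self.bpm.phenotypes)
        self.genome_count_ = pd.Series(counts, dtype=int)
        self.unmapped_taxa_ = unmapped
        return self

    def _species_profiles(self, values: pd.DataFrame) -> pd.DataFrame:
        keys = self.bpm.species.map(_norm_name)
        grouped = values.groupby(keys.to_numpy())
        self._genome_counts = grouped.size().to_dict()
        if self.genome_agg == "any":
            return grouped.max().astype(float)
        return grouped.mean()

    # -- transform ---------------------------------------------------------
    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Wide CPI matrix (samples x phenotypes, percent)."""
        return self.profile(table).pivot(
            index="sample", columns="phenotype", values="cpi"
        )

    def profile(self, table: pd.DataFrame, values: pd.DataFrame | None = None
                ) -> pd.DataFrame:
        """Long-format CPI: sample, phenotype, cpi, mapped_fraction.

        ``values`` overrides the fitted community phenotype matrix (used
        for derived producer phenotypes); its rows must be taxa.
        """
        if not hasattr(self, "cpm_"):
            self.fit()
        cpm = self.cpm_ if values is None else values
        return cpi(table, cpm, renormalize=self.renormalize)

    # -- pathway sets ------------------------------------------------------
    def producer_profile(self, pset: PathwaySet, context: str) -> pd.DataFrame:
        """Per-taxon producer phenotype for a pathway set in a context.

        A *genome* is a producer if it encodes ANY route in the context's
        active subset (the OR is taken per genome, before species
        averaging); the taxon value is then the genome aggregate.
        """
        active = pset.active(context)
        missing = [m for m in active if m not in self.bpm.values.columns]
        if missing:
            raise ValueError(f"pathway(s) absent from BPM: {missing}")
        producer = self.bpm.values[active].max(axis=1).to_frame(pset.name)
        keys = self.bpm.species.map(_norm_name)
        grouped = producer.groupby(keys.to_numpy())
        per_species = (
            grouped.max().astype(float)
            if self.genome_agg == "any"
            else grouped.mean()
        )
        if not hasattr(self, "cpm_"):
            self.fit()
        rows = {}
        species_col = self.taxonomy["species"]
        for taxon in self.cpm_.index:
            key = _norm_name(species_col.get(taxon))
            rows[taxon] = per_species.loc[key]
        return pd.DataFrame(rows).T

    def pathway_set_profile(
        self, table: pd.DataFrame, pset: PathwaySet, context: str
    ) -> pd.DataFrame:
        """CPI of a multi-route capability under a media context."""
        values = self.producer_profile(pset, context)
        return self.profile(table, values=values)


# ---------------------------------------------------------------------------
# functional wrappers


def map_taxa(
    taxonomy: pd.DataFrame,
    bpm: BinaryPhenotypeMatrix,
    genome_agg: str = "mean",
) -> tuple[pd.DataFrame, list[str]]:
    """Community phenotype matrix + list of unmapped taxa."""
    prof = CommunityPhenotypeProfiler(bpm, taxonomy, genome_agg=genome_agg).fit()
    return prof.cpm_, prof.unmapped_taxa_


def cpi(
    table: pd.DataFrame,
    cpm: pd.DataFrame,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Long-format CPI of a normalized table against a taxon x phenotype CPM.

    Taxa absent from the CPM are unmapped: by default their abundance
    dilutes the index (CPI uses the full denominator), while
    ``renormalize=True`` rescales over mapped abundance only. A sample
    with no mappable abundance gets CPI NaN (undefined, not zero).
    """
    mapped = [t for t in table.index if t in cpm.index]
    records = []
    for sample in table.columns:
        ab = table[sample].astype(float)
        total = float(ab.sum())
        mapped_ab = ab.loc[mapped]
        mapped_sum = float(mapped_ab.sum())
        mf = mapped_sum / total if total > 0 else 0.0
        for phen in cpm.columns:
            if mapped_sum == 0.0:
                val = np.nan  # undefined: no mappable abundance
            else:
                dot = float(mapped_ab @ cpm.loc[mapped, phen])
                dot /= mapped_sum if renormalize else total
                val = 100.0 * dot
            records.append(
                {
                    "sample": sample,
                    "phenotype": phen,
                    "cpi": val,
                    "mapped_fraction": mf,
                    "renormalized": renormalize,
                }
            )
    return pd.DataFrame.from_records(records)


def pathway_set_cpi(
    table: pd.DataFrame,
    profiler: CommunityPhenotypeProfiler,
    pset: PathwaySet,
    context: str,
) -> pd.DataFrame:
    return profiler.pathway_set_profile(table, pset, context)


def sugar_capability(catabolic, transporter):
    """Sugar utilization = catabolic pathway AND uptake transporter.

    Both inputs must be binary; scalars or aligned arrays are accepted.
    """
    cat = np.asarray(catabolic)
    tra = np.asarray(transporter)
    for arr in (cat, tra):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("sugar capability inputs must be binary")
    out = (cat.astype(int) & tra.astype(int))
    return out.item() if out.ndim == 0 else out


def combine_sugar_bpm(
    catabolic: pd.DataFrame, transporter: pd.DataFrame
) -> pd.DataFrame:
    """Elementwise AND of aligned catabolic and transporter matrices."""
    transporter = transporter.reindex(
        index=catabolic.index, columns=catabolic.columns
    )
    if transporter.isna().any().any():
        raise ValueError("transporter matrix does not cover catabolic matrix")
    return pd.DataFrame(
        sugar_capability(catabolic.to_numpy(), transporter.to_numpy()),
        index=catabolic.index,
        columns=catabolic.columns,
    )


def cpi_delta(
    herb: pd.DataFrame, control: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-phenotype mean CPI difference (condition minus control).

    Input frames are long-format CPI tables (``profile`` output). Returns
    a table with columns mean_herb, mean_control, delta, direction
    ('increased'/'decreased'/'unchanged'), plus the panel net effect (the
    average of the positive and negative changes). Phenotypes present on
    only one side are skipped with a warning.
    """
    mh = herb.groupby("phenotype")["cpi"].mean()
    mc = control.groupby("phenotype")["cpi"].mean()
    common = mh.index.intersection(mc.index)
    skipped = set(mh.index).symmetric_difference(mc.index)
    if skipped:
        warnings.warn(f"phenotypes on one side only, skipped: {sorted(skipped)}",
                      stacklevel=2)
    delta = (mh[common] - mc[common]).rename("delta")
    direction = pd.Series(
        np.where(delta > 0, "increased", np.where(delta < 0, "decreased",
                                                  "unchanged")),
        index=delta.index,
        name="direction",
    )
    out = pd.DataFrame(
        {
            "mean_herb": mh[common],
            "mean_control": mc[common],
            "delta": delta,
            "direction": direction,
        }
    )
    net = float(delta.mean()) if len(delta) else float("nan")
    return out, net
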