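"""Phylotype table I/O, sample QC, normalization, and taxonomic aggregation.

A phylotype table is a :class:`pandas.DataFrame` with one row per phylotype
(a unique 16S amplicon sequence variant, approximating a strain/species
level taxon) and one column per sample. Raw tables hold non-negative
integer read counts; normalized tables hold relative abundances whose
columns each sum to one. Sample metadata is a DataFrame indexed by sample
id with at least a ``condition`` column and optionally ``replicate``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "read_table",
    "write_table",
    "read_metadata",
    "read_taxonomy",
    "SampleQC",
    "TotalSumNormalizer",
    "Rarefier",
    "RankAggregator",
    "qc_filter_samples",
    "normalize",
    "aggregate",
]

RANKS = ("species", "genus", "family")
UNASSIGNED = "unassigned"

_NORM_TOL = 1e-6


def read_table(path) -> pd.DataFrame:
    """Read a tab-delimited feature table (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_table(df)
    return df


def write_table(table: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    table.to_csv(path, sep="\t", float_format=float_format)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (columns: sample, condition, replicate)."""
    md = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if "condition" not in md.columns:
        raise ValueError("sample metadata requires a 'condition' column")
    return md


def read_taxonomy(path) -> pd.DataFrame:
    """Read a phylotype -> (species, genus, family) lineage map.

    Missing species entries mark the phylotype as unassigned at species
    rank; they stay in diversity and screening analyses but are excluded
    from genome mapping.
    """
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [r for r in RANKS if r not in tax.columns]
    if missing:
        raise ValueError(f"taxonomy map lacks rank column(s): {missing}")
    return tax


def _check_table(table: pd.DataFrame) -> None:
    if not table.index.is_unique:
        raise ValueError("duplicate phylotype ids in table")
    if not table.columns.is_unique:
        raise ValueError("duplicate sample ids in table")
    vals = table.to_numpy()
    if vals.size and np.nanmin(vals) < 0:
        raise ValueError("negative entries in phylotype table")


def is_normalized(table: pd.DataFrame, tol: float = _NORM_TOL) -> bool:
    """True if every sample column sums to 1 within ``tol``."""
    sums = table.sum(axis=0).to_numpy(dtype=float)
    return bool(len(sums)) and bool(np.all(np.abs(sums - 1.0) <= tol))


class SampleQC(BaseEstimator, TransformerMixin):
    """Drop samples with fewer than ``min_reads`` total reads.

    Mirrors the read-coverage gate applied to amplicon libraries before
    any comparison: a sample is excluded iff its column sum is *strictly*
    below the threshold (default 5,000 reads), so a sample at exactly the
    threshold is retained.

    Attributes
    ----------
    depths_ : pandas.Series
        Per-sample read depth seen during ``fit``.
    excluded_ : pandas.DataFrame
        Excluded sample ids with their depths.
    """

    def __init__(self, min_reads: int = 5000):
        self.min_reads = min_reads

    def fit(self, X: pd.DataFrame, y=None):
        _check_table(X)
        if is_normalized(X):
            raise ValueError(
                "QC requires raw read counts, but the table looks normalized"
            )
        depths = X.sum(axis=0)
        self.depths_ = depths
        keep = depths >= self.min_reads
        self.retained_ = list(X.columns[keep])
        self.excluded_ = pd.DataFrame(
            {"depth": depths[~keep]}, index=X.columns[~keep]
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = [c for c in X.columns if c in set(self.retained_)]
        return X[cols]


class TotalSumNormalizer(BaseEstimator, TransformerMixin):
    """Convert counts to relative abundances (total-sum scaling)."""

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        _check_table(X)
        sums = X.sum(axis=0)
        if (sums == 0).any():
            bad = list(X.columns[sums == 0])
            raise ValueError(f"cannot normalize all-zero sample(s): {bad}")
        return X / sums


class Rarefier(BaseEstimator, TransformerMixin):
    """Subsample each sample's reads without replacement to a fixed depth.

    Samples shallower than ``depth`` are dropped with a warning. With
    ``as_relative=True`` the rarefied counts are additionally divided by
    ``depth``.
    """

    def __init__(self, depth: int, seed: int = 0, as_relative: bool = False):
        self.depth = depth
        self.seed = seed
        self.as_relative = as_relative

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        _check_table(X)
        if is_normalized(X):
            raise ValueError("rarefaction requires raw counts")
        rng = np.random.default_rng(self.seed)
        out = {}
        for sample in X.columns:
            counts = X[sample].to_numpy().astype(np.int64)
            total = int(counts.sum())
            if total < self.depth:
                warnings.warn(
                    f"sample {sample!r} has {total} < {self.depth} reads; dropped",
                    stacklevel=2,
                )
                continue
            if total == self.depth:
                sub = counts
            else:
                sub = rng.multivariate_hypergeometric(counts, self.depth)
            out[sample] = sub
        res = pd.DataFrame(out, index=X.index)
        if self.as_relative:
            res = res / float(self.depth)
        return res


class RankAggregator(BaseEstimator, TransformerMixin):
    """Sum phylotype abundances within a taxonomic rank.

    Phylotypes without an assignment at ``rank`` are pooled under
    ``"unassigned"``. Aggregation conserves each sample's total abundance.
    """

    def __init__(self, taxonomy: pd.DataFrame, rank: str = "family"):
        self.taxonomy = taxonomy
        self.rank = rank

    def fit(self, X: pd.DataFrame, y=None):
        if self.rank not in self.taxonomy.columns:
            raise ValueError(f"rank {self.rank!r} not in taxonomy map")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        labels = self.taxonomy[self.rank].reindex(X.index)
        labels = labels.where(labels.notna() & (labels != ""), UNASSIGNED)
        out = X.groupby(labels.to_numpy()).sum()
        out.index.name = self.rank
        return out


def qc_filter_samples(
    table: pd.DataFrame, min_reads: int = 5000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter low-depth samples; return (filtered table, exclusion report)."""
    qc = SampleQC(min_reads=min_reads).fit(table)
    return qc.transform(table), qc.excluded_


def normalize(
    table: pd.DataFrame,
    method: str = "total_sum",
    depth: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalize a count table.

    ``method="total_sum"`` divides each sample by its read total;
    ``method="rarefy"`` subsamples to ``depth`` reads (seeded) and then
    divides, so both methods return relative abundances.
    """
    if method == "total_sum":
        return TotalSumNormalizer().fit_transform(table)
    if method == "rarefy":
        if depth is None:
            raise ValueError("rarefy requires a depth")
        return Rarefier(depth=depth, seed=seed, as_relative=True).fit_transform(table)
    raise ValueError(f"unknown normalization method {method!r}")


def aggregate(
    table: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Aggregate a (normalized) table to species/genus/family rank."""
    return RankAggregator(taxonomy=taxonomy, rank=rank).fit_transform(table)
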