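"""Fold-change screening of taxa against control cultures.

A taxon's mean relative abundance over the replicates of a supplemented
condition is compared to its mean over control replicates. Taxa with a
ratio of at least k (default 5) are "up", at most 1/k are "down"; taxa
detected in only one condition get dedicated classes instead of an
inflated ratio. No pseudocount and no hypothesis test: this is the
fold-classification screen, scale-invariant by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["FoldChangeScreen", "fold_screen", "screen_summary"]

CLASSES = ("up", "down", "herb_only", "control_only", "null")


class FoldChangeScreen(BaseEstimator):
    """Classify taxa by mean-abundance fold change versus control.

    Parameters
    ----------
    condition, control : str
        Condition labels in the sample metadata.
    k : float
        Fold threshold (> 1); up requires ratio >= k, down ratio <= 1/k.
    min_detect : float
        Mean abundance at or below which a taxon counts as undetected
        (default 0: any positive mean is a detection).

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per taxon: control_mean, condition_mean, ratio, class.
    summary_ : dict
        Class counts; ``n_up_total`` adds herb-only taxa to the up count
        (the convention used when tallying enriched taxa), with the
        herb-only subtotal still reported separately.
    """

    def __init__(
        self,
        condition: str,
        control: str = "control",
        k: float = 5.0,
        min_detect: float = 0.0,
    ):
        self.condition = condition
        self.control = control
        self.k = k
        self.min_detect = min_detect

    def fit(self, table: pd.DataFrame, metadata: pd.DataFrame):
        if self.k <= 1:
            raise ValueError("fold threshold k must exceed 1")
        for label in (self.condition, self.control):
            if not (metadata["condition"] == label).any():
                raise ValueError(f"condition {label!r} not in metadata")
        cond_samples = [
            s for s in table.columns
            if metadata.loc[s, "condition"] == self.condition
        ]
        ctrl_samples = [
            s for s in table.columns
            if metadata.loc[s, "condition"] == self.control
        ]
        cond_mean = table[cond_samples].mean(axis=1)
        ctrl_mean = table[ctrl_samples].mean(axis=1)
        ratio = np.where(ctrl_mean > 0, cond_mean / ctrl_mean, np.nan)
        det_cond = cond_mean > self.min_detect
        det_ctrl = ctrl_mean > self.min_detect
        cls = np.full(len(table.index), "null", dtype=object)
        cls[det_cond & ~det_ctrl] = "herb_only"
        cls[~det_cond & det_ctrl] = "control_only"
        both = det_cond & det_ctrl
        cls[both & (ratio >= self.k)] = "up"
        cls[both & (ratio <= 1.0 / self.k)] = "down"
        self.results_ = pd.DataFrame(
            {
                "control_mean": ctrl_mean,
                "condition_mean": cond_mean,
                "ratio": ratio,
                "class": cls,
            },
            index=table.index,
        )
        self.summary_ = screen_summary(self.results_)
        return self


def fold_screen(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    condition: str,
    control: str = "control",
    k: float = 5.0,
    min_detect: float = 0.0,
) -> pd.DataFrame:
    """Per-taxon fold-change classification table."""
    return FoldChangeScreen(
        condition=condition, control=control, k=k, min_detect=min_detect
    ).fit(table, metadata).results_


def screen_summary(results: pd.DataFrame) -> dict:
    """Class counts for a screen result table.

    ``n_up_total`` counts herb-only taxa within the enriched total (they
    are, after all, infinitely enriched); the herb-only subtotal stays
    visible so either convention can be read off.
    """
    if results.empty:
        raise ValueError("empty screen results")
    counts = results["class"].value_counts()
    out = {f"n_{c}": int(counts.get(c, 0)) for c in CLASSES}
    out["n_up_total"] = out["n_up"] + out["n_herb_only"]
    return out
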