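"""Tn5-input ratio normalization of vector coverage statistics.

Per-base CPM already controls for sequencing depth, but the share of the
library that maps to the vector still scales with vector copy number.
The second normalization removes that abundance signal: every chromatin
library's vector coverage statistic is divided by the *mean* vector
coverage of the Tn5 input libraries of the matching condition
(species/context, capsid, timepoint — not the chromatin target: one
input pool normalizes all marks of its condition).
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .coverage import CoverageStat
from .errors import ValidationError
from .samples import CONDITION_KEY, TN5_INPUT, Condition, LibraryMeta

logger = logging.getLogger(__name__)

STAT_COLUMNS = ["sample_id", "target", "replicate", "species", "context",
                "capsid", "timepoint", "raw_value", "masked_length",
                "denominator_mode", "region_length", "total_fragments"]

#: Tn5 means below this trigger a warning (ratio becomes unstable).
LOW_TN5_WARNING = 1e-6


def stats_table(entries: Iterable[tuple[CoverageStat, LibraryMeta]]
                ) -> pd.DataFrame:
    """Assemble the long-format per-sample coverage table."""
    rows = []
    for stat, meta in entries:
        cond = meta.condition
        rows.append({
            "sample_id": meta.sample_id, "target": meta.target,
            "replicate": meta.replicate, "species": cond.species,
            "context": cond.context, "capsid": cond.capsid,
            "timepoint": cond.timepoint, "raw_value": stat.raw_value,
            "masked_length": stat.masked_length,
            "denominator_mode": stat.denominator_mode,
            "region_length": stat.region_length,
            "total_fragments": stat.total_fragments,
        })
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def _condition_match(df: pd.DataFrame, condition: Condition) -> pd.DataFrame:
    m = pd.Series(True, index=df.index)
    for col, val in zip(CONDITION_KEY, condition.key()):
        m &= df[col] == val
    return df[m]


def mean_tn5_coverage(stats: pd.DataFrame, condition: Condition) -> float:
    """Arithmetic mean of the Tn5 input raw coverages for one condition."""
    tn5 = stats[stats["target"] == TN5_INPUT]
    match = _condition_match(tn5, condition)
    if match.empty:
        raise ValidationError(
            f"no Tn5 input library for condition {condition.label()}")
    mean = float(match["raw_value"].mean())
    if mean <= 0:
        raise ValidationError(
            f"Tn5 mean coverage is zero for condition {condition.label()}")
    if mean < LOW_TN5_WARNING:
        logger.warning("very low Tn5 mean coverage (%g) for %s",
                       mean, condition.label())
    return mean


def tn5_normalize_dataset(stats: pd.DataFrame) -> pd.DataFrame:
    """Divide each chromatin sample's coverage by its condition's Tn5 mean.

    Tn5 rows are consumed as the denominator and excluded from the output.
    All rows must share one denominator mode and mask extent, otherwise the
    ratio would mix incompatible statistics.
    """
    if stats.empty:
        raise ValidationError("empty coverage table")
    for col in ("denominator_mode", "masked_length", "region_length"):
        if stats[col].nunique() > 1:
            raise ValidationError(
                f"mixed {col} values in one dataset: "
                f"{sorted(stats[col].unique())}")
    ct = stats[stats["target"] != TN5_INPUT].copy()
    if ct.empty:
        raise ValidationError("no chromatin samples to normalize")
    means = {}
    for _, row in ct.drop_duplicates(subset=list(CONDITION_KEY)).iterrows():
        cond = Condition(capsid=row["capsid"], species=row["species"],
                         context=row["context"], timepoint=row["timepoint"])
        means[cond.key()] = mean_tn5_coverage(stats, cond)
    keys = list(zip(*(ct[c] for c in CONDITION_KEY)))
    ct["raw"] = ct["raw_value"]
    ct["tn5_mean"] = [means[k] for k in keys]
    ct["normalized"] = ct["raw"] / ct["tn5_mean"]
    cols = ["sample_id", "target", "replicate", *CONDITION_KEY,
            "raw", "tn5_mean", "normalized"]
    return ct[cols].reset_index(drop=True)
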