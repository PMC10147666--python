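"""Scenario presets: small simulated studies with documented ground truth.

Each preset builds a :class:`~epivector.pipeline.PipelineConfig` whose
injected enrichments encode a qualitative pattern of interest, runs the
pipeline, and checks that the reported normalized coverages reproduce
the pattern:

``fig2_like``
    Capsid x species grid (LK03/DJ x human/mouse cell lines) where the
    LK03-mouse condition is depleted for active histone marks
    (gene-body enrichment 1 vs 8 elsewhere). The expected call is
    LK03-mouse < LK03-human normalized coverage per active mark.
``fig3_like``
    Adds the rescued capsid (AM) in mouse: LK03-mouse stays depleted,
    AM-mouse and AM/LK03-human are enriched.
``fig4_like``
    One condition at two timepoints: the late timepoint has 10x fewer
    vector genomes but higher per-copy chromatinization, so normalized
    coverage rises while the abundance proxy (Tn5 raw coverage) falls.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pipeline import (LibrarySpec, PipelineConfig, PipelineResult,
                       ReferenceSpec, run_pipeline)
from .samples import ACTIVE_MARKS, TN5_INPUT
from .stats import timepoint_ratio, welch_t

PRESETS = ("fig2_like", "fig3_like", "fig4_like")

_ENRICHED = 8.0
_DEPLETED = 1.0

#: Tn5 inputs are sequenced deeper than the chromatin libraries (they are
#: shared normalizers, so their counting noise propagates into every
#: mark's normalized value): >15M vs >2M fragments per sample.
TN5_DEPTH_FACTOR = 7.5


def _roster(conditions, marks, enrichment, replicates, n_fragments,
            n_tn5_replicates=2, **common):
    libs = []
    tn5_fragments = int(n_fragments * TN5_DEPTH_FACTOR)
    for cond in conditions:
        for mark in marks:
            for rep in range(1, replicates + 1):
                libs.append(LibrarySpec(
                    target=mark, replicate=rep, n_fragments=n_fragments,
                    gene_body_enrichment=enrichment[(cond, mark)],
                    **dict(zip(("capsid", "species", "context", "timepoint"),
                               cond)), **common))
        for rep in range(1, n_tn5_replicates + 1):
            libs.append(LibrarySpec(
                target=TN5_INPUT, replicate=rep, n_fragments=tn5_fragments,
                **dict(zip(("capsid", "species", "context", "timepoint"),
                           cond)), **common))
    return libs


def fig2_like_config(seed: int = 0, n_fragments: int = 200_000,
                     depletion: float = _ENRICHED,
                     marks=("H3K4me3",), replicates: int = 3,
                     null: bool = False) -> PipelineConfig:
    """LK03/DJ x human/mouse grid with LK03-mouse active-mark depletion.

    ``depletion`` is the fold-difference injected between the enriched
    conditions and LK03-mouse; ``null=True`` gives every condition the
    same enrichment (no true effect).
    """
    conditions = [(capsid, species, "cell_line", "day3")
                  for capsid in ("LK03", "DJ")
                  for species in ("human", "mouse")]
    enrichment = {}
    for cond in conditions:
        for mark in marks:
            if null:
                enrichment[(cond, mark)] = _DEPLETED  # no effect anywhere
            elif (cond[0] == "LK03" and cond[1] == "mouse"
                    and mark in ACTIVE_MARKS):
                enrichment[(cond, mark)] = _DEPLETED
            else:
                enrichment[(cond, mark)] = _DEPLETED * depletion
    comparisons = [{
        "name": f"{mark}_LK03_mouse_vs_human", "test": "welch_t",
        "target": mark, "filter": {"capsid": "LK03"},
        "group_by": "species", "groups": ["mouse", "human"],
    } for mark in marks]
    comparisons += [{
        "name": f"{mark}_capsid_x_species", "test": "anova_2way",
        "target": mark, "factors": ["capsid", "species"],
    } for mark in marks]
    libs = _roster(conditions, marks, enrichment, replicates, n_fragments)
    return PipelineConfig(libraries=tuple(libs), seed=seed,
                          comparisons=tuple(comparisons),
                          write_tracks=False)


def fig3_like_config(seed: int = 0, n_fragments: int = 200_000,
                     marks=("H3K4me3",), replicates: int = 3
                     ) -> PipelineConfig:
    """LK03 vs rescued AM capsid: the single-residue insertion restores
    active-mark enrichment in mouse."""
    conditions = [(capsid, species, "cell_line", "day3")
                  for capsid in ("LK03", "AM")
                  for species in ("human", "mouse")]
    enrichment = {}
    for cond in conditions:
        for mark in marks:
            depleted = cond[0] == "LK03" and cond[1] == "mouse"
            enrichment[(cond, mark)] = _DEPLETED if depleted else _ENRICHED
    comparisons = [{
        "name": f"{mark}_capsid_in_mouse", "test": "anova_1way",
        "target": mark, "filter": {"species": "mouse"},
        "factors": ["capsid"],
    } for mark in marks] + [{
        "name": f"{mark}_capsid_x_species", "test": "anova_2way",
        "target": mark, "factors": ["capsid", "species"],
    } for mark in marks]
    libs = _roster(conditions, marks, enrichment, replicates, n_fragments)
    return PipelineConfig(libraries=tuple(libs), seed=seed,
                          comparisons=tuple(comparisons),
                          write_tracks=False)


def fig4_like_config(seed: int = 0, n_fragments: int = 200_000,
                     marks=("H3K4me3",), replicates: int = 3,
                     copy_loss: float = 10.0,
                     chromatinization_gain: float = 8.0) -> PipelineConfig:
    """Day-15 vs day-3 mouse liver: vector copies drop ``copy_loss``-fold
    while per-copy chromatinization rises ``chromatinization_gain``-fold
    (surviving genomes are the chromatinized ones)."""
    conditions = [("LK03", "mouse", "liver", tp) for tp in ("day3", "day15")]
    enrichment = {}
    scales = {"day3": 1.0, "day15": 1.0 / copy_loss}
    for cond in conditions:
        for mark in marks:
            enrichment[(cond, mark)] = (_DEPLETED if cond[3] == "day3"
                                        else _DEPLETED * chromatinization_gain)
    comparisons = [{
        "name": f"{mark}_day15_over_day3", "test": "timepoint_ratio",
        "target": mark, "group_by": "timepoint",
        "groups": ["day15", "day3"],
    } for mark in marks]
    libs = []
    for cond in conditions:
        for mark in marks:
            for rep in range(1, replicates + 1):
                libs.append(LibrarySpec(
                    target=mark, replicate=rep, n_fragments=n_fragments,
                    gene_body_enrichment=enrichment[(cond, mark)],
                    copy_number_scale=scales[cond[3]],
                    capsid=cond[0], species=cond[1], context=cond[2],
                    timepoint=cond[3]))
        for rep in (1, 2):
            libs.append(LibrarySpec(
                target=TN5_INPUT, replicate=rep,
                n_fragments=int(n_fragments * TN5_DEPTH_FACTOR),
                copy_number_scale=scales[cond[3]],
                capsid=cond[0], species=cond[1], context=cond[2],
                timepoint=cond[3]))
    return PipelineConfig(libraries=tuple(libs), seed=seed,
                          comparisons=tuple(comparisons),
                          write_tracks=False)


def scenario_study(preset: str, seed: int = 0, outdir=None, **kwargs) -> dict:
    """Build, run and qualitatively assess one preset scenario.

    Returns a bundle with the config, the :class:`PipelineResult` and an
    ``assertions`` dict stating whether the injected pattern was
    recovered by the reported statistics.
    """
    if preset == "fig2_like":
        config = fig2_like_config(seed=seed, **kwargs)
    elif preset == "fig3_like":
        config = fig3_like_config(seed=seed, **kwargs)
    elif preset == "fig4_like":
        config = fig4_like_config(seed=seed, **kwargs)
    else:
        raise ConfigurationError(f"unknown preset {preset!r}")
    result = run_pipeline(config, outdir=outdir)
    assertions = _assess(preset, result)
    return {"preset": preset, "config": config, "result": result,
            "assertions": assertions}


def _assess(preset: str, result: PipelineResult) -> dict:
    norm, tests = result.norm, result.tests
    if preset in ("fig2_like", "fig3_like"):
        out = {"p_values": {}, "pattern_holds": True}
        welch_rows = tests[tests["test"] == "welch_t"]
        for _, row in welch_rows.iterrows():
            mark = row["name"].split("_")[0]
            sub = norm[(norm["target"] == mark) & (norm["capsid"] == "LK03")]
            lo = sub.loc[sub["species"] == "mouse", "normalized"].mean()
            hi = sub.loc[sub["species"] == "human", "normalized"].mean()
            ok = lo < hi and row["p_value"] < result.config.alpha
            out["p_values"][row["name"]] = float(row["p_value"])
            out[row["name"]] = {"mouse_mean": float(lo),
                                "human_mean": float(hi), "called": bool(ok)}
            out["pattern_holds"] &= ok
        for _, row in tests[tests["test"] == "anova_1way"].iterrows():
            out["p_values"][f"{row['name']}:{row['term']}"] = float(row["p_value"])
        for _, row in tests[tests["test"] == "anova_2way"].iterrows():
            out["p_values"][f"{row['name']}:{row['term']}"] = float(row["p_value"])
        if preset == "fig3_like":
            out["pattern_holds"] = True
            for mark in norm["target"].unique():
                mouse = norm[(norm["target"] == mark)
                             & (norm["species"] == "mouse")]
                lk = mouse.loc[mouse["capsid"] == "LK03", "normalized"].mean()
                am = mouse.loc[mouse["capsid"] == "AM", "normalized"].mean()
                out[f"{mark}_mouse_AM_over_LK03"] = float(am / lk)
                out["pattern_holds"] &= am > lk
        return out
    if preset == "fig4_like":
        out = {"pattern_holds": True}
        for mark in norm["target"].unique():
            sub = norm[norm["target"] == mark]
            nr = timepoint_ratio(
                sub.loc[sub["timepoint"] == "day15", "normalized"],
                sub.loc[sub["timepoint"] == "day3", "normalized"])
            stats = result.stats
            tn5 = stats[stats["target"] == TN5_INPUT]
            cr = timepoint_ratio(
                tn5.loc[tn5["timepoint"] == "day15", "raw_value"],
                tn5.loc[tn5["timepoint"] == "day3", "raw_value"])
            out[f"{mark}_normalized_ratio"] = nr
            out[f"{mark}_copy_proxy_ratio"] = cr
            out["pattern_holds"] &= (nr > 1.0) and (cr < 1.0)
        return out
    raise ConfigurationError(preset)


def null_call_rate(n_runs: int = 200, seed: int = 0, alpha: float = 0.01,
                   n_fragments: int = 20_000, replicates: int = 3) -> float:
    """Fraction of null fig2-like runs (all enrichments equal) that would
    still call LK03-mouse < LK03-human at ``alpha``. Runs are reduced to
    the compared LK03 pair to keep many replicate studies cheap."""
    calls = 0
    for i in range(n_runs):
        config = fig2_like_config(seed=seed + i, n_fragments=n_fragments,
                                  replicates=replicates, null=True)
        config = replace(config, libraries=tuple(
            lib for lib in config.libraries if lib.capsid == "LK03"),
            comparisons=tuple(c for c in config.comparisons
                              if c["test"] == "welch_t"))
        result = run_pipeline(config)
        for _, row in result.tests.iterrows():
            sub = result.norm
            lo = sub.loc[sub["species"] == "mouse", "normalized"].mean()
            hi = sub.loc[sub["species"] == "human", "normalized"].mean()
            if row["p_value"] < alpha and lo < hi:
                calls += 1
                break
    return calls / n_runs
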