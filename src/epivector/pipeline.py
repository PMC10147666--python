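"""End-to-end orchestration: simulate/ingest -> dedup -> CPM tracks ->
ITR-masked coverage -> Tn5 normalization -> group statistics -> report.

A run is fully determined by one :class:`PipelineConfig` (loadable from
YAML) and its global seed. Per-library random streams are derived from
``SeedSequence([global_seed, crc32(sample_id)])`` so that adding or
removing one library never perturbs the fragments of another.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import (DENOMINATOR_MODES, UNMASKED_LENGTH, deduplicate,
                       per_base_cpm_track, region_coverage_stat,
                       write_bedgraph)
from .errors import ConfigurationError, ValidationError
from .fragments import read_fragments_bed, write_fragments_bed
from .genome import (GenomeBuild, IntervalSet, build_combined_reference,
                     build_vector_genome, itr_mask, serialize_reference)
from .normalize import stats_table, tn5_normalize_dataset
from .samples import (CONDITION_KEY, TN5_INPUT, Condition, LibraryMeta)
from .simulate import (SimulationConfig, chromatin_config, scale_copy_number,
                       simulate_chromatin_library, simulate_tn5_library)
from .stats import GroupSample, anova, significance_stars, timepoint_ratio, welch_t

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceSpec:
    vector_length: int = 4000
    itr_length: int = 145
    vector_name: str = "gAAV"
    host_contigs: tuple[tuple[str, int], ...] = (("chrH", 1_000_000),)


@dataclass(frozen=True)
class LibrarySpec:
    """One library of the roster: identity plus simulation ground truth.

    ``vector_fraction`` is the *abundance-only* (input-like) vector share;
    for chromatin targets the realized share is additionally scaled by the
    library's enrichment, and ``copy_number_scale`` rescales the vector's
    abundance odds to emulate copy-number differences between conditions.
    If ``fragments_path`` is set the library is ingested from BED instead
    of simulated.
    """

    target: str
    capsid: str
    species: str
    context: str = "cell_line"
    timepoint: str = "day3"
    replicate: int = 1
    sample_id: str | None = None
    n_fragments: int = 100_000
    vector_fraction: float = 0.01
    gene_body_enrichment: float = 1.0
    itr_multiplier: float = 5.0
    duplicate_rate: float = 0.1
    copy_number_scale: float = 1.0
    fragment_length: tuple[float, float] = (180.0, 50.0)
    fragments_path: str | None = None

    def resolved_sample_id(self) -> str:
        if self.sample_id:
            return self.sample_id
        return (f"{self.target}_{self.capsid}_{self.species}_{self.context}"
                f"_{self.timepoint}_r{self.replicate}")

    def condition(self) -> Condition:
        return Condition(capsid=self.capsid, species=self.species,
                         context=self.context, timepoint=self.timepoint)

    def meta(self) -> LibraryMeta:
        return LibraryMeta(sample_id=self.resolved_sample_id(),
                           condition=self.condition(), target=self.target,
                           replicate=self.replicate,
                           total_fragments=self.n_fragments)


@dataclass(frozen=True)
class PipelineConfig:
    libraries: tuple[LibrarySpec, ...]
    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    denominator_mode: str = UNMASKED_LENGTH
    comparisons: tuple[dict, ...] = ()
    seed: int = 0
    write_fragments: bool = False
    write_tracks: bool = True
    alpha: float = 0.05


@dataclass
class PipelineResult:
    config: PipelineConfig
    build: GenomeBuild
    mask: IntervalSet
    stats: pd.DataFrame
    norm: pd.DataFrame
    tests: pd.DataFrame
    outdir: Path | None = None


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> PipelineConfig:
    ref = doc.get("reference", {})
    refspec = ReferenceSpec(
        vector_length=int(ref.get("vector_length", 4000)),
        itr_length=int(ref.get("itr_length", 145)),
        vector_name=ref.get("vector_name", "gAAV"),
        host_contigs=tuple((str(n), int(l))
                           for n, l in ref.get("host_contigs",
                                               [["chrH", 1_000_000]])))
    libs = []
    for entry in doc.get("libraries", []):
        entry = dict(entry)
        if "fragment_length" in entry:
            entry["fragment_length"] = tuple(entry["fragment_length"])
        libs.append(LibrarySpec(**entry))
    return PipelineConfig(
        libraries=tuple(libs), reference=refspec,
        denominator_mode=doc.get("denominator_mode", UNMASKED_LENGTH),
        comparisons=tuple(doc.get("comparisons", [])),
        seed=int(doc.get("seed", 0)),
        write_fragments=bool(doc.get("write_fragments", False)),
        write_tracks=bool(doc.get("write_tracks", True)),
        alpha=float(doc.get("alpha", 0.05)))


def validate_config(config: PipelineConfig) -> None:
    """Schema-level checks, run before any compute."""
    if config.denominator_mode not in DENOMINATOR_MODES:
        raise ConfigurationError(
            f"unknown denominator_mode {config.denominator_mode!r}")
    if not config.libraries:
        raise ConfigurationError("library roster is empty")
    seen = set()
    tn5_conditions = set()
    ct_conditions: dict[tuple, str] = {}
    for lib in config.libraries:
        key = (lib.condition().key(), lib.target, lib.replicate)
        if key in seen:
            raise ConfigurationError(
                f"duplicate library (condition, target, replicate): {key}")
        seen.add(key)
        if lib.target == TN5_INPUT:
            tn5_conditions.add(lib.condition().key())
        else:
            ct_conditions[lib.condition().key()] = lib.condition().label()
    missing = [label for key, label in ct_conditions.items()
               if key not in tn5_conditions]
    if missing:
        raise ValidationError(
            "conditions lacking a Tn5 input library: " + ", ".join(sorted(missing)))


def library_seed(global_seed: int, sample_id: str) -> int:
    """Stable per-library substream seed (< 2^31)."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(sample_id.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _simulate_one(lib: LibrarySpec, build: GenomeBuild, seed: int):
    base = SimulationConfig(
        n_fragments=lib.n_fragments,
        vector_fraction=lib.vector_fraction,
        itr_multiplier=lib.itr_multiplier,
        duplicate_rate=lib.duplicate_rate,
        fragment_length=lib.fragment_length,
        seed=seed)
    if lib.copy_number_scale != 1.0:
        base = scale_copy_number(base, lib.copy_number_scale)
    meta = lib.meta()
    if lib.target == TN5_INPUT:
        return simulate_tn5_library(base, build, meta)
    cfg = chromatin_config(base, build.vector, lib.gene_body_enrichment,
                           seed=seed)
    return simulate_chromatin_library(cfg, build, meta)


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute all stages; write report files when ``outdir`` is given."""
    validate_config(config)
    ref = config.reference
    vector = build_vector_genome(ref.vector_length, ref.itr_length,
                                 name=ref.vector_name)
    build = build_combined_reference(list(ref.host_contigs), vector)
    mask = itr_mask(vector)

    out = Path(outdir) if outdir is not None else None
    run_log: dict = {"epivector": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "seed": config.seed,
                     "libraries": []}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        serialize_reference(build, mask, out / "reference", seed=config.seed)

    entries = []
    for lib in config.libraries:
        meta = lib.meta()
        if lib.fragments_path is not None:
            frags = read_fragments_bed(lib.fragments_path, meta=meta)
        else:
            frags = _simulate_one(lib, build,
                                  library_seed(config.seed, meta.sample_id))
        n_in = len(frags)
        frags = deduplicate(frags)
        if out is not None and config.write_fragments:
            (out / "fragments").mkdir(exist_ok=True)
            write_fragments_bed(
                frags, out / "fragments" / f"{meta.sample_id}.bed")
        track = per_base_cpm_track(frags, build, vector.name)
        if out is not None and config.write_tracks:
            (out / "tracks").mkdir(exist_ok=True)
            write_bedgraph(track, out / "tracks" / f"{meta.sample_id}.bedgraph")
        stat = region_coverage_stat(track, vector.length, mask,
                                    config.denominator_mode,
                                    sample_id=meta.sample_id)
        entries.append((stat, meta))
        run_log["libraries"].append({
            "sample_id": meta.sample_id, "fragments_in": n_in,
            "fragments_dedup": len(frags),
            "duplicates_removed": n_in - len(frags),
            "raw_coverage": stat.raw_value})

    stats = stats_table(entries)
    norm = tn5_normalize_dataset(stats)
    tests = run_comparisons(norm, config.comparisons)
    if out is not None:
        stats.to_csv(out / "stats.tsv", sep="\t", index=False)
        norm.to_csv(out / "norm.tsv", sep="\t", index=False)
        tests.to_csv(out / "tests.tsv", sep="\t", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=1)
    return PipelineResult(config=config, build=build, mask=mask, stats=stats,
                          norm=norm, tests=tests, outdir=out)


# ---------------------------------------------------------------------------
# comparison stage (re-runnable on a stored norm table)

TEST_COLUMNS = ["name", "test", "term", "statistic", "df", "p_value",
                "stars", "group_means"]


def _apply_filter(df: pd.DataFrame, spec: dict) -> pd.DataFrame:
    sub = df
    if spec.get("target"):
        sub = sub[sub["target"] == spec["target"]]
    for col, val in spec.get("filter", {}).items():
        sub = sub[sub[col] == val]
    return sub


def run_comparisons(norm: pd.DataFrame, comparisons) -> pd.DataFrame:
    """Evaluate the configured comparisons on the normalized table.

    Each comparison is a mapping with ``test`` one of ``welch_t``,
    ``anova_1way``, ``anova_2way`` or ``timepoint_ratio``, an optional
    ``target``/``filter`` restriction, and either ``group_by`` +
    ``groups`` (two-group tests/ratios) or ``factors`` (ANOVA). Values
    compared are the Tn5-normalized coverages unless ``value_col`` says
    otherwise.
    """
    rows = []
    for spec in comparisons:
        sub = _apply_filter(norm, spec)
        col = spec.get("value_col", "normalized")
        test = spec["test"]
        name = spec.get("name", test)
        if test in ("welch_t", "timepoint_ratio"):
            by = spec["group_by"]
            g1, g2 = spec["groups"]
            a = sub.loc[sub[by] == g1, col].to_numpy()
            b = sub.loc[sub[by] == g2, col].to_numpy()
            if len(a) == 0 or len(b) == 0:
                raise ValidationError(
                    f"comparison {name!r}: empty group ({g1!r} or {g2!r})")
            means = f"{g1}={np.mean(a):.6g};{g2}={np.mean(b):.6g}"
            if test == "welch_t":
                res = welch_t(a, b)
                rows.append([name, test, f"{by}:{g1}-vs-{g2}", res.statistic,
                             f"{res.df:.6g}", res.p_value,
                             res.significance_stars, means])
            else:
                ratio = timepoint_ratio(a, b)
                rows.append([name, test, f"{by}:{g1}/{g2}", ratio, "",
                             float("nan"), "", means])
        elif test in ("anova_1way", "anova_2way"):
            factors = {f: sub[f].to_numpy() for f in spec["factors"]}
            for res in anova(sub[col].to_numpy(), factors):
                dfs = (f"{res.df[0]:.6g},{res.df[1]:.6g}"
                       if isinstance(res.df, tuple) else f"{res.df:.6g}")
                rows.append([name, test, res.term, res.statistic, dfs,
                             res.p_value, res.significance_stars, ""])
        else:
            raise ConfigurationError(f"unknown comparison test {test!r}")
    return pd.DataFrame(rows, columns=TEST_COLUMNS)
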