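"""Per-base CPM coverage tracks and the ITR-masked coverage statistic.

The track value at base ``b`` is the number of deduplicated fragments
overlapping ``b``, scaled to counts per million by ``1e6 / N`` where
``N`` is the library's total deduplicated fragment count across *all*
contigs (genome-wide CPM, as standard coverage tools compute it).

The scalar summary of a vector contig is the length-weighted mean of the
normalized per-base counts over the vector with ITR intervals excluded:

    stat = sum_over_unmasked_intervals(value * interval_length) / D

with ``D`` either the unmasked length (default) or the full vector
("gAAV") size — the two readings of dividing by genome size after
removing the ITRs from the calculation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError
from .fragments import FragmentSet
from .genome import GenomeBuild, IntervalSet

logger = logging.getLogger(__name__)

UNMASKED_LENGTH = "unmasked_length"
FULL_GAAV_SIZE = "full_gAAV_size"
DENOMINATOR_MODES = (UNMASKED_LENGTH, FULL_GAAV_SIZE)


@dataclass(frozen=True)
class CoverageTrack:
    """Merged constant-value intervals of per-base CPM; zero runs omitted."""

    contig: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    total_fragments_used: int
    contig_length: int | None = None

    def __post_init__(self):
        if len(self.starts) and (
                np.any(self.starts >= self.ends)
                or np.any(self.starts[1:] < self.ends[:-1])):
            raise ConfigurationError("track intervals unsorted or overlapping")
        if np.any(self.values < 0):
            raise ConfigurationError("negative coverage value")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def extent(self) -> int:
        return int(self.ends[-1]) if len(self.ends) else 0

    def per_base(self, length: int | None = None) -> np.ndarray:
        """Expand to a dense per-base array (zeros where no interval)."""
        length = length if length is not None else (
            self.contig_length or self.extent)
        arr = np.zeros(length, dtype=float)
        for s, e, v in zip(self.starts, self.ends, self.values):
            arr[s:e] = v
        return arr

    def equals(self, other: "CoverageTrack") -> bool:
        return (self.contig == other.contig
                and np.array_equal(self.starts, other.starts)
                and np.array_equal(self.ends, other.ends)
                and np.array_equal(self.values, other.values))


@dataclass(frozen=True)
class CoverageStat:
    """Length-weighted, mask-excluded mean CPM over one region."""

    sample_id: str
    region: str
    raw_value: float
    masked_length: int
    denominator_mode: str
    region_length: int
    total_fragments: int = 0


def deduplicate(fragments: FragmentSet) -> FragmentSet:
    """Collapse fragments with identical (contig, start, end, strand),
    keeping the first occurrence in input order (PCR-duplicate removal)."""
    if fragments.dedup_applied:
        raise ValidationError("deduplication already applied")
    df = pd.DataFrame({"contig": fragments.contig, "start": fragments.start,
                       "end": fragments.end, "strand": fragments.strand})
    keep = ~df.duplicated(keep="first").to_numpy()
    removed = int((~keep).sum())
    logger.info("deduplicate[%s]: %d of %d fragments removed",
                fragments.meta.sample_id, removed, len(fragments))
    return FragmentSet(
        meta=fragments.meta,
        contig=fragments.contig[keep],
        start=fragments.start[keep],
        end=fragments.end[keep],
        strand=fragments.strand[keep],
        is_duplicate_origin=None if fragments.is_duplicate_origin is None
        else fragments.is_duplicate_origin[keep],
        dedup_applied=True,
    )


def _runs_from_dense(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compress a dense array into nonzero constant runs."""
    change = np.flatnonzero(np.diff(cov)) + 1
    bounds = np.concatenate(([0], change, [len(cov)]))
    starts, ends = bounds[:-1], bounds[1:]
    vals = cov[starts]
    nz = vals != 0
    return starts[nz], ends[nz], vals[nz]


def per_base_cpm_track(fragments: FragmentSet, build: GenomeBuild,
                       contig: str, require_dedup: bool = True
                       ) -> CoverageTrack:
    """Per-base CPM track on one contig (bin size 1).

    ``require_dedup`` enforces that PCR duplicates were removed first; it
    may be relaxed for invariance checks since CPM itself is scale-free.
    """
    if require_dedup and not fragments.dedup_applied:
        raise ValidationError("per_base_cpm_track requires deduplicated input")
    n_total = len(fragments)
    if n_total == 0:
        raise ValidationError("CPM normalization undefined for empty library")
    length = build.contig(contig).length
    sub = fragments.subset_contig(contig)
    delta = np.zeros(length + 1, dtype=np.int64)
    np.add.at(delta, sub.start, 1)
    np.add.at(delta, sub.end, -1)
    cov = np.cumsum(delta[:-1]).astype(float) * (1e6 / n_total)
    starts, ends, values = _runs_from_dense(cov)
    return CoverageTrack(contig=contig, starts=starts, ends=ends,
                         values=values, total_fragments_used=n_total,
                         contig_length=length)


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track: CoverageTrack, path) -> None:
    """4-column bedGraph, 0-based half-open; zero-value runs omitted.

    Values are written with shortest round-trip float repr so that
    write -> read is the identity on the statistic."""
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.contig}\t{s}\t{e}\t{float(v)!r}\n")


def read_bedgraph(path, total_fragments_used: int = 0,
                  contig_length: int | None = None) -> CoverageTrack:
    contig = None
    starts, ends, values = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError("expected 4 bedGraph columns",
                                 path=str(path), line_number=ln)
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(str(exc), path=str(path), line_number=ln)
            if contig is None:
                contig = parts[0]
            elif parts[0] != contig:
                raise ParseError("multi-contig bedGraph not supported here",
                                 path=str(path), line_number=ln)
            if starts and s < ends[-1]:
                raise ParseError("overlapping or unsorted intervals",
                                 path=str(path), line_number=ln)
            if v != 0.0:
                starts.append(s)
                ends.append(e)
                values.append(v)
    if contig is None:
        raise ParseError("empty bedGraph", path=str(path))
    return CoverageTrack(contig=contig,
                         starts=np.array(starts, dtype=np.int64),
                         ends=np.array(ends, dtype=np.int64),
                         values=np.array(values, dtype=float),
                         total_fragments_used=total_fragments_used,
                         contig_length=contig_length)


# ---------------------------------------------------------------------------
# the coverage statistic

def region_coverage_stat(track: CoverageTrack, region_length: int,
                         mask: IntervalSet | None = None,
                         denominator_mode: str = UNMASKED_LENGTH,
                         sample_id: str = "") -> CoverageStat:
    """Length-weighted mean CPM over ``[0, region_length)`` minus the mask.

    Intervals partially overlapping the mask contribute only their
    unmasked bases; zero-coverage bases count as zeros.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ConfigurationError(
            f"unknown denominator mode {denominator_mode!r}")
    if mask is None:
        mask = IntervalSet.empty()
    if mask.intervals and track.contig not in mask.contigs:
        raise ValidationError(
            f"mask contigs {mask.contigs} do not include track contig "
            f"{track.contig!r}")
    if region_length < track.extent:
        raise ValidationError(
            f"region_length {region_length} smaller than track extent "
            f"{track.extent}")
    masked_length = mask.overlap_length(track.contig, 0, region_length)
    if denominator_mode == UNMASKED_LENGTH:
        denom = region_length - masked_length
    else:
        denom = region_length
    if denom <= 0:
        raise ValidationError("zero-length denominator")
    total = 0.0
    mask_ivs = mask.on_contig(track.contig)
    for s, e, v in zip(track.starts, track.ends, track.values):
        overlap = sum(max(0, min(e, me) - max(s, ms)) for ms, me in mask_ivs)
        total += v * ((e - s) - overlap)
    return CoverageStat(sample_id=sample_id or "", region=track.contig,
                        raw_value=total / denom, masked_length=masked_length,
                        denominator_mode=denominator_mode,
                        region_length=region_length,
                        total_fragments=track.total_fragments_used)
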