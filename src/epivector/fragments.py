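"""Fragment-level alignment records.

The unit of everything downstream is the sequenced *fragment* (the
tagmented DNA molecule), not the individual read: a paired-end 2x75
library determines each fragment's interval exactly, and coverage is
fragment coverage. ``FragmentSet`` stores fragments columnar (numpy)
for speed at multi-million-fragment scale and knows how to round-trip
through BED and paired-end SAM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigurationError, ParseError
from .genome import GenomeBuild
from .samples import Condition, LibraryMeta

DEFAULT_READ_LENGTH = 75


@dataclass(frozen=True)
class FragmentRecord:
    contig: str
    start: int
    end: int
    strand: str
    sample_id: str = ""
    is_duplicate_origin: bool = False


@dataclass
class FragmentSet:
    """Columnar collection of aligned fragment intervals for one library."""

    meta: LibraryMeta
    contig: np.ndarray          # dtype object/str
    start: np.ndarray           # int64
    end: np.ndarray             # int64
    strand: np.ndarray          # '<U1'
    is_duplicate_origin: np.ndarray | None = None
    dedup_applied: bool = False

    def __post_init__(self):
        n = len(self.start)
        if not (len(self.contig) == len(self.end) == len(self.strand) == n):
            raise ConfigurationError("fragment columns have unequal lengths")
        if n and np.any(self.start >= self.end):
            raise ConfigurationError("fragment with start >= end")

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord], meta: LibraryMeta,
                     dedup_applied: bool = False) -> "FragmentSet":
        recs = list(records)
        return cls(
            meta=meta,
            contig=np.array([r.contig for r in recs], dtype=object),
            start=np.array([r.start for r in recs], dtype=np.int64),
            end=np.array([r.end for r in recs], dtype=np.int64),
            strand=np.array([r.strand for r in recs], dtype="<U1"),
            is_duplicate_origin=np.array(
                [r.is_duplicate_origin for r in recs], dtype=bool),
            dedup_applied=dedup_applied,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "contig": self.contig, "start": self.start, "end": self.end,
            "strand": self.strand, "sample_id": self.meta.sample_id,
        })

    def key_multiset(self) -> list[tuple]:
        """Sorted (contig, start, end, strand) keys, for equality checks."""
        return sorted(zip(self.contig.tolist(), self.start.tolist(),
                          self.end.tolist(), self.strand.tolist()))

    def subset_contig(self, contig: str) -> "FragmentSet":
        m = self.contig == contig
        return FragmentSet(self.meta, self.contig[m], self.start[m],
                           self.end[m], self.strand[m],
                           None if self.is_duplicate_origin is None
                           else self.is_duplicate_origin[m],
                           self.dedup_applied)

    def validate_against(self, build: GenomeBuild) -> None:
        lengths = {c.name: c.length for c in build.contigs}
        for name in np.unique(self.contig.astype(str)):
            if name not in lengths:
                raise ConfigurationError(f"fragment on unknown contig {name!r}")
            m = self.contig == name
            if np.any(self.start[m] < 0) or np.any(self.end[m] > lengths[name]):
                raise ConfigurationError(
                    f"fragment outside bounds of contig {name!r}")


# ---------------------------------------------------------------------------
# BED

def write_fragments_bed(fragments: FragmentSet, path: str | Path,
                        build: GenomeBuild | None = None) -> None:
    """BED6 with name = sample_id, score = 0."""
    if build is not None:
        fragments.validate_against(build)
    sid = fragments.meta.sample_id
    with open(path, "w") as fh:
        for c, s, e, st in zip(fragments.contig, fragments.start,
                               fragments.end, fragments.strand):
            fh.write(f"{c}\t{s}\t{e}\t{sid}\t0\t{st}\n")


def read_fragments_bed(path: str | Path, meta: LibraryMeta | None = None
                       ) -> FragmentSet:
    contigs, starts, ends, strands = [], [], [], []
    sample_id = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError("expected 6 BED columns",
                                 path=str(path), line_number=ln)
            try:
                contigs.append(parts[0])
                starts.append(int(parts[1]))
                ends.append(int(parts[2]))
                strands.append(parts[5])
            except ValueError as exc:
                raise ParseError(str(exc), path=str(path), line_number=ln)
            sample_id = parts[3]
    if meta is None:
        meta = LibraryMeta(sample_id=sample_id or "unknown",
                           condition=Condition("other", "human"),
                           target="Tn5_input")
    return FragmentSet(
        meta=meta,
        contig=np.array(contigs, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype="<U1"),
    )


# ---------------------------------------------------------------------------
# SAM (paired-end view)

def write_fragments_sam(fragments: FragmentSet, path: str | Path,
                        build: GenomeBuild,
                        read_length: int = DEFAULT_READ_LENGTH) -> None:
    """Emit each fragment as a proper FR read pair with ``read_length`` bp
    reads anchored at the fragment ends (mates overlap for short fragments).

    The first-in-pair read sits at the 5' end of the fragment's strand, so
    strand round-trips through the pair orientation.
    """
    fragments.validate_against(build)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": c.length} for c in build.contigs],
    })
    tid = {c.name: i for i, c in enumerate(build.contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (c, s, e, st) in enumerate(zip(
                fragments.contig, fragments.start, fragments.end,
                fragments.strand)):
            s, e = int(s), int(e)
            flen = e - s
            rlen = min(read_length, flen)
            qname = f"{fragments.meta.sample_id}:{i}"
            fwd = pysam.AlignedSegment(header)
            fwd.query_name = qname
            fwd.reference_id = tid[str(c)]
            fwd.reference_start = s
            fwd.cigarstring = f"{rlen}M"
            fwd.query_sequence = "N" * rlen
            fwd.mapping_quality = 60
            rev = pysam.AlignedSegment(header)
            rev.query_name = qname
            rev.reference_id = tid[str(c)]
            rev.reference_start = e - rlen
            rev.cigarstring = f"{rlen}M"
            rev.query_sequence = "N" * rlen
            rev.mapping_quality = 60
            first, second = (fwd, rev) if st == "+" else (rev, fwd)
            for seg, mate, is_first in ((first, second, True),
                                        (second, first, False)):
                seg.is_paired = True
                seg.is_proper_pair = True
                seg.is_read1 = is_first
                seg.is_read2 = not is_first
                seg.is_reverse = seg is rev
                seg.mate_is_reverse = mate is rev
                seg.next_reference_id = seg.reference_id
                seg.next_reference_start = mate.reference_start
                seg.template_length = flen if seg is fwd else -flen
            out.write(first)
            out.write(second)


def read_fragments_sam(path: str | Path, meta: LibraryMeta | None = None
                       ) -> FragmentSet:
    """Reconstruct fragments from proper pairs written by
    :func:`write_fragments_sam` (first-in-pair orientation gives strand)."""
    contigs, starts, ends, strands = [], [], [], []
    sample_id = None
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if not seg.is_read1 or seg.is_unmapped:
                continue
            flen = abs(seg.template_length)
            if seg.is_reverse:
                end = seg.reference_end
                start = end - flen
                strand = "-"
            else:
                start = seg.reference_start
                end = start + flen
                strand = "+"
            contigs.append(seg.reference_name)
            starts.append(start)
            ends.append(end)
            strands.append(strand)
            if sample_id is None:
                sample_id = seg.query_name.rsplit(":", 1)[0]
    if meta is None:
        meta = LibraryMeta(sample_id=sample_id or "unknown",
                           condition=Condition("other", "human"),
                           target="Tn5_input")
    return FragmentSet(
        meta=meta,
        contig=np.array(contigs, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype="<U1"),
    )


def write_fragments(fragments: FragmentSet, path: str | Path,
                    format: str = "BED", build: GenomeBuild | None = None,
                    read_length: int = DEFAULT_READ_LENGTH) -> None:
    """Dispatch on format; SAM requires the genome build for its header."""
    fmt = format.upper()
    if fmt == "BED":
        write_fragments_bed(fragments, path, build=build)
    elif fmt == "SAM":
        if build is None:
            raise ConfigurationError("SAM output requires a GenomeBuild")
        write_fragments_sam(fragments, path, build, read_length=read_length)
    else:
        raise ConfigurationError(f"unknown fragment format {format!r}")
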