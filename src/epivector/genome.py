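"""Combined host + vector reference model.

The vector genome (``gAAV``) is the ITR-to-ITR expression cassette of a
recombinant AAV vector: two inverted terminal repeats flanking promoter,
transgene, regulatory and polyA elements. For coverage quantification it
is appended to the host reference as one extra contig. ITR intervals get
their own mask because ITR signal is systematically overrepresented in
tagmentation libraries and is excluded from the coverage statistic.

All coordinates are 0-based half-open (BED convention); an interval
``[start, end)`` has length ``end - start``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, ConfigurationError

ITR_LEFT = "ITR_left"
ITR_RIGHT = "ITR_right"
INNER_LABELS = ("promoter", "transgene", "regulatory", "polyA")
_FASTA_WIDTH = 60

#: Inner cassette layout used when none is specified: lengths sum to
#: ``length - 2 * itr_length`` after proportional rescaling.
DEFAULT_INNER_LAYOUT = (("promoter", 600), ("transgene", 2310),
                        ("regulatory", 600), ("polyA", 200))


@dataclass(frozen=True)
class Feature:
    label: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ConfigurationError(
                f"feature {self.label}: invalid interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VectorGenome:
    """ITR-to-ITR vector genome with its feature annotation."""

    name: str
    length: int
    features: tuple[Feature, ...]
    sequence: str | None = None

    def __post_init__(self):
        labels = [f.label for f in self.features]
        if labels.count(ITR_LEFT) > 1 or labels.count(ITR_RIGHT) > 1:
            raise ConfigurationError("duplicate ITR features")
        for f in self.features:
            if f.end > self.length:
                raise ConfigurationError(
                    f"feature {f.label} exceeds vector length {self.length}")
        left = self.feature(ITR_LEFT, required=False)
        right = self.feature(ITR_RIGHT, required=False)
        if left is not None and left.start != 0:
            raise ConfigurationError("ITR_left must start at position 0")
        if right is not None and right.end != self.length:
            raise ConfigurationError("ITR_right must end at the vector end")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ConfigurationError("sequence length != vector length")

    def feature(self, label: str, required: bool = True) -> Feature | None:
        for f in self.features:
            if f.label == label:
                return f
        if required:
            raise AnnotationError(f"vector {self.name} lacks feature {label!r}")
        return None

    @property
    def gene_body(self) -> tuple[int, int]:
        """The non-ITR interval [ITR_left.end, ITR_right.start)."""
        return (self.feature(ITR_LEFT).end, self.feature(ITR_RIGHT).start)


@dataclass(frozen=True)
class Contig:
    name: str
    length: int
    is_vector: bool = False


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered host contigs plus the single flagged vector contig."""

    contigs: tuple[Contig, ...]
    vector: VectorGenome

    def __post_init__(self):
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ConfigurationError("contig names are not unique")
        vec = [c for c in self.contigs if c.is_vector]
        if len(vec) != 1:
            raise ConfigurationError("exactly one contig must be flagged as vector")
        if vec[0].name != self.vector.name or vec[0].length != self.vector.length:
            raise ConfigurationError("vector contig does not match VectorGenome")

    @property
    def vector_contig(self) -> Contig:
        return next(c for c in self.contigs if c.is_vector)

    @property
    def host_contigs(self) -> tuple[Contig, ...]:
        return tuple(c for c in self.contigs if not c.is_vector)

    def contig(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, merged, non-abutting intervals keyed by contig."""

    intervals: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_contig: dict[str, list[list[int]]] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise ConfigurationError(
                    f"invalid interval [{start},{end}) on {contig}")
            by_contig.setdefault(contig, []).append([start, end])
        merged: list[tuple[str, int, int]] = []
        for contig in sorted(by_contig):
            ivs = sorted(by_contig[contig])
            cur = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur[1]:  # overlap or abut -> merge
                    cur[1] = max(cur[1], e)
                else:
                    merged.append((contig, cur[0], cur[1]))
                    cur = [s, e]
            merged.append((contig, cur[0], cur[1]))
        return cls(tuple(merged))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(())

    def on_contig(self, contig: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.intervals if c == contig]

    def total_length(self, contig: str | None = None) -> int:
        return sum(e - s for c, s, e in self.intervals
                   if contig is None or c == contig)

    def overlap_length(self, contig: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the set on ``contig``."""
        total = 0
        for s, e in self.on_contig(contig):
            total += max(0, min(end, e) - max(start, s))
        return total

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c for c, _, _ in self.intervals))


def build_vector_genome(length: int,
                        itr_length: int,
                        feature_layout: Sequence[tuple[str, int]] | None = None,
                        name: str = "gAAV",
                        seed: int | None = None) -> VectorGenome:
    """Construct an ITR-to-ITR vector genome from an ordered feature layout.

    ``feature_layout`` lists the inner (non-ITR) features as (label, length)
    in cassette order; the two ITRs are added automatically at the ends.
    When ``seed`` is given a reproducible random nucleotide sequence is
    attached.
    """
    if itr_length < 1:
        raise ConfigurationError("itr_length must be >= 1")
    inner_span = length - 2 * itr_length
    if inner_span < 0:
        raise ConfigurationError("ITRs do not fit inside the vector length")
    if feature_layout is None:
        feature_layout = _scale_layout(DEFAULT_INNER_LAYOUT, inner_span)
    if sum(l for _, l in feature_layout) != inner_span:
        raise ConfigurationError(
            f"inner feature lengths sum to {sum(l for _, l in feature_layout)}, "
            f"expected {inner_span} for length={length}, itr_length={itr_length}")
    features = [Feature(ITR_LEFT, 0, itr_length)]
    pos = itr_length
    for label, flen in feature_layout:
        if flen <= 0:
            raise ConfigurationError(f"feature {label} has non-positive length")
        features.append(Feature(label, pos, pos + flen))
        pos += flen
    features.append(Feature(ITR_RIGHT, length - itr_length, length))
    sequence = None
    if seed is not None:
        sequence = random_sequence(length, seed)
    return VectorGenome(name=name, length=length, features=tuple(features),
                        sequence=sequence)


def _scale_layout(layout, span: int) -> list[tuple[str, int]]:
    total = sum(l for _, l in layout)
    scaled = [(label, max(1, round(l * span / total))) for label, l in layout]
    # absorb rounding drift into the largest feature
    drift = span - sum(l for _, l in scaled)
    big = max(range(len(scaled)), key=lambda i: scaled[i][1])
    scaled[big] = (scaled[big][0], scaled[big][1] + drift)
    return scaled


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def build_combined_reference(host_contigs: Sequence[tuple[str, int]],
                             vector: VectorGenome) -> GenomeBuild:
    """Append the vector as the last contig of the combined reference."""
    contigs = []
    for name, length in host_contigs:
        if name == vector.name:
            raise ConfigurationError(
                f"host contig name collides with vector name {name!r}")
        contigs.append(Contig(name, int(length), is_vector=False))
    contigs.append(Contig(vector.name, vector.length, is_vector=True))
    return GenomeBuild(contigs=tuple(contigs), vector=vector)


def itr_mask(vector: VectorGenome) -> IntervalSet:
    """The two ITR intervals, as the mask excluded from coverage statistics."""
    left = vector.feature(ITR_LEFT)
    right = vector.feature(ITR_RIGHT)
    return IntervalSet.from_intervals([
        (vector.name, left.start, left.end),
        (vector.name, right.start, right.end),
    ])


# ---------------------------------------------------------------------------
# serialization

def serialize_reference(build: GenomeBuild, mask: IntervalSet, outdir: str | Path,
                        seed: int = 0) -> dict[str, Path]:
    """Write FASTA + BED + JSON reference files; see :func:`read_reference`.

    Host contigs without a stored sequence get a seeded synthetic one so the
    FASTA is deterministic for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fa",
        "features": outdir / "features.bed",
        "mask": outdir / "itr_mask.bed",
        "build": outdir / "build.json",
    }
    records = []
    for i, contig in enumerate(build.contigs):
        if contig.is_vector and build.vector.sequence is not None:
            seq = build.vector.sequence
        else:
            seq = random_sequence(contig.length, seed + i)
        records.append(SeqRecord(Seq(seq), id=contig.name, description=""))
    with open(paths["fasta"], "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WIDTH)
        writer.write_file(records)
    with open(paths["features"], "w") as fh:
        for f in build.vector.features:
            fh.write(f"{build.vector.name}\t{f.start}\t{f.end}\t{f.label}\n")
    write_bed(mask, paths["mask"])
    with open(paths["build"], "w") as fh:
        json.dump({
            "contigs": [[c.name, c.length, c.is_vector] for c in build.contigs],
            "vector": {
                "name": build.vector.name,
                "length": build.vector.length,
                "features": [[f.label, f.start, f.end]
                             for f in build.vector.features],
                "has_sequence": build.vector.sequence is not None,
            },
        }, fh, indent=1)
    return paths


def read_reference(refdir: str | Path) -> tuple[GenomeBuild, IntervalSet]:
    """Inverse of :func:`serialize_reference`."""
    refdir = Path(refdir)
    with open(refdir / "build.json") as fh:
        doc = json.load(fh)
    seqs = {rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(refdir / "reference.fa"), "fasta")}
    vinfo = doc["vector"]
    vector = VectorGenome(
        name=vinfo["name"], length=vinfo["length"],
        features=tuple(Feature(l, s, e) for l, s, e in vinfo["features"]),
        sequence=seqs.get(vinfo["name"]) if vinfo["has_sequence"] else None)
    contigs = tuple(Contig(n, l, v) for n, l, v in doc["contigs"])
    build = GenomeBuild(contigs=contigs, vector=vector)
    return build, read_bed(refdir / "itr_mask.bed")


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals.intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path: str | Path) -> IntervalSet:
    from .errors import ParseError
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("expected >= 3 BED columns",
                                 path=str(path), line_number=ln)
            try:
                out.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(str(exc), path=str(path), line_number=ln)
    return IntervalSet.from_intervals(out) if out else IntervalSet.empty()
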