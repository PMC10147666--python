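import numpy as np
import pytest

from epivector.coverage import CoverageTrack
from epivector.genome import (IntervalSet, build_combined_reference,
                              build_vector_genome, itr_mask)
from epivector.samples import Condition, LibraryMeta


@pytest.fixture(scope="session")
def vector():
    return build_vector_genome(4000, 145, seed=11)


@pytest.fixture(scope="session")
def build(vector):
    return build_combined_reference([("chrH", 100_000)], vector)


@pytest.fixture(scope="session")
def mask(vector):
    return itr_mask(vector)


@pytest.fixture
def condition():
    return Condition("LK03", "human")


@pytest.fixture
def meta(condition):
    return LibraryMeta("lib1", condition, "H3K4me3")


@pytest.fixture
def tn5_meta(condition):
    return LibraryMeta("tn5_1", condition, "Tn5_input")


def make_track(intervals, contig="gAAV", n=1, length=None):
    """CoverageTrack from a list of (start, end, value)."""
    nz = [(s, e, v) for s, e, v in intervals if v != 0]
    return CoverageTrack(
        contig=contig,
        starts=np.array([s for s, _, _ in nz], dtype=np.int64),
        ends=np.array([e for _, e, _ in nz], dtype=np.int64),
        values=np.array([v for _, _, v in nz], dtype=float),
        total_fragments_used=n, contig_length=length)


def naive_region_stat(track, region_length, mask_intervals, mode):
    """Independent per-base-loop oracle for the coverage statistic."""
    per_base = np.zeros(region_length)
    for s, e, v in zip(track.starts, track.ends, track.values):
        per_base[s:e] = v
    masked = np.zeros(region_length, dtype=bool)
    for s, e in mask_intervals:
        masked[s:min(e, region_length)] = True
    unmasked_sum = per_base[~masked].sum()
    denom = (region_length - masked.sum()) if mode == "unmasked_length" \
        else region_length
    return unmasked_sum / denom


def random_track_and_mask(rng, contig="gAAV"):
    """Small random piecewise track + random mask for oracle comparisons."""
    length = int(rng.integers(50, 400))
    n_iv = int(rng.integers(1, 12))
    bounds = np.sort(rng.choice(length, size=2 * n_iv, replace=False))
    intervals = []
    for i in range(n_iv):
        s, e = int(bounds[2 * i]), int(bounds[2 * i + 1])
        if s < e:
            intervals.append((s, e, float(rng.uniform(0, 50))))
    n_m = int(rng.integers(0, 4))
    mask_iv = []
    for _ in range(n_m):
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, length + 1))
        mask_iv.append((contig, s, e))
    mask = IntervalSet.from_intervals(mask_iv) if mask_iv else IntervalSet.empty()
    return make_track(intervals, contig=contig, length=length), length, mask
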