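"""Synthetic fragment libraries and qPCR plates with known ground truth.

The simulator emulates the structure of tagmentation sequencing data from
cells carrying episomal AAV vector genomes: a combined host+vector
reference, paired-end 2x75 libraries of a few million fragments, a small
fraction of fragments originating from the vector contig, PCR duplicates,
and — for chromatin (Cut&Tag) libraries — mark-dependent enrichment over
the vector plus systematic ITR overrepresentation. Tn5 "input" libraries
are the abundance-only counterpart: uniform within the vector apart from
the ITR effect.

Model
-----
Each fragment is assigned to the vector contig with probability
``vector_fraction``, otherwise to a host contig (host contigs weighted by
length, positions uniform). Vector fragment midpoints are drawn with
per-base weight ``enrichment_profile x itr_multiplier`` (the multiplier
applies over ITR intervals). Fragment lengths follow a lognormal with
arithmetic mean/sd on a nucleosomal scale, truncated to a plausible
range. PCR duplicates are exact copies of already-drawn fragments,
appended after the first pass so the ground truth of every duplicate is
known.

Because an affinity assay captures more vector material when the vector
carries more of the targeted mark, a condition with gene-body enrichment
``E`` should also yield proportionally more vector fragments.
:func:`chromatin_config` encodes this: it scales the vector-assignment
odds by the ratio of total vector sampling weight to the unenriched
weight, so that downstream Tn5-normalized coverage recovers ``E``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fragments import FragmentSet
from .genome import GenomeBuild, VectorGenome, itr_mask
from .samples import LibraryMeta, TN5_INPUT


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated library.

    ``enrichment_profile`` is piecewise constant over vector coordinates:
    a list of (start, end, weight) multipliers, ``None`` meaning uniform.
    """

    n_fragments: int = 2_000_000
    vector_fraction: float = 0.01
    enrichment_profile: tuple[tuple[int, int, float], ...] | None = None
    itr_multiplier: float = 5.0
    duplicate_rate: float = 0.1
    fragment_length: tuple[float, float] = (180.0, 50.0)
    fragment_length_bounds: tuple[int, int] = (50, 1000)
    read_length: int = 75
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.vector_fraction <= 1.0:
            raise ConfigurationError("vector_fraction must be in [0, 1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ConfigurationError("duplicate_rate must be in [0, 1)")
        if self.n_fragments <= 0:
            raise ConfigurationError("n_fragments must be positive")
        if self.itr_multiplier < 0:
            raise ConfigurationError("itr_multiplier must be >= 0")
        if self.enrichment_profile is not None:
            for s, e, w in self.enrichment_profile:
                if not (0 <= s < e) or not np.isfinite(w) or w < 0:
                    raise ConfigurationError(
                        f"invalid profile segment ({s},{e},{w})")


def vector_base_weights(vector: VectorGenome, config: SimulationConfig,
                        uniform_profile: bool = False) -> np.ndarray:
    """Per-base midpoint sampling weight over the vector contig."""
    w = np.ones(vector.length, dtype=float)
    if not uniform_profile and config.enrichment_profile is not None:
        for s, e, mult in config.enrichment_profile:
            w[s:min(e, vector.length)] *= mult
    for _, s, e in itr_mask(vector).intervals:
        w[s:e] *= config.itr_multiplier
    return w


def _truncated_lognormal(rng: np.random.Generator, n: int,
                         mean: float, sd: float,
                         bounds: tuple[int, int]) -> np.ndarray:
    """Lognormal with arithmetic mean/sd, rejection-truncated to bounds."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    sigma = np.sqrt(sigma2)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(n - filled, 16))
        draw = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = np.round(draw[:take]).astype(np.int64)
        filled += take
    return out


def _simulate_library(config: SimulationConfig, build: GenomeBuild,
                      meta: LibraryMeta, uniform_profile: bool) -> FragmentSet:
    rng = np.random.default_rng(config.seed)
    vec = build.vector_contig
    weights = vector_base_weights(build.vector, config, uniform_profile)
    wsum = weights.sum()
    if config.vector_fraction > 0 and wsum <= 0:
        raise ConfigurationError(
            "vector sampling weights are all zero but vector_fraction > 0")

    n_total = config.n_fragments
    n_dup = int(rng.binomial(n_total, config.duplicate_rate))
    n_base = n_total - n_dup

    on_vector = rng.random(n_base) < config.vector_fraction
    lengths = _truncated_lognormal(rng, n_base, *config.fragment_length,
                                   bounds=config.fragment_length_bounds)
    contig = np.empty(n_base, dtype=object)
    start = np.empty(n_base, dtype=np.int64)

    k = int(on_vector.sum())
    if k:
        mid = rng.choice(vec.length, size=k, p=weights / wsum)
        lv = lengths[on_vector]
        sv = np.clip(mid - lv // 2, 0, np.maximum(vec.length - lv, 0))
        contig[on_vector] = vec.name
        start[on_vector] = sv

    hosts = build.host_contigs
    n_host = n_base - k
    if n_host:
        if not hosts:
            raise ConfigurationError(
                "no host contigs but vector_fraction < 1 sampled host fragments")
        hlen = np.array([c.length for c in hosts], dtype=float)
        hidx = rng.choice(len(hosts), size=n_host, p=hlen / hlen.sum())
        lh = lengths[~on_vector]
        hmax = np.array([hosts[i].length for i in hidx], dtype=np.int64)
        sh = (rng.random(n_host) * np.maximum(hmax - lh, 1)).astype(np.int64)
        names = np.array([c.name for c in hosts], dtype=object)
        contig[~on_vector] = names[hidx]
        start[~on_vector] = sh

    end = start + lengths
    strand = np.where(rng.random(n_base) < 0.5, "+", "-").astype("<U1")
    dup_origin = np.zeros(n_base, dtype=bool)

    if n_dup:
        src = rng.integers(0, n_base, size=n_dup)
        contig = np.concatenate([contig, contig[src]])
        start = np.concatenate([start, start[src]])
        end = np.concatenate([end, end[src]])
        strand = np.concatenate([strand, strand[src]]).astype("<U1")
        dup_origin = np.concatenate(
            [dup_origin, np.ones(n_dup, dtype=bool)])

    meta = replace(meta, total_fragments=n_total)
    return FragmentSet(meta=meta, contig=contig, start=start, end=end,
                       strand=strand, is_duplicate_origin=dup_origin)


def simulate_chromatin_library(config: SimulationConfig, build: GenomeBuild,
                               meta: LibraryMeta) -> FragmentSet:
    """Cut&Tag-like library: mark-dependent enrichment over the vector."""
    if meta.target == TN5_INPUT:
        raise ConfigurationError(
            "chromatin simulator requires a non-input target; "
            "use simulate_tn5_library for Tn5 inputs")
    return _simulate_library(config, build, meta, uniform_profile=False)


def simulate_tn5_library(config: SimulationConfig, build: GenomeBuild,
                         meta: LibraryMeta) -> FragmentSet:
    """Input library: abundance-only signal (profile forced uniform);
    the ITR multiplier still applies, as ITR overrepresentation is seen in
    every library type."""
    if meta.target != TN5_INPUT:
        raise ConfigurationError("Tn5 simulator requires target == Tn5_input")
    return _simulate_library(config, build, meta, uniform_profile=True)


# ---------------------------------------------------------------------------
# matched study-condition helpers

def gene_body_profile(vector: VectorGenome, multiplier: float
                      ) -> tuple[tuple[int, int, float], ...]:
    """Uniform enrichment over the non-ITR cassette."""
    gb_start, gb_end = vector.gene_body
    return ((gb_start, gb_end, float(multiplier)),)


def enrichment_weight_ratio(vector: VectorGenome,
                            config: SimulationConfig) -> float:
    """Total vector sampling weight relative to the unenriched library."""
    enriched = vector_base_weights(vector, config, uniform_profile=False)
    uniform = vector_base_weights(vector, config, uniform_profile=True)
    return float(enriched.sum() / uniform.sum())


def _scale_odds(p: float, factor: float) -> float:
    if p >= 1.0:
        return 1.0
    odds = p / (1.0 - p) * factor
    return odds / (1.0 + odds)


def chromatin_config(base: SimulationConfig, vector: VectorGenome,
                     gene_body_multiplier: float, seed: int | None = None
                     ) -> SimulationConfig:
    """Chromatin-library config matched to a Tn5-like base config.

    Sets the gene-body enrichment profile and scales the vector-assignment
    odds by the total-weight ratio, modelling that marked vector genomes
    yield proportionally more captured fragments.
    """
    cfg = replace(base,
                  enrichment_profile=gene_body_profile(vector,
                                                       gene_body_multiplier))
    ratio = enrichment_weight_ratio(vector, cfg)
    cfg = replace(cfg, vector_fraction=_scale_odds(base.vector_fraction, ratio))
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def scale_copy_number(config: SimulationConfig, factor: float
                      ) -> SimulationConfig:
    """Multiply the vector's abundance (assignment odds) by ``factor``,
    emulating a change in vector copy number per nucleus."""
    if factor <= 0:
        raise ConfigurationError("copy-number factor must be positive")
    return replace(config,
                   vector_fraction=_scale_odds(config.vector_fraction, factor))


# ---------------------------------------------------------------------------
# qPCR plate simulator

def simulate_qpcr_plate(true_copies: Sequence[float], efficiency: float,
                        ct_at_1e6: float, noise_sd: float,
                        n_technical: int = 2,
                        seed: int | None = None) -> pd.DataFrame:
    """Simulate Ct values for a plate of reactions with known input copies.

    Under per-cycle amplification efficiency ``e`` (product multiplies by
    ``1 + e`` each cycle), the threshold cycle for ``c`` input molecules is

        Ct = ct_at_1e6 - log(c / 1e6) / log(1 + e) + Normal(0, noise_sd)

    with ``n_technical`` technical replicate wells per reaction.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ConfigurationError("efficiency must be in (0, 1]")
    copies = np.asarray(true_copies, dtype=float)
    if np.any(copies <= 0):
        raise ConfigurationError("true_copies must be positive")
    if n_technical < 1:
        raise ConfigurationError("n_technical must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i, c in enumerate(copies):
        base_ct = ct_at_1e6 - np.log(c / 1e6) / np.log(1.0 + efficiency)
        for t in range(n_technical):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"reaction": i, "true_copies": c,
                         "tech_rep": t + 1, "ct": base_ct + noise})
    return pd.DataFrame(rows)
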