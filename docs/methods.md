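# Methods

## Coordinate and counting conventions

All intervals are 0-based half-open (BED/bedGraph convention); an
interval `[start, end)` has length `end − start`. The formulation of the
coverage statistic sometimes written with a `(end − start + 1)` length
term reflects 1-based inclusive display coordinates; under the half-open
convention the same quantity is `end − start`, which is what this
package computes. Coverage counts *fragments*, not reads: a paired-end
2×75 library determines each tagmented fragment's interval exactly, and
a fragment overlapping a base contributes 1 to that base regardless of
whether its two reads cover it.

## The coverage statistic

Per-base CPM at base `b`: `cov(b) = n(b) · 1e6 / N`, where `n(b)` is the
number of deduplicated fragments overlapping `b` and `N` is the
library's total deduplicated fragment count across **all** contigs
(genome-wide CPM, matching standard coverage tools). Deduplication
collapses fragments identical in (contig, start, end, strand), keeping
the first occurrence; PCR duplicates are the target, and coincidental
collisions are accepted as in standard duplicate marking.

The scalar vector statistic is the length-weighted mean of `cov` over
`[0, L_vector)` with the two ITR intervals masked out. Intervals
partially overlapping the mask are split exactly at mask boundaries;
bases with no coverage count as zeros. The denominator is switchable:

- `unmasked_length` (default): mean over the ITR-excluded bases —
  the per-base average of what is actually summed;
- `full_gAAV_size`: the masked sum divided by the full vector length.

The source formulation removes ITRs "from the calculation" without
stating which denominator remains, so both are implemented and must not
be mixed within one dataset (the normalization stage refuses mixed
modes). The choice rescales all samples of a dataset by the same
constant and therefore cancels from the Tn5-normalized ratios.

ITRs are masked because their tagmentation signal is overrepresented in
every library type (plausibly through recognition of residual
single-stranded/hairpin ITR structures), so they carry abundance
artifact rather than mark signal.

## Tn5 ratio normalization

CPM controls sequencing depth but not vector copy number: the vector's
share of a library scales with how many episomes each nucleus carries.
The second normalization divides each chromatin library's vector
statistic by the arithmetic **mean** statistic of the Tn5 input
libraries of the matching condition. The matching key is
(species/context, capsid, timepoint) — deliberately *not* the chromatin
target or the replicate: one input pool normalizes every mark profiled
in its condition. Zero or missing input coverage is a hard error; means
below 1e-6 trigger a warning because the ratio becomes unstable.

A consequence of the pooled denominator is that all replicates of a
group share one normalizer, so input-library counting noise moves the
whole group together and inflates between-group test statistics if the
inputs are shallow. The study design this package emulates counters
that by sequencing input libraries several-fold deeper than the
chromatin libraries; the scenario presets encode a 7.5× depth factor
(2M vs 15M fragments per sample at full scale).

## The synthetic-data generator

The generator emulates the *structure* of tagmentation libraries from
vector-transduced cells, with every distortion parameterized and known:

- **Reference**: one synthetic host contig (default 1 Mb) plus a 4 kb
  vector with 145 bp ITRs and a promoter/transgene/regulatory/polyA
  cassette. Species identity is metadata; host sequence content is
  irrelevant to fragment-interval simulation, so hg38/mm10-scale
  references are not needed.
- **Fragment placement**: each fragment lands on the vector with
  probability `vector_fraction`, otherwise uniformly on the host
  (contigs weighted by length). Vector fragment midpoints are drawn
  with per-base weight `enrichment_profile × itr_multiplier` (the
  multiplier, default 5, applies over ITR intervals in chromatin *and*
  input libraries; input libraries force the profile itself uniform).
- **Fragment lengths**: lognormal with arithmetic mean 180 bp, sd 50 bp,
  truncated to [50, 1000] bp — nucleosomal scale for a tagmentation
  library. Lengths are not specified by the emulated protocol; this is
  a package default.
- **Duplicates**: a Binomial(n, duplicate_rate) share of the output
  (default rate 0.1) consists of exact copies of already-drawn
  fragments appended after the first pass, so the ground truth of every
  duplicate is exact and the expected duplicate share equals the rate.
- **Depth**: default 2e6 fragments per library, scaled down in tests
  and presets (2e4–5e5) to keep many-replicate studies cheap; all
  statistics are depth-normalized, so scale enters only through
  counting noise.

**Enrichment and abundance are coupled.** An affinity assay captures
more vector material when the vector carries more of the targeted mark,
so a condition with gene-body enrichment `E` must also yield
proportionally more vector fragments — with a fixed `vector_fraction`,
an enrichment profile would only redistribute signal within the vector
and no ratio could recover `E`. `chromatin_config()` therefore scales
the vector-assignment odds by the total-weight ratio
`(E·L_body + m·L_ITR)/(L_body + m·L_ITR)`, the factor by which the
vector's bound material increases. `scale_copy_number()` applies the
same odds scaling for copy-number changes. Two systematic effects
remain and are visible in the recovered ratios:

- *competitive sampling*: the vector competes with the host for a fixed
  read total, so the recovered ratio is `E / (1 − p₀ + p₀·W)` rather
  than `E` (≈5% shortfall at `E = 8` with base fraction 0.01);
- *kernel smoothing*: a fragment whose midpoint sits in the enriched
  gene body deposits part of its mass inside the masked ITR, where it
  is excluded; with 180 bp fragments against 145 bp ITRs this removes
  a further few percent at high `E`.

Both shrink as the base vector fraction and the fragment-length /
ITR-length ratio shrink; at the default conditions the acceptance
measurements recover injected 2-/8-fold enrichments within the ±15%
band. Real Cut&Tag measurements share both effects.

What the generator does **not** emulate: sequence content and errors,
adapter/GC bias, chromatin accessibility structure on the host,
antibody efficiency differences between marks, biological
between-replicate variability (replicates differ only by counting
noise), and concatemeric/fragmented episome forms. Passing tests
therefore demonstrate the correctness of the quantification machinery
under known ground truth — not that the biology of any particular
dataset is reproduced.

### qPCR plate model

`Ct = ct_at_1e6 − log(copies/1e6)/log(1 + efficiency) + N(0, σ)`,
with technical replicate wells (default 2) drawn independently. This is
the exact inverse of the standard-curve estimator, so noiseless plates
round-trip to machine precision; with σ = 0.3 cycles the median fitted
efficiency over 100 plates recovers the truth within ±0.03.

## Assay quantifications

- ΔΔCt uses amplification base 2 (plain ΔΔCt; efficiency-corrected
  variants are out of scope). Technical wells are averaged on the Ct
  scale before any transformation — cycles are the measured quantity,
  and copy-scale averaging would weight wells unequally. Undetermined
  (non-finite) wells are excluded with a logged warning, never imputed.
- Standard curves: least-squares `Ct ~ log10(copies)` over ≥3 points
  spanning ≥2 log10; `efficiency = 10^(−1/slope) − 1`; absolute copies
  by inversion. Host copy number is interpreted as diploid-genome
  equivalents when genomic-DNA standards are used, giving
  copies-per-cell as a plain ratio.
- DNase-protection: protected fraction = copies(+DNase)/copies(−DNase);
  values above 1 are reported with a warning (measurement noise), not
  clamped.
- Luciferase: RLU / tissue mg, with technical replicates reported as
  mean ± SEM.

## Statistics layer

- **Boxplot summaries** use Tukey hinges (fourths) by default, matching
  the hinge-based legend convention; a linear-interpolation quartile is
  available via `quartile_method="linear"`. Whiskers reach the most
  extreme data point within 1.5 × IQR of its hinge; points beyond are
  outliers.
- **Welch's t** and **ANOVA** are computed from their closed forms
  (numpy + scipy distribution functions). The two-way ANOVA uses Type
  II sums of squares — replicate counts vary in practice, and Type II
  is the common default for unbalanced fixed-effects layouts. A
  constant response reports F = 0, p = 1; a perfect fit with real
  effects reports the affected term as F = ∞, p = 0 (term sums of
  squares are classified against a 1e-12 relative floor so lstsq
  round-off is not mistaken for signal).
- Stars follow the per-comparison scheme * <0.05, ** <0.01, *** <0.001;
  no multiple-testing correction is applied beyond reporting all
  p-values.
- Timepoint comparisons are ratios of group means (late/early),
  requiring positive means.

## Pipeline determinism

One global seed drives everything. Per-library streams are derived as
`SeedSequence([global_seed, crc32(sample_id)])`, so adding or removing
a library never perturbs another library's fragments. All TSV outputs
are written with shortest round-trip float formatting; identical config
+ seed reproduces them byte-for-byte, and the comparison stage re-run
on a stored `norm.tsv` reproduces `tests.tsv`.

## Scenario presets

`fig2_like` injects an 8-fold active-mark depletion specific to the
LK03-mouse condition on a capsid × species grid; `fig3_like` adds the
rescued single-insertion capsid (AM) restoring enrichment in mouse;
`fig4_like` opposes a 10-fold copy-number loss to an 8-fold per-copy
chromatinization gain between timepoints, so the normalized coverage
and the abundance proxy (input-library raw coverage) must move in
opposite directions. The null variant of `fig2_like` sets every
enrichment to 1. These encode qualitative sign/ordering patterns with
free-parameter magnitudes; the injected values are emulation choices,
not estimates of the underlying biology.

## Known limitations

- The exact ITR boundary coordinates used when masking real data are a
  configuration input; defaults (145 bp at each end of a 4 kb vector)
  are conventional AAV2-scale values, and fixtures never depend on a
  real vector sequence.
- The ITR-overrepresentation multiplier interacts with fragment-length
  smoothing: with nucleosome-scale fragments the *coverage* ratio over
  the 145 bp ITRs understates the sampling-weight multiplier by design
  of the measurement, which is why the ratio-recovery test uses short
  fragments to isolate the sampling property.
- Whether real pipelines counted reads or fragments per base, and
  which ANOVA sums-of-squares type was used, are not derivable from
  the emulated protocol; fragment counting and Type II are this
  package's documented choices.
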