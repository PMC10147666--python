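"""Molecular-assay quantification: ddCt, qPCR standard curves, copy
number, DNase-protection uncoating fraction, luciferase per tissue weight.

Technical qPCR replicates are averaged on the Ct scale (cycles are the
measured quantity; copy-scale averaging would weight wells unequally)
before any transformation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtMeasurement:
    """One sample x target measurement: technical Ct values and their mean."""

    sample_id: str
    target: str
    technical_cts: tuple[float, ...]

    def __post_init__(self):
        cts = [c for c in self.technical_cts if math.isfinite(c)]
        dropped = len(self.technical_cts) - len(cts)
        if dropped:
            logger.warning("%s/%s: %d non-finite (undetermined) Ct well(s) "
                           "excluded", self.sample_id, self.target, dropped)
            object.__setattr__(self, "technical_cts", tuple(cts))
        if not self.technical_cts:
            raise ValidationError(
                f"{self.sample_id}/{self.target}: no usable Ct wells")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.technical_cts))


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Ct ~ log10(copies) from a dilution series."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if self.slope >= 0:
            raise ValidationError(
                f"standard curve slope must be negative, got {self.slope}")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass(frozen=True)
class CopyNumberResult:
    sample_id: str
    gaav_copies: float
    host_genome_copies: float

    @property
    def copies_per_cell(self) -> float:
        if self.host_genome_copies <= 0:
            raise ValidationError("copies_per_cell undefined without host copies")
        return self.gaav_copies / self.host_genome_copies


def ddct_fold_change(target: CtMeasurement, reference: CtMeasurement,
                     target_cal: CtMeasurement, reference_cal: CtMeasurement
                     ) -> float:
    """Relative expression 2^-ddCt: the target gene is normalized to a
    housekeeping reference within each sample, then to the calibrator."""
    for ct in (target, reference, target_cal, reference_cal):
        if ct is None:
            raise ValidationError("missing Ct measurement for ddCt")
    dct_sample = target.mean_ct - reference.mean_ct
    dct_cal = target_cal.mean_ct - reference_cal.mean_ct
    return 2.0 ** (-(dct_sample - dct_cal))


def fit_standard_curve(dilution_series: Sequence[tuple[float, CtMeasurement]]
                       ) -> StandardCurve:
    """Fit Ct ~ log10(copies) to >=3 dilution points spanning >=2 log10."""
    if len(dilution_series) < 3:
        raise ValidationError("standard curve needs >= 3 dilution points")
    copies = np.array([c for c, _ in dilution_series], dtype=float)
    if np.any(copies <= 0):
        raise ValidationError("standard copies must be positive")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 2.0:
        raise ValidationError("dilution series must span >= 2 log10")
    cts = np.array([m.mean_ct for _, m in dilution_series])
    res = sps.linregress(logc, cts)
    return StandardCurve(slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2))


def absolute_copies(ct: CtMeasurement, curve: StandardCurve) -> float:
    """Interpolate molecule count from the standard curve."""
    return curve.copies(ct.mean_ct)


def encapsidated_fraction(copies_plus_dnase: float, copies_minus_dnase: float
                          ) -> dict[str, float]:
    """DNase-protection assay: the share of nuclear vector genomes still
    inside capsids (protected), and its complement (uncoated)."""
    if copies_minus_dnase <= 0:
        raise ValidationError("untreated copy count must be positive")
    ratio = copies_plus_dnase / copies_minus_dnase
    if ratio > 1.0:
        logger.warning("protected fraction %.3f > 1 (measurement noise); "
                       "reporting as-is", ratio)
    return {"protected": ratio, "uncoated": 1.0 - ratio}


def luciferase_per_weight(rlu: float | Sequence[float], tissue_mg: float
                          ) -> dict[str, float]:
    """Tissue-weight-normalized luciferase activity (RLU/mg).

    Accepts a single reading or technical replicates; replicates are
    reported as mean with SEM.
    """
    if tissue_mg <= 0:
        raise ValidationError("tissue weight must be positive")
    values = np.atleast_1d(np.asarray(rlu, dtype=float)) / tissue_mg
    out = {"rlu_per_mg": float(values.mean()), "n": int(values.size)}
    if values.size > 1:
        out["sem"] = float(values.std(ddof=1) / np.sqrt(values.size))
    return out
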