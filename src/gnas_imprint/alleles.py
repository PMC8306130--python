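"""Allele-specific GNAS expression at rs7121 and imprinting-relaxation calls.

GNAS is expressed from the maternal allele only in the normal pituitary. A
transcribed synonymous SNP in exon 5 (rs7121, c.393C>T, p.(Ile131Ile), the
Fok1 restriction polymorphism) lets pyrosequencing apportion expression
between the two alleles — but only in samples whose genomic DNA is
heterozygous, which is the informativeness gate applied first.

Allelic quantification (AQ) is reported on the minor-allele convention:
100 × min(C, T) / (C + T), so AQ ∈ [0, 50] and 50 means perfectly biallelic.
Imprinting is called *relaxed* when the minor allele contributes strictly
more than a threshold share of total expression (default 20%, optionally
re-derived from normal-pituitary references but never lowered below the
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AllelicSignals",
    "RelaxationCall",
    "compute_aq",
    "call_heterozygous",
    "call_relaxation",
    "derive_relaxation_threshold",
    "DEFAULT_RELAXATION_THRESHOLD",
    "DEFAULT_HET_TOLERANCE",
]

logger = logging.getLogger(__name__)

DEFAULT_RELAXATION_THRESHOLD = 20.0  # percent of total expression
DEFAULT_HET_TOLERANCE = 15.0  # percentage points of gDNA allele skew


@dataclass(frozen=True)
class AllelicSignals:
    """Paired pyrosequencing peak intensities at rs7121 for one material."""

    sample_id: str
    material: Literal["gDNA", "cDNA"]
    signal_c: float
    signal_t: float

    def __post_init__(self) -> None:
        if self.material not in ("gDNA", "cDNA"):
            raise ValueError(f"material must be gDNA or cDNA, got {self.material!r}")
        if self.signal_c < 0 or self.signal_t < 0:
            raise ValueError("allele signals must be nonnegative")


@dataclass(frozen=True)
class RelaxationCall:
    sample_id: str
    informative: bool
    aq_minor: float | None
    status: Literal["relaxed", "unrelaxed", "not_informative"]

    def __post_init__(self) -> None:
        if (self.status == "not_informative") != (not self.informative):
            raise ValueError("status/informative mismatch")
        if self.aq_minor is not None and not (0.0 <= self.aq_minor <= 50.0):
            raise ValueError("minor-allele AQ must lie in [0, 50]")


def compute_aq(signals: AllelicSignals) -> float:
    """Minor-allele share of the total signal, in percent (range [0, 50]).

    Symmetric in the allele labels and invariant to rescaling both signals.
    """
    total = signals.signal_c + signals.signal_t
    if total <= 0:
        raise ValueError(
            f"sample {signals.sample_id}: both allele signals are zero"
        )
    return 100.0 * min(signals.signal_c, signals.signal_t) / total


def call_heterozygous(
    gdna: AllelicSignals, tolerance: float = DEFAULT_HET_TOLERANCE
) -> bool:
    """Heterozygosity gate on genomic DNA.

    A heterozygote's gDNA alleles amplify near 50/50; PCR skew is tolerated
    up to ``tolerance`` percentage points, i.e. the call is heterozygous when
    the gDNA minor-allele AQ is at least 50 − tolerance.
    """
    if gdna.material != "gDNA":
        raise ValueError("heterozygosity is called on gDNA signals")
    if not (0.0 <= tolerance < 50.0):
        raise ValueError("tolerance must lie in [0, 50)")
    return compute_aq(gdna) >= 50.0 - tolerance


def call_relaxation(
    cdna: AllelicSignals,
    heterozygous: bool,
    threshold: float = DEFAULT_RELAXATION_THRESHOLD,
) -> RelaxationCall:
    """Call imprinting relaxation from cDNA allelic signals.

    Non-heterozygous samples are uninformative (the assay cannot see the
    second allele). Otherwise the call is *relaxed* iff the minor allele
    exceeds ``threshold`` percent of total expression — strictly, so an AQ
    exactly at the threshold stays *unrelaxed*.
    """
    if cdna.material != "cDNA":
        raise ValueError("relaxation is called on cDNA signals")
    if not (0.0 < threshold <= 50.0):
        raise ValueError(f"threshold must lie in (0, 50], got {threshold}")
    if not heterozygous:
        return RelaxationCall(cdna.sample_id, False, None, "not_informative")
    aq = compute_aq(cdna)
    status = "relaxed" if aq > threshold else "unrelaxed"
    return RelaxationCall(cdna.sample_id, True, aq, status)


def derive_relaxation_threshold(
    normal_aqs: Sequence[float],
    k_sd: float = 2.0,
    floor: float = DEFAULT_RELAXATION_THRESHOLD,
) -> float:
    """Derive the relaxation cut-off from normal-pituitary cDNA AQ values.

    The normal pituitary expresses GNAS monoallelically, so its minor-allele
    AQ reflects assay background only; mean + ``k_sd``·SD of those values is a
    data-driven upper bound on monoallelic background. The operational
    threshold never drops below ``floor`` (default 20): when the derived
    value is lower, the floor is used and the substitution logged; a derived
    value above the floor is used as-is and logged.
    """
    values = np.asarray(normal_aqs, dtype=float)
    if values.size < 2:
        raise ValueError(
            f"need at least 2 normal-pituitary AQ values, got {values.size}"
        )
    if np.any((values < 0) | (values > 50)):
        raise ValueError("AQ values must lie in [0, 50]")
    derived = float(values.mean() + k_sd * values.std(ddof=1))
    if derived > floor:
        logger.info(
            "derived relaxation threshold %.2f%% exceeds the %.0f%% default; "
            "using the derived value",
            derived,
            floor,
        )
        return derived
    logger.info(
        "derived relaxation threshold %.2f%% is below the %.0f%% default; "
        "keeping the default",
        derived,
        floor,
    )
    return floor
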