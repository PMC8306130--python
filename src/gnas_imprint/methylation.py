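"""A/B DMR methylation: per-CpG measurements, region-level summary, status.

The A/B differentially methylated region sits immediately upstream of the
GNAS promoter (chr20, GRCh37: 57,463,600–57,463,700) and is methylated on the
maternal allele in tissues where GNAS is imprinted, the pituitary among them.
Two assay modes quantify it:

* ``pyroseq6`` — bisulfite pyrosequencing of 6 CpG doublets in the window,
  reported in percent; the region methylation level (ML) is the arithmetic
  mean of the 6 CpGs.
* ``array3`` — three Infinium EPIC probes (cg26767990, cg17652507,
  cg22407822) covering a subset of the same CpGs, reported as beta fractions
  in [0, 1]; their mean is the methylation index (MI).

The two scales never mix silently: every value carries a unit tag
(``percent`` vs ``fraction``) and conversion is an explicit ×100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .stats import NormalRange

__all__ = [
    "REGION_START",
    "REGION_END",
    "ARRAY_PROBES",
    "CpGMeasurement",
    "MethylationProfile",
    "MethylationCall",
    "compute_ml",
    "classify_methylation",
    "profiles_from_table",
    "calls_to_table",
    "region_bed",
]

# GRCh37 chr20 coordinates of the assayed A/B DMR window (1-based inclusive)
REGION_START = 57463600
REGION_END = 57463700

#: EPIC array probes covering three of the six pyrosequenced CpG doublets
ARRAY_PROBES = ("cg26767990", "cg17652507", "cg22407822")

Platform = Literal["pyroseq6", "array3"]

_PLATFORM_COUNT = {"pyroseq6": 6, "array3": 3}
_PLATFORM_UNIT = {"pyroseq6": "percent", "array3": "fraction"}
_UNIT_MAX = {"percent": 100.0, "fraction": 1.0}


@dataclass(frozen=True)
class CpGMeasurement:
    """One CpG's methylation value at a genomic position in the A/B window."""

    position: int
    value: float
    probe_id: str | None = None

    def validate(self, unit: str) -> None:
        if not (REGION_START <= self.position <= REGION_END):
            raise ValueError(
                f"position {self.position} outside A/B DMR window "
                f"[{REGION_START}, {REGION_END}] (GRCh37 chr20)"
            )
        hi = _UNIT_MAX[unit]
        if not (0.0 <= self.value <= hi):
            raise ValueError(
                f"methylation value {self.value} outside [0, {hi}] ({unit})"
            )


@dataclass(frozen=True)
class MethylationProfile:
    """All CpG measurements of one sample on one platform."""

    sample_id: str
    platform: Platform
    measurements: tuple[CpGMeasurement, ...]

    def __post_init__(self) -> None:
        if self.platform not in _PLATFORM_COUNT:
            raise ValueError(f"unknown platform {self.platform!r}")
        expected = _PLATFORM_COUNT[self.platform]
        if len(self.measurements) != expected:
            raise ValueError(
                f"{self.platform} profile needs exactly {expected} "
                f"measurements, got {len(self.measurements)}"
            )
        unit = self.unit
        positions = [m.position for m in self.measurements]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicated CpG positions in profile")
        for m in self.measurements:
            m.validate(unit)
            if self.platform == "array3":
                if m.probe_id not in ARRAY_PROBES:
                    raise ValueError(
                        f"array measurement needs a probe_id from "
                        f"{ARRAY_PROBES}, got {m.probe_id!r}"
                    )
        if self.platform == "array3":
            probes = [m.probe_id for m in self.measurements]
            if len(set(probes)) != len(probes):
                raise ValueError("duplicated array probes in profile")

    @property
    def unit(self) -> str:
        return _PLATFORM_UNIT[self.platform]


@dataclass(frozen=True)
class MethylationCall:
    sample_id: str
    ml: float
    unit: str
    status: Literal["hypo", "normo", "hyper"]


def compute_ml(profile: MethylationProfile) -> float:
    """Region methylation level/index: mean of the per-CpG values.

    Returned on the profile's native scale (percent for pyrosequencing,
    beta fraction for the array). Permutation-invariant by construction.
    """
    return float(np.mean([m.value for m in profile.measurements]))


def classify_methylation(
    ml: float, normal_range: NormalRange, unit: str = "percent"
) -> Literal["hypo", "normo", "hyper"]:
    """Classify a methylation level against a reference normal range.

    Bounds are inclusive toward ``normo`` (ties break to the null class).
    The unit tag of the range must match the value's unit.
    """
    if normal_range.unit and normal_range.unit != unit:
        raise ValueError(
            f"unit mismatch: value is {unit!r}, range is {normal_range.unit!r}"
        )
    if not np.isfinite(ml):
        raise ValueError("methylation level must be finite")
    if ml < normal_range.lower:
        return "hypo"
    if ml > normal_range.upper:
        return "hyper"
    return "normo"


def profiles_from_table(table: pd.DataFrame) -> list[MethylationProfile]:
    """Build per-sample profiles from a long methylation table.

    Expected columns: ``sample_id``, ``platform``, ``position``, ``probe_id``
    (may be empty for pyrosequencing rows) and ``value``.
    """
    required = {"sample_id", "platform", "position", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"methylation table missing columns: {sorted(missing)}")
    profiles = []
    for (sample_id, platform), grp in table.groupby(
        ["sample_id", "platform"], sort=True
    ):
        meas = tuple(
            CpGMeasurement(
                position=int(row.position),
                value=float(row.value),
                probe_id=(
                    None
                    if "probe_id" not in table.columns or pd.isna(row.probe_id)
                    else str(row.probe_id)
                ),
            )
            for row in grp.itertuples()
        )
        profiles.append(
            MethylationProfile(str(sample_id), str(platform), meas)
        )
    return profiles


def calls_to_table(calls: Iterable[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "ml": c.ml,
                "unit": c.unit,
                "status": c.status,
            }
            for c in calls
        ]
    )


def region_bed(positions: Sequence[int]) -> pd.DataFrame:
    """Export CpG positions as BED rows (0-based half-open) on chr20."""
    for p in positions:
        if not (REGION_START <= p <= REGION_END):
            raise ValueError(f"position {p} outside the A/B DMR window")
    return pd.DataFrame(
        {
            "chrom": "chr20",
            "start": [p - 1 for p in positions],
            "end": list(positions),
            "name": [f"AB_DMR_CpG_{p}" for p in positions],
        }
    )
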