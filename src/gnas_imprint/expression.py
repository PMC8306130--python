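"""qPCR absolute quantification against plasmid standard curves.

Each transcript assay (GNAS, SSTR2, AIP and the BGUS housekeeping gene) has
its own plasmid dilution series. Ordinary least squares of Cq on log10(input
copies) gives a per-assay standard curve; sample Cq values are inverted
through it to absolute copy numbers. Per-sample copy numbers are normalized
to BGUS and reported on the conventional "× 1000 copies per copy BGUS"
scale: value_k = (copies_gene / copies_BGUS) / 1000, so a printed 536 means
536,000 transcript copies per BGUS copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENES",
    "HOUSEKEEPING_GENE",
    "StandardCurve",
    "ExpressionResult",
    "fit_standard_curve",
    "quantify",
    "normalize",
    "classify_overexpression",
    "quantify_samples",
]

logger = logging.getLogger(__name__)

GENES = ("GNAS", "SSTR2", "AIP", "BGUS")
HOUSEKEEPING_GENE = "BGUS"


@dataclass(frozen=True)
class StandardCurve:
    """Fitted plasmid standard curve cq = slope·log10(copies) + intercept."""

    gene: str
    points: tuple[tuple[float, float], ...]  # (log10_copies, cq)
    slope: float
    intercept: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 1.0 = perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class ExpressionResult:
    """Absolute and BGUS-normalized expression of one gene in one sample.

    ``value_k`` is on the ×1000-copies-per-copy-BGUS reporting scale and is
    None (flagged missing) when the sample has no usable BGUS quantification.
    """

    sample_id: str
    gene: str
    copies: float
    value_k: float | None


def fit_standard_curve(
    gene: str, points: Sequence[tuple[float, float]]
) -> StandardCurve:
    """Fit a standard curve by OLS of Cq on log10 input copies.

    Requires at least 3 points spanning at least 2 decades of input and a
    negative slope (Cq decreases with more template).
    """
    pts = [(float(lc), float(cq)) for lc, cq in points]
    if len(pts) < 3:
        raise ValueError(f"{gene}: standard curve needs >= 3 points, got {len(pts)}")
    log_copies = np.array([p[0] for p in pts])
    cqs = np.array([p[1] for p in pts])
    if np.ptp(log_copies) < 2.0:
        raise ValueError(
            f"{gene}: standard curve must span >= 2 decades of input copies"
        )
    slope, intercept = np.polyfit(log_copies, cqs, 1)
    if slope >= 0:
        raise ValueError(f"{gene}: standard-curve slope must be negative")
    return StandardCurve(gene, tuple(pts), float(slope), float(intercept))


def quantify(cq: float, curve: StandardCurve) -> float:
    """Invert a Cq through the standard curve: copies = 10^((cq−b)/m)."""
    if not np.isfinite(cq):
        raise ValueError("Cq must be finite")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def normalize(gene_copies: float, bgus_copies: float) -> float:
    """BGUS-normalized expression on the ×1000 reporting scale."""
    if bgus_copies <= 0:
        raise ValueError("BGUS copies must be positive for normalization")
    if gene_copies < 0:
        raise ValueError("gene copies must be nonnegative")
    return (gene_copies / bgus_copies) / 1000.0


def classify_overexpression(value_k: float, threshold: float) -> bool:
    """True iff expression strictly exceeds the overexpression threshold."""
    return value_k > threshold


def quantify_samples(
    qpcr: pd.DataFrame, curves: dict[str, StandardCurve]
) -> pd.DataFrame:
    """Quantify and normalize a long qPCR table.

    ``qpcr`` columns: sample_id, gene, cq. Returns one row per sample × gene
    with absolute ``copies`` and BGUS-normalized ``value_k`` (NaN for BGUS
    rows themselves and for samples lacking BGUS, which are logged and must
    be excluded listwise from expression comparisons).
    """
    required = {"sample_id", "gene", "cq"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    unknown = set(qpcr["gene"].unique()) - set(GENES)
    if unknown:
        raise ValueError(f"unknown gene(s) in qPCR table: {sorted(unknown)}")

    rows = []
    copies_map: dict[tuple[str, str], float] = {}
    for row in qpcr.itertuples():
        curve = curves.get(row.gene)
        if curve is None:
            raise ValueError(f"no standard curve for gene {row.gene!r}")
        copies_map[(row.sample_id, row.gene)] = quantify(float(row.cq), curve)

    sample_ids = qpcr["sample_id"].unique()
    for sid in sample_ids:
        bgus = copies_map.get((sid, HOUSEKEEPING_GENE))
        if bgus is None or bgus <= 0:
            logger.warning(
                "sample %s lacks BGUS quantification; normalized expression "
                "flagged missing",
                sid,
            )
        for gene in GENES:
            copies = copies_map.get((sid, gene))
            if copies is None:
                continue
            if gene == HOUSEKEEPING_GENE or bgus is None or bgus <= 0:
                value_k = np.nan
            else:
                value_k = normalize(copies, bgus)
            rows.append(
                {
                    "sample_id": sid,
                    "gene": gene,
                    "copies": copies,
                    "value_k": value_k,
                }
            )
    return pd.DataFrame(rows)
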