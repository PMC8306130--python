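"""gsp-oncogene calling from a GNAS coding sequence.

Constitutively activating GNAS mutations in somatotroph tumors — the *gsp*
oncogene — cluster at two hotspot residues of Gsα: arginine 201 and
glutamine 227 (exons 8 and 9). The caller takes an in-frame coding sequence
aligned to a reference CDS (codon 1 = first codon), translates both hotspot
codons, and reports:

* ``positive`` — a non-synonymous change at codon 201 (reference Arg) or
  codon 227 (reference Gln),
* ``negative`` — both hotspots encode the reference residue (synonymous
  changes included),
* ``undetermined`` — an ambiguous base (N) or a stop codon at a hotspot.

Variants elsewhere in the CDS never affect the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from Bio.Seq import Seq

__all__ = [
    "HOTSPOT_CODONS",
    "GspCall",
    "call_gsp",
    "call_gsp_many",
]

#: hotspot codon index (1-based) -> expected reference residue
HOTSPOT_CODONS: dict[int, str] = {201: "R", 227: "Q"}

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GspCall:
    sample_id: str
    status: Literal["positive", "negative", "undetermined"]
    codon: int | None = None
    reference_residue: str | None = None
    observed_residue: str | None = None


def _codon(seq: str, index_1based: int) -> str:
    start = (index_1based - 1) * 3
    return seq[start : start + 3]


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, or None if ambiguous (contains N)."""
    if "N" in codon:
        return None
    return str(Seq(codon).translate())


def call_gsp(
    sample_id: str,
    cds: str,
    reference_cds: str,
    hotspots: dict[int, str] | None = None,
) -> GspCall:
    """Call gsp status by inspecting the hotspot codons of an aligned CDS.

    ``hotspots`` maps 1-based codon indices to the expected reference
    residues; the default is the canonical {201: R, 227: Q}. The input must
    be the coding strand, same length as the reference and long enough to
    contain every hotspot codon.
    """
    hotspots = HOTSPOT_CODONS if hotspots is None else hotspots
    cds = cds.upper()
    reference_cds = reference_cds.upper()
    if len(cds) != len(reference_cds):
        raise ValueError(
            f"{sample_id}: CDS length {len(cds)} differs from reference "
            f"{len(reference_cds)}"
        )
    max_codon = max(hotspots)
    if len(cds) < 3 * max_codon:
        raise ValueError(
            f"{sample_id}: CDS too short ({len(cds)} nt) to contain codon "
            f"{max_codon}"
        )
    bad = set(cds) - _ALPHABET
    if bad:
        raise ValueError(f"{sample_id}: invalid bases in CDS: {sorted(bad)}")

    for codon_idx in sorted(hotspots):
        expected = hotspots[codon_idx]
        ref_codon = _codon(reference_cds, codon_idx)
        ref_aa = _translate(ref_codon)
        if ref_aa != expected:
            raise ValueError(
                f"reference codon {codon_idx} translates to {ref_aa}, "
                f"expected {expected}"
            )
        obs_aa = _translate(_codon(cds, codon_idx))
        if obs_aa is None or obs_aa == "*":
            return GspCall(sample_id, "undetermined", codon_idx, expected, obs_aa)
        if obs_aa != expected:
            return GspCall(sample_id, "positive", codon_idx, expected, obs_aa)
    return GspCall(sample_id, "negative")


def call_gsp_many(
    records: Iterable[tuple[str, str]], reference_cds: str
) -> list[GspCall]:
    """Call gsp for (sample_id, cds) pairs against one reference."""
    return [call_gsp(sid, cds, reference_cds) for sid, cds in records]
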