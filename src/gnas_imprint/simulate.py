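"""Synthetic somatotroph-tumor cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage — methylation calling, allelic quantification,
absolute qPCR quantification, gsp calling, group assignment — can be
exercised end-to-end against known labels without any external data:

* a gsp-positive subgroup (default 25% of tumors) whose A/B DMR methylation
  is Gaussian near 40% and whose GNAS expression is comparatively low;
* gsp-negative tumors with variable methylation (a normo/hyper/hypo
  mixture) and a relaxed-imprinting fraction (default 44%) whose GNAS,
  SSTR2 and AIP expression is reduced relative to unrelaxed tumors;
* rs7121 heterozygosity drawn at 2·maf·(1−maf) with maf = 0.35, gating which
  samples are informative for allelic quantification;
* normal pituitaries: strictly monoallelic GNAS expression and Gaussian
  methylation near 40%.

Parental origin of the expressed allele is simulated internally (GNAS is
maternally expressed in the pituitary) but never exported: the emitted
observables carry exactly the information the assays can see.

Determinism: one global seed drives an independent substream per sample
(seeded by (seed, sample index)), so identical seed + config gives
bit-identical tables and resizing a cohort leaves shared samples unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import GENES, HOUSEKEEPING_GENE
from .methylation import ARRAY_PROBES

__all__ = [
    "CPG_POSITIONS",
    "PROBE_AT_POSITION",
    "MethylationModel",
    "ExpressionModel",
    "AQModel",
    "SimulationConfig",
    "CohortTables",
    "simulate_cohort",
    "simulate_normal_pituitaries",
    "synthetic_reference_cds",
]

# Fixed CpG positions used by the simulator inside the assayed window
# (the assay datasheet does not print per-CpG coordinates; these are a
# synthetic but fixed choice within chr20:57,463,600-57,463,700).
CPG_POSITIONS = (57463609, 57463621, 57463633, 57463650, 57463672, 57463688)

#: three of the six CpGs are also covered by EPIC array probes
PROBE_AT_POSITION = {
    57463621: ARRAY_PROBES[0],
    57463650: ARRAY_PROBES[1],
    57463672: ARRAY_PROBES[2],
}

_REFERENCE_N_CODONS = 240
_STOPS = {"TAA", "TAG", "TGA"}

# gsp hotspot substitutions the simulator draws from (codon 201 CGT=Arg,
# codon 227 CAG=Gln in the synthetic reference)
_GSP_MUTATIONS = (
    (201, "TGT"),  # R201C
    (201, "CAT"),  # R201H
    (227, "CGG"),  # Q227R
    (227, "CTG"),  # Q227L
)


def synthetic_reference_cds(n_codons: int = _REFERENCE_N_CODONS) -> str:
    """Deterministic synthetic stand-in for the GNAS coding sequence.

    Not the real transcript: a fixed in-frame sequence of ``n_codons`` codons
    with no internal stops, an ATG start, and the two gsp hotspots pinned to
    their canonical residues (codon 201 = CGT/Arg, codon 227 = CAG/Gln). The
    gsp caller only inspects those two codons, so a synthetic backbone is
    sufficient and keeps the package self-contained.
    """
    if n_codons < 227:
        raise ValueError("reference must contain at least 227 codons")
    bases = "ACGT"
    codons: list[str] = ["ATG"]
    i = 0
    while len(codons) < n_codons:
        c = bases[i % 4] + bases[(i // 4) % 4] + bases[(i // 16) % 4]
        i += 1
        if c in _STOPS:
            continue
        codons.append(c)
    codons[200] = "CGT"  # Arg201
    codons[226] = "CAG"  # Gln227
    return "".join(codons)


@dataclass(frozen=True)
class MethylationModel:
    """Per-group sample-level A/B ML distributions (percent) and CpG noise.

    gsp-negative tumors are a normo/hyper/hypo mixture; the hyper and hypo
    weights default to the observed fractions (20% and 3%) and the remainder
    is normo-methylated.
    """

    normal_mean: float = 40.0
    normal_sd: float = 2.5
    gsp_pos_mean: float = 40.0
    gsp_pos_sd: float = 2.5
    gspneg_normo_mean: float = 40.0
    gspneg_normo_sd: float = 2.5
    gspneg_hyper_mean: float = 60.0
    gspneg_hyper_sd: float = 6.0
    gspneg_hypo_mean: float = 27.0
    gspneg_hypo_sd: float = 2.0
    p_hyper: float = 0.20
    p_hypo: float = 0.03
    cpg_noise_sd: float = 3.0

    def validate(self) -> None:
        for name in (
            "normal_sd", "gsp_pos_sd", "gspneg_normo_sd", "gspneg_hyper_sd",
            "gspneg_hypo_sd", "cpg_noise_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.p_hyper <= 1 and 0 <= self.p_hypo <= 1):
            raise ValueError("mixture weights must lie in [0, 1]")
        if self.p_hyper + self.p_hypo > 1:
            raise ValueError("hyper + hypo weights exceed 1")


@dataclass(frozen=True)
class ExpressionModel:
    """Per-gene, per-group normalized-expression targets (value_k scale).

    Most strata are log-normal, parameterized by their median and a log-scale
    sigma (the source data report group medians, not dispersions, so sigma is
    a documented free knob). The gsp-positive GNAS stratum is a Gaussian
    truncated at zero — its real-world counterpart is compatible with a
    normal distribution, and the overexpression threshold construction
    (mean + 1·SD, normality-gated) relies on that — with defaults chosen so
    the population median is 293 and mean + SD is 517.
    """

    gnas_gsp_pos_mean: float = 293.0
    gnas_gsp_pos_sd: float = 224.0
    lognormal_sigma: float = 0.5
    medians: dict = field(
        default_factory=lambda: {
            # gene -> {group -> median value_k}
            "GNAS": {"gspneg_unrelaxed": 755.0, "gspneg_relaxed": 405.0,
                     "normal": 500.0},
            "SSTR2": {"gsp_positive": 106.0, "gspneg_unrelaxed": 634.0,
                      "gspneg_relaxed": 203.0, "normal": 300.0},
            "AIP": {"gsp_positive": 102.7, "gspneg_unrelaxed": 207.5,
                    "gspneg_relaxed": 105.1, "normal": 150.0},
        }
    )
    bgus_median_copies: float = 50.0
    bgus_sigma: float = 0.5
    # technical-replicate Cq scatter only: the per-stratum value_k
    # distributions above already describe *observed* normalized expression
    # (between-tumor spread including assay error), so the Cq encoding must
    # not add biological-scale noise on top
    cq_noise_sd: float = 0.05

    def validate(self) -> None:
        if self.gnas_gsp_pos_sd <= 0 or self.lognormal_sigma <= 0:
            raise ValueError("expression scales must be positive")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be nonnegative")

    def draw_value_k(
        self, gene: str, group: str, rng: np.random.Generator
    ) -> float:
        if gene == "GNAS" and group == "gsp_positive":
            # truncated-at-zero Gaussian, by rejection
            while True:
                v = rng.normal(self.gnas_gsp_pos_mean, self.gnas_gsp_pos_sd)
                if v > 0:
                    return float(v)
        median = self.medians[gene][group]
        return float(
            np.exp(rng.normal(np.log(median), self.lognormal_sigma))
        )


@dataclass(frozen=True)
class AQModel:
    """Minor-allele fraction distributions for cDNA allelic quantification.

    Fractions are Beta-shaped on disjoint supports: unrelaxed (and normal)
    samples are concentrated below 10% (assay background on a monoallelic
    transcript), relaxed samples between 20% and 50%.
    """

    unrelaxed_max: float = 0.10
    relaxed_low: float = 0.20
    relaxed_high: float = 0.50
    beta_a: float = 2.0
    beta_b: float = 2.0
    gdna_het_sd: float = 0.02
    signal_total: float = 1000.0
    signal_noise_sd: float = 2.0

    def validate(self) -> None:
        if not (0 < self.unrelaxed_max <= self.relaxed_low < self.relaxed_high <= 0.5):
            raise ValueError("AQ supports must satisfy 0 < unrelaxed_max <= "
                             "relaxed_low < relaxed_high <= 0.5")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("beta parameters must be positive")

    def draw_minor_fraction(self, relaxed: bool, rng: np.random.Generator) -> float:
        b = rng.beta(self.beta_a, self.beta_b)
        if relaxed:
            return self.relaxed_low + (self.relaxed_high - self.relaxed_low) * b
        return self.unrelaxed_max * b


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated cohort."""

    n_tumors: int = 82
    n_normals: int = 6
    p_gsp: float = 0.25
    maf_rs7121: float = 0.35
    p_relaxed_given_gspneg: float = 0.44
    p_ssa_pretreated: float = 0.18
    methylation: MethylationModel = field(default_factory=MethylationModel)
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    aq: AQModel = field(default_factory=AQModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 0 or self.n_normals < 0:
            raise ValueError("cohort sizes must be nonnegative")
        for name in ("p_gsp", "maf_rs7121", "p_relaxed_given_gspneg",
                     "p_ssa_pretreated"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        self.methylation.validate()
        self.expression.validate()
        self.aq.validate()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class CohortTables:
    """All assay tables of one simulated cohort plus its ground truth."""

    samples: pd.DataFrame
    methylation: pd.DataFrame
    allelic: pd.DataFrame
    qpcr: pd.DataFrame
    standard_curves: pd.DataFrame
    sequences: list[tuple[str, str]]  # (sample_id, cds)
    ground_truth: pd.DataFrame
    reference_cds: str
    config: SimulationConfig | None = None

    def write(self, outdir: str | Path) -> None:
        """Write all tables as TSV, sequences as FASTA, config as JSON."""
        from .io import write_fasta, write_tsv

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"version": __version__}
        if self.config is not None:
            meta["seed"] = str(self.config.seed)
        write_tsv(self.samples, out / "samples.tsv", meta)
        write_tsv(self.methylation, out / "methylation.tsv", meta)
        write_tsv(self.allelic, out / "allelic.tsv", meta)
        write_tsv(self.qpcr, out / "qpcr.tsv", meta)
        write_tsv(self.standard_curves, out / "standard_curves.tsv", meta)
        write_tsv(self.ground_truth, out / "ground_truth.tsv", meta)
        write_fasta(self.sequences, out / "sequences.fasta")
        write_fasta([("reference", self.reference_cds)],
                    out / "reference_cds.fasta")
        if self.config is not None:
            (out / "config.json").write_text(self.config.to_json())


# ---------------------------------------------------------------------------
# per-sample generation
# ---------------------------------------------------------------------------

_CURVE_SLOPE = -3.3219280948873623  # perfect doubling: -1 / log10(2)
_CURVE_INTERCEPTS = {"GNAS": 38.0, "SSTR2": 39.0, "AIP": 39.5, "BGUS": 37.0}
_CURVE_LOG10_RANGE = (1, 8)  # dilution series 10^1 .. 10^7 copies
_CURVE_POINT_NOISE_SD = 0.05


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _standard_curves(seed: int) -> pd.DataFrame:
    rng = _sample_rng(seed, 2_000_000)
    rows = []
    for gene in GENES:
        for lc in range(*_CURVE_LOG10_RANGE):
            cq = (
                _CURVE_SLOPE * lc
                + _CURVE_INTERCEPTS[gene]
                + rng.normal(0.0, _CURVE_POINT_NOISE_SD)
            )
            rows.append({"gene": gene, "log10_copies": float(lc), "cq": cq})
    return pd.DataFrame(rows)


def _truncate(value: float, lo: float, hi: float) -> float:
    return float(min(max(value, lo), hi))


def _draw_methylation(
    group: str, model: MethylationModel, rng: np.random.Generator
) -> tuple[float, str]:
    """Sample-level ML (percent) and its true class label."""
    if group == "normal":
        return _truncate(rng.normal(model.normal_mean, model.normal_sd), 0, 100), "normo"
    if group == "gsp_positive":
        return _truncate(rng.normal(model.gsp_pos_mean, model.gsp_pos_sd), 0, 100), "normo"
    u = rng.random()
    if u < model.p_hyper:
        ml = rng.normal(model.gspneg_hyper_mean, model.gspneg_hyper_sd)
        label = "hyper"
    elif u < model.p_hyper + model.p_hypo:
        ml = rng.normal(model.gspneg_hypo_mean, model.gspneg_hypo_sd)
        label = "hypo"
    else:
        ml = rng.normal(model.gspneg_normo_mean, model.gspneg_normo_sd)
        label = "normo"
    return _truncate(ml, 0, 100), label


def _methylation_rows(
    sample_id: str, ml: float, noise_sd: float, rng: np.random.Generator
) -> list[dict]:
    rows = []
    for pos in CPG_POSITIONS:
        value = _truncate(rng.normal(ml, noise_sd), 0, 100)
        rows.append(
            {
                "sample_id": sample_id,
                "platform": "pyroseq6",
                "position": pos,
                "probe_id": PROBE_AT_POSITION.get(pos, ""),
                "value": value,
            }
        )
    return rows


def _allelic_rows(
    sample_id: str,
    heterozygous: bool,
    minor_fraction: float,
    aq: AQModel,
    rng: np.random.Generator,
) -> list[dict]:
    """gDNA and cDNA signal pairs at rs7121.

    The expressed (maternal) allele is drawn internally and not exported:
    signals only reveal the minor/major split the pyrosequencer sees.
    """
    total = aq.signal_total
    maternal_is_c = bool(rng.random() < 0.5)

    def noisy(x: float) -> float:
        return max(0.0, x + rng.normal(0.0, aq.signal_noise_sd))

    if heterozygous:
        f_gdna_c = _truncate(rng.normal(0.5, aq.gdna_het_sd), 0.0, 1.0)
        gdna_c, gdna_t = noisy(total * f_gdna_c), noisy(total * (1 - f_gdna_c))
        minor = minor_fraction  # share of the non-expressed allele
        f_c = (1.0 - minor) if maternal_is_c else minor
        cdna_c, cdna_t = noisy(total * f_c), noisy(total * (1 - f_c))
    else:
        # homozygous: one allele only, in gDNA and cDNA alike
        back = 0.01
        f_c = (1.0 - back) if maternal_is_c else back
        gdna_c, gdna_t = noisy(total * f_c), noisy(total * (1 - f_c))
        cdna_c, cdna_t = noisy(total * f_c), noisy(total * (1 - f_c))
    return [
        {"sample_id": sample_id, "material": "gDNA",
         "signal_c": gdna_c, "signal_t": gdna_t},
        {"sample_id": sample_id, "material": "cDNA",
         "signal_c": cdna_c, "signal_t": cdna_t},
    ]


def _qpcr_rows(
    sample_id: str,
    group: str,
    model: ExpressionModel,
    rng: np.random.Generator,
) -> list[dict]:
    bgus_copies = float(
        np.exp(rng.normal(np.log(model.bgus_median_copies), model.bgus_sigma))
    )
    rows = []
    for gene in GENES:
        if gene == HOUSEKEEPING_GENE:
            copies = bgus_copies
        else:
            value_k = model.draw_value_k(gene, group, rng)
            copies = value_k * 1000.0 * bgus_copies
        cq = (
            _CURVE_SLOPE * np.log10(copies)
            + _CURVE_INTERCEPTS[gene]
            + rng.normal(0.0, model.cq_noise_sd)
        )
        rows.append({"sample_id": sample_id, "gene": gene, "cq": float(cq)})
    return rows


def _mutate_reference(reference: str, rng: np.random.Generator) -> str:
    codon_idx, new_codon = _GSP_MUTATIONS[rng.integers(len(_GSP_MUTATIONS))]
    start = (codon_idx - 1) * 3
    return reference[:start] + new_codon + reference[start + 3 :]


def simulate_cohort(config: SimulationConfig) -> CohortTables:
    """Simulate a full tumor + normal-pituitary cohort with ground truth.

    Returns every assay table the analysis pipeline consumes, plus one
    ground-truth row per sample. ``true_relaxed`` is recorded as ``"NA"``
    for samples that are homozygous at rs7121 (and for normals, which are
    monoallelic by construction when heterozygous, hence ``"false"``).
    """
    config.validate()
    reference = synthetic_reference_cds()

    samples_rows, meth_rows, allelic_rows, qpcr_rows = [], [], [], []
    truth_rows, sequences = [], []

    def add_sample(sample_id: str, sample_type: str, index: int) -> None:
        rng = _sample_rng(config.seed, index)
        is_tumor = sample_type == "tumor"
        true_gsp = bool(is_tumor and rng.random() < config.p_gsp)
        # rs7121 genotype: two alleles at minor-allele frequency maf
        n_minor = int(rng.random() < config.maf_rs7121) + int(
            rng.random() < config.maf_rs7121
        )
        heterozygous = n_minor == 1
        if is_tumor and not true_gsp:
            latent_relaxed = bool(rng.random() < config.p_relaxed_given_gspneg)
        else:
            latent_relaxed = False  # gsp-positive tumors and normals

        if not is_tumor:
            group = "normal"
        elif true_gsp:
            group = "gsp_positive"
        else:
            group = "gspneg_relaxed" if latent_relaxed else "gspneg_unrelaxed"

        ml, ml_class = _draw_methylation(
            "normal" if group == "normal" else
            ("gsp_positive" if group == "gsp_positive" else "gspneg"),
            config.methylation, rng,
        )
        meth_rows.extend(
            _methylation_rows(sample_id, ml, config.methylation.cpg_noise_sd, rng)
        )
        minor_fraction = config.aq.draw_minor_fraction(latent_relaxed, rng)
        allelic_rows.extend(
            _allelic_rows(sample_id, heterozygous, minor_fraction, config.aq, rng)
        )
        qpcr_rows.extend(_qpcr_rows(sample_id, group, config.expression, rng))
        cds = _mutate_reference(reference, rng) if true_gsp else reference
        sequences.append((sample_id, cds))
        ssa = bool(is_tumor and rng.random() < config.p_ssa_pretreated)
        samples_rows.append(
            {
                "sample_id": sample_id,
                "sample_type": sample_type,
                "cohort": "simulated",
                "ssa_pretreated": ssa,
            }
        )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "sample_type": sample_type,
                "true_gsp": true_gsp,
                "true_heterozygous": heterozygous,
                "true_relaxed": (
                    "NA" if not heterozygous
                    else ("true" if latent_relaxed else "false")
                ),
                "true_methylation_class": ml_class,
            }
        )

    for i in range(config.n_tumors):
        add_sample(f"T{i + 1:04d}", "tumor", i)
    for i in range(config.n_normals):
        add_sample(f"N{i + 1:04d}", "normal", 1_000_000 + i)

    empty = {
        "samples": ["sample_id", "sample_type", "cohort", "ssa_pretreated"],
        "methylation": ["sample_id", "platform", "position", "probe_id", "value"],
        "allelic": ["sample_id", "material", "signal_c", "signal_t"],
        "qpcr": ["sample_id", "gene", "cq"],
        "ground_truth": [
            "sample_id", "sample_type", "true_gsp", "true_heterozygous",
            "true_relaxed", "true_methylation_class",
        ],
    }

    def frame(rows: list[dict], key: str) -> pd.DataFrame:
        return pd.DataFrame(rows, columns=empty[key] if not rows else None)

    return CohortTables(
        samples=frame(samples_rows, "samples"),
        methylation=frame(meth_rows, "methylation"),
        allelic=frame(allelic_rows, "allelic"),
        qpcr=frame(qpcr_rows, "qpcr"),
        standard_curves=_standard_curves(config.seed),
        sequences=sequences,
        ground_truth=frame(truth_rows, "ground_truth"),
        reference_cds=reference,
        config=config,
    )


def simulate_normal_pituitaries(n: int, seed: int) -> CohortTables:
    """Simulate normal-pituitary controls only (monoallelic, ML ≈ N(40, 2.5))."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return simulate_cohort(SimulationConfig(n_tumors=0, n_normals=n, seed=seed))
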