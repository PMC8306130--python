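"""End-to-end cohort analysis: per-sample calls, thresholds, typology, stats.

The pipeline reproduces the analysis logic of the three-group somatotroph
tumor typology:

1. per-sample calls — gsp status from the coding sequence, A/B DMR
   methylation level, rs7121 heterozygosity and cDNA allelic quantification,
   BGUS-normalized absolute expression of GNAS/SSTR2/AIP;
2. reference thresholds — GNAS overexpression cut-off (mean + 1·SD of the
   gsp-positive tumors, normality-gated), methylation normal range
   (mean ± 2·SD of the gsp-positive tumors, normality-gated), relaxation
   threshold (from normal-pituitary AQ, floored at 20%);
3. typology — G1 gsp-positive; among gsp-negative informative tumors,
   G2 unrelaxed and G3 relaxed; everything else unclassified;
4. cohort summary — per-group medians/ranges, Mann–Whitney comparisons of
   the quantitative endpoints, Fisher tests of the categorical contrasts,
   and (for simulated cohorts) confusion matrices against ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alleles import (
    DEFAULT_HET_TOLERANCE,
    DEFAULT_RELAXATION_THRESHOLD,
    AllelicSignals,
    call_heterozygous,
    call_relaxation,
    compute_aq,
    derive_relaxation_threshold,
)
from .expression import (
    classify_overexpression,
    fit_standard_curve,
    quantify_samples,
)
from .gsp import call_gsp
from .io import read_fasta, read_tsv, write_tsv
from .methylation import compute_ml, profiles_from_table
from .simulate import CohortTables, SimulationConfig, simulate_cohort
from .stats import NormalRange, derive_normal_range, fisher_exact, mann_whitney

__all__ = [
    "ReferenceThresholds",
    "CohortSummary",
    "PipelineResult",
    "load_cohort",
    "compute_sample_calls",
    "derive_thresholds",
    "assign_groups",
    "summarize",
    "run_pipeline",
    "PRINTED_THRESHOLDS",
]

GROUPS = ("G1_gsp_positive", "G2_gspneg_unrelaxed", "G3_gspneg_relaxed",
          "unclassified")
_ENDPOINTS = ("GNAS", "SSTR2", "AIP", "ml")


@dataclass(frozen=True)
class ReferenceThresholds:
    """The three reference-derived cut-offs driving classification."""

    overexpression: float  # value_k; strictly-greater-than rule
    methylation_range: NormalRange  # percent; inclusive bounds => normo
    relaxation_threshold: float  # percent minor allele; strictly-greater
    source: str = "derived"  # "derived" | "fixed"
    overexpression_range: NormalRange | None = None

    def to_dict(self) -> dict:
        d = {
            "overexpression": self.overexpression,
            "methylation_mean": self.methylation_range.mean,
            "methylation_sd": self.methylation_range.sd,
            "methylation_lower": self.methylation_range.lower,
            "methylation_upper": self.methylation_range.upper,
            "methylation_fallback": self.methylation_range.fallback,
            "methylation_normality_p": self.methylation_range.normality_p,
            "relaxation_threshold": self.relaxation_threshold,
            "source": self.source,
        }
        if self.overexpression_range is not None:
            d["overexpression_normality_p"] = self.overexpression_range.normality_p
            d["overexpression_fallback"] = self.overexpression_range.fallback
        return d


#: the published cut-offs, usable as a fixed threshold set for new cohorts
PRINTED_THRESHOLDS = ReferenceThresholds(
    overexpression=517.0,
    methylation_range=NormalRange(
        mean=42.4, sd=5.7, k_sd=2.0, lower=31.0, upper=53.8,
        normality_p=1.0, unit="percent",
    ),
    relaxation_threshold=DEFAULT_RELAXATION_THRESHOLD,
    source="fixed",
)


@dataclass
class CohortSummary:
    group_counts: dict
    gsp_positive_total: int
    gsp_positive_informative: int
    group_stats: dict  # group -> endpoint -> {n, median, min, max}
    comparisons: list  # list of dicts, one per pairwise test
    thresholds: dict
    alpha: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    records: pd.DataFrame
    thresholds: ReferenceThresholds
    summary: CohortSummary
    gating_log: list
    confusion: dict | None = None
    report_text: str = ""


def load_cohort(indir: str | Path) -> CohortTables:
    """Load an input bundle (TSV tables + FASTA) from a directory."""
    indir = Path(indir)
    sequences = read_fasta(indir / "sequences.fasta")
    reference = dict(read_fasta(indir / "reference_cds.fasta"))["reference"]
    return CohortTables(
        samples=read_tsv(indir / "samples.tsv"),
        methylation=read_tsv(indir / "methylation.tsv"),
        allelic=read_tsv(indir / "allelic.tsv"),
        qpcr=read_tsv(indir / "qpcr.tsv"),
        standard_curves=read_tsv(indir / "standard_curves.tsv"),
        sequences=sequences,
        ground_truth=(
            read_tsv(indir / "ground_truth.tsv")
            if (indir / "ground_truth.tsv").exists()
            else pd.DataFrame()
        ),
        reference_cds=reference,
    )


# ---------------------------------------------------------------------------
# per-sample calls
# ---------------------------------------------------------------------------

def compute_sample_calls(
    tables: CohortTables,
    het_tolerance: float = DEFAULT_HET_TOLERANCE,
    gating_log: list | None = None,
) -> pd.DataFrame:
    """One row per sample with every per-sample call except those that
    need cohort-level thresholds (methylation class, relaxation status,
    overexpression), which are added downstream.
    """
    log = gating_log if gating_log is not None else []

    required = {"sample_id", "sample_type", "ssa_pretreated"}
    missing = required - set(tables.samples.columns)
    if missing:
        raise ValueError(f"samples table missing columns: {sorted(missing)}")

    # gsp from sequences
    gsp_by_sample = {}
    for sid, cds in tables.sequences:
        gsp_by_sample[sid] = call_gsp(sid, cds, tables.reference_cds)

    # methylation level per sample
    ml_by_sample = {}
    if len(tables.methylation):
        for profile in profiles_from_table(tables.methylation):
            ml_by_sample[profile.sample_id] = compute_ml(profile)

    # allelic signals
    het_by_sample: dict[str, bool] = {}
    aq_by_sample: dict[str, float] = {}
    if len(tables.allelic):
        for sid, grp in tables.allelic.groupby("sample_id"):
            sig = {
                row.material: AllelicSignals(
                    str(sid), row.material,
                    float(row.signal_c), float(row.signal_t),
                )
                for row in grp.itertuples()
            }
            if "gDNA" in sig:
                het_by_sample[str(sid)] = call_heterozygous(
                    sig["gDNA"], het_tolerance
                )
            if "cDNA" in sig:
                aq_by_sample[str(sid)] = compute_aq(sig["cDNA"])

    # expression
    curves = {
        gene: fit_standard_curve(
            gene,
            [(row.log10_copies, row.cq) for row in grp.itertuples()],
        )
        for gene, grp in tables.standard_curves.groupby("gene")
    }
    expr = quantify_samples(tables.qpcr, curves)
    value_k = expr.pivot_table(
        index="sample_id", columns="gene", values="value_k", aggfunc="first"
    )

    rows = []
    for s in tables.samples.itertuples():
        sid = str(s.sample_id)
        gsp = gsp_by_sample.get(sid)
        if gsp is None:
            log.append(f"{sid}: no coding sequence; gsp undetermined")
        het = het_by_sample.get(sid)
        if het is None:
            log.append(f"{sid}: no gDNA signals; treated as uninformative")
            het = False
        row = {
            "sample_id": sid,
            "sample_type": s.sample_type,
            "ssa_pretreated": bool(s.ssa_pretreated),
            "gsp_status": gsp.status if gsp else "undetermined",
            "gsp_codon": gsp.codon if gsp else None,
            "ml": ml_by_sample.get(sid, np.nan),
            "heterozygous": het,
            "aq_minor": aq_by_sample.get(sid, np.nan),
        }
        for gene in ("GNAS", "SSTR2", "AIP"):
            v = np.nan
            if sid in value_k.index and gene in value_k.columns:
                v = float(value_k.loc[sid, gene])
            if not np.isfinite(v):
                log.append(f"{sid}: missing {gene} normalized expression")
            row[f"value_k_{gene}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def derive_thresholds(
    records: pd.DataFrame,
    alpha: float = 0.05,
    relaxation_floor: float = DEFAULT_RELAXATION_THRESHOLD,
    gating_log: list | None = None,
) -> ReferenceThresholds:
    """Derive the three cut-offs from the cohort's own reference groups.

    gsp-positive tumors anchor the GNAS overexpression threshold
    (mean + 1·SD) and the methylation normal range (mean ± 2·SD), both gated
    on the D'Agostino–Pearson normality test; heterozygous normal
    pituitaries anchor the relaxation threshold (mean + 2·SD of their cDNA
    AQ, floored at ``relaxation_floor``).
    """
    log = gating_log if gating_log is not None else []

    gpos = records[
        (records.sample_type == "tumor") & (records.gsp_status == "positive")
    ]
    gnas_ref = gpos["value_k_GNAS"].dropna().to_numpy()
    ml_ref = gpos["ml"].dropna().to_numpy()
    failures = []
    if gnas_ref.size < 8:
        failures.append(
            f"gsp-positive GNAS expression reference (n={gnas_ref.size} < 8)"
        )
    if ml_ref.size < 8:
        failures.append(
            f"gsp-positive methylation reference (n={ml_ref.size} < 8)"
        )
    if failures:
        raise ValueError(
            "reference group(s) too small to derive thresholds: "
            + "; ".join(failures)
        )

    expr_range = derive_normal_range(gnas_ref, k_sd=1.0, alpha=alpha,
                                     unit="value_k")
    if expr_range.fallback:
        log.append(
            "gsp-positive GNAS expression failed the normality gate "
            f"(p={expr_range.normality_p:.3g}); overexpression threshold "
            "falls back to the 97.5th percentile"
        )
    ml_range = derive_normal_range(ml_ref, k_sd=2.0, alpha=alpha,
                                   unit="percent")
    if ml_range.fallback:
        log.append(
            "gsp-positive methylation failed the normality gate "
            f"(p={ml_range.normality_p:.3g}); normal range falls back to "
            "empirical percentiles"
        )

    normals = records[
        (records.sample_type == "normal") & records.heterozygous
    ]
    normal_aqs = normals["aq_minor"].dropna().to_numpy()
    if normal_aqs.size >= 2:
        relax_thr = derive_relaxation_threshold(
            normal_aqs, k_sd=2.0, floor=relaxation_floor
        )
        if relax_thr != relaxation_floor:
            log.append(
                f"relaxation threshold derived from {normal_aqs.size} "
                f"heterozygous normals: {relax_thr:.2f}%"
            )
        else:
            log.append(
                f"relaxation threshold floored at {relaxation_floor:.0f}% "
                f"(derived value from {normal_aqs.size} normals was lower)"
            )
    else:
        relax_thr = relaxation_floor
        log.append(
            f"fewer than 2 heterozygous normals (n={normal_aqs.size}); "
            f"relaxation threshold kept at the {relaxation_floor:.0f}% default"
        )

    return ReferenceThresholds(
        overexpression=expr_range.upper,
        methylation_range=ml_range,
        relaxation_threshold=relax_thr,
        source="derived",
        overexpression_range=expr_range,
    )


# ---------------------------------------------------------------------------
# typology
# ---------------------------------------------------------------------------

def assign_groups(
    records: pd.DataFrame, thresholds: ReferenceThresholds
) -> pd.DataFrame:
    """Add threshold-dependent calls and the three-group labels.

    Group assignment is total: every tumor gets exactly one of G1/G2/G3/
    unclassified; normals get an empty label. G1 membership follows gsp
    status alone; relaxation is only interpreted in gsp-negative informative
    tumors.
    """
    out = records.copy()

    from .methylation import classify_methylation

    def ml_status(ml: float) -> str:
        if not np.isfinite(ml):
            return "missing"
        return classify_methylation(ml, thresholds.methylation_range,
                                    unit=thresholds.methylation_range.unit or "percent")

    out["ml_status"] = out["ml"].map(ml_status)

    def relax_status(row) -> str:
        if not row.heterozygous or not np.isfinite(row.aq_minor):
            return "not_informative"
        call = call_relaxation(
            AllelicSignals(row.sample_id, "cDNA",
                           row.aq_minor, 100.0 - row.aq_minor),
            heterozygous=True,
            threshold=thresholds.relaxation_threshold,
        )
        return call.status

    out["relaxation_status"] = [relax_status(r) for r in out.itertuples()]
    out["gnas_overexpressed"] = [
        bool(np.isfinite(v) and classify_overexpression(v, thresholds.overexpression))
        for v in out["value_k_GNAS"]
    ]

    def group(row) -> str:
        if row.sample_type != "tumor":
            return ""
        if row.gsp_status == "positive":
            return "G1_gsp_positive"
        if row.gsp_status == "negative":
            if row.relaxation_status == "relaxed":
                return "G3_gspneg_relaxed"
            if row.relaxation_status == "unrelaxed":
                return "G2_gspneg_unrelaxed"
        return "unclassified"

    out["group"] = [group(r) for r in out.itertuples()]
    return out


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _endpoint_values(df: pd.DataFrame, endpoint: str) -> np.ndarray:
    col = "ml" if endpoint == "ml" else f"value_k_{endpoint}"
    return df[col].dropna().to_numpy()


def _mw_comparison(
    name: str, endpoint: str, a: np.ndarray, b: np.ndarray,
    label_a: str, label_b: str, alpha: float,
) -> dict:
    entry = {
        "name": name,
        "endpoint": endpoint,
        "group_a": label_a,
        "group_b": label_b,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)) if a.size else None,
        "median_b": float(np.median(b)) if b.size else None,
        "test": "mann_whitney",
    }
    if a.size == 0 or b.size == 0:
        entry.update(skipped=True, reason="empty group",
                     statistic=None, p_value=None, method=None,
                     significant=None)
        return entry
    res = mann_whitney(a, b)
    entry.update(
        skipped=False, statistic=res.statistic, p_value=res.p_value,
        method=res.method, significant=bool(res.p_value <= alpha),
    )
    return entry


def _fisher_comparison(
    name: str, table: np.ndarray, labels: dict, alpha: float
) -> dict:
    entry = {"name": name, "test": "fisher_exact", **labels,
             "table": [[int(x) for x in row] for row in table]}
    if table.sum() == 0:
        entry.update(skipped=True, reason="empty table", p_value=None,
                     significant=None)
        return entry
    res = fisher_exact(table)
    entry.update(skipped=False, p_value=res.p_value,
                 significant=bool(res.p_value <= alpha))
    return entry


def summarize(
    records: pd.DataFrame,
    thresholds: ReferenceThresholds,
    alpha: float = 0.05,
) -> CohortSummary:
    """Cohort-level medians, ranges and pairwise tests.

    Quantitative endpoints are compared with the Mann–Whitney test across
    the printed contrasts (gsp-positive vs gsp-negative; relaxed vs
    unrelaxed gsp-negative; hyper- vs normo-methylated gsp-negative;
    SSA-pretreated vs not); categorical contrasts use Fisher's exact test.
    Comparisons with an empty arm are emitted flagged, not dropped.
    """
    tumors = records[records.sample_type == "tumor"]
    normals = records[records.sample_type == "normal"]

    group_counts = {g: int((tumors.group == g).sum()) for g in GROUPS}
    gpos = tumors[tumors.gsp_status == "positive"]
    gneg = tumors[tumors.gsp_status == "negative"]
    g2 = tumors[tumors.group == "G2_gspneg_unrelaxed"]
    g3 = tumors[tumors.group == "G3_gspneg_relaxed"]

    group_stats: dict = {}
    for gname, df in (
        ("G1_gsp_positive", tumors[tumors.group == "G1_gsp_positive"]),
        ("G2_gspneg_unrelaxed", g2),
        ("G3_gspneg_relaxed", g3),
        ("unclassified", tumors[tumors.group == "unclassified"]),
        ("normal_pituitary", normals),
    ):
        stats = {}
        for endpoint in _ENDPOINTS:
            vals = _endpoint_values(df, endpoint)
            stats[endpoint] = {
                "n": int(vals.size),
                "median": float(np.median(vals)) if vals.size else None,
                "min": float(vals.min()) if vals.size else None,
                "max": float(vals.max()) if vals.size else None,
            }
        group_stats[gname] = stats

    comparisons = []
    for endpoint in _ENDPOINTS:
        comparisons.append(_mw_comparison(
            f"gsp_positive_vs_gsp_negative_{endpoint}", endpoint,
            _endpoint_values(gpos, endpoint), _endpoint_values(gneg, endpoint),
            "gsp_positive", "gsp_negative", alpha,
        ))
    for endpoint in _ENDPOINTS:
        comparisons.append(_mw_comparison(
            f"unrelaxed_vs_relaxed_gspneg_{endpoint}", endpoint,
            _endpoint_values(g2, endpoint), _endpoint_values(g3, endpoint),
            "G2_gspneg_unrelaxed", "G3_gspneg_relaxed", alpha,
        ))
    hyper = gneg[gneg.ml_status == "hyper"]
    normo = gneg[gneg.ml_status == "normo"]
    for endpoint in ("GNAS", "SSTR2", "AIP"):
        comparisons.append(_mw_comparison(
            f"hyper_vs_normo_methylated_gspneg_{endpoint}", endpoint,
            _endpoint_values(hyper, endpoint), _endpoint_values(normo, endpoint),
            "gspneg_hyper", "gspneg_normo", alpha,
        ))
    ssa = gneg[gneg.ssa_pretreated]
    no_ssa = gneg[~gneg.ssa_pretreated]
    for endpoint in ("GNAS", "SSTR2", "AIP"):
        comparisons.append(_mw_comparison(
            f"ssa_pretreated_vs_untreated_gspneg_{endpoint}", endpoint,
            _endpoint_values(ssa, endpoint), _endpoint_values(no_ssa, endpoint),
            "gspneg_ssa", "gspneg_no_ssa", alpha,
        ))
    comparisons.append(_mw_comparison(
        "normals_vs_gsp_negative_ml", "ml",
        _endpoint_values(normals, "ml"), _endpoint_values(gneg, "ml"),
        "normal_pituitary", "gsp_negative", alpha,
    ))

    informative = gneg[gneg.relaxation_status.isin(["relaxed", "unrelaxed"])]
    relax_over = np.array([
        [
            int(((informative.relaxation_status == "relaxed")
                 & informative.gnas_overexpressed).sum()),
            int(((informative.relaxation_status == "relaxed")
                 & ~informative.gnas_overexpressed).sum()),
        ],
        [
            int(((informative.relaxation_status == "unrelaxed")
                 & informative.gnas_overexpressed).sum()),
            int(((informative.relaxation_status == "unrelaxed")
                 & ~informative.gnas_overexpressed).sum()),
        ],
    ])
    comparisons.append(_fisher_comparison(
        "relaxation_vs_gnas_overexpression",
        relax_over,
        {"rows": ["relaxed", "unrelaxed"],
         "cols": ["overexpressed", "not_overexpressed"]},
        alpha,
    ))
    relax_hyper = np.array([
        [
            int(((informative.relaxation_status == "relaxed")
                 & (informative.ml_status == "hyper")).sum()),
            int(((informative.relaxation_status == "relaxed")
                 & (informative.ml_status != "hyper")).sum()),
        ],
        [
            int(((informative.relaxation_status == "unrelaxed")
                 & (informative.ml_status == "hyper")).sum()),
            int(((informative.relaxation_status == "unrelaxed")
                 & (informative.ml_status != "hyper")).sum()),
        ],
    ])
    comparisons.append(_fisher_comparison(
        "relaxation_vs_hypermethylation",
        relax_hyper,
        {"rows": ["relaxed", "unrelaxed"], "cols": ["hyper", "not_hyper"]},
        alpha,
    ))

    return CohortSummary(
        group_counts=group_counts,
        gsp_positive_total=int((tumors.gsp_status == "positive").sum()),
        gsp_positive_informative=int(
            (gpos.relaxation_status.isin(["relaxed", "unrelaxed"])).sum()
        ),
        group_stats=group_stats,
        comparisons=comparisons,
        thresholds=thresholds.to_dict(),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ground-truth comparison
# ---------------------------------------------------------------------------

def confusion_vs_truth(
    records: pd.DataFrame, ground_truth: pd.DataFrame
) -> dict:
    """Confusion matrices and accuracies of the calls against simulator truth."""
    merged = records.merge(ground_truth, on="sample_id", suffixes=("", "_gt"))
    tumors = merged[merged.sample_type == "tumor"]

    gsp_pred = tumors.gsp_status == "positive"
    gsp_true = tumors.true_gsp.astype(bool)
    gsp_acc = float((gsp_pred == gsp_true).mean()) if len(tumors) else float("nan")

    info = tumors[
        tumors.relaxation_status.isin(["relaxed", "unrelaxed"])
        & (tumors.true_relaxed != "NA")
    ]
    relax_pred = info.relaxation_status == "relaxed"
    relax_true = info.true_relaxed == "true"
    relax_acc = (
        float((relax_pred == relax_true).mean()) if len(info) else float("nan")
    )
    relax_matrix = {
        "true_relaxed_called_relaxed": int((relax_true & relax_pred).sum()),
        "true_relaxed_called_unrelaxed": int((relax_true & ~relax_pred).sum()),
        "true_unrelaxed_called_relaxed": int((~relax_true & relax_pred).sum()),
        "true_unrelaxed_called_unrelaxed": int((~relax_true & ~relax_pred).sum()),
    }

    classes = ("hypo", "normo", "hyper")
    meth = tumors[tumors.ml_status.isin(classes)]
    meth_matrix = {
        f"true_{t}_called_{p}": int(
            ((meth.true_methylation_class == t) & (meth.ml_status == p)).sum()
        )
        for t in classes
        for p in classes
    }
    meth_acc = (
        float((meth.true_methylation_class == meth.ml_status).mean())
        if len(meth) else float("nan")
    )

    return {
        "gsp_accuracy": gsp_acc,
        "relaxation_accuracy": relax_acc,
        "relaxation_confusion": relax_matrix,
        "relaxation_n": int(len(info)),
        "methylation_accuracy": meth_acc,
        "methylation_confusion": meth_matrix,
        "methylation_n": int(len(meth)),
    }


# ---------------------------------------------------------------------------
# report + orchestration
# ---------------------------------------------------------------------------

def _format_report(
    summary: CohortSummary, thresholds: ReferenceThresholds,
    confusion: dict | None, meta: dict,
) -> str:
    lines = []
    lines.append("GNAS locus epigenotyping report")
    lines.append("=" * 48)
    for k, v in meta.items():
        lines.append(f"{k}: {v}")
    lines.append("")
    lines.append("Reference thresholds")
    lines.append("-" * 48)
    t = summary.thresholds
    lines.append(
        f"GNAS overexpression: value_k > {t['overexpression']:.1f} "
        f"({'fixed' if t['source'] == 'fixed' else 'mean + 1 SD of gsp-positive tumors'})"
    )
    lines.append(
        f"A/B ML normal range: [{t['methylation_lower']:.1f}, "
        f"{t['methylation_upper']:.1f}] %"
        + (" (percentile fallback)" if t["methylation_fallback"] else "")
    )
    lines.append(
        f"Imprinting relaxation: minor allele > "
        f"{t['relaxation_threshold']:.1f}% of total GNAS expression"
    )
    lines.append("")
    lines.append("Tumor typology")
    lines.append("-" * 48)
    for g in GROUPS:
        lines.append(f"{g}: n = {summary.group_counts[g]}")
    lines.append(
        f"gsp-positive (all): n = {summary.gsp_positive_total}; "
        f"informative at rs7121: n = {summary.gsp_positive_informative}"
    )
    lines.append("")
    lines.append("Per-group medians (value_k = x1000 copies/copy BGUS; ml = %)")
    lines.append("-" * 48)
    for g, stats in summary.group_stats.items():
        parts = []
        for endpoint in _ENDPOINTS:
            s = stats[endpoint]
            if s["median"] is None:
                continue
            parts.append(
                f"{endpoint} {s['median']:.1f} "
                f"[{s['min']:.1f}-{s['max']:.1f}] (n={s['n']})"
            )
        lines.append(f"{g}: " + ("; ".join(parts) if parts else "no data"))
    lines.append("")
    lines.append(f"Pairwise tests (alpha = {summary.alpha})")
    lines.append("-" * 48)
    for c in summary.comparisons:
        if c.get("skipped"):
            lines.append(f"{c['name']}: skipped ({c['reason']})")
            continue
        if c["test"] == "mann_whitney":
            lines.append(
                f"{c['name']}: median {c['median_a']:.1f} (n={c['n_a']}) vs "
                f"{c['median_b']:.1f} (n={c['n_b']}), U={c['statistic']:.1f}, "
                f"p={c['p_value']:.4g} [{c['method']}]"
                + (" *" if c["significant"] else "")
            )
        else:
            lines.append(
                f"{c['name']}: table {c['table']}, p={c['p_value']:.4g}"
                + (" *" if c["significant"] else "")
            )
    if confusion is not None:
        lines.append("")
        lines.append("Ground-truth comparison (simulated cohort)")
        lines.append("-" * 48)
        lines.append(f"gsp-call accuracy: {confusion['gsp_accuracy']:.4f}")
        lines.append(
            f"relaxation-call accuracy: {confusion['relaxation_accuracy']:.4f} "
            f"(n={confusion['relaxation_n']})"
        )
        lines.append(
            f"methylation-class accuracy: {confusion['methylation_accuracy']:.4f} "
            f"(n={confusion['methylation_n']})"
        )
        lines.append(f"relaxation confusion: {confusion['relaxation_confusion']}")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    config: SimulationConfig | None = None,
    indir: str | Path | None = None,
    outdir: str | Path | None = None,
    thresholds: ReferenceThresholds | None = None,
    alpha: float = 0.05,
    het_tolerance: float = DEFAULT_HET_TOLERANCE,
) -> PipelineResult:
    """Run the full analysis: (simulate or load) → call → threshold →
    classify → summarize → report.

    Exactly one of ``config`` (simulate-first mode) or ``indir`` (load an
    existing input bundle) must be given. Pass ``thresholds`` (e.g.
    ``PRINTED_THRESHOLDS``) to skip within-cohort derivation. With
    ``outdir`` set, writes records TSV, summary/threshold JSON, a plain-text
    report and the gating log; in simulate-first mode the input bundle is
    written there too.
    """
    if (config is None) == (indir is None):
        raise ValueError("provide exactly one of config or indir")
    gating_log: list = []

    if config is not None:
        tables = simulate_cohort(config)
        meta_seed = config.seed
        config_hash = hashlib.sha256(
            config.to_json().encode()
        ).hexdigest()[:12]
    else:
        tables = load_cohort(indir)
        meta_seed = None
        config_hash = None

    records = compute_sample_calls(tables, het_tolerance, gating_log)
    if thresholds is None:
        thresholds = derive_thresholds(records, alpha=alpha,
                                       gating_log=gating_log)
    else:
        gating_log.append(f"using externally supplied thresholds "
                          f"({thresholds.source})")
    records = assign_groups(records, thresholds)
    summary = summarize(records, thresholds, alpha=alpha)

    confusion = None
    if len(tables.ground_truth):
        confusion = confusion_vs_truth(records, tables.ground_truth)

    meta = {"version": __version__}
    if meta_seed is not None:
        meta["seed"] = meta_seed
        meta["config_hash"] = config_hash
    report = _format_report(summary, thresholds, confusion, meta)

    result = PipelineResult(
        records=records,
        thresholds=thresholds,
        summary=summary,
        gating_log=gating_log,
        confusion=confusion,
        report_text=report,
    )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if config is not None:
            tables.write(out / "inputs")
        str_meta = {k: str(v) for k, v in meta.items()}
        write_tsv(records, out / "tumor_records.tsv", str_meta)
        (out / "cohort_summary.json").write_text(summary.to_json())
        (out / "thresholds.json").write_text(
            json.dumps(thresholds.to_dict(), indent=2, sort_keys=True)
        )
        (out / "report.txt").write_text(report)
        (out / "gating_log.txt").write_text(
            "\n".join(gating_log) + ("\n" if gating_log else "")
        )
        if confusion is not None:
            (out / "confusion.json").write_text(
                json.dumps(confusion, indent=2, sort_keys=True)
            )
    return result
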