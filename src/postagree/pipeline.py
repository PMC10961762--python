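"""End-to-end study pipeline.

Orchestrates the full analysis from either rating-level data
(:func:`run_full_study`) or from the study's published cross-tabulation
fixtures (:func:`run_from_fixtures`), producing a :class:`StudyReport`
with, per image variant:

* the 4-category and binary clinical-vs-consensus cross-tabulations of
  the full panel;
* binary cross-tabulations of the low/high-entropy item halves and of
  the junior/senior rater subgroups (consensus recomputed per subgroup);
* agreement statistics (Po, Pe, kappa, PABAK, z, p, Landis band) and
  sensitivity/specificity for every stratum;
* chi-square comparisons (S vs G; low vs high entropy; junior vs senior)
  and, for rating-level input, the Wilcoxon signed-rank test on paired
  per-image entropies of the two variants.

Reports serialize deterministically to JSON, CSV or markdown.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .agreement import (
    AgreementResult,
    DiagnosticResult,
    agreement_report,
    build_crosstab,
    collapse_binary,
    sensitivity_specificity,
)
from .comparisons import TestResult, UndefinedTestError, compare_proportions, wilcoxon_signed_rank
from .consensus import ConsensusLabel, Item, assign_labels, consensus_frame
from .data_model import (
    BINARY_CATEGORIES,
    FOUR_CATEGORIES,
    CrossTab,
    RatingTable,
    ReferenceLabels,
    ValidationError,
    Variant,
    study_crosstab,
)
from .entropy import EntropyProfile, entropy_profile, median_split

__all__ = ["StudyConfig", "StratumResult", "StudyReport", "run_full_study",
           "run_from_fixtures", "render_report"]

logger = logging.getLogger(__name__)

STRATA = ("all", "low_entropy", "high_entropy", "lt10y", "gt10y")


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the analysis.

    ``experience_threshold_years`` splits the panel into junior/senior
    groups; raters exactly at the threshold are junior unless
    ``senior_is_inclusive``.  ``pabak_convention`` selects the headline
    PABAK form (``binary_formula`` = 2*Po-1 for any K, or
    ``multicategory``).
    """

    experience_threshold_years: float = 10.0
    senior_is_inclusive: bool = False
    pabak_convention: str = "binary_formula"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.experience_threshold_years <= 0:
            raise ValidationError("experience_threshold_years must be positive")
        if self.pabak_convention not in ("binary_formula", "multicategory"):
            raise ValidationError(f"unknown PABAK convention {self.pabak_convention!r}")


@dataclass(frozen=True)
class StratumResult:
    variant: str
    stratum: str
    kind: str  # "4cat" | "binary"
    crosstab: CrossTab
    agreement: AgreementResult
    diagnostics: DiagnosticResult | None

    def as_dict(self) -> dict:
        out = {
            "variant": self.variant, "stratum": self.stratum, "kind": self.kind,
            "categories": list(self.crosstab.categories),
            "counts": self.crosstab.counts.tolist(),
            "n": self.crosstab.n,
        }
        out.update(self.agreement.as_dict())
        if self.diagnostics is not None:
            out.update(self.diagnostics.as_dict())
        return out


@dataclass
class StudyReport:
    strata: dict[tuple[str, str, str], StratumResult]  # (variant, stratum, kind)
    comparisons: dict[str, TestResult | None]
    entropy_wilcoxon: TestResult | None = None
    consensus: pd.DataFrame | None = None
    entropy: pd.DataFrame | None = None
    config: StudyConfig = field(default_factory=StudyConfig)

    def stratum(self, variant: str, stratum: str, kind: str = "binary") -> StratumResult:
        return self.strata[(variant, stratum, kind)]

    def as_dict(self) -> dict:
        out: dict = {
            "config": {
                "experience_threshold_years": self.config.experience_threshold_years,
                "senior_is_inclusive": self.config.senior_is_inclusive,
                "pabak_convention": self.config.pabak_convention,
                "seed": self.config.seed,
            },
            "strata": {
                f"{v}/{s}/{k}": res.as_dict()
                for (v, s, k), res in sorted(self.strata.items())
            },
            "comparisons": {
                name: (t.as_dict() if t is not None else None)
                for name, t in sorted(self.comparisons.items())
            },
            "entropy_wilcoxon": (
                self.entropy_wilcoxon.as_dict() if self.entropy_wilcoxon else None
            ),
        }
        if self.consensus is not None:
            out["consensus"] = self.consensus.to_dict(orient="records")
        if self.entropy is not None:
            ent = self.entropy.copy()
            ent["split"] = ent["split"].astype(object).where(ent["split"].notna(), None)
            out["entropy"] = ent.to_dict(orient="records")
        return out


def _stratum_result(variant: str, stratum: str, kind: str, crosstab: CrossTab,
                    config: StudyConfig) -> StratumResult:
    diag = sensitivity_specificity(crosstab) if crosstab.k == 2 else None
    return StratumResult(
        variant=variant, stratum=stratum, kind=kind, crosstab=crosstab,
        agreement=agreement_report(crosstab, config.pabak_convention),
        diagnostics=diag,
    )


def _diag_comparison(name: str, d1: DiagnosticResult, d2: DiagnosticResult,
                     measure: str) -> TestResult | None:
    """Chi-square on a diagnostic proportion between two strata; None when
    a zero marginal makes the test undefined."""
    if measure == "sensitivity":
        x1, n1 = d1.tp, d1.tp + d1.fn
        x2, n2 = d2.tp, d2.tp + d2.fn
    else:
        x1, n1 = d1.tn, d1.tn + d1.fp
        x2, n2 = d2.tn, d2.tn + d2.fp
    try:
        return compare_proportions(x1, n1, x2, n2)
    except UndefinedTestError as exc:
        logger.info("comparison %s undefined: %s", name, exc)
        return None


def _all_comparisons(strata: Mapping[tuple[str, str, str], StratumResult]) -> dict:
    comparisons: dict[str, TestResult | None] = {}
    variants = sorted({v for (v, _, _) in strata})

    def diag(variant: str, stratum: str) -> DiagnosticResult:
        return strata[(variant, stratum, "binary")].diagnostics

    for measure in ("sensitivity", "specificity"):
        if set(variants) >= {"S", "G"}:
            name = f"{measure}_S_vs_G"
            comparisons[name] = _diag_comparison(
                name, diag("S", "all"), diag("G", "all"), measure)
        for variant in variants:
            name = f"{measure}_entropy_{variant}"
            comparisons[name] = _diag_comparison(
                name, diag(variant, "low_entropy"), diag(variant, "high_entropy"),
                measure)
            name = f"{measure}_experience_{variant}"
            comparisons[name] = _diag_comparison(
                name, diag(variant, "lt10y"), diag(variant, "gt10y"), measure)
    return comparisons


def run_from_fixtures(config: StudyConfig | None = None) -> StudyReport:
    """Recompute every statistic from the study's published matrices.

    The raw ratings behind them are unpublished, so the rating-level
    stages (consensus, entropy profile, Wilcoxon) are absent; every
    agreement statistic and chi-square comparison is recomputed from the
    ten shipped cross-tabulations.
    """
    config = config or StudyConfig()
    strata: dict[tuple[str, str, str], StratumResult] = {}
    for variant in ("S", "G"):
        four = study_crosstab("table1", variant, "all")
        strata[(variant, "all", "4cat")] = _stratum_result(variant, "all", "4cat",
                                                           four, config)
        strata[(variant, "all", "binary")] = _stratum_result(
            variant, "all", "binary", collapse_binary(four), config)
        for stratum in ("low_entropy", "high_entropy"):
            strata[(variant, stratum, "binary")] = _stratum_result(
                variant, stratum, "binary",
                study_crosstab("table2", variant, stratum), config)
        for stratum in ("lt10y", "gt10y"):
            strata[(variant, stratum, "binary")] = _stratum_result(
                variant, stratum, "binary",
                study_crosstab("table3", variant, stratum), config)
    return StudyReport(strata=strata, comparisons=_all_comparisons(strata),
                       config=config)


def run_full_study(
    table: RatingTable,
    reference: ReferenceLabels,
    config: StudyConfig | None = None,
) -> StudyReport:
    """Run the complete analysis chain on rating-level data.

    Stages: full-panel consensus -> 4-category and binary
    cross-tabulations per variant -> entropy profile and paired Wilcoxon
    (when both variants are present) -> median entropy split ->
    entropy-stratum cross-tabulations -> junior/senior subgroup
    relabeling -> experience-stratum cross-tabulations -> agreement
    statistics and chi-square comparisons for everything.  Fully
    deterministic in its inputs.
    """
    config = config or StudyConfig()
    reference.validate_against(table)
    variants = sorted({var for _, var in table.items}, key=lambda v: v.value)
    logger.info("pipeline start: %d raters, %d items, variants %s",
                table.n_raters, len(table.items), [v.value for v in variants])

    labels = assign_labels(table)
    strata: dict[tuple[str, str, str], StratumResult] = {}
    for variant in variants:
        four = build_crosstab(reference, labels, variant, FOUR_CATEGORIES)
        strata[(variant.value, "all", "4cat")] = _stratum_result(
            variant.value, "all", "4cat", four, config)
        strata[(variant.value, "all", "binary")] = _stratum_result(
            variant.value, "all", "binary", collapse_binary(four), config)

    profile = entropy_profile(table)
    entropy_wilcoxon = None
    if len(variants) == 2:
        paired = profile.paired(variants[0], variants[1])
        try:
            entropy_wilcoxon = wilcoxon_signed_rank(list(paired.itertuples(index=False)))
        except UndefinedTestError as exc:
            logger.info("entropy Wilcoxon undefined: %s", exc)

    for variant in variants:
        low, high = median_split(profile, variant)
        logger.info("variant %s entropy split: %d low, %d high",
                    variant.value, len(low), len(high))
        for stratum, imgs in (("low_entropy", set(low)), ("high_entropy", set(high))):
            subset = {it: lab for it, lab in labels.items()
                      if it[1] == variant and it[0] in imgs}
            ct = build_crosstab(reference, subset, variant, BINARY_CATEGORIES)
            strata[(variant.value, stratum, "binary")] = _stratum_result(
                variant.value, stratum, "binary", ct, config)

    junior, senior = table.split_by_experience(
        config.experience_threshold_years, config.senior_is_inclusive)
    logger.info("experience split at %gy: %d junior, %d senior",
                config.experience_threshold_years, junior.n_raters, senior.n_raters)
    for stratum, subtable in (("lt10y", junior), ("gt10y", senior)):
        sub_labels = assign_labels(subtable)
        for variant in variants:
            ct = build_crosstab(reference, sub_labels, variant, BINARY_CATEGORIES)
            strata[(variant.value, stratum, "binary")] = _stratum_result(
                variant.value, stratum, "binary", ct, config)

    return StudyReport(
        strata=strata,
        comparisons=_all_comparisons(strata),
        entropy_wilcoxon=entropy_wilcoxon,
        consensus=consensus_frame(labels),
        entropy=profile.frame.copy(),
        config=config,
    )


# ---------------------------------------------------------------------------
# rendering

def render_report(report: StudyReport, fmt: str, outdir: str | Path) -> list[Path]:
    """Serialize a report deterministically; returns the files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = outdir / "report.json"
        path.write_text(json.dumps(report.as_dict(), indent=1, sort_keys=True,
                                   allow_nan=False) + "\n")
        return [path]
    if fmt == "csv":
        return _render_csv(report, outdir)
    if fmt == "markdown":
        path = outdir / "report.md"
        path.write_text(_render_markdown(report))
        return [path]
    raise ValueError(f"unknown report format {fmt!r} (expected json, csv or markdown)")


def _render_csv(report: StudyReport, outdir: Path) -> list[Path]:
    written = []
    strata_rows = [res.as_dict() for _, res in sorted(report.strata.items())]
    for row in strata_rows:
        row["counts"] = json.dumps(row["counts"])
        row["categories"] = json.dumps(row["categories"])
    path = outdir / "strata.csv"
    pd.DataFrame(strata_rows).to_csv(path, index=False)
    written.append(path)

    comp_rows = []
    for name, t in sorted(report.comparisons.items()):
        row = {"comparison": name}
        row.update(t.as_dict() if t is not None else {"method": None, "p": None})
        if "table" in row:
            row["table"] = json.dumps(row["table"])
        comp_rows.append(row)
    if report.entropy_wilcoxon is not None:
        row = {"comparison": "entropy_S_vs_G"}
        row.update(report.entropy_wilcoxon.as_dict())
        comp_rows.append(row)
    path = outdir / "comparisons.csv"
    pd.DataFrame(comp_rows).to_csv(path, index=False)
    written.append(path)

    if report.consensus is not None:
        path = outdir / "consensus.csv"
        report.consensus.to_csv(path, index=False)
        written.append(path)
    if report.entropy is not None:
        path = outdir / "entropy.csv"
        report.entropy.to_csv(path, index=False)
        written.append(path)
    return written


def _md_table(crosstab: CrossTab) -> str:
    cats = list(crosstab.categories)
    head = "| clinical \\\\ imaging | " + " | ".join(cats) + " |"
    sep = "|" + "---|" * (len(cats) + 1)
    rows = [
        "| " + cats[i] + " | " + " | ".join(str(v) for v in crosstab.counts[i]) + " |"
        for i in range(len(cats))
    ]
    return "\n".join([head, sep, *rows])


def _fmt(value, nd=4) -> str:
    if value is None:
        return "undefined"
    return f"{value:.{nd}f}"


def _render_markdown(report: StudyReport) -> str:
    lines = ["# Agreement report", ""]
    for (variant, stratum, kind), res in sorted(report.strata.items()):
        a, d = res.agreement, res.diagnostics
        lines += [f"## {variant} / {stratum} / {kind} (n={res.crosstab.n})", "",
                  _md_table(res.crosstab), ""]
        lines.append(
            f"Po={_fmt(a.po)}, Pe={_fmt(a.pe)}, kappa={_fmt(a.kappa)}, "
            f"PABAK={_fmt(a.pabak_binary, 2)} ({a.landis}), "
            f"z={_fmt(a.z, 3)}, p={_fmt(a.p)}"
        )
        if d is not None:
            lines.append(
                f"sensitivity={_fmt(d.sensitivity)}, specificity={_fmt(d.specificity)}"
            )
        lines.append("")
    lines += ["## Comparisons", ""]
    for name, t in sorted(report.comparisons.items()):
        if t is None:
            lines.append(f"- {name}: undefined (zero marginal)")
        else:
            lines.append(f"- {name}: chi2={_fmt(t.statistic, 4)}, p={_fmt(t.p)}")
    if report.entropy_wilcoxon is not None:
        t = report.entropy_wilcoxon
        lines.append(f"- entropy_S_vs_G (Wilcoxon): Z={_fmt(t.statistic, 3)}, p={_fmt(t.p)}")
    lines.append("")
    return "\n".join(lines)
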