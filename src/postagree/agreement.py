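"""Agreement statistics on clinical-vs-consensus cross-tabulations.

Given a K x K contingency table with the clinical reference on rows and
the panel consensus on columns, this module computes:

* Po, Pe -- observed agreement (diagonal proportion) and chance
  agreement from marginal products;
* Cohen's kappa = (Po - Pe) / (1 - Pe);
* PABAK, the prevalence- and bias-adjusted kappa.  The default
  convention is 2*Po - 1 regardless of K (the form under which every
  agreement value in the source study is reported, including the
  4-category tables); the common multi-category form
  (K*Po - 1)/(K - 1) is available via ``convention="multicategory"``;
* a large-sample significance test z = kappa / SE0 with Fleiss's
  standard error under the independence null, with a two-sided normal
  p-value;
* sensitivity and specificity of the binary (ideal vs non-ideal)
  collapse, with NON_IDEAL as the positive class: sensitivity is the
  proportion of clinically non-ideal items the consensus flags
  non-ideal, specificity the proportion of clinically ideal items it
  labels ideal;
* the Landis-Koch verbal interpretation band of an agreement value.

Degenerate tables (a single observed category, an empty clinical row)
raise :class:`UndefinedStatisticError` or yield ``None`` fields rather
than silently reporting 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .consensus import ConsensusLabel, Item
from .data_model import (
    BINARY_CATEGORIES,
    FOUR_CATEGORIES,
    Category,
    CrossTab,
    ReferenceLabels,
    ValidationError,
    Variant,
)

__all__ = [
    "AgreementResult",
    "DiagnosticResult",
    "UndefinedStatisticError",
    "build_crosstab",
    "collapse_binary",
    "observed_agreement",
    "expected_agreement",
    "cohens_kappa",
    "pabak",
    "kappa_significance",
    "sensitivity_specificity",
    "landis_interpretation",
    "agreement_report",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for this table."""


@dataclass(frozen=True)
class AgreementResult:
    po: float
    pe: float
    kappa: float | None
    pabak_binary: float
    pabak_multicat: float
    z: float | None
    p: float | None
    landis: str

    def as_dict(self) -> dict:
        return {
            "po": self.po, "pe": self.pe, "kappa": self.kappa,
            "pabak_binary": self.pabak_binary,
            "pabak_multicat": self.pabak_multicat,
            "z": self.z, "p": self.p, "landis": self.landis,
        }


@dataclass(frozen=True)
class DiagnosticResult:
    sensitivity: float | None
    specificity: float | None
    tp: int
    fn: int
    fp: int
    tn: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
        }


def build_crosstab(
    reference: ReferenceLabels,
    consensus: Mapping[Item, ConsensusLabel],
    variant: Variant,
    categories: tuple[str, ...] = FOUR_CATEGORIES,
) -> CrossTab:
    """Cross-tabulate reference (rows) against consensus (columns) labels.

    ``categories`` selects the label space: the four Kendall categories
    or the binary ideal/non-ideal collapse.
    """
    items = [(img, var) for (img, var) in consensus if var == variant]
    if not items:
        raise ValidationError(f"no consensus labels for variant {variant.value}")
    missing = [img for img, _ in items if img not in reference]
    if missing:
        raise ValidationError(f"items without reference label: {sorted(missing)[:5]}")
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    binary = tuple(categories) == BINARY_CATEGORIES
    for img, var in items:
        ref = reference[img]
        cons = consensus[(img, var)].label
        if binary:
            r, c = index[ref.to_binary().value], index[cons.to_binary().value]
        else:
            r, c = index[ref.value], index[cons.value]
        counts[r, c] += 1
    return CrossTab(tuple(categories), counts)


def collapse_binary(crosstab: CrossTab) -> CrossTab:
    """Collapse a 4-category table to ideal vs non-ideal.

    The NON_IDEAL row/column is the sum of the KL, SB and FB rows/columns.
    """
    if crosstab.categories != FOUR_CATEGORIES:
        raise ValidationError(
            f"expected the four canonical categories, got {crosstab.categories}"
        )
    m = crosstab.counts
    collapsed = np.array(
        [[m[0, 0], m[0, 1:].sum()],
         [m[1:, 0].sum(), m[1:, 1:].sum()]], dtype=int
    )
    return CrossTab(BINARY_CATEGORIES, collapsed)


def _check_nonempty(crosstab: CrossTab) -> None:
    if crosstab.n < 1:
        raise UndefinedStatisticError("empty cross-tabulation")


def observed_agreement(crosstab: CrossTab) -> float:
    """Po: diagonal sum over the table total."""
    _check_nonempty(crosstab)
    return float(np.trace(crosstab.counts) / crosstab.n)


def expected_agreement(crosstab: CrossTab) -> float:
    """Pe: chance agreement from the marginal products."""
    _check_nonempty(crosstab)
    n = crosstab.n
    return float((crosstab.row_totals() / n * (crosstab.col_totals() / n)).sum())


def cohens_kappa(crosstab: CrossTab) -> float:
    """Cohen's kappa = (Po - Pe)/(1 - Pe); undefined when Pe = 1."""
    po = observed_agreement(crosstab)
    pe = expected_agreement(crosstab)
    if pe >= 1.0:
        raise UndefinedStatisticError(
            "kappa undefined: chance agreement Pe = 1 (single observed category)"
        )
    return (po - pe) / (1.0 - pe)


def pabak(crosstab: CrossTab, convention: str = "binary_formula") -> float:
    """Prevalence- and bias-adjusted kappa.

    ``binary_formula`` (default): 2*Po - 1, for any K.
    ``multicategory``: (K*Po - 1)/(K - 1).
    The two coincide for K = 2.
    """
    po = observed_agreement(crosstab)
    if convention == "binary_formula":
        return 2.0 * po - 1.0
    if convention == "multicategory":
        k = crosstab.k
        return (k * po - 1.0) / (k - 1.0)
    raise ValueError(f"unknown PABAK convention {convention!r}")


def kappa_significance(crosstab: CrossTab) -> tuple[float, float]:
    """z and two-sided p for kappa under the independence null.

    Uses Fleiss's large-sample standard error of kappa under H0::

        SE0 = sqrt(Pe + Pe^2 - sum_i pi. p.i (pi. + p.i)) / ((1 - Pe) sqrt(n))

    where pi. and p.i are the row and column marginal proportions.
    """
    _check_nonempty(crosstab)
    if crosstab.n < 2:
        raise UndefinedStatisticError("kappa significance needs n >= 2")
    n = crosstab.n
    pe = expected_agreement(crosstab)
    if pe >= 1.0:
        raise UndefinedStatisticError("kappa undefined: Pe = 1")
    kappa = cohens_kappa(crosstab)
    pr = crosstab.row_totals() / n
    pc = crosstab.col_totals() / n
    inner = pe + pe**2 - float((pr * pc * (pr + pc)).sum())
    if inner <= 0:
        raise UndefinedStatisticError("degenerate marginals: SE0 = 0")
    se0 = np.sqrt(inner) / ((1.0 - pe) * np.sqrt(n))
    z = kappa / se0
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p


def sensitivity_specificity(crosstab: CrossTab) -> DiagnosticResult:
    """Sensitivity/specificity of a binary table; NON_IDEAL is positive.

    With rows = clinical, columns = consensus and category order
    (IDEAL, NON_IDEAL): tn = counts[0,0], fp = counts[0,1],
    fn = counts[1,0], tp = counts[1,1].  A zero clinical row makes the
    corresponding measure ``None`` (undefined), never silently 0.
    """
    if crosstab.k != 2:
        raise ValidationError(f"need a 2x2 table, got K={crosstab.k}")
    m = crosstab.counts
    tn, fp, fn, tp = int(m[0, 0]), int(m[0, 1]), int(m[1, 0]), int(m[1, 1])
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return DiagnosticResult(sensitivity=sens, specificity=spec,
                            tp=tp, fn=fn, fp=fp, tn=tn)


_LANDIS_BANDS = (
    (0.00, "no agreement"),        # below 0.00
    (0.20, "slight agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.00, "almost perfect agreement"),
)


def landis_interpretation(value: float) -> str:
    """Landis-Koch verbal band for an agreement coefficient in [-1, 1].

    Bands: <0 no; 0-0.20 slight; 0.21-0.40 fair; 0.41-0.60 moderate;
    0.61-0.80 substantial; 0.81-1.00 almost perfect.  Each band is
    inclusive of its upper edge.
    """
    if not -1.0 <= value <= 1.0:
        raise ValidationError(f"agreement value out of [-1, 1]: {value}")
    if value < 0.0:
        return _LANDIS_BANDS[0][1]
    for upper, band in _LANDIS_BANDS[1:]:
        if value <= upper:
            return band
    return _LANDIS_BANDS[-1][1]  # pragma: no cover — value == 1 handled above


def agreement_report(
    crosstab: CrossTab, pabak_convention: str = "binary_formula"
) -> AgreementResult:
    """All agreement measures for one table, with the Landis band of the
    default-convention PABAK."""
    po = observed_agreement(crosstab)
    pe = expected_agreement(crosstab)
    pb = pabak(crosstab, "binary_formula")
    pm = pabak(crosstab, "multicategory")
    try:
        kappa = cohens_kappa(crosstab)
        z, p = kappa_significance(crosstab)
    except UndefinedStatisticError:
        # single-category strata: kappa has no chance correction to make
        kappa = cohens_kappa(crosstab) if pe < 1.0 else None
        z, p = None, None
    headline = pb if pabak_convention == "binary_formula" else pm
    return AgreementResult(po=po, pe=pe, kappa=kappa, pabak_binary=pb,
                           pabak_multicat=pm, z=z, p=p,
                           landis=landis_interpretation(headline))
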