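"""Domain types and I/O for panel rating data and cross-tabulations.

The study design this package analyses is a complete block: a panel of R
raters each assigns one of four standing-posture categories (the Kendall
classification: ideal, kyphosis-lordosis, sway back, flat back) plus a
1-5 confidence score to every item, where an item is one image rendered
in one of two variants -- silhouette (S) or grayscale (G).  A separate
clinical reference label (visual inspection + palpation by experienced
physical therapists) exists per image and serves as the ground truth the
panel's consensus is compared against.

Ratings travel as long/tidy CSV (one record per row); cross-tabulations
as labeled JSON or CSV matrices.  The study's published cross-tabulation
matrices ship as packaged JSON fixtures, retrievable via
:func:`study_crosstab`.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "BinaryClass",
    "Variant",
    "RatingRecord",
    "RatingTable",
    "ReferenceLabels",
    "CrossTab",
    "BINARY_CATEGORIES",
    "FOUR_CATEGORIES",
    "ValidationError",
    "CompletenessError",
    "read_ratings",
    "write_ratings",
    "read_reference_labels",
    "write_reference_labels",
    "read_crosstab",
    "write_crosstab",
    "study_crosstab",
    "study_crosstab_keys",
]


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class CompletenessError(ValidationError):
    """A rating table is not a complete rater x item block."""


class Category(enum.Enum):
    """Four-category Kendall posture classification, in canonical order."""

    IDEAL = "IDEAL"
    KL = "KL"  # kyphosis-lordosis
    SB = "SB"  # sway back
    FB = "FB"  # flat back

    @property
    def order(self) -> int:
        return _CATEGORY_ORDER[self]

    def __lt__(self, other: "Category") -> bool:
        if not isinstance(other, Category):
            return NotImplemented
        return self.order < other.order

    def to_binary(self) -> "BinaryClass":
        return BinaryClass.IDEAL if self is Category.IDEAL else BinaryClass.NON_IDEAL

    @classmethod
    def parse(cls, token: str) -> "Category":
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown posture category {token!r}") from None


_CATEGORY_ORDER = {c: i for i, c in enumerate(Category)}


class BinaryClass(enum.Enum):
    """Ideal vs non-ideal collapse; NON_IDEAL is the positive class."""

    IDEAL = "IDEAL"
    NON_IDEAL = "NON_IDEAL"


class Variant(enum.Enum):
    """Image rendering presented to the panel: silhouette or grayscale."""

    S = "S"
    G = "G"

    @classmethod
    def parse(cls, token: str) -> "Variant":
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown image variant {token!r}") from None


FOUR_CATEGORIES: tuple[str, ...] = tuple(c.value for c in Category)
BINARY_CATEGORIES: tuple[str, ...] = tuple(b.value for b in BinaryClass)

CONFIDENCE_LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class RatingRecord:
    """One rater's categorical choice and confidence for one item."""

    rater_id: str
    experience_years: float
    image_id: str
    variant: Variant
    category: Category
    confidence: int

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(
                f"confidence must be in {CONFIDENCE_LEVELS}, got {self.confidence!r}"
            )
        if self.experience_years < 0:
            raise ValidationError(
                f"experience_years must be non-negative, got {self.experience_years!r}"
            )

    @property
    def item(self) -> tuple[str, Variant]:
        return (self.image_id, self.variant)


class RatingTable:
    """A validated complete block of :class:`RatingRecord`.

    Invariants enforced at construction:

    * exactly one record per (rater, image, variant) -- duplicates rejected;
    * every rater rates every item -- missing cells rejected;
    * a rater's ``experience_years`` is constant across their rows.
    """

    def __init__(self, records: Iterable[RatingRecord]):
        records = tuple(records)
        if not records:
            raise ValidationError("rating table must contain at least one record")
        seen: dict[tuple[str, str, Variant], RatingRecord] = {}
        experience: dict[str, float] = {}
        for rec in records:
            key = (rec.rater_id, rec.image_id, rec.variant)
            if key in seen:
                raise ValidationError(
                    f"duplicate record for rater {rec.rater_id!r}, "
                    f"item ({rec.image_id!r}, {rec.variant.value})"
                )
            seen[key] = rec
            prev = experience.setdefault(rec.rater_id, rec.experience_years)
            if prev != rec.experience_years:
                raise ValidationError(
                    f"rater {rec.rater_id!r} has inconsistent experience_years "
                    f"({prev} vs {rec.experience_years})"
                )
        raters = sorted(experience)
        items = sorted({(r.image_id, r.variant) for r in records},
                       key=lambda it: (it[0], it[1].value))
        expected = len(raters) * len(items)
        if len(records) != expected:
            missing = [
                (rid, img, var.value)
                for rid in raters
                for (img, var) in items
                if (rid, img, var) not in seen
            ]
            raise CompletenessError(
                f"incomplete block: {len(records)} records for {len(raters)} raters x "
                f"{len(items)} items (expected {expected}); missing cells e.g. "
                f"{missing[:5]}"
            )
        self._records = records
        self._experience = experience
        self._items = items
        self._by_item: dict[tuple[str, Variant], list[RatingRecord]] = {}
        for rec in records:
            self._by_item.setdefault(rec.item, []).append(rec)

    @property
    def records(self) -> tuple[RatingRecord, ...]:
        return self._records

    @property
    def raters(self) -> Mapping[str, float]:
        """Map rater_id -> experience in years."""
        return dict(self._experience)

    @property
    def n_raters(self) -> int:
        return len(self._experience)

    @property
    def items(self) -> list[tuple[str, Variant]]:
        return list(self._items)

    @property
    def image_ids(self) -> list[str]:
        return sorted({img for img, _ in self._items})

    def records_for_item(self, image_id: str, variant: Variant) -> list[RatingRecord]:
        try:
            return list(self._by_item[(image_id, variant)])
        except KeyError:
            raise KeyError(f"no records for item ({image_id!r}, {variant.value})") from None

    def subset_raters(self, rater_ids: Iterable[str]) -> "RatingTable":
        """Restrict to a rater subgroup (e.g. an experience stratum)."""
        keep = set(rater_ids)
        unknown = keep - set(self._experience)
        if unknown:
            raise ValidationError(f"unknown rater ids: {sorted(unknown)}")
        if not keep:
            raise ValidationError("rater subset must be non-empty")
        return RatingTable(r for r in self._records if r.rater_id in keep)

    def split_by_experience(
        self, threshold_years: float = 10.0, senior_is_inclusive: bool = False
    ) -> tuple["RatingTable", "RatingTable"]:
        """Partition raters into junior/senior tables at ``threshold_years``.

        Raters exactly at the threshold go to the junior group unless
        ``senior_is_inclusive`` is set (the study's >10y / <10y groups
        leave the boundary undefined; strict ``>`` is the default).
        """
        if threshold_years <= 0:
            raise ValidationError("threshold_years must be positive")
        senior = {
            rid for rid, yrs in self._experience.items()
            if (yrs >= threshold_years if senior_is_inclusive else yrs > threshold_years)
        }
        junior = set(self._experience) - senior
        if not junior or not senior:
            raise ValidationError(
                f"experience threshold {threshold_years} leaves an empty group "
                f"(junior={len(junior)}, senior={len(senior)})"
            )
        return self.subset_raters(junior), self.subset_raters(senior)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rater_id": [r.rater_id for r in self._records],
                "experience_years": [r.experience_years for r in self._records],
                "image_id": [r.image_id for r in self._records],
                "variant": [r.variant.value for r in self._records],
                "category": [r.category.value for r in self._records],
                "confidence": [r.confidence for r in self._records],
            }
        )

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingTable):
            return NotImplemented
        return sorted(self._records, key=_record_key) == sorted(other._records, key=_record_key)


def _record_key(r: RatingRecord):
    return (r.rater_id, r.image_id, r.variant.value)


class ReferenceLabels:
    """Clinical reference label (the ground-truth category) per image."""

    def __init__(self, labels: Mapping[str, Category]):
        if not labels:
            raise ValidationError("reference labels must be non-empty")
        self._labels = {str(k): v for k, v in labels.items()}

    def __getitem__(self, image_id: str) -> Category:
        return self._labels[image_id]

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceLabels):
            return NotImplemented
        return self._labels == other._labels

    @property
    def image_ids(self) -> list[str]:
        return sorted(self._labels)

    def as_dict(self) -> dict[str, Category]:
        return dict(self._labels)

    def validate_against(self, table: RatingTable) -> None:
        """Every rated image must carry a reference label.

        Labels for images never rated are tolerated with a warning (a
        reference set may legitimately be wider than one questionnaire).
        """
        rated = set(table.image_ids)
        missing = rated - set(self._labels)
        if missing:
            raise ValidationError(
                f"images without a reference label: {sorted(missing)[:5]}"
            )
        extra = set(self._labels) - rated
        if extra:
            warnings.warn(
                f"{len(extra)} reference labels have no ratings (e.g. "
                f"{sorted(extra)[:3]})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CrossTab:
    """K x K contingency table: reference labels on rows, consensus on columns."""

    categories: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError(f"counts must be square, got shape {counts.shape}")
        if counts.shape[0] != len(self.categories):
            raise ValidationError(
                f"{len(self.categories)} categories but counts shape {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(int)
            if not np.array_equal(as_int, counts):
                raise ValidationError("counts must be integers")
            counts = as_int
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def k(self) -> int:
        return len(self.categories)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.categories),
                            columns=list(self.categories))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossTab):
            return NotImplemented
        return self.categories == other.categories and np.array_equal(
            self.counts, other.counts
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray needs explicit hash
        return hash((self.categories, self.counts.tobytes()))


# ---------------------------------------------------------------------------
# ratings CSV I/O

_RATING_COLUMNS = ["rater_id", "experience_years", "image_id", "variant",
                   "category", "confidence"]


def read_ratings(path: str | Path) -> RatingTable:
    """Read a long-format ratings CSV into a validated :class:`RatingTable`.

    Expected columns: rater_id, experience_years, image_id, variant,
    category, confidence.  Category and variant tokens are
    case-insensitive.  Raises :class:`ValidationError` naming the
    offending line for malformed rows, and :class:`CompletenessError`
    when the block is incomplete.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            records.append(
                RatingRecord(
                    rater_id=str(row.rater_id),
                    experience_years=float(row.experience_years),
                    image_id=str(row.image_id),
                    variant=Variant.parse(row.variant),
                    category=Category.parse(row.category),
                    confidence=_parse_confidence(row.confidence),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path}, line {idx}: {exc}") from exc
    return RatingTable(records)


def _parse_confidence(token) -> int:
    value = float(token)
    if not value.is_integer():
        raise ValidationError(f"confidence must be an integer, got {token!r}")
    return int(value)


def write_ratings(table: RatingTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_reference_labels(path: str | Path) -> ReferenceLabels:
    """Read a two-column CSV (image_id, category) of clinical labels."""
    df = pd.read_csv(path, dtype=str)
    for col in ("image_id", "category"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    labels: dict[str, Category] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        if row.image_id in labels:
            raise ValidationError(f"{path}, line {idx}: duplicate image_id {row.image_id!r}")
        labels[str(row.image_id)] = Category.parse(row.category)
    return ReferenceLabels(labels)


def write_reference_labels(labels: ReferenceLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"image_id": labels.image_ids,
         "category": [labels[i].value for i in labels.image_ids]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cross-tabulation I/O

def write_crosstab(crosstab: CrossTab, path: str | Path) -> None:
    """Write a cross-tabulation as labeled JSON (``.json``) or CSV matrix.

    The JSON dialect records the row/column semantics explicitly::

        {"categories": [...], "rows": "clinical", "cols": "imaging",
         "counts": [[...], ...]}
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "categories": list(crosstab.categories),
            "rows": "clinical",
            "cols": "imaging",
            "counts": crosstab.counts.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        crosstab.to_frame().to_csv(path, index_label="clinical\\imaging")


def read_crosstab(path: str | Path) -> CrossTab:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return CrossTab(tuple(payload["categories"]),
                        np.asarray(payload["counts"], dtype=int))
    df = pd.read_csv(path, index_col=0)
    cats = tuple(df.columns)
    if tuple(df.index) != cats:
        raise ValidationError(f"{path}: row labels {tuple(df.index)} != column labels {cats}")
    return CrossTab(cats, df.to_numpy(dtype=int))


# ---------------------------------------------------------------------------
# packaged study fixtures

STUDY_TABLE_IDS = ("table1", "table2", "table3")
STUDY_STRATA = ("all", "low_entropy", "high_entropy", "lt10y", "gt10y")


def _load_study_tables() -> dict[tuple[str, str, str], CrossTab]:
    text = resources.files("postagree.data").joinpath("study_tables.json").read_text()
    raw = json.loads(text)
    out: dict[tuple[str, str, str], CrossTab] = {}
    for entry in raw["tables"]:
        key = (entry["table_id"], entry["variant"], entry["stratum"])
        out[key] = CrossTab(tuple(entry["categories"]),
                            np.asarray(entry["counts"], dtype=int))
    return out


_STUDY_TABLES: dict[tuple[str, str, str], CrossTab] | None = None


def study_crosstab(table_id: str, variant: str | Variant, stratum: str = "all") -> CrossTab:
    """Return one of the study's published cross-tabulation matrices.

    ``table_id`` is ``table1`` (full panel, 4-category), ``table2``
    (entropy strata, binary) or ``table3`` (experience strata, binary);
    ``variant`` is ``S`` or ``G``; ``stratum`` is ``all``,
    ``low_entropy``/``high_entropy`` or ``lt10y``/``gt10y``.
    """
    global _STUDY_TABLES
    if _STUDY_TABLES is None:
        _STUDY_TABLES = _load_study_tables()
    variant = variant.value if isinstance(variant, Variant) else str(variant).upper()
    key = (table_id, variant, stratum)
    if key not in _STUDY_TABLES:
        raise KeyError(
            f"no study cross-tabulation for {key}; available: "
            f"{sorted(_STUDY_TABLES)}"
        )
    return _STUDY_TABLES[key]


def study_crosstab_keys() -> list[tuple[str, str, str]]:
    """All (table_id, variant, stratum) keys of the shipped fixtures."""
    global _STUDY_TABLES
    if _STUDY_TABLES is None:
        _STUDY_TABLES = _load_study_tables()
    return sorted(_STUDY_TABLES)
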