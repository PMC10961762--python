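"""Shannon entropy of panel votes and the low/high-entropy item split.

The entropy of an item's vote distribution measures how scattered the
panel's assessments are: 0 bits when the panel is unanimous, log2(4) = 2
bits when the four categories receive equal votes.  Items are split into
low- and high-entropy halves at the median; the low half is the
candidate pool for reliable training labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Category, RatingTable, ValidationError, Variant
from .consensus import tally_votes

__all__ = ["Split", "EntropyProfile", "shannon_entropy", "entropy_profile",
           "median_split"]


class Split(enum.Enum):
    LOW = "LOW"
    HIGH = "HIGH"


def shannon_entropy(vote_counts: Mapping[Category, int] | Sequence[int]) -> float:
    """Entropy in bits of a categorical vote distribution.

    H = -sum_c p_c log2 p_c with p_c = count_c / total and 0*log 0 := 0.
    Bounded by log2(K); 2.0 for the four posture categories.
    """
    if isinstance(vote_counts, Mapping):
        counts = np.array([vote_counts.get(c, 0) for c in Category], dtype=float)
    else:
        counts = np.asarray(list(vote_counts), dtype=float)
    if (counts < 0).any():
        raise ValidationError("vote counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("cannot compute entropy of zero votes")
    # scipy normalises and applies the 0*log0 convention
    return float(stats.entropy(counts, base=2))


@dataclass
class EntropyProfile:
    """Per-item vote entropy, optionally annotated with LOW/HIGH split."""

    frame: pd.DataFrame  # columns: image_id, variant, entropy_bits[, split]

    def entropies(self, variant: Variant) -> pd.Series:
        sub = self.frame[self.frame["variant"] == variant.value]
        return sub.set_index("image_id")["entropy_bits"]

    def items_in(self, variant: Variant, split: Split) -> list[str]:
        sub = self.frame
        mask = (sub["variant"] == variant.value) & (sub["split"] == split.value)
        return sorted(sub.loc[mask, "image_id"])

    def paired(self, va: Variant, vb: Variant) -> pd.DataFrame:
        """Per-image entropies of two variants aligned for a paired test."""
        a = self.entropies(va)
        b = self.entropies(vb)
        return pd.DataFrame({va.value: a, vb.value: b}).dropna()


def entropy_profile(table: RatingTable) -> EntropyProfile:
    """Compute the vote entropy of every item in a rating table."""
    rows = [
        {
            "image_id": image_id,
            "variant": variant.value,
            "entropy_bits": shannon_entropy(
                tally_votes(table.records_for_item(image_id, variant)).vote_counts
            ),
        }
        for image_id, variant in table.items
    ]
    frame = pd.DataFrame(rows)
    frame["split"] = pd.NA
    return EntropyProfile(frame)


def median_split(
    profile: EntropyProfile, variant: Variant
) -> tuple[list[str], list[str]]:
    """Split one variant's items into low/high-entropy halves.

    Items are sorted by ascending entropy, ties broken by ascending
    image_id (a stable, documented rule -- entropy ties at the median
    boundary must not make the split depend on input order).  For even n
    the halves are equal; for odd n LOW gets floor(n/2).  The profile's
    ``split`` column is filled in place for the variant.
    """
    ent = profile.entropies(variant)
    if len(ent) < 2:
        raise ValidationError(
            f"need at least 2 items in variant {variant.value} to split, got {len(ent)}"
        )
    order = sorted(ent.index, key=lambda img: (ent[img], img))
    n_low = len(order) // 2
    low, high = order[:n_low], order[n_low:]
    frame = profile.frame
    in_variant = frame["variant"] == variant.value
    frame.loc[in_variant & frame["image_id"].isin(low), "split"] = Split.LOW.value
    frame.loc[in_variant & frame["image_id"].isin(high), "split"] = Split.HIGH.value
    return low, high
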