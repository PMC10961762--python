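"""Majority-vote consensus labeling with confidence tie-breaking.

Each item receives the category chosen by the largest number of raters.
When the vote is tied, the tie is broken among the vote-tied categories
by the highest total confidence (the sum of the 1-5 confidence scores of
the raters who chose that category).  A residual double tie -- equal
votes and equal confidence totals -- falls back deterministically to the
first tied category in canonical order (IDEAL < KL < SB < FB) and is
flagged ``unresolved_tie`` so downstream analyses can exclude such items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import Category, RatingRecord, RatingTable, ValidationError, Variant

__all__ = ["VoteTally", "ConsensusLabel", "tally_votes", "consensus_label",
           "assign_labels", "consensus_frame"]

Item = tuple[str, Variant]


@dataclass(frozen=True)
class VoteTally:
    """Vote counts and per-category confidence totals for one item."""

    item: Item
    vote_counts: Mapping[Category, int]
    confidence_totals: Mapping[Category, int]
    n_raters: int

    def __post_init__(self) -> None:
        counts = {c: int(self.vote_counts.get(c, 0)) for c in Category}
        conf = {c: int(self.confidence_totals.get(c, 0)) for c in Category}
        if sum(counts.values()) != self.n_raters:
            raise ValidationError("vote counts must sum to n_raters")
        for c in Category:
            if counts[c] == 0 and conf[c] != 0:
                raise ValidationError(f"confidence total without votes for {c.value}")
            if counts[c] > 0 and conf[c] < counts[c]:
                raise ValidationError(
                    f"confidence total below vote count for {c.value} "
                    "(each confidence is at least 1)"
                )
        object.__setattr__(self, "vote_counts", counts)
        object.__setattr__(self, "confidence_totals", conf)


@dataclass(frozen=True)
class ConsensusLabel:
    """Consensus outcome for one item, with tie-break provenance."""

    item: Item
    label: Category
    tie_broken: bool
    unresolved_tie: bool
    tally: VoteTally


def tally_votes(records: Iterable[RatingRecord]) -> VoteTally:
    """Count votes and confidence totals for the records of one item.

    All records must belong to the same (image_id, variant) and come
    from distinct raters.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot tally an empty set of records")
    items = {r.item for r in records}
    if len(items) > 1:
        raise ValidationError(f"records span multiple items: {sorted_items(items)}")
    raters = [r.rater_id for r in records]
    if len(set(raters)) != len(raters):
        dupes = sorted({r for r in raters if raters.count(r) > 1})
        raise ValidationError(f"duplicate rater(s) in tally: {dupes}")
    counts = {c: 0 for c in Category}
    conf = {c: 0 for c in Category}
    for r in records:
        counts[r.category] += 1
        conf[r.category] += r.confidence
    return VoteTally(item=records[0].item, vote_counts=counts,
                     confidence_totals=conf, n_raters=len(records))


def sorted_items(items: Iterable[Item]) -> list[tuple[str, str]]:
    return sorted((img, var.value) for img, var in items)


def consensus_label(tally: VoteTally) -> ConsensusLabel:
    """Apply the majority rule with confidence tie-break to one tally."""
    if tally.n_raters < 1:
        raise ValidationError("tally has no votes")
    max_votes = max(tally.vote_counts.values())
    tied = [c for c in Category if tally.vote_counts[c] == max_votes]
    if len(tied) == 1:
        return ConsensusLabel(tally.item, tied[0], tie_broken=False,
                              unresolved_tie=False, tally=tally)
    max_conf = max(tally.confidence_totals[c] for c in tied)
    conf_tied = [c for c in tied if tally.confidence_totals[c] == max_conf]
    # canonical-order fallback on a double tie; Category iterates canonically
    label = conf_tied[0]
    return ConsensusLabel(tally.item, label, tie_broken=True,
                          unresolved_tie=len(conf_tied) > 1, tally=tally)


def assign_labels(
    table: RatingTable, rater_ids: Iterable[str] | None = None
) -> dict[Item, ConsensusLabel]:
    """One consensus label per (image_id, variant) in the table.

    ``rater_ids`` restricts the vote to a subgroup (e.g. an experience
    stratum); the identical majority rule is applied to the subset's
    votes.
    """
    if rater_ids is not None:
        table = table.subset_raters(rater_ids)
    return {
        item: consensus_label(tally_votes(table.records_for_item(*item)))
        for item in table.items
    }


def consensus_frame(labels: Mapping[Item, ConsensusLabel]) -> pd.DataFrame:
    """Flatten consensus labels to the output CSV schema."""
    rows = []
    for (image_id, variant), lab in sorted(
        labels.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        row = {"image_id": image_id, "variant": variant.value,
               "label": lab.label.value}
        for c in Category:
            row[f"vote_{c.value.lower()}"] = lab.tally.vote_counts[c]
        for c in Category:
            row[f"conf_{c.value.lower()}"] = lab.tally.confidence_totals[c]
        row["tie_broken"] = lab.tie_broken
        row["unresolved_tie"] = lab.unresolved_tie
        rows.append(row)
    return pd.DataFrame(rows)
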