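"""Synthetic rating-panel generator.

The study's raw 28-rater x 56-image response matrix is not published, so
every rating-level stage of the pipeline is exercised on simulated data
with the same design: a complete block of R raters scoring I images in
two variants (silhouette and grayscale), a latent true category per
image balanced across the four postures, per-rater accuracy that may
depend on experience, and a confidence score drawn conditional on
whether the vote was correct.

The generative law is a latent-class model with per-rater confusion:
rater r's vote for an item with truth t equals t with probability
``accuracy(r)`` and otherwise falls on a wrong category drawn from a
confusion kernel (uniform over the other three by default, or confined
to the non-ideal block to emulate panels that recognise ideal posture
reliably but confuse the three non-ideal subtypes).  Votes are
independent across raters and items given the parameters; real panels
plausibly violate this (shared difficulty per image beyond the truth
label), which is why entropy varies less between items here than in the
study.

Defaults mirror the study scale: 28 raters (12 with more than 10 years'
experience, 16 with less), 7 images per category, both variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    Category,
    RatingRecord,
    RatingTable,
    ReferenceLabels,
    ValidationError,
    Variant,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_ratings",
           "recover_parameters"]

_CATEGORIES = tuple(Category)


def _check_probs(name: str, probs: Sequence[float], length: int) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.shape != (length,) or (arr < 0).any() or not np.isclose(arr.sum(), 1.0):
        raise ValidationError(
            f"{name} must be {length} non-negative probabilities summing to 1, got {probs}"
        )
    return arr


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic panel.

    ``junior_accuracy``/``senior_accuracy`` are the probabilities that a
    rater in the respective experience group picks the true category.
    ``confusion`` selects the error kernel: ``"uniform"`` spreads errors
    over the other three categories; ``"within_nonideal"`` keeps errors
    on non-ideal truths inside the non-ideal block (errors on ideal
    truths necessarily leave it).  Confidence scores 1-5 are drawn from
    ``confidence_correct`` when the vote matches the truth and
    ``confidence_incorrect`` otherwise, so correct votes are
    stochastically more confident.
    """

    n_raters: int = 28
    n_images_per_category: int = 7
    variants: tuple[Variant, ...] = (Variant.S, Variant.G)
    senior_fraction: float = 12 / 28
    junior_years_range: tuple[float, float] = (0.0, 10.0)
    senior_years_range: tuple[float, float] = (10.5, 25.0)
    junior_accuracy: float = 0.6
    senior_accuracy: float = 0.6
    confusion: str = "uniform"
    confidence_correct: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30, 0.35)
    confidence_incorrect: tuple[float, ...] = (0.25, 0.30, 0.25, 0.15, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValidationError("n_raters must be >= 1")
        if self.n_images_per_category < 1:
            raise ValidationError("n_images_per_category must be >= 1")
        if not 0.0 <= self.senior_fraction <= 1.0:
            raise ValidationError("senior_fraction must be in [0, 1]")
        for name in ("junior_accuracy", "senior_accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.confusion not in ("uniform", "within_nonideal"):
            raise ValidationError(f"unknown confusion kernel {self.confusion!r}")
        _check_probs("confidence_correct", self.confidence_correct, 5)
        _check_probs("confidence_incorrect", self.confidence_incorrect, 5)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SyntheticDataset:
    """A simulated panel plus the latent truth that generated it."""

    table: RatingTable
    reference: ReferenceLabels
    config: SimulationConfig


def _wrong_category(truth: Category, kernel: str, rng: np.random.Generator) -> Category:
    others = [c for c in _CATEGORIES if c is not truth]
    if kernel == "within_nonideal" and truth is not Category.IDEAL:
        others = [c for c in others if c is not Category.IDEAL]
    return others[rng.integers(len(others))]


def simulate_ratings(config: SimulationConfig) -> SyntheticDataset:
    """Draw a complete synthetic rating block; reproducible given seed."""
    rng = np.random.default_rng(config.seed)
    n_senior = int(round(config.senior_fraction * config.n_raters))
    width = max(2, len(str(config.n_raters)))
    rater_ids = [f"r{i + 1:0{width}d}" for i in range(config.n_raters)]
    is_senior = np.array([i < n_senior for i in range(config.n_raters)])
    years = np.where(
        is_senior,
        rng.uniform(*config.senior_years_range, size=config.n_raters),
        rng.uniform(*config.junior_years_range, size=config.n_raters),
    ).round(1)
    accuracy = np.where(is_senior, config.senior_accuracy, config.junior_accuracy)

    n_images = 4 * config.n_images_per_category
    iw = max(2, len(str(n_images)))
    image_ids = [f"img{i + 1:0{iw}d}" for i in range(n_images)]
    truth = {
        img: _CATEGORIES[i % 4]  # balanced across the four postures
        for i, img in enumerate(image_ids)
    }

    conf_correct = np.asarray(config.confidence_correct)
    conf_incorrect = np.asarray(config.confidence_incorrect)
    records = []
    for ridx, rid in enumerate(rater_ids):
        for img in image_ids:
            for variant in config.variants:
                correct = rng.random() < accuracy[ridx]
                if correct:
                    category = truth[img]
                    conf = rng.choice(5, p=conf_correct) + 1
                else:
                    category = _wrong_category(truth[img], config.confusion, rng)
                    conf = rng.choice(5, p=conf_incorrect) + 1
                records.append(
                    RatingRecord(
                        rater_id=rid,
                        experience_years=float(years[ridx]),
                        image_id=img,
                        variant=variant,
                        category=category,
                        confidence=int(conf),
                    )
                )
    return SyntheticDataset(
        table=RatingTable(records),
        reference=ReferenceLabels(truth),
        config=config,
    )


def recover_parameters(dataset: SyntheticDataset) -> dict:
    """Empirical accuracy per rater and vote distribution per item.

    Used to validate the generator: at moderate item counts every
    rater's empirical accuracy concentrates around the generating
    accuracy (binomial), and vote distributions reflect the confusion
    kernel.
    """
    truth = dataset.reference
    correct: dict[str, list[bool]] = {}
    for rec in dataset.table.records:
        correct.setdefault(rec.rater_id, []).append(rec.category is truth[rec.image_id])
    rater_accuracy = {rid: float(np.mean(v)) for rid, v in correct.items()}

    rows = []
    for image_id, variant in dataset.table.items:
        recs = dataset.table.records_for_item(image_id, variant)
        n = len(recs)
        row = {"image_id": image_id, "variant": variant.value,
               "truth": truth[image_id].value}
        for c in _CATEGORIES:
            row[f"p_{c.value.lower()}"] = sum(r.category is c for r in recs) / n
        rows.append(row)
    return {
        "rater_accuracy": rater_accuracy,
        "item_vote_distributions": pd.DataFrame(rows),
    }
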