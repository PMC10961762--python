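import itertools

import pytest

from postagree import (
    Category,
    RatingRecord,
    RatingTable,
    ReferenceLabels,
    SimulationConfig,
    Variant,
    simulate_ratings,
)


def make_record(rater="r1", years=5.0, image="img1", variant=Variant.S,
                category=Category.IDEAL, confidence=3):
    return RatingRecord(rater_id=rater, experience_years=years, image_id=image,
                        variant=variant, category=category, confidence=confidence)


def block_table(votes_by_image, n_raters, variants=(Variant.S,), years=None,
                confidence=3):
    """Complete block where image ``i`` receives the vote sequence
    ``votes_by_image[i]`` (length n_raters, Category entries) in every
    variant.  ``years`` maps rater index -> experience (default 5.0)."""
    records = []
    for img, votes in votes_by_image.items():
        assert len(votes) == n_raters
        for ridx, cat in enumerate(votes):
            for var in variants:
                records.append(
                    RatingRecord(
                        rater_id=f"r{ridx + 1:02d}",
                        experience_years=(years or {}).get(ridx, 5.0),
                        image_id=img,
                        variant=var,
                        category=cat,
                        confidence=confidence,
                    )
                )
    return RatingTable(records)


def unanimous_table(truth, n_raters=4, variants=(Variant.S, Variant.G)):
    """Every rater votes the true category of every image."""
    return block_table(
        {img: [cat] * n_raters for img, cat in truth.items()},
        n_raters=n_raters, variants=variants,
    )


def balanced_truth(n_per_category=2):
    cats = itertools.cycle(Category)
    return {f"img{i + 1:02d}": next(cats) for i in range(4 * n_per_category)}


@pytest.fixture(scope="session")
def study_scale_dataset():
    """Synthetic panel at the study's scale: 28 raters, 28 images, S+G."""
    return simulate_ratings(
        SimulationConfig(seed=20240322, junior_accuracy=0.6, senior_accuracy=0.7)
    )


@pytest.fixture()
def small_reference():
    return ReferenceLabels(balanced_truth(1))
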