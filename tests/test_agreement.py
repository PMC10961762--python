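"""Agreement statistics: Po/Pe, Cohen's kappa, PABAK, the Fleiss-SE0
significance test, sensitivity/specificity, and Landis bands.

The parametrized expectations below are the study's published values,
all exact ratios of the fixture table entries.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from postagree import (
    BINARY_CATEGORIES,
    Category,
    CrossTab,
    FOUR_CATEGORIES,
    ReferenceLabels,
    UndefinedStatisticError,
    ValidationError,
    Variant,
    agreement_report,
    assign_labels,
    build_crosstab,
    cohens_kappa,
    collapse_binary,
    expected_agreement,
    kappa_significance,
    landis_interpretation,
    observed_agreement,
    pabak,
    sensitivity_specificity,
    study_crosstab,
)
from conftest import block_table

# (table_id, variant, stratum, collapse) -> published pabak, kappa, sens, spec, p
BINARY_EXPECTATIONS = [
    ("table1", "S", "all", True, 0.5714, 0.4286, 18 / 21, 4 / 7, 0.0233),
    ("table1", "G", "all", True, 0.5000, 0.4167, 16 / 21, 5 / 7, 0.0228),
    ("table2", "S", "low_entropy", False, 0.8571, 0.7586, 11 / 11, 2 / 3, 0.0034),
    ("table2", "S", "high_entropy", False, 0.2857, 0.1860, 7 / 10, 2 / 4, 0.4805),
    ("table2", "G", "low_entropy", False, 0.8571, 0.8108, 10 / 10, 3 / 4, 0.0020),
    ("table2", "G", "high_entropy", False, 0.1429, 0.1429, 6 / 11, 2 / 3, 0.5148),
    ("table3", "S", "lt10y", False, 0.7857, 0.7273, 19 / 21, 6 / 7, 0.0001),
    ("table3", "S", "gt10y", False, 0.4286, 0.1579, 18 / 21, 2 / 7, 0.3927),
    ("table3", "G", "lt10y", False, 0.5000, 0.4167, 16 / 21, 5 / 7, 0.0228),
    ("table3", "G", "gt10y", False, 0.7143, 0.6190, 19 / 21, 5 / 7, 0.0011),
]


def fixture_binary(table_id, variant, stratum, collapse):
    ct = study_crosstab(table_id, variant, stratum)
    return collapse_binary(ct) if collapse else ct


class TestPublishedBinaryStatistics:
    @pytest.mark.parametrize(
        "table_id,variant,stratum,collapse,pb,kp,sens,spec,p", BINARY_EXPECTATIONS)
    def test_full_quadruple(self, table_id, variant, stratum, collapse,
                            pb, kp, sens, spec, p):
        ct = fixture_binary(table_id, variant, stratum, collapse)
        assert pabak(ct) == pytest.approx(pb, abs=5e-5)
        assert cohens_kappa(ct) == pytest.approx(kp, abs=5e-5)
        diag = sensitivity_specificity(ct)
        assert diag.sensitivity == pytest.approx(sens, abs=1e-12)
        assert diag.specificity == pytest.approx(spec, abs=1e-12)
        _, p_obs = kappa_significance(ct)
        assert p_obs == pytest.approx(p, abs=5e-5)

    def test_g_binary_z_statistic(self):
        ct = collapse_binary(study_crosstab("table1", "G", "all"))
        z, _ = kappa_significance(ct)
        assert z == pytest.approx(2.277, abs=5e-4)


class TestPublishedFourCategoryStatistics:
    @pytest.mark.parametrize("variant,pb,kp", [
        ("S", -0.1429, 0.2381),
        ("G", -0.2857, 0.1429),
    ])
    def test_pabak_and_kappa(self, variant, pb, kp):
        ct = study_crosstab("table1", variant, "all")
        assert pabak(ct, "binary_formula") == pytest.approx(pb, abs=5e-5)
        assert cohens_kappa(ct) == pytest.approx(kp, abs=5e-5)

    @pytest.mark.parametrize("variant", ["S", "G"])
    def test_uniform_row_marginals_make_kappa_the_multicategory_pabak(self, variant):
        """With 7 items per clinical category the row marginals are
        uniform, so Cohen's kappa collapses to (K*Po - 1)/(K - 1)."""
        ct = study_crosstab("table1", variant, "all")
        assert cohens_kappa(ct) == pytest.approx(
            pabak(ct, "multicategory"), abs=1e-12)


class TestKappaAndPabak:
    def test_kappa_zero_when_po_equals_pe(self):
        ct = CrossTab(BINARY_CATEGORIES, np.array([[1, 1], [1, 1]]))
        assert cohens_kappa(ct) == pytest.approx(0.0)
        z, p = kappa_significance(ct)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_agreement(self):
        ct = CrossTab(BINARY_CATEGORIES, np.array([[3, 0], [0, 9]]))
        assert cohens_kappa(ct) == pytest.approx(1.0)
        assert pabak(ct) == pytest.approx(1.0)

    def test_single_category_table_is_undefined(self):
        ct = CrossTab(BINARY_CATEGORIES, np.array([[5, 0], [0, 0]]))
        with pytest.raises(UndefinedStatisticError, match="Pe = 1"):
            cohens_kappa(ct)

    def test_pabak_conventions(self):
        ct = study_crosstab("table1", "S", "all")  # Po = 12/28
        assert pabak(ct, "binary_formula") == pytest.approx(2 * 12 / 28 - 1)
        assert pabak(ct, "multicategory") == pytest.approx((4 * 12 / 28 - 1) / 3)
        with pytest.raises(ValueError, match="convention"):
            pabak(ct, "bogus")

    def test_pabak_zero_at_half_agreement(self):
        ct = CrossTab(BINARY_CATEGORIES, np.array([[3, 1], [2, 0]]))
        assert observed_agreement(ct) == pytest.approx(0.5)
        assert pabak(ct) == pytest.approx(0.0)

    def test_binary_conventions_coincide(self):
        ct = collapse_binary(study_crosstab("table1", "G", "all"))
        assert pabak(ct, "binary_formula") == pytest.approx(
            pabak(ct, "multicategory"))

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.lists(st.integers(0, 30), min_size=4, max_size=4),
                    min_size=4, max_size=4).filter(lambda m: sum(map(sum, m)) > 0),
           st.permutations([0, 1, 2, 3]))
    def test_invariant_under_simultaneous_category_permutation(self, counts, perm):
        m = np.array(counts)
        ct = CrossTab(FOUR_CATEGORIES, m)
        permuted = CrossTab(FOUR_CATEGORIES, m[np.ix_(perm, perm)])
        assert pabak(permuted) == pytest.approx(pabak(ct), abs=1e-12)
        try:
            k = cohens_kappa(ct)
        except UndefinedStatisticError:
            return
        assert cohens_kappa(permuted) == pytest.approx(k, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.lists(st.integers(0, 30), min_size=3, max_size=3),
                    min_size=3, max_size=3).filter(lambda m: sum(map(sum, m)) > 0))
    def test_po_pe_match_explicit_double_loops(self, counts):
        """Oracle: recompute Po and Pe with explicit loops."""
        m = np.array(counts)
        n = m.sum()
        ct = CrossTab(("A", "B", "C"), m)
        po = sum(m[i, i] for i in range(3)) / n
        pe = sum(
            (sum(m[i, j] for j in range(3)) / n) * (sum(m[j, i] for j in range(3)) / n)
            for i in range(3)
        )
        assert observed_agreement(ct) == pytest.approx(po, abs=1e-12)
        assert expected_agreement(ct) == pytest.approx(pe, abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.lists(st.integers(0, 20), min_size=2, max_size=2),
                    min_size=2, max_size=2))
    def test_kappa_matches_sklearn_on_expanded_labels(self, counts):
        """Independent route: expand the table into paired label lists
        and compare with scikit-learn's Cohen's kappa."""
        m = np.array(counts)
        if m.sum() == 0:
            return
        ref, cons = [], []
        for i in range(2):
            for j in range(2):
                ref += [i] * m[i, j]
                cons += [j] * m[i, j]
        ct = CrossTab(BINARY_CATEGORIES, m)
        try:
            ours = cohens_kappa(ct)
        except UndefinedStatisticError:
            return
        theirs = cohen_kappa_score(ref, cons, labels=[0, 1])
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestSensitivitySpecificity:
    def test_non_ideal_is_the_positive_class(self):
        ct = collapse_binary(study_crosstab("table1", "S", "all"))
        d = sensitivity_specificity(ct)
        assert (d.tn, d.fp, d.fn, d.tp) == (4, 3, 3, 18)

    def test_zero_ideal_row_leaves_specificity_undefined(self):
        ct = CrossTab(BINARY_CATEGORIES, np.array([[0, 0], [0, 5]]))
        d = sensitivity_specificity(ct)
        assert d.sensitivity == pytest.approx(1.0)
        assert d.specificity is None

    def test_requires_two_by_two(self):
        with pytest.raises(ValidationError, match="2x2"):
            sensitivity_specificity(study_crosstab("table1", "S", "all"))


class TestLandisBands:
    @pytest.mark.parametrize("value,band", [
        (-1.0, "no agreement"),
        (-0.14, "no agreement"),
        (-1e-9, "no agreement"),
        (0.0, "slight agreement"),
        (0.20, "slight agreement"),
        (0.21, "fair agreement"),
        (0.40, "fair agreement"),
        (0.57, "moderate agreement"),
        (0.60, "moderate agreement"),
        (0.79, "substantial agreement"),
        (0.86, "almost perfect agreement"),
        (1.0, "almost perfect agreement"),
    ])
    def test_band_boundaries(self, value, band):
        assert landis_interpretation(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            landis_interpretation(1.5)


class TestBuildAndCollapse:
    def test_crosstab_from_label_maps(self, small_reference):
        table = block_table(
            {"img01": [Category.IDEAL] * 3, "img02": [Category.SB] * 3,
             "img03": [Category.SB] * 3, "img04": [Category.FB] * 3},
            n_raters=3)
        ct = build_crosstab(small_reference, assign_labels(table), Variant.S)
        # truth: img01 IDEAL, img02 KL, img03 SB, img04 FB
        assert ct.counts[0, 0] == 1          # IDEAL -> IDEAL
        assert ct.counts[1, 2] == 1          # KL mislabeled SB
        assert ct.counts[2, 2] == 1          # SB -> SB
        assert ct.counts[3, 3] == 1
        assert ct.n == 4

    def test_binary_crosstab_equals_collapse_of_four(self, study_scale_dataset):
        labels = assign_labels(study_scale_dataset.table)
        ref = study_scale_dataset.reference
        for variant in (Variant.S, Variant.G):
            four = build_crosstab(ref, labels, variant, FOUR_CATEGORIES)
            two = build_crosstab(ref, labels, variant, BINARY_CATEGORIES)
            assert two == collapse_binary(four)

    def test_identical_maps_give_diagonal(self, small_reference):
        table = block_table(
            {img: [small_reference[img]] * 3 for img in small_reference.image_ids},
            n_raters=3)
        ct = build_crosstab(small_reference, assign_labels(table), Variant.S)
        assert np.trace(ct.counts) == ct.n == 4

    def test_missing_reference_label_rejected(self):
        table = block_table({"imgX": [Category.KL] * 3}, n_raters=3)
        ref = ReferenceLabels({"other": Category.KL})
        with pytest.raises(ValidationError):
            build_crosstab(ref, assign_labels(table), Variant.S)

    def test_no_items_for_variant_rejected(self, small_reference):
        table = block_table({"img01": [Category.KL] * 3}, n_raters=3)
        with pytest.raises(ValidationError, match="no consensus labels"):
            build_crosstab(small_reference, assign_labels(table), Variant.G)

    def test_collapse_of_diagonal(self):
        ct = CrossTab(FOUR_CATEGORIES, np.diag([7, 7, 7, 7]))
        assert collapse_binary(ct).counts.tolist() == [[7, 0], [0, 21]]

    def test_collapse_requires_canonical_four(self):
        ct = CrossTab(BINARY_CATEGORIES, np.array([[1, 0], [0, 1]]))
        with pytest.raises(ValidationError):
            collapse_binary(ct)


class TestAgreementReport:
    def test_report_fields_cohere(self):
        ct = collapse_binary(study_crosstab("table1", "S", "all"))
        rep = agreement_report(ct)
        assert rep.po == pytest.approx(22 / 28)
        assert rep.landis == "moderate agreement"
        assert rep.pabak_binary == pytest.approx(rep.pabak_multicat)  # K = 2

    def test_headline_follows_convention(self):
        ct = study_crosstab("table1", "S", "all")
        binary_rep = agreement_report(ct, "binary_formula")
        multi_rep = agreement_report(ct, "multicategory")
        assert binary_rep.landis == "no agreement"       # PABAK -0.14
        assert multi_rep.landis == "fair agreement"      # (4*Po-1)/3 = 0.238
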