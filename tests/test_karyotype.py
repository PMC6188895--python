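import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsaorta.karyotype import (
    AAFProfile,
    BandConfig,
    IscnParseError,
    ReadCountSite,
    SexChromCategory,
    classify_second_sex_chromosome,
    compute_aaf_profile,
    dichotomize_copy_number,
    estimate_mosaic_fraction,
    locus_copy_number,
    mosaic_fraction_linear_fit,
    parse_iscn,
)
from tsaorta.synthetic import (
    simulate_x_read_counts,
    simulate_y_read_counts,
)


def _profile(aafs, depth=1000):
    """Noise-free profile with sites at exact allele fractions."""
    sites = [
        ReadCountSite("X", 1000 + 1000 * i, int(round(depth * (1 - a))),
                      int(round(depth * a)))
        for i, a in enumerate(aafs)
    ]
    return AAFProfile(sites)


class TestAafProfile:
    @pytest.mark.parametrize(
        "ref,alt,expected", [(30, 30, 0.5), (70, 0, 0.0), (40, 20, 1 / 3)]
    )
    def test_exact_fractions(self, ref, alt, expected):
        prof = compute_aaf_profile([ReadCountSite("X", 100, ref, alt)], min_depth=1)
        assert prof.aaf[0] == pytest.approx(expected, abs=1e-15)

    def test_min_depth_filter(self):
        sites = [ReadCountSite("X", 1, 3, 2), ReadCountSite("X", 2, 50, 50)]
        prof = compute_aaf_profile(sites, min_depth=10)
        assert len(prof) == 1 and prof.sites[0].position == 2

    def test_empty_input_is_empty_profile(self):
        assert len(compute_aaf_profile([], min_depth=10)) == 0

    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            AAFProfile([ReadCountSite("X", 5, 1, 1), ReadCountSite("X", 5, 1, 1)])


class TestClassification:
    @pytest.mark.parametrize(
        "iscn,expected",
        [
            ("45,X", SexChromCategory.MONOSOMY_X),
            ("46,XX", SexChromCategory.XX),
            ("46,XY", SexChromCategory.XY_MATERIAL),
            ("45,X[50%]/46,XX[50%]", SexChromCategory.XX_MOSAIC),
        ],
    )
    def test_pure_profiles_classified(self, iscn, expected):
        k = parse_iscn(iscn)
        x = compute_aaf_profile(simulate_x_read_counts(k, 300, 71, seed=11))
        y = compute_aaf_profile(
            simulate_y_read_counts(k, 50, 71, seed=11), min_depth=0
        )
        status = classify_second_sex_chromosome(x, y)
        assert status.category is expected

    def test_classification_accuracy_on_simulated_cohorts(self):
        # every replicate of the three reference karyotypes must classify
        # correctly at cohort-like depth and site counts
        for iscn, expected in [
            ("45,X", SexChromCategory.MONOSOMY_X),
            ("46,XX", SexChromCategory.XX),
            ("46,XY", SexChromCategory.XY_MATERIAL),
        ]:
            k = parse_iscn(iscn)
            for rep in range(20):
                x = compute_aaf_profile(
                    simulate_x_read_counts(k, 200, 71, seed=100 + rep)
                )
                y = compute_aaf_profile(
                    simulate_y_read_counts(k, 50, 71, seed=100 + rep), min_depth=0
                )
                assert classify_second_sex_chromosome(x, y).category is expected

    def test_xy_heterozygosity_confined_to_par(self):
        k = parse_iscn("46,XY")
        x = compute_aaf_profile(simulate_x_read_counts(k, 500, 71, seed=3))
        status = classify_second_sex_chromosome(x, None)
        # PAR shows heterozygosity, the rest of X none
        assert status.par_het_mass > 0.05
        assert status.het_band_mass < 0.05

    def test_empty_profile_undetermined(self):
        status = classify_second_sex_chromosome(AAFProfile([]), None)
        assert status.category is SexChromCategory.UNDETERMINED


class TestMosaicEstimate:
    def test_pure_xx_bands_give_zero(self):
        prof = _profile([0.5] * 40)
        est = estimate_mosaic_fraction(prof, method="median")
        assert est.fraction_45X == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_bands_invert_exactly(self):
        # f=0.5: bands at 2/3 and 1/3
        prof = _profile([1 / 3, 2 / 3] * 20, depth=3000)
        est = estimate_mosaic_fraction(prof, method="median")
        assert est.upper_band_estimate == pytest.approx(0.5, abs=1e-9)
        assert est.lower_band_estimate == pytest.approx(0.5, abs=1e-9)
        assert est.fraction_45X == pytest.approx(0.5, abs=1e-9)

    # at f > ~0.87 the bands leave the (0.10, 0.90) het window, so the
    # exact-inversion property holds on the window's interior
    @pytest.mark.parametrize("f", [0.1, 0.3, 0.6, 0.8])
    def test_expected_value_profiles_invert_exactly(self, f):
        u = 1 / (2 - f)
        l = (1 - f) / (2 - f)
        prof = _profile([l, u] * 25, depth=200000)
        est = estimate_mosaic_fraction(prof, method="median")
        assert est.fraction_45X == pytest.approx(f, abs=1e-4)

    def test_simulated_cohort_recovery(self):
        k = parse_iscn("45,X[30%]/46,XX[70%]")
        errs = []
        for rep in range(20):
            sites = simulate_x_read_counts(k, 300, 70, seed=500 + rep)
            est = estimate_mosaic_fraction(compute_aaf_profile(sites))
            errs.append(abs(est.fraction_45X - 0.3))
        assert np.mean(errs) < 0.05

    def test_too_few_informative_sites_undefined(self):
        prof = _profile([0.0, 1.0] * 30)
        est = estimate_mosaic_fraction(prof)
        assert not est.defined and est.n_informative_sites == 0

    def test_linear_fit_agrees_with_analytic_on_clean_bands(self):
        prof = _profile([1 / 3, 2 / 3] * 20, depth=3000)
        # the straight-line surrogate for the curved inversion carries
        # approximation error at interior f; it is a comparison method only
        est = mosaic_fraction_linear_fit(prof)
        assert est.fraction_45X == pytest.approx(0.5, abs=0.1)


class TestIscnParsing:
    def test_monosomy(self):
        k = parse_iscn("45,X")
        assert len(k.cell_lines) == 1
        assert k.cell_lines[0].n_intact_x == 1
        assert k.cell_lines[0].fraction == 1.0

    def test_mosaic_fractions(self):
        k = parse_iscn("45,X[30%]/46,XX[70%]")
        assert [cl.fraction for cl in k.cell_lines] == [0.30, 0.70]
        assert [cl.n_intact_x for cl in k.cell_lines] == [1, 2]

    def test_unlabeled_two_line_split(self):
        k = parse_iscn("45,X/46,XY")
        assert [cl.fraction for cl in k.cell_lines] == [0.5, 0.5]
        assert k.cell_lines[1].y_present

    def test_unparseable_token_named(self):
        with pytest.raises(IscnParseError, match="inv"):
            parse_iscn("46,X,inv(X)(p11q13)")

    def test_empty_string_rejected(self):
        with pytest.raises(IscnParseError):
            parse_iscn("  ")

    def test_format_parse_idempotent(self, cohort_karyotype_rows):
        for iscn, _ in cohort_karyotype_rows:
            k1 = parse_iscn(iscn)
            k2 = parse_iscn(k1.format())
            assert [
                (c.fraction, c.n_intact_x, c.y_present, c.structural_terms)
                for c in k1.cell_lines
            ] == [
                (c.fraction, c.n_intact_x, c.y_present, c.structural_terms)
                for c in k2.cell_lines
            ]


class TestLocusCopyNumber:
    def test_printed_copy_number_column_reproduced(self, cohort_karyotype_rows):
        for iscn, printed in cohort_karyotype_rows:
            assert locus_copy_number(parse_iscn(iscn)) == pytest.approx(
                printed, abs=1e-9
            ), iscn

    @pytest.mark.parametrize(
        "iscn,expected",
        [
            ("45,X[30%]/46,XX[70%]", 1.7),
            ("45,X[50%]/47,XXX[50%]", 2.0),
            ("45,X[82%]/46,X,del(Xp22.3p11.4)[18%]", 1.2),
            ("46,X,i(Xq)", 1.0),
        ],
    )
    def test_reference_cases(self, iscn, expected):
        assert locus_copy_number(parse_iscn(iscn)) == pytest.approx(expected)

    def test_bounded_by_per_line_extremes(self, cohort_karyotype_rows):
        from tsaorta.karyotype import TIMP1_LOCUS_HG19

        for iscn, _ in cohort_karyotype_rows:
            k = parse_iscn(iscn)
            per_line = [cl.x_locus_copies(TIMP1_LOCUS_HG19) for cl in k.cell_lines]
            value = locus_copy_number(k, rounding=None)
            assert min(per_line) - 0.021 <= value <= max(per_line) + 0.021

    @given(frac=st.integers(1, 99))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_cell_line_fractions(self, frac):
        k = parse_iscn(f"45,X[{frac}%]/46,XX[{100 - frac}%]")
        value = locus_copy_number(k, rounding=None)
        assert value == pytest.approx(frac / 100 + 2 * (100 - frac) / 100, abs=1e-9)


class TestDichotomize:
    @pytest.mark.parametrize(
        "copies,label",
        [(1.0, "1 copy"), (1.1, "1 copy"), (1.2, ">1 copy"), (1.7, ">1 copy"),
         (2.0, ">1 copy")],
    )
    def test_threshold(self, copies, label):
        assert dichotomize_copy_number(copies) == label
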