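"""Calibration fits, formula algebra and plate correction."""

import numpy as np
import pytest

from fucoquant.calibration import (
    DEFAULT_PLATE_CALIBRATION,
    PUBLISHED_BG_445,
    PUBLISHED_BG_663,
    PUBLISHED_FORMULA,
    BackgroundModel,
    SingularFitError,
    convert_specific_extinction,
    cuvette_to_plate,
    derive_extract_formula,
    expand_whole_cell_formula,
    fit_background,
    fit_extinction,
    fit_plate_calibration,
    plate_to_cuvette,
)
from fucoquant.spectral_model import dilution_series


class TestFitExtinction:
    def test_arnon_series_recovers_82_04(self):
        c = np.arange(1.0, 8.0)
        pairs = np.column_stack([c, 0.08204 * c])
        eps = fit_extinction(pairs, pigment="chl_a", wavelength=663.0)
        assert eps.value == pytest.approx(82.04, rel=1e-12)
        assert eps.source == "fitted"

    def test_identity_slope(self):
        c = np.array([1.0, 2.0, 3.0])
        eps = fit_extinction(np.column_stack([c, c / 1000.0]))
        assert eps.value == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "pigment, wavelength, expected",
        [
            ("chl_a", 445.0, 66.8),
            ("chl_a", 663.0, 82.04),
            ("fucoxanthin", 445.0, 156.54),
        ],
    )
    def test_round_trip_with_generator(self, pigment, wavelength, expected):
        """Noise-free synthetic dilution series returns the embedded coefficient."""
        table = dilution_series(pigment, [1, 2, 3, 4, 5, 6, 7])
        col = "a445" if wavelength == 445.0 else "a663"
        eps = fit_extinction(
            table[["concentration_mg_per_L", col]].to_numpy(),
            pigment=pigment,
            wavelength=wavelength,
        )
        assert eps.value == pytest.approx(expected, rel=1e-9)

    def test_identical_concentrations_singular(self):
        with pytest.raises(SingularFitError):
            fit_extinction([(1.0, 0.1), (1.0, 0.2)])


@pytest.mark.parametrize(
    "one_percent, expected", [(1600.0, 160.0), (10.0, 1.0), (820.4, 82.04)]
)
def test_convert_specific_extinction(one_percent, expected):
    """1% w/v is 10 g/L, so the per-g/L coefficient is a tenth of the 1% one."""
    assert convert_specific_extinction(one_percent) == pytest.approx(expected)


def test_convert_specific_extinction_rejects_nonpositive():
    with pytest.raises(ValueError):
        convert_specific_extinction(0.0)


class TestFitBackground:
    @pytest.mark.parametrize(
        "slope, intercept", [(0.14, 1.0), (0.233, 0.217), (0.0, 0.5)]
    )
    def test_recovers_exact_line(self, slope, intercept):
        a750 = np.linspace(0.1, 0.8, 10)
        pairs = np.column_stack([a750, slope * a750 + intercept])
        bg = fit_background(pairs, wavelength=445.0)
        assert bg.slope == pytest.approx(slope, abs=1e-12)
        assert bg.intercept == pytest.approx(intercept, abs=1e-12)
        assert bg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_slope_recovery_rate(self):
        """Slope recovered within +/-0.01 in >=95% of seeded replicates
        (n = 100 points, noise sd 0.005)."""
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a750 = rng.uniform(0.1, 0.8, size=100)
            y = 0.14 * a750 + 1.0 + rng.normal(0, 0.005, size=100)
            bg = fit_background(np.column_stack([a750, y]), 445.0)
            hits += abs(bg.slope - 0.14) <= 0.01
        assert hits / n_rep >= 0.95

    def test_degenerate_design_rejected(self):
        with pytest.raises(SingularFitError):
            fit_background([(0.3, 1.0), (0.3, 1.1), (0.3, 1.2)], 445.0)


class TestFormulaAlgebra:
    def test_derived_extract_coefficients(self):
        f = derive_extract_formula(156.54, 66.8, 82.04)
        assert round(f.coef_a445, 2) == 6.39
        # re-derivation gives 5.20, not the published 5.18
        assert round(f.coef_a663, 2) == 5.20
        assert f.provenance == "derived"

    def test_unit_coefficients(self):
        f = derive_extract_formula(1000.0, 1000.0, 1000.0)
        assert f.coef_a445 == pytest.approx(1.0)
        assert f.coef_a663 == pytest.approx(1.0)

    def test_nonpositive_coefficient_rejected(self):
        with pytest.raises(ValueError):
            derive_extract_formula(0.0, 66.8, 82.04)

    def test_expansion_reproduces_published_constants(self):
        """Collecting the background terms gives the published 0.312 and -5.27."""
        f = expand_whole_cell_formula(6.39, 5.18, PUBLISHED_BG_445, PUBLISHED_BG_663)
        assert round(f.coef_a750, 3) == 0.312
        assert round(f.constant, 2) == -5.27

    def test_zero_background_reduces_to_extract_formula(self):
        z445 = BackgroundModel(445.0, 0.0, 0.0)
        z663 = BackgroundModel(663.0, 0.0, 0.0)
        f = expand_whole_cell_formula(6.39, 5.18, z445, z663)
        assert f.coef_a750 == 0.0
        assert f.constant == 0.0

    def test_wavelength_mismatch_rejected(self):
        with pytest.raises(ValueError):
            expand_whole_cell_formula(6.39, 5.18, PUBLISHED_BG_663, PUBLISHED_BG_445)

    def test_expansion_equals_stepwise_background_subtraction(self):
        """The collected form equals explicit background subtraction exactly
        (full-precision coefficients, no rounding)."""
        f = expand_whole_cell_formula(6.39, 5.18, PUBLISHED_BG_445, PUBLISHED_BG_663)
        rng = np.random.default_rng(0)
        for a445, a663, a750 in rng.uniform(0, 2, size=(50, 3)):
            stepwise = 6.39 * (a445 - PUBLISHED_BG_445(a750)) - 5.18 * (
                a663 - PUBLISHED_BG_663(a750)
            )
            assert f.evaluate(a445, a663, a750) == pytest.approx(stepwise, abs=1e-12)


class TestPlateCalibration:
    @pytest.mark.parametrize(
        "reading, wavelength, expected",
        [(0.504, 445.0, 1.0), (0.444, 750.0, 1.0), (0.0, 663.0, 0.0)],
    )
    def test_plate_to_cuvette_defaults(self, reading, wavelength, expected):
        assert plate_to_cuvette(reading, wavelength) == pytest.approx(expected)

    def test_round_trip_identity(self):
        for wl in (445.0, 663.0, 750.0):
            x = 0.63
            back = plate_to_cuvette(cuvette_to_plate(x, wl), wl)
            assert back == pytest.approx(x, rel=1e-12)

    def test_unknown_wavelength_lists_calibrated(self):
        with pytest.raises(KeyError, match="445"):
            plate_to_cuvette(0.5, 550.0, DEFAULT_PLATE_CALIBRATION)

    def test_fit_through_origin_scales(self):
        cuv = np.linspace(0.1, 1.0, 6)
        pairs = {
            445.0: np.column_stack([cuv, 0.5 * cuv]),
            663.0: np.column_stack([cuv, 0.497 * cuv]),
        }
        calib = fit_plate_calibration(pairs)
        assert calib.scale(445.0) == pytest.approx(0.5, rel=1e-12)
        assert calib.scale(663.0) == pytest.approx(0.497, rel=1e-12)

    def test_all_zero_cuvette_singular(self):
        with pytest.raises(SingularFitError):
            fit_plate_calibration({445.0: [(0.0, 0.1), (0.0, 0.2)]})

    def test_published_formula_constants(self):
        assert (
            PUBLISHED_FORMULA.coef_a445,
            PUBLISHED_FORMULA.coef_a663,
            PUBLISHED_FORMULA.coef_a750,
            PUBLISHED_FORMULA.constant,
        ) == (6.39, 5.18, 0.312, -5.27)
        assert PUBLISHED_FORMULA.provenance == "published"
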