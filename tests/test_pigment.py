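"""Beer-Lambert quantification, peak detection, stability, EC50."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycorefinery.pigment import (
    DoseResponse,
    Spectrum,
    StabilitySeries,
    antioxidant_activity,
    beer_lambert_absorbance,
    beer_lambert_concentration,
    classify_stability,
    detect_peaks,
    ec50_interpolate,
    residual_intensity,
)
from mycorefinery.synthetic import DoseResponseSpec, SpectrumSpec, make_dose_response, make_spectrum


# ---------------------------------------------------------------------------
# Beer-Lambert


@pytest.mark.parametrize(
    "A,a,b,expected", [(0.5, 1, 1, 0.5), (0.0, 2.0, 0.5, 0.0), (1.2, 0.6, 2, 1.0)]
)
def test_beer_lambert_concentration(A, a, b, expected):
    assert beer_lambert_concentration(A, a, b) == pytest.approx(expected)


def test_beer_lambert_rejects_nonpositive_coefficients():
    with pytest.raises(ValueError):
        beer_lambert_concentration(0.5, 0, 1)
    with pytest.raises(ValueError):
        beer_lambert_concentration(0.5, 1, -1)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(c=st.floats(0, 100), a=st.floats(0.01, 10), b=st.floats(0.1, 10))
def test_beer_lambert_round_trip_identity(c, a, b):
    assert beer_lambert_concentration(
        beer_lambert_absorbance(c, a, b), a, b
    ) == pytest.approx(c, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# spectra and peaks


def test_spectrum_rejects_unordered_abscissa():
    with pytest.raises(ValueError, match="monotone"):
        Spectrum(x=[1, 3, 2], y=[0, 1, 0])


def test_spectrum_resorts_descending_ftir_axis():
    s = Spectrum(x=[4000, 3000, 2000], y=[1, 2, 3], kind="ftir")
    assert list(s.x) == [2000, 3000, 4000]
    assert list(s.y) == [3, 2, 1]


def test_three_gaussian_uvvis_peaks_recovered_within_1nm():
    spectrum, truth = make_spectrum(SpectrumSpec(seed=11, noise_sd=0.002))
    peaks = detect_peaks(spectrum)
    assert len(peaks) == 3
    for (center, _h), peak in zip(truth, peaks):
        assert peak.position == pytest.approx(center, abs=1.0)


def test_flat_spectrum_has_no_peaks():
    s = Spectrum(x=np.linspace(200, 800, 100), y=np.full(100, 0.3))
    assert detect_peaks(s) == []


def test_ftir_band_positions_recovered():
    spec = SpectrumSpec(
        seed=5, kind="ftir", x_start=500, x_stop=4000, n_points=1751,
        peaks=[(1630.55, 0.6, 8.0), (3451.71, 1.0, 10.0)], noise_sd=0.002,
    )
    spectrum, truth = make_spectrum(spec)
    found = sorted(p.position for p in detect_peaks(spectrum))
    assert found[0] == pytest.approx(1630.55, abs=1.0)
    assert found[1] == pytest.approx(3451.71, abs=1.0)


def test_saturated_region_masked_from_peaks():
    # a clipped plateau at the ceiling must not be reported as a peak
    x = np.linspace(200, 800, 601)
    y = 2.0 * np.exp(-0.5 * ((x - 207) / 4) ** 2) + 0.4 * np.exp(-0.5 * ((x - 520) / 15) ** 2)
    y = np.minimum(y, 1.0)
    s = Spectrum(x=x, y=y)
    positions = [p.position for p in detect_peaks(s, ceiling=1.0)]
    assert all(abs(p - 207) > 20 for p in positions)
    assert any(abs(p - 520) < 1.5 for p in positions)


def test_peak_recovery_within_half_step_at_high_snr():
    # sharp, well-sampled bands: refinement beats the grid resolution
    for seed in range(20):
        spec = SpectrumSpec(
            seed=seed, x_start=200, x_stop=800, n_points=601,
            peaks=[(320.0 + 13.7 * (seed % 7), 1.0, 3.0)], noise_sd=1.0 / 50,
        )
        spectrum, truth = make_spectrum(spec)
        peaks = detect_peaks(spectrum, prominence=0.3)
        best = min(peaks, key=lambda p: abs(p.position - truth[0][0]))
        assert abs(best.position - truth[0][0]) <= 0.5


def test_too_few_points_errors():
    with pytest.raises(ValueError, match="at least"):
        detect_peaks(Spectrum(x=[1, 2, 3], y=[0, 1, 0]))


# ---------------------------------------------------------------------------
# stability


def _series(times, intensities, label="x"):
    return StabilitySeries(condition=label, times_min=times, intensities=intensities)


def test_constant_intensity_gives_100_percent_everywhere():
    r = residual_intensity(_series([0, 30, 60], [2.0, 2.0, 2.0]))
    assert np.allclose(r, 100.0)


def test_final_retention_is_simple_ratio():
    r = residual_intensity(_series([0, 150], [1.0, 0.64]))
    assert r[-1] == pytest.approx(64.0)


def test_zero_reference_intensity_errors():
    with pytest.raises(ValueError, match="I\\(0\\)"):
        residual_intensity(_series([0, 30], [0.0, 0.0]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(scale=st.floats(1e-6, 1e6))
def test_retention_scale_invariant(scale):
    base = _series([0, 30, 60], [1.0, 0.8, 0.5])
    scaled = _series([0, 30, 60], np.array([1.0, 0.8, 0.5]) * scale)
    assert np.allclose(residual_intensity(base), residual_intensity(scaled))


def test_classification_against_threshold():
    stable = _series([0, 150], [1.0, 0.93], "pH 7")
    degrading = _series([0, 150], [1.0, 0.64], "80 degC")
    assert classify_stability(stable) == "stable"
    assert classify_stability(degrading) == "degrading"
    assert classify_stability(degrading, threshold=0.0) == "stable"


# ---------------------------------------------------------------------------
# antioxidant activity


def test_activity_anchors():
    assert antioxidant_activity(0.1, 0.1, 0.9) == 0.0
    assert antioxidant_activity(0.9, 0.1, 0.9) == 100.0
    assert antioxidant_activity(0.6, 0.1, 0.9) == pytest.approx(62.5)


def test_activity_undefined_when_control_equals_blank():
    with pytest.raises(ValueError, match="undefined"):
        antioxidant_activity(0.5, 0.2, 0.2)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    s=st.floats(0, 2), bl=st.floats(0, 2), shift=st.floats(-5, 5),
)
def test_activity_invariant_under_common_shift(s, bl, shift):
    ctrl = bl + 0.8
    assert antioxidant_activity(s + shift, bl + shift, ctrl + shift) == pytest.approx(
        antioxidant_activity(s, bl, ctrl), rel=1e-9, abs=1e-9
    )


# ---------------------------------------------------------------------------
# EC50


def test_ec50_bracketing_pair_linear_interpolation():
    dr = DoseResponse(concentrations=[20, 40], activities=[45.6, 72.8])
    res = ec50_interpolate(dr)
    assert res.value == pytest.approx(23.24, abs=0.005)
    assert res.bracket == (20.0, 40.0)


def test_ec50_exact_hit_returns_that_concentration():
    dr = DoseResponse(concentrations=[10, 25, 40], activities=[30.0, 50.0, 80.0])
    res = ec50_interpolate(dr)
    assert res.value == 25.0


def test_ec50_outside_range_errors():
    low = DoseResponse(concentrations=[10, 20], activities=[10.0, 30.0])
    with pytest.raises(ValueError, match="outside measured range"):
        ec50_interpolate(low)
    high = DoseResponse(concentrations=[10, 20], activities=[60.0, 90.0])
    with pytest.raises(ValueError, match="outside measured range"):
        ec50_interpolate(high)


def test_ec50_multiple_crossings_uses_first_with_warning():
    dr = DoseResponse(
        concentrations=[10, 20, 30, 40], activities=[40.0, 60.0, 45.0, 70.0]
    )
    res = ec50_interpolate(dr)
    assert res.bracket == (10.0, 20.0)
    assert res.warnings


def test_ec50_converges_to_logistic_midpoint_with_grid_refinement():
    errors = []
    for spacing in (20.0, 10.0, 5.0, 2.5):
        grid = np.arange(2.5, 100.0 + spacing, spacing)
        spec = DoseResponseSpec(
            seed=0, midpoint=23.6, slope=0.08, concentrations=grid, noise_sd=0.0
        )
        dr, midpoint = make_dose_response(spec)
        errors.append(abs(ec50_interpolate(dr).value - midpoint))
    assert errors[-1] < errors[0]
    assert errors == sorted(errors, reverse=True)
    assert errors[-1] < 0.1


def test_ec50_log_scale_option():
    dr = DoseResponse(concentrations=[20, 40], activities=[45.6, 72.8])
    lin = ec50_interpolate(dr).value
    log = ec50_interpolate(dr, log_scale=True).value
    assert log != lin
    assert 20 < log < 40
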