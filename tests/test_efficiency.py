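"""Normalized fluorescence, η computation and group comparisons."""

import numpy as np
import pytest

from twopeff.efficiency import (
    LaserRecord,
    Measurement,
    compute_eta,
    eta_scale,
    normalize_fluorescence,
    pairwise_compare,
    reference_regression,
    run_study,
    spotsize_efficiency_correlation,
)

FS = 1e-15
POWERS = np.linspace(4e-3, 10e-3, 6)


def record(label="ref", rep=80.78e6, tau=82 * FS, powers=POWERS, fluor=None, c=1e8):
    if fluor is None:
        fluor = c * powers**2
    return LaserRecord(
        label=label,
        rep_rate=rep,
        pulse_duration=tau,
        measurements=[Measurement(p, f) for p, f in zip(powers, fluor)],
    )


def test_noiseless_quadratic_series_has_slope_2():
    fit = reference_regression(record())
    assert fit.slope == pytest.approx(2.0, abs=1e-9)


def test_linear_series_has_slope_1():
    fit = reference_regression(record(fluor=3.0 * POWERS))
    assert fit.slope == pytest.approx(1.0, abs=1e-9)


def test_noisy_slope_recovery(rng):
    """1% multiplicative noise, n=18: slope distributes as 2.00 ± 0.02."""
    slopes = []
    powers = np.tile(POWERS, 3)
    for _ in range(300):
        f = 1e8 * powers**2 * (1 + 0.01 * rng.standard_normal(powers.size))
        slopes.append(reference_regression(record(powers=powers, fluor=f)).slope)
    assert np.mean(slopes) == pytest.approx(2.0, abs=0.01)
    assert np.std(slopes) < 0.03


def test_regression_input_validation():
    with pytest.raises(ValueError, match="positive"):
        reference_regression(record(fluor=np.full(6, -1.0)))
    with pytest.raises(ValueError, match="3 distinct"):
        reference_regression(record(powers=np.array([5e-3] * 4), fluor=np.ones(4)))


def test_reference_normalizes_to_unity():
    ref = record()
    fit = reference_regression(ref)
    ratios = normalize_fluorescence(ref, fit)
    assert np.mean(ratios) == pytest.approx(1.0, abs=1e-9)


def test_half_fluorescence_normalizes_to_half():
    ref = record()
    fit = reference_regression(ref)
    test = record(label="dim", fluor=0.5 * 1e8 * POWERS**2)
    assert normalize_fluorescence(test, fit) == pytest.approx(0.5)


def test_extrapolation_warns_but_returns():
    ref = record()
    fit = reference_regression(ref)
    test = record(label="out", powers=np.array([2e-3, 6e-3, 12e-3]))
    with pytest.warns(UserWarning, match="outside the reference power range"):
        vals = normalize_fluorescence(test, fit)
    assert vals == pytest.approx(1.0)


def test_noisy_f_ratio_recovery(rng):
    ref = record()
    fit = reference_regression(ref)
    means = []
    for _ in range(200):
        f = 0.75 * 1e8 * POWERS**2 * (1 + 0.01 * rng.standard_normal(6))
        means.append(np.mean(normalize_fluorescence(record(label="t", fluor=f), fit)))
    assert np.mean(means) == pytest.approx(0.75, abs=0.01)


@pytest.mark.parametrize(
    "f_ratio,rep_mhz,tau_fs,expected",
    [
        (0.57, 80.13, 158.0, 1.09),  # long-pulse laser exceeding the reference
        (0.75, 80.51, 94.0, 0.86),  # short-pulse fiber laser
        (1.0, 80.78, 82.0, 1.00),  # the reference against itself
    ],
)
def test_compute_eta_worked_examples(f_ratio, rep_mhz, tau_fs, expected):
    """η = (F_test/F_ref)·(R_test·τ_test)/(R_ref·τ_ref), to 2 decimals."""
    ref = LaserRecord("ref", 80.78e6, 82 * FS)
    test = LaserRecord("test", rep_mhz * 1e6, tau_fs * FS)
    res = compute_eta([f_ratio], test, ref)
    assert round(res.eta_mean, 2) == expected
    assert res.eta_mean == pytest.approx(f_ratio * eta_scale(test, ref), rel=1e-12)


def test_eta_reciprocity():
    """Swapping test and reference inverts η exactly."""
    a = LaserRecord("a", 80.13e6, 158 * FS)
    b = LaserRecord("b", 80.78e6, 82 * FS)
    f = 0.57
    forward = compute_eta([f], a, b).eta_mean
    backward = compute_eta([1.0 / f], b, a).eta_mean
    assert forward * backward == pytest.approx(1.0, rel=1e-12)


def test_compute_eta_requires_points():
    with pytest.raises(ValueError, match="nonempty"):
        compute_eta([], LaserRecord("a", 1.0, 1.0), LaserRecord("b", 1.0, 1.0))


def test_pairwise_identical_groups_not_significant():
    g = {"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0, 1.0]}
    table = pairwise_compare(g)
    assert table.loc["a", "b"] == 1.0
    assert np.isnan(table.loc["b", "a"])  # upper-triangular layout


def test_pairwise_separated_groups_significant(rng):
    a = 1.0 + 0.01 * rng.standard_normal(12)
    b = 1.05 + 0.01 * rng.standard_normal(12)  # 5 SD apart
    table = pairwise_compare({"a": a, "b": b})
    assert table.loc["a", "b"] < 1e-4


def test_pairwise_three_groups_only_shifted_significant(rng):
    base = {
        "a": 1.0 + 0.01 * rng.standard_normal(12),
        "b": 1.0 + 0.01 * rng.standard_normal(12),
        "c": 1.2 + 0.01 * rng.standard_normal(12),
    }
    table = pairwise_compare(base)
    assert table.loc["a", "c"] < 0.05
    assert table.loc["b", "c"] < 0.05
    assert table.loc["a", "b"] > 0.05


def test_pairwise_requires_group_sizes():
    with pytest.raises(ValueError, match="fewer than 3"):
        pairwise_compare({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


def test_correlation_endpoints():
    assert spotsize_efficiency_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert spotsize_efficiency_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="zero-variance"):
        spotsize_efficiency_correlation([1, 1, 1], [1, 2, 3])


def test_correlation_monte_carlo(rng):
    """Pairs drawn with true correlation 0.5 average to r ≈ 0.5."""
    rs = []
    for _ in range(1000):
        x = rng.standard_normal(10)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(10)
        rs.append(spotsize_efficiency_correlation(x, y))
    assert np.mean(rs) == pytest.approx(0.5, abs=0.05)


def test_run_study_self_normalization():
    """The reference analyzed against itself yields f_ratio = η = 1 exactly."""
    ref = record()
    study = run_study([ref], reference_label="ref")
    res = study.results[0]
    assert res.f_ratio_mean == pytest.approx(1.0, abs=1e-9)
    assert res.eta_mean == pytest.approx(1.0, abs=1e-9)
    # exact quadratic data: η identical at every power level
    assert study.points["eta"].std() < 1e-9


def test_run_study_saturation_guard():
    sat = 1e8 * POWERS**2 / (1 + (POWERS / 8e-3) ** 2)
    bad = record(label="sat", fluor=sat)
    with pytest.raises(ValueError, match="slope"):
        run_study([record(), bad], reference_label="ref")


def test_run_study_missing_reference():
    with pytest.raises(ValueError, match="reference laser"):
        run_study([record()], reference_label="nope")
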