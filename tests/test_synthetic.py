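"""Ground-truth properties of the synthetic-data generator."""

import numpy as np
import pytest

from twopeff.efficiency import LaserRecord, Measurement, run_study
from twopeff.images import measure_spot, normalize_image, peak_intensity, power_series_analysis
from twopeff.pulses import fwhm, pulse_energy
from twopeff.synthetic import (
    DEFAULT_POWERS,
    SyntheticLaserSpec,
    SyntheticSceneSpec,
    composite_spec,
    demo_lasers,
    make_pulse_trace,
    make_spot_series,
    make_study,
    quantize_12bit,
    simulate_study_frames,
)

FS = 1e-15
NJ = 1e-9


def recover_etas(lasers, scene, seed, powers=DEFAULT_POWERS):
    """Run the full image→regression→η pipeline on generated frames."""
    frames = simulate_study_frames(lasers, lasers[0].label, scene, powers=powers, seed=seed)
    records = {l.label: LaserRecord(l.label, l.rep_rate, l.pulse_fwhm) for l in lasers}
    for frame in frames:
        m = measure_spot(frame)
        records[frame.laser_label].measurements.append(
            Measurement(frame.incident_power, m.peak_intensity, frame.session_id)
        )
    study = run_study(list(records.values()), reference_label=lasers[0].label)
    return {r.label: r for r in study.results}


def test_quantization_is_12bit_in_16():
    q = quantize_12bit(np.array([0.0, 7.9, 8.0, 100.0, 1e9]))
    assert q.dtype == np.uint16
    assert set(q % 16) == {0}
    assert q[-1] == 65520
    assert q[3] == 96  # 100 rounds to the nearest multiple of 16


def test_zero_side_lobes_reduces_to_sech2():
    spec = composite_spec(100 * FS, NJ, 0.0)
    assert spec.shape == "sech2"
    tr = make_pulse_trace(spec)
    assert fwhm(tr) == pytest.approx(100 * FS, rel=1e-3)
    assert pulse_energy(tr) == pytest.approx(NJ, rel=1e-3)


def test_acf_width_tuning_hits_target():
    tr = make_pulse_trace(composite_spec(100 * FS, NJ, 0.25), target_acf_width=154 * FS)
    from twopeff.autocorr import acf_width, intensity_acf

    assert acf_width(intensity_acf(tr)) == pytest.approx(154 * FS, rel=5e-3)
    with pytest.raises(ValueError, match="composite"):
        make_pulse_trace(
            composite_spec(100 * FS, NJ, 0.0), target_acf_width=154 * FS
        )


def test_noiseless_quadratic_law_is_exact(small_scene):
    """With all noise off and count-aligned amplitudes, doubling the power
    exactly quadruples the background-subtracted peak signal."""
    scene = SyntheticSceneSpec(
        image_shape=(128, 128),
        spot_amplitude=6.4,
        background_level=96.0,
        read_noise_sd=0.0,
        reference_power=10e-3,
    )
    laser = SyntheticLaserSpec("exact", 80e6, 100 * FS, noise_cv=0.0)
    frames = make_spot_series(
        laser, scene, powers=[5e-3, 10e-3], exposures=[1000.0, 1000.0], shot_noise=False
    )
    peaks = [float(f.pixels.max()) - 96.0 for f in frames]
    assert peaks[1] == pytest.approx(4.0 * peaks[0], abs=1e-9)


def test_exposure_invariance_of_generated_frames(small_scene, quiet_laser):
    scene = SyntheticSceneSpec(
        image_shape=(128, 128), read_noise_sd=0.0, spot_amplitude=10.0
    )
    frames = make_spot_series(
        quiet_laser, scene, powers=[10e-3, 10e-3], exposures=[600.0, 5000.0],
        shot_noise=False,
    )
    peaks = [peak_intensity(normalize_image(f))[0] for f in frames]
    assert abs(peaks[0] - peaks[1]) / peaks[1] < 5e-3


def test_determinism_same_seed_identical_frames(small_scene):
    laser = SyntheticLaserSpec("det", 80e6, 100 * FS, noise_cv=0.02)
    a = make_spot_series(laser, small_scene, seed=7)
    b = make_spot_series(laser, small_scene, seed=7)
    for fa, fb in zip(a, b):
        assert np.array_equal(fa.pixels, fb.pixels)
        assert fa.exposure_ms == fb.exposure_ms
    c = make_spot_series(laser, small_scene, seed=8)
    assert any(not np.array_equal(fa.pixels, fc.pixels) for fa, fc in zip(a, c))


def test_generated_series_passes_and_fails_slope_guard(small_scene, quiet_laser):
    clean = make_spot_series(quiet_laser, small_scene, seed=11)
    powers = np.array([f.incident_power for f in clean])
    peaks = np.array([measure_spot(f).peak_intensity for f in clean])
    slope, _, flagged = power_series_analysis(powers, peaks)
    assert slope == pytest.approx(2.0, abs=0.05)
    assert not flagged
    sat = make_spot_series(
        quiet_laser, small_scene, seed=11, saturation_power=8e-3
    )
    peaks_sat = np.array([measure_spot(f).peak_intensity for f in sat])
    slope, _, flagged = power_series_analysis(powers, peaks_sat)
    assert slope < 2.0
    assert flagged


def test_saturation_refused_without_flag(small_scene):
    bright = SyntheticLaserSpec("bright", 80e6, 100 * FS)
    scene = SyntheticSceneSpec(image_shape=(128, 128), spot_amplitude=1e5)
    with pytest.raises(ValueError, match="ceiling"):
        make_spot_series(bright, scene, powers=[10e-3], exposures=[5000.0])
    frames = make_spot_series(
        bright, scene, powers=[10e-3], exposures=[5000.0], allow_saturation=True,
        shot_noise=False,
    )
    assert frames[0].pixels.max() == 65520


def test_end_to_end_eta_recovery_two_seeds(small_scene):
    """Different seeds give different noise but the same ground truth."""
    lasers = [
        SyntheticLaserSpec("ref", 80.78e6, 82 * FS, 1.0, noise_cv=0.01),
        SyntheticLaserSpec("t", 80.51e6, 94 * FS, 0.86, noise_cv=0.01),
    ]
    for seed in (5, 6):
        res = recover_etas(lasers, small_scene, seed)["t"]
        assert res.eta_mean == pytest.approx(0.86, abs=max(2 * res.eta_sd, 0.02))


def test_study_duplicate_labels_rejected(small_scene):
    lasers = [
        SyntheticLaserSpec("x", 80e6, 100 * FS),
        SyntheticLaserSpec("x", 80e6, 100 * FS),
    ]
    with pytest.raises(ValueError, match="duplicate"):
        simulate_study_frames(lasers, "x", small_scene, seed=0)


def test_make_study_writes_consumable_fixture(tmp_path, small_scene):
    lasers = demo_lasers(noise_cv=0.01)[:3]
    paths = make_study(
        lasers, "tisa-ref", small_scene, tmp_path / "study", seed=21,
        powers=DEFAULT_POWERS,
    )
    assert paths.manifest.is_file() and paths.lasers.is_file()
    tifs = sorted(paths.image_dir.glob("*.tif"))
    assert len(tifs) == len(lasers) * len(DEFAULT_POWERS)
    # byte-identical rerun with the same seed
    paths2 = make_study(
        lasers, "tisa-ref", small_scene, tmp_path / "study2", seed=21,
        powers=DEFAULT_POWERS,
    )
    assert paths.manifest.read_bytes() == paths2.manifest.read_bytes()
    for a, b in zip(tifs, sorted(paths2.image_dir.glob("*.tif"))):
        assert a.read_bytes() == b.read_bytes()
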