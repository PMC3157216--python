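"""Analytic PET chain: projector, count calibration, noise, reconstruction."""

import math

import numpy as np
import pytest

from myelinpet import petsim


def disk_image(n=128, radius=30.0, value=1.0, center=None):
    cy = cx = (n - 1) / 2.0 if center is None else None
    if center is not None:
        cy, cx = center
    y, x = np.mgrid[:n, :n]
    return np.where((x - cx) ** 2 + (y - cy) ** 2 <= radius**2, value, 0.0)


@pytest.fixture(scope="module")
def geom():
    return petsim.ProjectionGeometry(n_angles=90, pixel_size_mm=1.0, psf_fwhm_mm=0.0)


def test_zero_activity_projects_to_zero(geom):
    sino = petsim.forward_project(np.zeros((64, 64)), None, geom)
    assert np.all(sino == 0.0)


def test_central_source_profile_constant_over_angles(geom):
    """A small source at the rotation center projects identically at every angle."""
    img = disk_image(65, 3.0, 1.0)
    sino = petsim.forward_project(img, None, geom)
    totals = sino.sum(axis=0)
    assert totals.std() / totals.mean() < 0.02


def test_uniform_disk_matches_chord_length_oracle(geom):
    """Projections of a uniform disk equal the analytic chord 2*sqrt(r^2-s^2)."""
    r = 30.0
    img = disk_image(128, r, 2.0)
    sino = petsim.forward_project(img, None, geom)
    bins = np.arange(sino.shape[0]) - (sino.shape[0] - 1) / 2.0
    with np.errstate(invalid="ignore"):
        chord = 2.0 * np.sqrt(np.clip(r**2 - bins**2, 0.0, None)) * 2.0
    interior = np.abs(bins) < r - 3
    err = np.abs(sino[interior] - chord[interior, None]) / chord[interior, None]
    assert np.median(err) < 0.03


def test_forward_projection_linear_in_activity(geom):
    img = disk_image(64, 20.0, 1.3)
    mu = np.where(img > 0, 0.0096, 0.0)
    a = petsim.forward_project(img, mu, geom)
    b = petsim.forward_project(3.5 * img, mu, geom)
    assert b == pytest.approx(3.5 * a, rel=1e-10)


def test_attenuation_reduces_counts(geom):
    img = disk_image(64, 20.0)
    sino_free = petsim.forward_project(img, None, geom)
    sino_att = petsim.forward_project(img, np.where(img > 0, 0.0096, 0.0), geom)
    mask = sino_free > 0
    assert np.all(sino_att[mask] < sino_free[mask] + 1e-12)


def test_count_scale_limits_and_closed_form():
    base = dict(injected_dose_mci=10.0, positron_yield=0.97, delay_to_scan=7200.0,
                half_life_s=6588.0, sensitivity=1.0)
    short = petsim.AcquisitionParams(frame_interval=1e-6, scan_duration=1e-6, **base)
    assert petsim.count_scale(short) == pytest.approx(0.0, abs=1e-3)
    # no-decay limit: multiplier = sens * dose * yield * duration
    no_decay = petsim.AcquisitionParams(scan_duration=1200.0,
                                        **{**base, "half_life_s": 1e15})
    assert petsim.count_scale(no_decay) == pytest.approx(10.0 * 0.97 * 1200.0, rel=1e-9)
    acq = petsim.AcquisitionParams(scan_duration=1200.0, **base)
    integral = 6588.0 / math.log(2.0) * (2.0 ** (-7200.0 / 6588.0) - 2.0 ** (-8400.0 / 6588.0))
    assert petsim.count_scale(acq) == pytest.approx(10.0 * 0.97 * integral, rel=1e-12)


def test_doubling_duration_without_decay_doubles_counts():
    mk = lambda dur: petsim.AcquisitionParams(scan_duration=dur, half_life_s=1e15)
    assert petsim.count_scale(mk(2400.0)) == pytest.approx(2.0 * petsim.count_scale(mk(1200.0)),
                                                           rel=1e-9)


def test_invalid_acquisition_rejected():
    with pytest.raises(ValueError):
        petsim.AcquisitionParams(scatter_fraction=0.6)
    with pytest.raises(ValueError):
        petsim.AcquisitionParams(scan_duration=1000.0, frame_interval=120.0)


def test_noise_zero_mean_zero_scatter_gives_zero_counts():
    acq = petsim.AcquisitionParams(scatter_fraction=0.0)
    sino = petsim.add_scatter_and_noise(np.zeros((32, 16)), acq, seed=1)
    assert np.all(sino.counts == 0)


def test_noise_deterministic_for_seed():
    acq = petsim.AcquisitionParams()
    mean = np.full((64, 32), 40.0)
    a = petsim.add_scatter_and_noise(mean, acq, seed=9)
    b = petsim.add_scatter_and_noise(mean, acq, seed=9)
    assert np.array_equal(a.counts, b.counts)
    c = petsim.add_scatter_and_noise(mean, acq, seed=10)
    assert not np.array_equal(a.counts, c.counts)


def test_poisson_mean_and_variance(rng):
    """Counts behave Poisson: sample mean ~ m and variance ~ m (5-sigma band)."""
    m = 200.0
    acq = petsim.AcquisitionParams(scatter_fraction=0.0)
    mean = np.full((100, 100), m)
    sino = petsim.add_scatter_and_noise(mean, acq, seed=3)
    vals = sino.counts.astype(float)
    n = vals.size
    assert abs(vals.mean() - m) < 5.0 * math.sqrt(m / n)
    assert abs(vals.var() - m) < 5.0 * m * math.sqrt(2.0 / n)


def test_scatter_fraction_of_total_counts():
    acq = petsim.AcquisitionParams(scatter_fraction=0.15)
    mean = np.full((64, 64), 100.0)
    sino = petsim.add_scatter_and_noise(mean, acq, seed=3)
    expected_scatter_total = 0.15 / 0.85 * mean.sum()
    assert sino.expected_scatter * mean.size == pytest.approx(expected_scatter_total)


def test_reconstruct_zero_sinogram_is_near_zero():
    geom = petsim.ProjectionGeometry(n_angles=90, pixel_size_mm=1.0)
    sino = petsim.SinogramData(np.zeros((64, 90)), geom, 0.0, 1.0, np.ones((64, 90)))
    img = petsim.reconstruct(sino)
    assert np.allclose(img, 0.0)


def test_uniform_disk_round_trip_recovers_activity_level():
    """Noiseless forward + FBP plateau within 5% of truth, with attenuation."""
    n = 128
    img = disk_image(n, 40.0, 3.0)
    mu = np.where(img > 0, 0.0096, 0.0)
    geom = petsim.ProjectionGeometry(n_angles=120, pixel_size_mm=1.1, psf_fwhm_mm=4.0)
    acq = petsim.AcquisitionParams()
    recon = petsim.simulate_scan(img, mu, acq, geom, seed=0, noiseless=True)
    y, x = np.mgrid[:n, :n]
    core = (x - (n - 1) / 2) ** 2 + (y - (n - 1) / 2) ** 2 <= 25.0**2
    assert recon[core].mean() == pytest.approx(3.0, rel=0.05)


def test_recovered_contrast_monotone_in_true_contrast():
    n = 128
    geom = petsim.ProjectionGeometry(n_angles=90, pixel_size_mm=1.0, psf_fwhm_mm=4.0)
    acq = petsim.AcquisitionParams()
    bg = disk_image(n, 50.0, 1.0)
    hot = disk_image(n, 10.0, 1.0, center=(64.0, 80.0))
    recovered = []
    for contrast in (2.0, 5.0, 10.0):
        img = bg + (contrast - 1.0) * hot
        recon = petsim.simulate_scan(img, None, acq, geom, seed=0, noiseless=True)
        recovered.append(recon[64, 80])
    assert recovered[0] < recovered[1] < recovered[2]


def test_paired_scan_shares_noise_between_members():
    """Identical phantoms under the paired-seed policy give identical images."""
    img = disk_image(96, 30.0, 1e-10)
    mu = np.where(img > 0, 0.0096, 0.0)
    geom = petsim.ProjectionGeometry(n_angles=90, pixel_size_mm=1.1)
    acq = petsim.AcquisitionParams()
    pair = petsim.simulate_paired_scan(img, img, img * 0.01, mu, acq, geom, seed=11)
    assert np.array_equal(pair.lesion_free, pair.lesion_bearing)
    again = petsim.simulate_paired_scan(img, img, img * 0.01, mu, acq, geom, seed=11)
    assert np.array_equal(pair.lesion_free, again.lesion_free)


def test_geometry_mismatch_rejected(geom):
    with pytest.raises(ValueError):
        petsim.forward_project(np.zeros((64, 64)), np.zeros((32, 32)), geom)
    with pytest.raises(ValueError):
        petsim.forward_project(np.zeros((32, 64)), None, geom)
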