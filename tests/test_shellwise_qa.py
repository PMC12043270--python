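"""Shell ADC, sub-group stability, kurtosis fitting and BIC selection."""

import numpy as np
import pytest

from neodmri import phantom_forge as pf
from neodmri.gradients import ShellScheme, direction_set
from neodmri.protocol_planner import build_schedule
from neodmri.shellwise_qa import (
    MonoExponentialFamily,
    ThreeCompartmentFamily,
    bic_grid_select,
    default_diffusivity_grid,
    fit_adc,
    fit_dki,
    subgroup_stability,
)


def _isotropic_phantom(md=0.071, mk=0.0):
    ph = pf.make_phantom((40, 40, 32), seed=1)
    ph.fa[:] = 0.0
    ph.mk[:] = mk
    ph.md_um2_per_ms[ph.mask] = md
    return ph


@pytest.fixture(scope="module")
def adc_scheme():
    return ShellScheme.from_shells({4000.0: direction_set(6, seed=0)}, n_b0=1)


def test_fit_adc_exact_inversion(adc_scheme):
    ph = _isotropic_phantom(md=0.071)
    vols = pf.simulate_dwi(ph, adc_scheme)
    adc, stats = fit_adc(vols, adc_scheme, 4000.0, ph.mask, ph.labels)
    assert np.allclose(adc[ph.mask], 0.071, atol=1e-12)
    assert stats.n_excluded_nonpositive == 0


def test_fit_adc_pilot_fixture(adc_scheme):
    """The pilot working point: tissue ADC 0.164 um2/ms at b=4000."""
    ph = _isotropic_phantom(md=0.164)
    vols = pf.simulate_dwi(ph, adc_scheme)
    _, stats = fit_adc(vols, adc_scheme, 4000.0, ph.tissue_mask(1, 2, 3), ph.labels)
    assert stats.median_adc["WM"] == pytest.approx(0.164, abs=1e-9)
    assert stats.median_attenuation["WM"] == pytest.approx(np.exp(-0.656), abs=1e-9)
    assert stats.voxel_count["WM"] == int((ph.labels == 1).sum())


def test_fit_adc_noise_bias_bounded(adc_scheme):
    """Rician noise at SNR 20 biases the WM median ADC by < 5%."""
    ph = _isotropic_phantom(md=0.164)
    vols = pf.simulate_dwi(ph, adc_scheme, sigma=5.0, seed=11, s0=100.0)
    _, stats = fit_adc(vols, adc_scheme, 4000.0, ph.mask, ph.labels)
    assert abs(stats.median_adc["WM"] / 0.164 - 1) < 0.05


def test_fit_adc_counts_nonpositive(adc_scheme):
    ph = _isotropic_phantom()
    vols = pf.simulate_dwi(ph, adc_scheme)
    wm = ph.labels == 1
    first_wm = tuple(np.argwhere(wm)[0])
    vols[first_wm] = 0.0
    _, stats = fit_adc(vols, adc_scheme, 4000.0, ph.mask, ph.labels)
    assert stats.n_excluded_nonpositive == 1


def test_fit_adc_requires_b0(adc_scheme):
    ph = _isotropic_phantom()
    scheme = ShellScheme(np.array([4000.0]), np.array([[1.0, 0, 0]]))
    vols = pf.simulate_dwi(ph, scheme)
    with pytest.raises(ValueError):
        fit_adc(vols, scheme, 4000.0, ph.mask)


@pytest.fixture(scope="module")
def drift_session():
    """Full interleaved session on an isotropic Gaussian phantom with the
    WM ADC settling exponentially from 0.076 to 0.071 um2/ms."""
    ph = _isotropic_phantom(md=0.071, mk=0.0)
    sched, scheme = build_schedule(seed=4)
    t = np.arange(len(scheme)) / len(scheme)
    md_t = 0.071 + 0.005 * np.exp(-t / 0.35)
    vols = pf.simulate_dwi(ph, scheme, drift=md_t / 0.071)
    return ph, sched, scheme, vols


def test_subgroup_drift_recovery(drift_session):
    ph, sched, scheme, vols = drift_session
    rep = subgroup_stability(vols, sched, ph.labels)
    series = rep.median_adc["WM"]
    assert series.size == 8  # one per high-b subset
    assert np.all(np.diff(series) < 0)  # monotone settling
    assert abs(series[0] / 0.076 - 1) < 0.03
    assert abs(series[-1] / 0.071 - 1) < 0.03
    assert np.all(np.diff(rep.mid_times) > 0)
    assert rep.cov["WM"] > 0


def test_subgroup_driftfree_cov_and_exchangeability(drift_session):
    ph, sched, scheme, _ = drift_session
    vols = pf.simulate_dwi(ph, scheme)  # no drift
    rep = subgroup_stability(vols, sched, ph.labels)
    assert np.allclose(rep.median_adc["WM"], 0.071, atol=1e-12)
    assert rep.cov["WM"] == pytest.approx(0.0, abs=1e-12)
    # exchangeability: the CoV of a constant series ignores subset labels
    perm = np.random.default_rng(0).permutation(rep.median_adc["WM"])
    cov_perm = np.std(perm, ddof=1) / np.mean(perm)
    assert abs(cov_perm - rep.cov["WM"]) < 1e-12


@pytest.fixture(scope="module")
def dki_scheme():
    dirs = {
        3000.0: direction_set(20, seed=1),
        6000.0: direction_set(24, seed=2),
        9000.0: direction_set(28, seed=3),
    }
    return ShellScheme.from_shells(dirs, n_b0=2)


@pytest.fixture(scope="module")
def wm_slice_mask(phantom):
    mask = phantom.tissue_mask(1).copy()
    mask &= np.arange(phantom.shape[2])[None, None, :] == 16
    return mask


def test_dki_recovers_generator_parameters(phantom, dki_scheme, wm_slice_mask):
    """Noiseless WM with MD 0.071, FA 0.4, MK 1.2 is recovered within 2%."""
    vols = pf.simulate_dwi(phantom, dki_scheme)
    maps = fit_dki(vols, dki_scheme, wm_slice_mask)
    m = wm_slice_mask
    assert np.median(np.abs(maps.md[m] / 0.071 - 1)) < 0.02
    assert np.median(np.abs(maps.fa[m] / 0.40 - 1)) < 0.02
    assert np.median(np.abs(maps.mk[m] / 1.2 - 1)) < 0.02
    assert not maps.negative_eigen[m].any()


def test_dki_error_shrinks_with_noise(phantom, dki_scheme, wm_slice_mask):
    errs = []
    for sigma in (2.0, 0.5, 0.0):
        vols = pf.simulate_dwi(phantom, dki_scheme, sigma=sigma, seed=5)
        maps = fit_dki(vols, dki_scheme, wm_slice_mask)
        errs.append(np.median(np.abs(maps.md[wm_slice_mask] / 0.071 - 1)))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-4


def test_dki_gaussian_signal_gives_zero_mk(dki_scheme, wm_slice_mask):
    ph = pf.make_phantom((40, 40, 32), seed=1)
    ph.mk[:] = 0.0
    vols = pf.simulate_dwi(ph, dki_scheme)
    maps = fit_dki(vols, dki_scheme, wm_slice_mask)
    assert np.abs(maps.mk[wm_slice_mask]).max() < 0.01


def test_dki_isotropic_voxels_flagged(dki_scheme, wm_slice_mask):
    ph = _isotropic_phantom(md=0.1, mk=0.0)
    vols = pf.simulate_dwi(ph, dki_scheme)
    maps = fit_dki(vols, dki_scheme, wm_slice_mask)
    m = wm_slice_mask
    assert np.all(maps.fa[m] < 1e-6)
    assert np.all(maps.mo[m] == 0.0)
    assert maps.isotropic_flag[m].all()


def test_dki_requires_two_shells_and_enough_volumes(phantom):
    single = ShellScheme.from_shells({3000.0: direction_set(12, seed=0)}, n_b0=1)
    vols = pf.simulate_dwi(phantom, single)
    with pytest.raises(ValueError):
        fit_dki(vols, single, phantom.mask)
    tiny = ShellScheme.from_shells(
        {3000.0: direction_set(2, seed=0), 6000.0: direction_set(2, seed=1)}, n_b0=1
    )
    vols = pf.simulate_dwi(phantom, tiny)
    with pytest.raises(ValueError):
        fit_dki(vols, tiny, phantom.mask)


@pytest.fixture(scope="module")
def compartment_scheme():
    dirs = {
        3000.0: direction_set(16, seed=1),
        6000.0: direction_set(20, seed=2),
        9000.0: direction_set(24, seed=3),
    }
    return ShellScheme.from_shells(dirs, n_b0=3)


def test_bic_grid_default_contains_reported_neighbourhood():
    grid = default_diffusivity_grid()
    for v in (0.01, 0.25, 0.30, 0.35, 1.0):
        assert np.any(np.isclose(grid, v))


def test_bic_mono_family_brute_force(compartment_scheme):
    """Mono-exponential data: BIC argmin lands on the grid point nearest
    the generating decay rate (independent brute-force oracle)."""
    rng = np.random.default_rng(1)
    d_true = 0.42
    atten = np.exp(-compartment_scheme.bvals * 1e-3 * d_true)
    sig = atten[None, :] * np.ones((12, 1)) + 0.002 * rng.standard_normal((12, len(compartment_scheme)))
    vols = sig.reshape(12, 1, 1, -1)
    mask = np.ones((12, 1, 1), dtype=bool)
    curve = bic_grid_select(vols, compartment_scheme, mask, MonoExponentialFamily())
    grid = curve.grid
    assert curve.argmin == grid[np.argmin(np.abs(grid - d_true))]


def test_bic_three_compartment_recovery(compartment_scheme):
    """Within-family synthetic data with axial diffusivity 0.3 um2/ms:
    the BIC grid argmin recovers 0.3."""
    fam = ThreeCompartmentFamily(d_free=1.5)
    rng = np.random.default_rng(7)
    nvox = 60
    fr = rng.dirichlet([4, 4, 1, 2], size=nvox)
    axes = rng.standard_normal((nvox, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    sig = fam.synthesize(compartment_scheme, 0.3, fr, axes)
    noisy = np.sqrt(
        (sig + 0.01 * rng.standard_normal(sig.shape)) ** 2
        + (0.01 * rng.standard_normal(sig.shape)) ** 2
    )
    vols = noisy.reshape(nvox, 1, 1, -1)
    curve = bic_grid_select(vols, compartment_scheme, np.ones((nvox, 1, 1), bool), fam)
    assert curve.argmin == pytest.approx(0.3)
    assert set(curve.sensitivity) == {0.25, 0.35}


def test_bic_flatness_flag_on_degenerate_signal(compartment_scheme):
    """A constant signal is fit exactly by the restricted pool at every
    axial diffusivity, so the whole BIC valley is flat."""
    vols = np.ones((5, 1, 1, len(compartment_scheme)))
    curve = bic_grid_select(vols, compartment_scheme, np.ones((5, 1, 1), bool),
                            ThreeCompartmentFamily())
    assert curve.flat
    assert np.ptp(curve.mean_bic) < 2.0


def test_bic_grid_validity(compartment_scheme):
    vols = np.ones((2, 1, 1, len(compartment_scheme)))
    with pytest.raises(ValueError):
        bic_grid_select(vols, compartment_scheme, np.ones((2, 1, 1), bool),
                        MonoExponentialFamily(), grid=np.array([-0.1, 0.5]))
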