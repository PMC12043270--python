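"""Synthetic phantom, field-map calibration, DWI signal and k-space encoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from neodmri import phantom_forge as pf
from neodmri.epi_geometry import AcquisitionGeometry
from neodmri.gradients import ShellScheme, direction_set


def test_phantom_determinism_and_seed_sensitivity():
    a = pf.make_phantom((40, 40, 32), seed=1)
    b = pf.make_phantom((40, 40, 32), seed=1)
    assert np.array_equal(a.labels, b.labels)
    c = pf.make_phantom((40, 40, 32), seed=2)
    assert not np.array_equal(a.labels, c.labels)


def test_phantom_tissue_parameters(phantom):
    assert np.all(phantom.md_um2_per_ms[phantom.labels == pf.WM] == 0.071)
    assert np.all(phantom.t2star_ms[phantom.labels == pf.WM] == 83.0)
    assert np.all(phantom.t2_ms[phantom.labels == pf.WM] == 178.0)
    m = phantom.mask
    for grid in (phantom.t2_ms, phantom.t2star_ms, phantom.md_um2_per_ms):
        assert np.all(np.isfinite(grid[m])) and np.all(grid[m] > 0)
    assert np.all((phantom.fa[m] >= 0) & (phantom.fa[m] < 1))
    assert np.all(phantom.mk[m] >= 0)
    assert np.allclose(np.linalg.norm(phantom.principal_dir, axis=-1), 1.0)


def test_cortical_ribbon_thickness(phantom):
    """The cortical shell should be 1-2 voxels thick at 0.8 mm spacing."""
    gm = phantom.labels == pf.CORTICAL_GM
    interior = phantom.mask & ~gm
    # every GM voxel within 2 voxels of non-GM brain tissue
    dist = ndimage.distance_transform_edt(~interior)
    assert dist[gm].max() <= 2.5


def test_lesion_adjacent_to_ventricles():
    ph = pf.make_phantom((40, 40, 32), seed=1, lesion=True)
    lesion = ph.labels == pf.LESION
    assert lesion.sum() > 0
    near_csf = ndimage.binary_dilation(ph.labels == pf.CSF, iterations=1)
    assert (lesion & near_csf).any()


def test_phantom_rejects_small_grids():
    with pytest.raises(ValueError):
        pf.make_phantom((16, 40, 40))


def test_fieldmap_percentile_calibration(phantom):
    fm = pf.make_fieldmap(phantom, 35.9, seed=0)
    q90 = np.percentile(np.abs(fm.off_resonance_hz[fm.mask]), 90)
    assert abs(q90 / 35.9 - 1) < 1e-3
    # linear 3T -> 7T extrapolation scales the percentile exactly
    scaled = fm.off_resonance_hz * (7.0 / 3.0)
    q90s = np.percentile(np.abs(scaled[fm.mask]), 90)
    assert q90s == pytest.approx(35.9 * 7 / 3, rel=1e-12)
    assert q90s == pytest.approx(83.8, abs=0.05)


def test_fieldmap_zero_and_seed_variation(phantom):
    zero = pf.make_fieldmap(phantom, 0.0, seed=0)
    assert np.all(zero.off_resonance_hz == 0)
    a = pf.make_fieldmap(phantom, 20.0, seed=1)
    b = pf.make_fieldmap(phantom, 20.0, seed=2)
    assert not np.allclose(a.off_resonance_hz, b.off_resonance_hz)
    for fm in (a, b):
        q90 = np.percentile(np.abs(fm.off_resonance_hz[fm.mask]), 90)
        assert abs(q90 / 20.0 - 1) < 1e-3


def _isotropic_phantom(md):
    ph = pf.make_phantom((40, 40, 32), seed=1)
    ph.fa[:] = 0.0
    ph.mk[:] = 0.0
    ph.md_um2_per_ms[ph.mask] = md
    return ph


@pytest.mark.parametrize(
    "b, md, expected",
    [(9000.0, 0.071, math.exp(-0.639)), (4000.0, 0.164, math.exp(-0.656))],
)
def test_dwi_closed_form_attenuation(b, md, expected):
    ph = _isotropic_phantom(md)
    scheme = ShellScheme(np.array([0.0, b]), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    vols = pf.simulate_dwi(ph, scheme, sigma=0.0)
    ratio = vols[..., 1][ph.mask] / vols[..., 0][ph.mask]
    assert np.allclose(ratio, expected, atol=1e-12)


def test_dwi_b0_equals_s0_and_positivity(phantom):
    scheme = ShellScheme.from_shells({6000.0: direction_set(4, seed=0)}, n_b0=1)
    vols = pf.simulate_dwi(phantom, scheme, sigma=0.0, s0=100.0)
    assert np.all(vols[..., 0][phantom.mask] == 100.0)
    dw = vols[..., 1:][phantom.mask]
    assert np.all(dw > 0) and np.all(dw <= 100.0 + 1e-9)


def test_dwi_kurtosis_term_raises_signal(phantom):
    """Positive MK lifts the high-b signal above the Gaussian prediction."""
    scheme = ShellScheme(np.array([0.0, 9000.0]), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    with_k = pf.simulate_dwi(phantom, scheme)
    ph0 = pf.make_phantom((40, 40, 32), seed=1)
    ph0.mk[:] = 0.0
    without_k = pf.simulate_dwi(ph0, scheme)
    wm = phantom.labels == pf.WM
    assert np.all(with_k[..., 1][wm] > without_k[..., 1][wm])


def test_negative_b_rejected():
    with pytest.raises(ValueError):
        pf.kurtosis_signal(np.array([1.0]), np.array([0.1]), np.array([0.0]),
                           np.array([0.0]), np.array([[1.0, 0, 0]]), -10.0,
                           np.array([1.0, 0, 0]))
    with pytest.raises(ValueError):
        ShellScheme(np.array([-10.0]), np.array([[1.0, 0, 0]]))


def test_dwi_noise_determinism_and_rician_mean(phantom):
    scheme = ShellScheme(np.array([0.0]), np.zeros((1, 3)))
    a = pf.simulate_dwi(phantom, scheme, sigma=2.0, seed=9)
    b = pf.simulate_dwi(phantom, scheme, sigma=2.0, seed=9)
    assert np.array_equal(a, b)
    # at SNR 50 the Rician mean converges to the noiseless signal within 1%
    noisy = pf.simulate_dwi(phantom, scheme, sigma=2.0, seed=3, s0=100.0)
    mean = noisy[..., 0][phantom.mask].mean()
    assert abs(mean / 100.0 - 1) < 0.01
    assert np.all(noisy >= 0)


@given(
    b=st.floats(0.0, 10000.0),
    md=st.floats(0.01, 1.5),
    fa=st.floats(0.0, 0.9),
    mk=st.floats(0.0, 2.0),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_kurtosis_signal_positive_and_bounded(b, md, fa, mk):
    s0 = np.array([100.0])
    principal = np.array([[0.6, 0.8, 0.0]])
    sig = pf.kurtosis_signal(s0, np.array([md]), np.array([fa]), np.array([mk]),
                             principal, b, np.array([1.0, 0, 0]))
    assert sig[0] > 0
    if mk == 0:
        assert sig[0] <= 100.0 + 1e-9


@pytest.fixture(scope="module")
def kspace_setup():
    ph = pf.make_phantom((32, 32, 32), seed=0)
    img = ph.t2_ms / 200.0
    coils = pf.make_coils((32, 32, 32), 16, seed=0)
    return ph, img[:, :, 8:16], coils.sensitivities[:, :, :, 8:16], coils


def test_kspace_roundtrip_ideal(kspace_setup):
    ph, img, sens, _ = kspace_setup
    coils = pf.CoilSet(sensitivities=sens, n_coils=16, geometry={})
    geom = AcquisitionGeometry(n_pe=32, n_ro=32, n_slices=8, n_segments=3, R=1, MB=1)
    ks = pf.simulate_kspace(img, coils, geom)
    grid = ks.grid()
    rec = np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(grid, axes=(1, 2)), axes=(1, 2)), axes=(1, 2)
    )
    ref = sens * img[None]
    assert np.abs(rec - ref).max() / np.abs(ref).max() < 1e-10


def test_kspace_line_timing_and_undersampling(kspace_setup):
    _, img, sens, _ = kspace_setup
    coils = pf.CoilSet(sensitivities=sens, n_coils=16, geometry={})
    geom = AcquisitionGeometry(n_pe=32, n_ro=32, n_slices=8, n_segments=2, R=2, MB=2)
    ks = pf.simulate_kspace(img, coils, geom)
    assert ks.pe_indices.size == math.ceil(32 / 2)
    dt = np.diff(ks.line_time_ms)
    assert np.all(dt > 0) and np.allclose(dt, geom.echo_spacing_ms)
    assert len(ks.slice_groups) == 4
    assert ks.n_padding_slices == 0


def test_kspace_slice_padding(kspace_setup):
    _, img, sens, _ = kspace_setup
    coils = pf.CoilSet(sensitivities=sens[:, :, :, :7], n_coils=16, geometry={})
    geom = AcquisitionGeometry(n_pe=32, n_ro=32, n_slices=7, n_segments=2, R=1, MB=2)
    ks = pf.simulate_kspace(img[:, :, :7], coils, geom)
    assert ks.n_padding_slices == 1
    assert ks.n_slices_padded == 8


def test_kspace_noise_seed(kspace_setup):
    _, img, sens, _ = kspace_setup
    coils = pf.CoilSet(sensitivities=sens, n_coils=16, geometry={})
    geom = AcquisitionGeometry(n_pe=32, n_ro=32, n_slices=8, n_segments=2, R=2, MB=1)
    a = pf.simulate_kspace(img, coils, geom, noise_sigma=0.1, seed=4)
    b = pf.simulate_kspace(img, coils, geom, noise_sigma=0.1, seed=4)
    assert np.array_equal(a.samples, b.samples)


def test_coilset_rss_positive_and_deterministic(phantom):
    coils = pf.make_coils(phantom.shape, 16, seed=0)
    assert np.all(coils.rss()[phantom.mask] > 0)
    again = pf.make_coils(phantom.shape, 16, seed=0)
    assert np.array_equal(coils.sensitivities, again.sensitivities)


def test_write_read_roundtrip(tmp_path, phantom):
    from neodmri.protocol_planner import build_schedule

    _, scheme = build_schedule(seed=0)
    rng = np.random.default_rng(0)
    vols = rng.random((8, 8, 4, len(scheme)))
    prefix = str(tmp_path / "dwi")
    paths = pf.write_volumes(vols, scheme, prefix)
    with open(paths["bval"]) as fh:
        assert len(fh.read().split()) == 301
    back, scheme2 = pf.read_volumes(prefix)
    assert np.allclose(back, vols, atol=1e-6)
    assert np.allclose(scheme2.bvals, scheme.bvals)
    assert np.allclose(scheme2.bvecs, scheme.bvecs, atol=1e-7)
    assert np.all(scheme2.bvecs[scheme2.bvals == 0] == 0)


def test_write_volumes_length_mismatch(tmp_path):
    scheme = ShellScheme(np.array([0.0, 1000.0]), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    with pytest.raises(ValueError):
        pf.write_volumes(np.zeros((4, 4, 4, 3)), scheme, str(tmp_path / "x"))
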