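"""Synthetic neonatal head phantom and image-formation forward models.

Everything downstream (PSF/distortion checks, parallel-imaging evaluation,
ADC/DKI/BIC QA) runs on data produced here, so each generator is a pure
function of its seed and parameters.

The anatomy is schematic rather than atlas-based: a brain ellipsoid whose
outer 1-2 voxel shell is cortical grey matter, a white-matter interior,
deep-grey nuclei, paired lateral ventricles (CSF), and optionally a dilated
peri-ventricular lesion ring.  Tissue parameters default to post-mortem
neonatal values at 7T / ~10 degC: white matter T2 178 ms, T2* 83 ms, MD
0.071 um2/ms.  Evaluation targets parameter recovery, not anatomical
realism.

Unit convention used throughout the package: b in s/mm2, diffusivity in
um2/ms, so the diffusion exponent is ``b x D x 1e-3`` (dimensionless).
Voxel axes are 0-based with readout = axis 0, phase encoding = axis 1,
slice = axis 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .epi_geometry import AcquisitionGeometry
from .gradients import ShellScheme

__all__ = [
    "TISSUE_TABLE",
    "TissuePhantom",
    "CoilSet",
    "FieldMap",
    "KSpaceData",
    "make_phantom",
    "make_coils",
    "make_fieldmap",
    "simulate_dwi",
    "simulate_kspace",
    "write_volumes",
    "read_volumes",
]

#: Tissue labels.
BACKGROUND, WM, CORTICAL_GM, DEEP_GM, CSF, LESION = 0, 1, 2, 3, 4, 5

#: Per-tissue parameter table: T2 (ms), T2* (ms), MD (um2/ms), FA, MK.
#: White-matter values anchor the post-mortem 7T working point (T2 178 ms,
#: T2* 83 ms, MD 0.071 um2/ms); CSF diffusivity sits near free water at
#: ~10 degC; the lesion emulates blood-stained dilated-ventricle contents.
TISSUE_TABLE: dict[int, dict[str, float]] = {
    WM: {"t2_ms": 178.0, "t2star_ms": 83.0, "md": 0.071, "fa": 0.40, "mk": 1.2},
    CORTICAL_GM: {"t2_ms": 160.0, "t2star_ms": 70.0, "md": 0.075, "fa": 0.15, "mk": 1.0},
    DEEP_GM: {"t2_ms": 150.0, "t2star_ms": 60.0, "md": 0.080, "fa": 0.10, "mk": 0.9},
    CSF: {"t2_ms": 1800.0, "t2star_ms": 400.0, "md": 1.50, "fa": 0.0, "mk": 0.0},
    LESION: {"t2_ms": 120.0, "t2star_ms": 45.0, "md": 0.30, "fa": 0.0, "mk": 0.5},
}


@dataclass
class TissuePhantom:
    """Labelled parameter volumes plus a principal-direction field."""

    labels: np.ndarray
    t2_ms: np.ndarray
    t2star_ms: np.ndarray
    md_um2_per_ms: np.ndarray
    fa: np.ndarray
    mk: np.ndarray
    principal_dir: np.ndarray  # (*shape, 3) unit vectors
    voxel_size_mm: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def tissue_mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.labels, labels)


@dataclass
class CoilSet:
    """Complex receive sensitivities for a ring array."""

    sensitivities: np.ndarray  # (n_coils, *shape) complex
    n_coils: int
    geometry: dict

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.sensitivities) ** 2, axis=0))


@dataclass
class FieldMap:
    """B0 off-resonance (Hz) with the head mask it was calibrated on."""

    off_resonance_hz: np.ndarray
    mask: np.ndarray
    q90_hz: float


@dataclass
class KSpaceData:
    """Multi-coil, readout-segmented, undersampled k-space.

    ``samples`` is indexed (coil, segment, acquired PE line, readout sample
    within segment, slice group).  ``calibration`` holds per-slice fully
    sampled low-resolution k-space (coil, PE, RO, slice) acquired without
    decay or off-resonance, mirroring a separate calibration prescan.
    """

    samples: np.ndarray
    pe_indices: np.ndarray  # acquired PE line indices on the full grid
    line_time_ms: np.ndarray  # time of each acquired line within the shot
    segment_bounds: np.ndarray  # RO column start of each segment (len n_segments+1)
    MB: int
    R: int
    echo_spacing_ms: float
    slice_groups: list[list[int]]  # members of each collapsed group
    n_slices_padded: int
    n_slices: int
    image_shape: tuple[int, int, int]
    calibration: np.ndarray

    @property
    def n_padding_slices(self) -> int:
        return self.n_slices_padded - self.n_slices

    def grid(self) -> np.ndarray:
        """Zero-filled (coil, n_ro, n_pe, n_groups) k-space grid."""
        n_coils = self.samples.shape[0]
        n_ro, n_pe = self.image_shape[0], self.image_shape[1]
        out = np.zeros((n_coils, n_ro, n_pe, len(self.slice_groups)), dtype=complex)
        for seg in range(len(self.segment_bounds) - 1):
            lo, hi = self.segment_bounds[seg], self.segment_bounds[seg + 1]
            out[:, lo:hi, self.pe_indices, :] = np.moveaxis(
                self.samples[:, seg, :, : hi - lo, :], 1, 2
            )
        return out


def _ellipsoid(shape, center, semi, grids=None) -> np.ndarray:
    zz = grids if grids is not None else np.indices(shape, dtype=float)
    r2 = sum(((zz[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def make_phantom(
    shape: tuple[int, int, int] = (64, 64, 48),
    voxel_size_mm: float = 0.8,
    lesion: bool = False,
    seed: int = 0,
) -> TissuePhantom:
    """Generate the labelled neonatal head phantom.

    Parameters
    ----------
    shape
        Grid size, at least 32 voxels per axis (smaller grids cannot hold a
        1-2 voxel cortical ribbon around distinct interior structures).
    voxel_size_mm
        Isotropic spacing.
    lesion
        Add a dilated-ventricle lesion ring (label 5) around the posterior
        ventricle, adjacent to CSF.
    seed
        Jitters the anatomy slightly (ellipsoid semi-axes) so different
        seeds give different but statistically matched phantoms.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError("each axis must be >= 32 voxels to contain a cortical ribbon")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.03 * rng.standard_normal(3)

    grids = np.indices(shape, dtype=float)
    center = np.array([(s - 1) / 2.0 for s in shape])
    semi = np.array([0.42 * s for s in shape]) * jitter

    brain = _ellipsoid(shape, center, semi, grids)
    # cortical ribbon: outer shell of the brain, 1-2 voxels at 0.8 mm spacing
    ribbon_vox = max(1, int(round(1.2 / voxel_size_mm)))
    interior = ndimage.binary_erosion(brain, iterations=ribbon_vox)
    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = CORTICAL_GM
    labels[interior] = WM

    # deep grey nuclei: paired ellipsoids lateral of the midline
    for side in (-1.0, 1.0):
        c = center + np.array([side * 0.12 * shape[0], 0.0, 0.02 * shape[2]])
        nucleus = _ellipsoid(shape, c, 0.09 * np.array(shape), grids)
        labels[nucleus & interior] = DEEP_GM

    # lateral ventricles: paired CSF ellipsoids anterior of the nuclei
    ventricles = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        c = center + np.array([side * 0.10 * shape[0], -0.12 * shape[1], 0.0])
        v = _ellipsoid(shape, c, np.array([0.05, 0.10, 0.07]) * np.array(shape), grids)
        ventricles |= v
    labels[ventricles & interior] = CSF

    if lesion:
        ring = ndimage.binary_dilation(ventricles, iterations=2) & ~ventricles
        labels[ring & interior & (labels == WM)] = LESION

    def _expand(key: str) -> np.ndarray:
        out = np.zeros(shape, dtype=float)
        for lab, params in TISSUE_TABLE.items():
            out[labels == lab] = params[key]
        return out

    # principal directions: smooth circumferential field in the axial plane
    dx = grids[0] - center[0]
    dy = grids[1] - center[1]
    vec = np.stack([-dy, dx, 0.3 * np.ones(shape)], axis=-1)
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    degenerate = norm[..., 0] < 1e-9
    vec[degenerate] = [1.0, 0.0, 0.0]
    norm[degenerate] = 1.0
    principal = vec / norm

    return TissuePhantom(
        labels=labels,
        t2_ms=_expand("t2_ms"),
        t2star_ms=_expand("t2star_ms"),
        md_um2_per_ms=_expand("md"),
        fa=_expand("fa"),
        mk=_expand("mk"),
        principal_dir=principal,
        voxel_size_mm=float(voxel_size_mm),
    )


def make_coils(
    shape: tuple[int, int, int],
    n_coils: int = 16,
    geometry: dict | None = None,
    seed: int = 0,
) -> CoilSet:
    """Loop-array receive sensitivities: two rings of ``n_coils/2`` elements.

    Element centres sit on two rings just outside the head (geometry
    defaults follow a 117 x 135 x 114 mm infant coil former), with a smooth
    Biot-Savart-like ``1/(r + d)`` magnitude falloff and a slowly varying
    phase.  Deterministic given seed and geometry.
    """
    geometry = geometry or {"radius_a_mm": 117.0 / 2, "radius_b_mm": 135.0 / 2, "length_mm": 114.0}
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    n_ring = max(1, n_coils // 2)
    center = np.array([(s - 1) / 2.0 for s in shape])
    # map grid to mm with the head filling most of the former
    scale = np.array([geometry["radius_a_mm"] * 2.2 / shape[0],
                      geometry["radius_b_mm"] * 2.2 / shape[1],
                      geometry["length_mm"] * 1.2 / shape[2]])
    coords = (np.indices(shape, dtype=float) - center[:, None, None, None]) * scale[:, None, None, None]

    sens = np.empty((n_coils, *shape), dtype=complex)
    idx = 0
    for ring_z in (-geometry["length_mm"] / 4, geometry["length_mm"] / 4):
        for k in range(n_ring):
            if idx >= n_coils:
                break
            ang = 2 * np.pi * k / n_ring + (np.pi / n_ring if ring_z > 0 else 0.0)
            cpos = np.array([geometry["radius_a_mm"] * np.cos(ang),
                             geometry["radius_b_mm"] * np.sin(ang),
                             ring_z])
            d = np.sqrt(sum((coords[i] - cpos[i]) ** 2 for i in range(3)))
            amp = (1.0 + 0.05 * rng.standard_normal()) / (d / 40.0 + 0.5)
            phase = (coords[0] * np.cos(ang) + coords[1] * np.sin(ang)) / 80.0 \
                + 0.3 * rng.standard_normal()
            sens[idx] = amp * np.exp(1j * phase)
            idx += 1
    return CoilSet(sensitivities=sens, n_coils=n_coils, geometry=geometry)


def make_fieldmap(
    phantom: TissuePhantom,
    q90_hz: float,
    smoothness_mm: float = 8.0,
    seed: int = 0,
) -> FieldMap:
    """Smooth random B0 off-resonance map calibrated to a target percentile.

    Gaussian white noise is low-pass filtered to correlation length
    ``smoothness_mm`` and rescaled so the 90th percentile of |f| within the
    head mask equals ``q90_hz`` (exact up to floating point; the contract
    is 0.1%).  A stand-in for a measured infant field map linearly scaled
    to field strength — scaling the map by ``alpha`` scales its percentile
    by ``alpha`` exactly.
    """
    if q90_hz < 0:
        raise ValueError("q90_hz must be >= 0")
    mask = phantom.mask
    if not mask.any():
        raise ValueError("phantom mask is empty")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(phantom.shape)
    sigma_vox = smoothness_mm / phantom.voxel_size_mm
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    f -= f[mask].mean()
    if q90_hz == 0:
        f = np.zeros_like(f)
    else:
        current = np.percentile(np.abs(f[mask]), 90)
        if current == 0:
            raise ValueError("degenerate field map; increase shape or reduce smoothness")
        f *= q90_hz / current
    f[~mask] = 0.0
    return FieldMap(off_resonance_hz=f, mask=mask, q90_hz=float(q90_hz))


def _axisym_eigenvalues(md: np.ndarray, fa: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (lam_par, lam_perp) of an axially symmetric tensor with
    the requested MD and FA: lam_par = MD(1+2d), lam_perp = MD(1-d) with
    d = FA / sqrt(3 - 2 FA^2)."""
    delta = fa / np.sqrt(3.0 - 2.0 * fa**2)
    return md * (1.0 + 2.0 * delta), md * (1.0 - delta)


def kurtosis_signal(
    s0: np.ndarray,
    md: np.ndarray,
    fa: np.ndarray,
    mk: np.ndarray,
    principal: np.ndarray,
    bval: float,
    bvec: np.ndarray,
) -> np.ndarray:
    """Noiseless kurtosis-representation signal for one volume.

    ``S = S0 exp(-b d_app 1e-3 + (1/6) b^2 d_app^2 1e-6 k_app)`` with
    ``d_app`` the directional diffusivity of the axially symmetric tensor
    built from (MD, FA, principal direction) and ``k_app`` the scalar MK.
    """
    if bval < 0:
        raise ValueError("negative b-value")
    if bval == 0:
        return s0.copy()
    lam_par, lam_perp = _axisym_eigenvalues(md, fa)
    cos = principal @ np.asarray(bvec, dtype=float)
    d_app = lam_perp + (lam_par - lam_perp) * cos**2
    c = bval * 1e-3
    return s0 * np.exp(-c * d_app + (c**2) * (d_app**2) * mk / 6.0)


def simulate_dwi(
    phantom: TissuePhantom,
    scheme: ShellScheme,
    sigma: float = 0.0,
    drift: np.ndarray | float | None = None,
    seed: int = 0,
    s0: float = 100.0,
) -> np.ndarray:
    """Simulate magnitude diffusion-weighted volumes.

    Parameters
    ----------
    phantom, scheme
        Ground-truth parameter maps and the gradient table (one volume per
        scheme entry).
    sigma
        Complex-channel noise scale; magnitudes are Rician
        (``sqrt((S+n1)^2 + n2^2)`` with iid Gaussian n1, n2).
    drift
        Per-volume multiplicative factor on MD (length N or scalar),
        emulating slow ADC drift across a session, e.g. thermal settling.
    seed
        Noise seed.

    Returns a float array of shape ``(*phantom.shape, N)``.
    """
    if len(scheme) == 0:
        raise ValueError("scheme is empty")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    n = len(scheme)
    if drift is None:
        drift_arr = np.ones(n)
    else:
        drift_arr = np.broadcast_to(np.atleast_1d(np.asarray(drift, dtype=float)), (n,)) \
            if np.ndim(drift) <= 1 and np.size(drift) in (1, n) else None
        if drift_arr is None:
            raise ValueError("drift must be scalar or one factor per volume")

    s0_map = np.where(phantom.mask, s0, 0.0)
    rng = np.random.default_rng(seed)
    out = np.empty((*phantom.shape, n), dtype=float)
    for v in range(n):
        sig = kurtosis_signal(
            s0_map,
            phantom.md_um2_per_ms * drift_arr[v],
            phantom.fa,
            phantom.mk,
            phantom.principal_dir,
            float(scheme.bvals[v]),
            scheme.bvecs[v],
        )
        if sigma > 0:
            re = sig + sigma * rng.standard_normal(sig.shape)
            im = sigma * rng.standard_normal(sig.shape)
            sig = np.sqrt(re**2 + im**2)
        out[..., v] = sig
    return out


def _segment_bounds(n_ro: int, n_segments: int) -> np.ndarray:
    sizes = [n_ro // n_segments + (1 if i < n_ro % n_segments else 0) for i in range(n_segments)]
    return np.concatenate([[0], np.cumsum(sizes)])


def simulate_kspace(
    image: np.ndarray,
    coils: CoilSet,
    geom: AcquisitionGeometry,
    t2star_ms: float | np.ndarray = math.inf,
    fieldmap: FieldMap | None = None,
    seed: int = 0,
    noise_sigma: float = 0.0,
    cal_lines: int = 24,
) -> KSpaceData:
    """Encode an object into segmented, multiband, undersampled k-space.

    Each acquired PE line at time ``t`` within the shot carries an amplitude
    factor ``exp(-t/T2*)`` and per-voxel phase ``2 pi f t`` from the field
    map before spatial encoding.  The PE traversal is linear (monotonic)
    with decay measured from the first acquired line.  Slice groups collapse
    MB slices (padding with empty slices when MB does not divide the slice
    count; the padding is recorded).  A fully sampled low-resolution
    per-slice calibration block is encoded separately without decay or
    off-resonance.
    """
    img = np.asarray(image)
    n_ro, n_pe, n_sl = img.shape
    if coils.sensitivities.shape[1:] != img.shape:
        raise ValueError("coil maps and image are not commensurate")
    t2s = np.broadcast_to(np.asarray(t2star_ms, dtype=float), img.shape)
    f_hz = np.zeros(img.shape) if fieldmap is None else np.asarray(fieldmap.off_resonance_hz, dtype=float)
    if f_hz.shape != img.shape:
        raise ValueError("field map and image are not commensurate")

    mb, r = geom.MB, geom.R
    n_pad = (-n_sl) % mb
    n_sl_pad = n_sl + n_pad
    n_groups = n_sl_pad // mb
    slice_groups = [[g + k * n_groups for k in range(mb)] for g in range(n_groups)]

    pe_indices = np.arange(0, n_pe, r)
    line_time_ms = np.arange(pe_indices.size) * geom.echo_spacing_ms
    bounds = _segment_bounds(n_ro, geom.n_segments)

    coil_img = coils.sensitivities * img[None]  # (nc, ro, pe, sl)
    n_coils = coil_img.shape[0]
    samples = np.zeros(
        (n_coils, geom.n_segments, pe_indices.size, int(np.diff(bounds).max()), n_groups),
        dtype=complex,
    )
    for j, (pe, t_ms) in enumerate(zip(pe_indices, line_time_ms)):
        t_s = t_ms / 1000.0
        with np.errstate(divide="ignore"):
            weight = np.exp(-(t_ms / t2s)) * np.exp(2j * np.pi * f_hz * t_s)
        modulated = coil_img * weight[None]
        # PE transform, pick this line, then RO transform
        line = np.fft.fftshift(
            np.fft.fft(np.fft.ifftshift(modulated, axes=2), axis=2), axes=2
        )[:, :, pe, :]
        line = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(line, axes=1), axis=1), axes=1)
        if n_pad:
            line = np.concatenate([line, np.zeros((n_coils, n_ro, n_pad), dtype=complex)], axis=2)
        collapsed = line.reshape(n_coils, n_ro, mb, n_groups).sum(axis=2)
        for seg in range(geom.n_segments):
            lo, hi = bounds[seg], bounds[seg + 1]
            samples[:, seg, j, : hi - lo, :] = collapsed[:, lo:hi, :]

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        samples = samples + noise_sigma * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        )

    # ideal per-slice calibration: central cal_lines PE lines, all RO columns
    full_k = np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(coil_img, axes=(1, 2)), axes=(1, 2)), axes=(1, 2)
    )
    lo = n_pe // 2 - cal_lines // 2
    calibration = full_k[:, :, lo : lo + cal_lines, :]
    calibration = np.moveaxis(calibration, 2, 1)  # (coil, cal_pe, ro, slice)

    return KSpaceData(
        samples=samples,
        pe_indices=pe_indices,
        line_time_ms=line_time_ms,
        segment_bounds=bounds,
        MB=mb,
        R=r,
        echo_spacing_ms=geom.echo_spacing_ms,
        slice_groups=slice_groups,
        n_slices_padded=n_sl_pad,
        n_slices=n_sl,
        image_shape=(n_ro, n_pe, n_sl),
        calibration=calibration,
    )


def write_volumes(
    volumes: np.ndarray,
    scheme: ShellScheme,
    prefix: str,
    voxel_size_mm: float = 0.8,
) -> dict[str, str]:
    """Write a 4-D series as NIfTI-1 plus FSL-dialect bval/bvec files.

    ``bval`` is one whitespace-separated row; ``bvec`` is three rows of
    x/y/z components with zero columns for b=0 volumes.  Returns the paths
    written.  Raises when the series length and scheme disagree.
    """
    volumes = np.asarray(volumes)
    if volumes.ndim != 4 or volumes.shape[3] != len(scheme):
        raise ValueError("volume count and scheme length disagree")
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    paths = {
        "nifti": f"{prefix}.nii.gz",
        "bval": f"{prefix}.bval",
        "bvec": f"{prefix}.bvec",
    }
    nib.save(nib.Nifti1Image(volumes.astype(np.float32), affine), paths["nifti"])
    np.savetxt(paths["bval"], scheme.bvals[None], fmt="%g")
    np.savetxt(paths["bvec"], scheme.bvecs.T, fmt="%.8f")
    return paths


def read_volumes(prefix: str) -> tuple[np.ndarray, ShellScheme]:
    """Read a series written by :func:`write_volumes`."""
    img = nib.load(f"{prefix}.nii.gz")
    vols = np.asarray(img.dataobj, dtype=float)
    bvals = np.loadtxt(f"{prefix}.bval")
    bvecs = np.loadtxt(f"{prefix}.bvec").T
    return vols, ShellScheme(np.atleast_1d(bvals), np.atleast_2d(bvecs))
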