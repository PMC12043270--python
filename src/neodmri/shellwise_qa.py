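"""Quantitative QA of multi-shell diffusion data.

Four estimators operating on (synthetic or real) diffusion-weighted volumes
with an FSL-style gradient table:

* per-shell ADC from the direction-averaged (powder) signal, with
  per-tissue medians and attenuation factors;
* acquisition-sub-group ADC stability across a long session (median ADC per
  interleaved subset, coefficient of variation per tissue);
* diffusion kurtosis fitting — an axially-constrained representation with a
  full diffusion tensor and a single scalar kurtosis term, solved by
  iterated weighted linear least squares — yielding S0/MD/FA/MO/MK maps;
* BIC model selection over a grid of fixed axial diffusivities for a
  pluggable model family, with the dispersion-free three-compartment
  family (intra-neurite stick, tortuosity-linked hindered, free and
  restricted isotropic water) bundled.

Conventions: log-linear fits exclude non-positive magnitudes voxel-wise
(and count them) rather than clamping; ADC/MD are in um2/ms with the
``b x D x 1e-3`` exponent convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .gradients import ShellScheme
from .phantom_forge import WM, CORTICAL_GM, DEEP_GM, CSF
from .protocol_planner import AcquisitionSchedule

__all__ = [
    "ShellStats",
    "StabilityReport",
    "DKIMaps",
    "BICCurve",
    "fit_adc",
    "subgroup_stability",
    "fit_dki",
    "bic_grid_select",
    "MonoExponentialFamily",
    "ThreeCompartmentFamily",
]

TISSUE_GROUPS = {"WM": (WM,), "GM": (CORTICAL_GM, DEEP_GM), "CSF": (CSF,)}


@dataclass
class ShellStats:
    """Per-tissue medians for one b shell."""

    shell_b: float
    median_adc: dict[str, float]
    median_attenuation: dict[str, float]
    voxel_count: dict[str, int]
    n_excluded_nonpositive: int = 0


@dataclass
class StabilityReport:
    """Sub-group ADC series and its per-tissue coefficient of variation."""

    mid_times: np.ndarray  # acquisition mid-time of each sub-group (volume index units)
    median_adc: dict[str, np.ndarray]  # per tissue, one value per sub-group
    cov: dict[str, float]  # std/mean of the sub-group medians
    shell_b: float = 0.0


@dataclass
class DKIMaps:
    """Kurtosis-fit parameter maps."""

    s0: np.ndarray
    md: np.ndarray
    fa: np.ndarray
    mo: np.ndarray
    mk: np.ndarray
    residual: np.ndarray
    negative_eigen: np.ndarray  # bool flag map
    isotropic_flag: np.ndarray  # MO reported as 0 where FA ~ 0


@dataclass
class BICCurve:
    """Mean BIC over a fixed-axial-diffusivity grid."""

    grid: np.ndarray
    mean_bic: np.ndarray
    argmin: float
    flat: bool
    sensitivity: dict = field(default_factory=dict)


def _powder_mean(volumes: np.ndarray, scheme: ShellScheme, b: float) -> np.ndarray:
    sel = scheme.shell_mask(b)
    if not sel.any():
        raise ValueError(f"no volumes at b={b}")
    return volumes[..., sel].mean(axis=-1)


def fit_adc(
    volumes: np.ndarray,
    scheme: ShellScheme,
    shell_b: float,
    mask: np.ndarray,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, ShellStats]:
    """Powder-averaged ADC of one shell against the b=0 signal.

    The direction-averaged shell signal is regressed log-linearly on b
    (with only b=0 and one shell this is the exact log-ratio).  Voxels with
    non-positive signal are excluded from the fit and counted.  Per-tissue
    medians use ``labels`` (WM=1, GM=2+3, CSF=4).
    """
    if not scheme.shell_mask(0.0).any():
        raise ValueError("scheme contains no b=0 volume")
    s0 = _powder_mean(volumes, scheme, 0.0)
    s_shell = _powder_mean(volumes, scheme, shell_b)
    mask = np.asarray(mask, dtype=bool)
    valid = mask & (s0 > 0) & (s_shell > 0)
    n_excluded = int(mask.sum() - valid.sum())
    adc = np.full(s0.shape, np.nan)
    adc[valid] = np.log(s0[valid] / s_shell[valid]) / (shell_b * 1e-3)

    med_adc, med_att, counts = {}, {}, {}
    if labels is not None:
        att = np.full(s0.shape, np.nan)
        att[valid] = s_shell[valid] / s0[valid]
        for name, labs in TISSUE_GROUPS.items():
            sel = np.isin(labels, labs) & valid
            counts[name] = int(sel.sum())
            med_adc[name] = float(np.median(adc[sel])) if counts[name] else float("nan")
            med_att[name] = float(np.median(att[sel])) if counts[name] else float("nan")
    stats = ShellStats(
        shell_b=float(shell_b), median_adc=med_adc, median_attenuation=med_att,
        voxel_count=counts, n_excluded_nonpositive=n_excluded,
    )
    return adc, stats


def subgroup_stability(
    volumes: np.ndarray,
    schedule: AcquisitionSchedule,
    labels: np.ndarray,
    shell_b: float | None = None,
    tissues: tuple[str, ...] = ("WM", "GM"),
) -> StabilityReport:
    """ADC stability across the interleaved sub-groups of one shell.

    For each scheduled subset of the chosen shell (default: the highest b),
    the ADC is fitted from the subset's own opening b=0 volume and its
    shell members (falling back to the nearest scheduled b=0 when a subset
    has none), and the per-tissue median is recorded against the subset's
    acquisition mid-time.  The coefficient of variation (std/mean of the
    sub-group medians) summarises drift.
    """
    positions = np.array([e.position for e in schedule.entries])
    bvals = np.array([e.b for e in schedule.entries])
    if shell_b is None:
        shell_b = float(bvals.max())
    subset_ids = [i for i, b in enumerate(schedule.subset_b) if abs(b - shell_b) <= 1.0]
    if not subset_ids:
        raise ValueError(f"schedule has no subsets at b={shell_b}")

    b0_positions = positions[bvals == 0]
    mid_times, medians = [], {t: [] for t in tissues}
    for sid in subset_ids:
        members = schedule.subset_members(sid)
        shell_pos = [e.position for e in members if e.b > 0]
        b0_pos = [e.position for e in members if e.b == 0]
        if not b0_pos:  # nearest scheduled b=0 by acquisition position
            centre = np.mean(shell_pos)
            b0_pos = [int(b0_positions[np.argmin(np.abs(b0_positions - centre))])]
        s0 = volumes[..., b0_pos].mean(axis=-1)
        s_shell = volumes[..., shell_pos].mean(axis=-1)
        valid = (s0 > 0) & (s_shell > 0)
        adc = np.full(s0.shape, np.nan)
        adc[valid] = np.log(s0[valid] / s_shell[valid]) / (shell_b * 1e-3)
        mid_times.append(float(np.mean([e.position for e in members])))
        for t in tissues:
            sel = np.isin(labels, TISSUE_GROUPS[t]) & valid
            medians[t].append(float(np.median(adc[sel])) if sel.any() else float("nan"))

    med = {t: np.asarray(v) for t, v in medians.items()}
    cov = {
        t: float(np.std(v, ddof=1) / np.mean(v)) if np.mean(v) != 0 else float("nan")
        for t, v in med.items()
    }
    return StabilityReport(
        mid_times=np.asarray(mid_times), median_adc=med, cov=cov, shell_b=float(shell_b)
    )


# ---------------------------------------------------------------------------
# diffusion kurtosis fit
# ---------------------------------------------------------------------------

def _tensor_design(scheme: ShellScheme) -> tuple[np.ndarray, np.ndarray]:
    g = scheme.bvecs
    c = scheme.bvals * 1e-3
    quad = np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=1,
    )
    return c, quad


def _tensor_metrics(D6: np.ndarray) -> tuple[np.ndarray, ...]:
    """MD, FA, MO and eigen flags from stacked tensor components (n, 6)."""
    n = D6.shape[0]
    T = np.empty((n, 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = D6[:, 0], D6[:, 1], D6[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = D6[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = D6[:, 4]
    T[:, 1, 2] = T[:, 2, 1] = D6[:, 5]
    ev = np.linalg.eigvalsh(T)
    md = ev.mean(axis=1)
    dev = ev - md[:, None]
    norm2 = np.sum(ev**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum(dev**2, axis=1) / np.where(norm2 > 0, norm2, np.nan))
    dev_norm = np.sqrt(np.sum(dev**2, axis=1))
    iso = dev_norm < 1e-9 * np.maximum(np.abs(md), 1e-30)
    mo = np.zeros(n)
    nz = ~iso
    # mode of anisotropy: 3 sqrt(6) det(deviatoric / |deviatoric|)
    mo[nz] = 3.0 * np.sqrt(6.0) * np.prod(dev[nz] / dev_norm[nz, None], axis=1)
    fa = np.where(iso, 0.0, fa)
    neg = ev.min(axis=1) < 0
    return md, np.clip(np.nan_to_num(fa), 0.0, 1.0), np.clip(mo, -1.0, 1.0), iso, neg


def fit_dki(
    volumes: np.ndarray,
    scheme: ShellScheme,
    mask: np.ndarray,
    n_iter: int = 6,
) -> DKIMaps:
    """Kurtosis fit: full tensor plus a scalar kurtosis term.

    Per voxel, ``ln S = ln S0 - b d_app 1e-3 + (1/6) b^2 d_app^2 1e-6 K``
    with ``d_app = g^T D g``.  The quadratic dependence of the kurtosis
    regressor on the tensor is handled by iterating a weighted linear
    least-squares solve, recomputing ``d_app`` from the current tensor
    estimate each round (signal-squared weights, the standard WLLS
    weighting for log-linear diffusion fits).

    Requires at least two nonzero shells and more measurements than the
    eight parameters; isotropic voxels get MO = 0 with a flag, and voxels
    with negative tensor eigenvalues are flagged.
    """
    if len(scheme.shells) < 2:
        raise ValueError("kurtosis fitting needs at least two nonzero b shells")
    if len(scheme) < 8:
        raise ValueError("fewer measurements than the 8 model parameters")
    c, quad = _tensor_design(scheme)
    mask = np.asarray(mask, dtype=bool)
    vox = volumes[mask]  # (nvox, nvol)
    pos = vox > 0
    if not pos.all():
        # exclude non-positive magnitudes voxel-wise via zero weights
        pass
    y = np.log(np.where(pos, vox, 1.0))
    w = np.where(pos, vox, 0.0) ** 2  # WLLS weights; zero drops excluded points

    nvox, nvol = vox.shape
    X_base = np.concatenate([np.ones((nvol, 1)), -c[:, None] * quad], axis=1)
    params = np.zeros((nvox, 8))
    # first pass without the kurtosis column
    for it in range(n_iter):
        if it == 0:
            u = np.zeros((nvox, nvol))
        else:
            d_app = params[:, 1:7] @ quad.T  # (nvox, nvol)
            u = (c[None, :] ** 2) * d_app**2 / 6.0
        sol = np.empty((nvox, 8))
        for v in range(nvox):
            X = np.concatenate([X_base, u[v][:, None]], axis=1)
            Xw = X * w[v][:, None]
            A = Xw.T @ X
            b = Xw.T @ y[v]
            try:
                sol[v] = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                sol[v] = np.linalg.lstsq(A, b, rcond=None)[0]
        params = sol

    d_app = params[:, 1:7] @ quad.T
    fit_y = X_base @ params[:, :7].T
    fit_y = fit_y.T + (c[None, :] ** 2) * d_app**2 / 6.0 * params[:, 7:8]
    rss = np.sum(w * (y - fit_y) ** 2, axis=1) / np.maximum(w.sum(axis=1), 1e-30)

    md, fa, mo, iso, neg = _tensor_metrics(params[:, 1:7])

    def _map(vals, fill=0.0, dtype=float):
        out = np.full(mask.shape, fill, dtype=dtype)
        out[mask] = vals
        return out

    return DKIMaps(
        s0=_map(np.exp(params[:, 0])),
        md=_map(md),
        fa=_map(fa),
        mo=_map(mo),
        mk=_map(params[:, 7]),
        residual=_map(rss),
        negative_eigen=_map(neg, fill=False, dtype=bool),
        isotropic_flag=_map(iso, fill=False, dtype=bool),
    )


# ---------------------------------------------------------------------------
# BIC grid selection over fixed axial diffusivity
# ---------------------------------------------------------------------------

def default_diffusivity_grid() -> np.ndarray:
    """Fixed axial diffusivities 0.01 then 0.05..1.0 in 0.05 um2/ms steps."""
    return np.concatenate([[0.01], np.round(np.arange(0.05, 1.0001, 0.05), 2)])


class MonoExponentialFamily:
    """Isotropic mono-exponential decay with the diffusivity held fixed.

    With D fixed at the grid value, only the amplitude is estimated
    (closed-form weighted projection), so the BIC grid search reduces to a
    brute-force scan for the best-matching decay rate.
    """

    n_params = 1
    valid_range = (0.0, 5.0)

    def fit(self, signals: np.ndarray, scheme: ShellScheme, d_fixed: float):
        atten = np.exp(-scheme.bvals * 1e-3 * d_fixed)  # (nvol,)
        s0 = (signals @ atten) / (atten @ atten)
        rss = np.sum((signals - s0[:, None] * atten[None, :]) ** 2, axis=1)
        return rss, self.n_params


class ThreeCompartmentFamily:
    """Dispersion-free stick + hindered + free-iso + restricted-iso model.

    Signal fractions f over four compartments sharing an axial diffusivity
    ``d_par``: an intra-neurite stick ``exp(-c d_par (g.n)^2)``, an
    extra-neurite hindered tensor with tortuosity-linked
    ``d_perp = d_par (1 - phi)``, free isotropic water at ``d_free``, and a
    fully restricted isotropic pool (no attenuation).  Fitting holds
    ``d_par`` fixed, estimates the fibre axis from a log-linear tensor fit,
    scans the tortuosity fraction ``phi`` over a coarse grid and solves the
    four non-negative amplitudes by NNLS; five effective parameters.
    """

    n_params = 5
    valid_range = (0.005, 3.0)

    def __init__(self, d_free: float = 1.5, phi_grid: np.ndarray | None = None):
        self.d_free = d_free
        self.phi_grid = np.linspace(0.05, 0.95, 13) if phi_grid is None else phi_grid

    # -- forward model ------------------------------------------------------
    def synthesize(
        self,
        scheme: ShellScheme,
        d_par: float,
        fractions: np.ndarray,
        axes: np.ndarray,
        s0: float = 1.0,
    ) -> np.ndarray:
        """Noiseless signals for per-voxel fractions (nvox, 4) and axes (nvox, 3)."""
        fractions = np.asarray(fractions, dtype=float)
        axes = np.asarray(axes, dtype=float)
        c = scheme.bvals * 1e-3
        cos2 = (axes @ scheme.bvecs.T) ** 2  # (nvox, nvol)
        f_ic = fractions[:, 0] / np.maximum(fractions[:, 0] + fractions[:, 1], 1e-12)
        d_perp = d_par * (1.0 - f_ic)
        a_stick = np.exp(-c[None, :] * d_par * cos2)
        a_hind = np.exp(-c[None, :] * (d_perp[:, None] + (d_par - d_perp[:, None]) * cos2))
        a_free = np.exp(-c * self.d_free)[None, :] * np.ones((len(axes), 1))
        a_rest = np.ones_like(a_stick)
        basis = np.stack([a_stick, a_hind, a_free, a_rest], axis=1)  # (nvox, 4, nvol)
        return s0 * np.einsum("vk,vkn->vn", fractions, basis)

    # -- fitting with fixed axial diffusivity -------------------------------
    def _axes_from_tensor(self, signals: np.ndarray, scheme: ShellScheme) -> np.ndarray:
        c, quad = _tensor_design(scheme)
        y = np.log(np.maximum(signals, 1e-12))
        X = np.concatenate([np.ones((len(c), 1)), -c[:, None] * quad], axis=1)
        beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # (nvox, 7)
        n = signals.shape[0]
        axes = np.empty((n, 3))
        T = np.empty((3, 3))
        for v in range(n):
            D6 = beta[v, 1:7]
            T[0, 0], T[1, 1], T[2, 2] = D6[0], D6[1], D6[2]
            T[0, 1] = T[1, 0] = D6[3]
            T[0, 2] = T[2, 0] = D6[4]
            T[1, 2] = T[2, 1] = D6[5]
            evals, evecs = np.linalg.eigh(T)
            axes[v] = evecs[:, -1]
        return axes

    def fit(self, signals: np.ndarray, scheme: ShellScheme, d_fixed: float):
        axes = self._axes_from_tensor(signals, scheme)
        c = scheme.bvals * 1e-3
        cos2 = (axes @ scheme.bvecs.T) ** 2
        a_free = np.exp(-c * self.d_free)
        nvox, nvol = signals.shape
        rss = np.full(nvox, np.inf)
        a_stick = np.exp(-c[None, :] * d_fixed * cos2)
        for phi in self.phi_grid:
            d_perp = d_fixed * (1.0 - phi)
            a_hind = np.exp(-c[None, :] * (d_perp + (d_fixed - d_perp) * cos2))
            for v in range(nvox):
                basis = np.stack([a_stick[v], a_hind[v], a_free, np.ones(nvol)], axis=1)
                _, res = nnls(basis, signals[v])
                rss[v] = min(rss[v], res**2)
        return rss, self.n_params


def bic_grid_select(
    volumes: np.ndarray,
    scheme: ShellScheme,
    mask: np.ndarray,
    model_family,
    grid: np.ndarray | None = None,
    flatness_delta: float = 2.0,
) -> BICCurve:
    """Select a fixed axial diffusivity by mean BIC over a mask.

    For each grid point the family is refitted with that diffusivity held
    fixed; the per-voxel ``BIC = n ln(RSS/n) + k ln(n)`` is averaged over
    the mask.  The flatness flag is raised when the BIC of both grid
    neighbours of the argmin lies within ``flatness_delta`` (a flat
    selection valley, in which parameters conditioned on the choice should
    be treated with care).  The curve also records the relative change of
    the fitted diffusivity-conditioned RSS between the argmin and its
    neighbours as a sensitivity report.
    """
    grid = default_diffusivity_grid() if grid is None else np.asarray(grid, dtype=float)
    lo, hi = model_family.valid_range
    if np.any(grid < lo) or np.any(grid > hi):
        raise ValueError(f"grid outside model validity range [{lo}, {hi}]")
    mask = np.asarray(mask, dtype=bool)
    signals = volumes[mask]
    n = signals.shape[1]
    mean_bic = np.empty(grid.size)
    for i, d in enumerate(grid):
        rss, k = model_family.fit(signals, scheme, float(d))
        bic = n * np.log(np.maximum(rss, 1e-30) / n) + k * np.log(n)
        mean_bic[i] = float(bic.mean())
    imin = int(np.argmin(mean_bic))
    neighbours = [j for j in (imin - 1, imin + 1) if 0 <= j < grid.size]
    flat = all(mean_bic[j] - mean_bic[imin] < flatness_delta for j in neighbours)
    sensitivity = {
        float(grid[j]): float(mean_bic[j] - mean_bic[imin]) for j in neighbours
    }
    return BICCurve(
        grid=grid, mean_bic=mean_bic, argmin=float(grid[imin]), flat=flat,
        sensitivity=sensitivity,
    )
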