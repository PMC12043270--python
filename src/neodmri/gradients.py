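"""Multi-shell gradient tables: b-values, unit direction sets and the
FSL-dialect container shared by the phantom simulator and the QA fitters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ShellScheme", "direction_set"]


@dataclass(frozen=True)
class ShellScheme:
    """A diffusion sampling scheme: one b-value and unit direction per volume.

    ``bvals`` has shape (N,), in s/mm2; ``bvecs`` has shape (N, 3) with unit
    rows for b > 0 and zero rows for b = 0 (FSL convention).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must have shape (len(bvals), 3)")
        if np.any(bvals < 0):
            raise ValueError("negative b-values are not allowed")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values."""
        return np.unique(self.bvals[self.bvals > 0])

    def shell_mask(self, b: float, tol: float = 1.0) -> np.ndarray:
        return np.abs(self.bvals - b) <= tol

    @classmethod
    def from_shells(cls, shells: dict[float, np.ndarray], n_b0: int = 1) -> "ShellScheme":
        """Concatenate ``n_b0`` leading b=0 volumes with per-shell direction sets."""
        bvals = [np.zeros(n_b0)]
        bvecs = [np.zeros((n_b0, 3))]
        for b, dirs in shells.items():
            dirs = np.asarray(dirs, dtype=float)
            bvals.append(np.full(len(dirs), float(b)))
            bvecs.append(dirs)
        return cls(np.concatenate(bvals), np.vstack(bvecs))


def direction_set(n: int, seed: int = 0, n_iter: int = 200, step: float = 0.05) -> np.ndarray:
    """Approximately uniform antipodally symmetric unit directions.

    Electrostatic-repulsion descent on the sphere: each direction repels
    every other direction and its antipode with an inverse-square force,
    starting from a seeded random configuration.  Deterministic given
    ``seed``.  Returns an (n, 3) array of unit vectors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if n == 1:
        return v
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            diff = v[:, None, :] - sign * v[None, :, :]  # (n, n, 3)
            dist2 = np.sum(diff**2, axis=2)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:
                # own antipode sits at distance 2; keep that term, it is finite
                np.fill_diagonal(dist2, 4.0)
            force += np.sum(diff / (dist2**1.5)[..., None], axis=1)
        # project onto tangent plane and take a small step
        force -= np.sum(force * v, axis=1, keepdims=True) * v
        fmax = np.abs(force).max()
        if fmax > 0:
            v = v + step * force / fmax
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def min_pairwise_angle(dirs: np.ndarray) -> float:
    """Smallest pairwise angle (degrees) between axes, antipodally folded."""
    dots = np.abs(dirs @ dirs.T)
    np.fill_diagonal(dots, -1.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))
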