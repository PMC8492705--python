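"""Momentum-basis representation of the pseudo-wavefunction.

Electrode positions are scattered points, and so are the momentum sampling
points, so the change of basis is a scattered-to-scattered (type-3)
nonuniform discrete Fourier transform

    phi_k(t) = sum_j psi_j(t) exp(-i (p_xk x_j + p_yk y_j)),

with the negative exponent as the forward (position -> momentum) convention
and momenta in reciprocal centimetres.  At the channel counts this package
targets (tens to a few hundred electrodes and momentum points) the transform
is evaluated exactly: the kernel matrix exp(-i p_k . r_j) is precomputed once
and applied to all samples in a single matrix product, which is both exact
and faster than FFT-accelerated approximations at this size.  A per-sample
explicit-sum evaluation (nudft_direct) is kept as an independent oracle.

The default momentum grid has exactly 92 points — the integer lattice
p_x in {-4..4} x p_y in {-4..5} (90 points) plus (-5,-4) and (-4,-5) — so a
92-channel montage pairs one-to-one with momentum points in the
index-matched sums used by the uncertainty module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .montage import Montage
from .wavefunction import NORM_TOL, PseudoWavefunction

logger = logging.getLogger(__name__)

__all__ = [
    "MomentumGrid",
    "MomentumProbability",
    "default_momentum_grid",
    "nudft_direct",
    "to_momentum_basis",
    "momentum_probability",
    "average_momentum_spectral",
]


@dataclass(frozen=True)
class MomentumGrid:
    """Ordered 2-D momentum sampling points (reciprocal cm, mass = 1).

    Point order is fixed: it defines the momentum index used wherever a
    momentum point is paired with an electrode index.
    """

    points: np.ndarray  # (N_p, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (N_p, 2)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def px(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def py(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class MomentumProbability:
    """Momentum-basis probability, momentum points x samples."""

    Ptilde: np.ndarray
    fs: float
    normalized: bool = True

    def __post_init__(self) -> None:
        self.Ptilde = np.asarray(self.Ptilde, dtype=float)
        if (self.Ptilde < 0).any():
            raise ValueError("momentum probabilities must be nonnegative")
        if self.normalized:
            sums = self.Ptilde.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=NORM_TOL, rtol=0):
                t = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"column {t} sums to {sums[t]!r}, expected 1"
                )


def default_momentum_grid() -> MomentumGrid:
    """The 92-point grid: integer lattice p_x in {-4..4} x p_y in {-4..5}
    ordered by p_x then p_y (both ascending), followed by (-5,-4) and
    (-4,-5)."""
    lattice = [(px, py) for px in range(-4, 5) for py in range(-4, 6)]
    return MomentumGrid(np.array(lattice + [(-5, -4), (-4, -5)], dtype=float))


def _kernel(montage: Montage, grid: MomentumGrid) -> np.ndarray:
    """(N_p, N) matrix exp(-i p_k . r_j) over projected electrode positions."""
    xy = montage.xy
    phase = grid.points @ xy.T  # (N_p, N)
    return np.exp(-1j * phase)


def _as_psi(wf) -> np.ndarray:
    psi = wf.psi if isinstance(wf, PseudoWavefunction) else np.asarray(wf)
    if psi.ndim != 2:
        raise ValueError("expected a channels x samples matrix")
    return psi.astype(complex, copy=False)


def nudft_direct(wf, montage: Montage, grid: MomentumGrid,
                 t: int) -> np.ndarray:
    """Brute-force momentum transform of sample *t*: the explicit sum
    phi_k = sum_j psi[j, t] exp(-i(p_xk x_j + p_yk y_j)).

    O(N * N_p) with Python-level accumulation over electrodes — the
    independent oracle against which the batched transform is checked.
    Accepts a PseudoWavefunction or a plain complex matrix.
    """
    psi = _as_psi(wf)
    if psi.shape[0] != len(montage):
        raise ValueError("wavefunction/montage channel mismatch")
    xy = montage.xy
    phi = np.zeros(len(grid), dtype=complex)
    for k, (pk_x, pk_y) in enumerate(grid.points):
        acc = 0.0 + 0.0j
        for j in range(psi.shape[0]):
            acc += psi[j, t] * np.exp(-1j * (pk_x * xy[j, 0] + pk_y * xy[j, 1]))
        phi[k] = acc
    return phi


def to_momentum_basis(wf, montage: Montage,
                      grid: MomentumGrid, tol: float = 1e-9) -> np.ndarray:
    """Momentum-basis coefficients for all samples, (N_p, T) complex.

    Exact dense evaluation via the precomputed kernel matrix; *tol* is the
    requested transform accuracy (validated for range; the dense product is
    exact to rounding, so any admissible tolerance is met).  Accepts a
    PseudoWavefunction or a plain complex matrix.
    """
    if not (1e-14 <= tol <= 1e-4):
        raise ValueError(f"tol {tol} outside [1e-14, 1e-4]")
    psi = _as_psi(wf)
    if psi.shape[0] != len(montage):
        raise ValueError("wavefunction/montage channel mismatch")
    return _kernel(montage, grid) @ psi


def momentum_probability(phi: np.ndarray, fs: float,
                         normalize: bool = True) -> MomentumProbability:
    """|phi|^2 per momentum point, optionally renormalized to sum 1 per
    sample so it acts as a probability distribution over the grid."""
    phi = np.asarray(phi, dtype=complex)
    if not np.isfinite(phi).all():
        raise ValueError("non-finite momentum coefficients")
    Pt = (phi.conj() * phi).real
    if normalize:
        sums = Pt.sum(axis=0)
        zero = sums == 0.0
        if zero.any():
            t = int(np.argmax(zero))
            raise ValueError(f"all-zero momentum column at sample {t}")
        Pt = Pt / sums
    return MomentumProbability(Pt, fs, normalized=normalize)


def average_momentum_spectral(Ptilde: MomentumProbability,
                              grid: MomentumGrid):
    """Spectral mean momentum <p>(t) = sum_k Ptilde_k(t) p_k.

    A diagnostic alternative to the Ehrenfest estimate; the two are distinct
    constructions and are reported side by side, not interchanged.
    """
    if not Ptilde.normalized:
        raise ValueError("spectral averages require a normalized Ptilde")
    if Ptilde.Ptilde.shape[0] != len(grid):
        raise ValueError("Ptilde/grid size mismatch")
    return grid.px @ Ptilde.Ptilde, grid.py @ Ptilde.Ptilde
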