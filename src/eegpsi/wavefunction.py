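"""Pseudo-wavefunction construction: analytic signal, normalization,
probability field.

Each channel's real time course s_j(t) is extended to its analytic signal
Psi_j(t) = s_j(t) + i H[s_j](t) = A_j(t) exp(i theta_j(t)), whose modulus is
the instantaneous amplitude envelope and argument the instantaneous phase.
Dividing the channel vector at every sample by its Euclidean norm across
channels yields the pseudo-wavefunction Psi_hat, a unit vector in channel
space whose squared moduli act as a per-electrode probability distribution
P_j(t) at each time point — the "brain state" the downstream observables act
on.  No physical claim is attached to this construction; it is a normalized
representation of where signal energy sits on the scalp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "PseudoWavefunction",
    "ProbabilityField",
    "analytic_signal",
    "normalize",
    "probability",
    "trim_edges",
]

NORM_TOL = 1e-10  # column-norm tolerance for type invariants


@dataclass
class PseudoWavefunction:
    """Complex channels x samples matrix with unit column norms."""

    psi: np.ndarray
    fs: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=complex)
        if self.psi.ndim != 2:
            raise ValueError("psi must be 2-D (channels x samples)")
        norms = np.sum(np.abs(self.psi) ** 2, axis=0)
        if not np.allclose(norms, 1.0, atol=NORM_TOL, rtol=0):
            t = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"column {t} has squared norm {norms[t]!r}, expected 1"
            )

    @property
    def n_channels(self) -> int:
        return self.psi.shape[0]

    @property
    def n_samples(self) -> int:
        return self.psi.shape[1]


@dataclass
class ProbabilityField:
    """Nonnegative channels x samples matrix; every column sums to 1."""

    P: np.ndarray
    fs: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2:
            raise ValueError("P must be 2-D (channels x samples)")
        if (self.P < 0).any():
            raise ValueError("probabilities must be nonnegative")
        sums = self.P.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=NORM_TOL, rtol=0):
            t = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"column {t} sums to {sums[t]!r}, expected 1")

    @property
    def n_channels(self) -> int:
        return self.P.shape[0]

    @property
    def n_samples(self) -> int:
        return self.P.shape[1]


def analytic_signal(rec) -> np.ndarray:
    """Per-channel analytic signal: the input plus i times its Hilbert
    transform.

    The real part of each output row equals the input row exactly; the
    imaginary part is the FFT-based discrete Hilbert transform, which carries
    the usual wrap-around artifacts near the record edges (see trim_edges).
    Requires at least 8 samples per channel.
    """
    data = np.asarray(rec.data, dtype=float)
    if data.shape[1] < 8:
        raise ValueError(f"record too short ({data.shape[1]} samples; need >= 8)")
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in input")
    return hilbert(data, axis=1)


def normalize(analytic: np.ndarray, fs: float,
              labels: list[str] | None = None) -> PseudoWavefunction:
    """Normalize the channel vector at every sample to unit Euclidean norm.

    psi[j, t] = Psi[j, t] / sqrt(sum_k |Psi[k, t]|^2).  Invariant under
    rescaling of the whole input; a sample where every channel is exactly
    zero cannot be normalized and raises.
    """
    analytic = np.asarray(analytic, dtype=complex)
    norms = np.sqrt(np.sum(np.abs(analytic) ** 2, axis=0))
    zero = norms == 0.0
    if zero.any():
        t = int(np.argmax(zero))
        raise ValueError(f"all channels zero at sample {t}; cannot normalize")
    return PseudoWavefunction(analytic / norms, fs, labels)


def probability(wf: PseudoWavefunction) -> ProbabilityField:
    """Per-electrode probability P_j(t) = |psi_j(t)|^2 (conjugate square)."""
    P = (wf.psi.conj() * wf.psi).real
    # exact renormalization guards accumulated rounding in long records
    P = P / P.sum(axis=0)
    return ProbabilityField(P, wf.fs, wf.labels)


def trim_edges(obj, n_edge: int):
    """Drop the first and last n_edge samples of a time-indexed object.

    Accepts an array (last axis = time), an EEGRecording, a
    PseudoWavefunction, or a ProbabilityField, and returns the same type.
    Used to discard Hilbert-transform edge artifacts before summary
    statistics; n_edge = 0 is the identity.
    """
    if n_edge < 0:
        raise ValueError("n_edge must be nonnegative")
    if n_edge == 0:
        return obj
    if isinstance(obj, PseudoWavefunction):
        _check_trim(obj.psi.shape[1], n_edge)
        return PseudoWavefunction(obj.psi[:, n_edge:-n_edge], obj.fs, obj.labels)
    if isinstance(obj, ProbabilityField):
        _check_trim(obj.P.shape[1], n_edge)
        return ProbabilityField(obj.P[:, n_edge:-n_edge], obj.fs, obj.labels)
    if hasattr(obj, "data") and hasattr(obj, "fs"):  # EEGRecording
        _check_trim(obj.data.shape[1], n_edge)
        return type(obj)(
            obj.data[:, n_edge:-n_edge],
            obj.fs,
            obj.labels,
            t0=obj.t0 + n_edge / obj.fs,
        )
    arr = np.asarray(obj)
    _check_trim(arr.shape[-1], n_edge)
    return arr[..., n_edge:-n_edge]


def _check_trim(n_samples: int, n_edge: int) -> None:
    if 2 * n_edge >= n_samples:
        raise ValueError(
            f"trim of {n_edge} samples per edge exceeds record "
            f"length {n_samples}"
        )
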