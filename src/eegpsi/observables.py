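"""Position-space observables, Ehrenfest momenta, region occupancy, and
phase-space summaries.

With electrode positions (x_j, y_j) fixed on the scalp and the probability
P_j(t) carried by the pseudo-wavefunction, the mean position is the
probability-weighted electrode coordinate

    <x(t)> = sum_j x_j P_j(t),

and the mean momentum follows the Ehrenfest route: with unit mass,
<p_x(t)> = d<x(t)>/dt = sum_j x_j dP_j(t)/dt.  Time derivatives are taken
per sample interval (central differences on interior samples, one-sided at
the two ends), so momenta carry units of cm per sample interval — at 250 Hz
that is the cm / 4 ms convention used throughout.

Region occupancy sums member-electrode probabilities into Prob_G(t); its
time average f_G is the frequency with which the state visits region G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage, RegionGrouping
from .wavefunction import ProbabilityField

__all__ = [
    "ObservableSeries",
    "RegionSeries",
    "PhaseSpaceSummary",
    "time_derivative",
    "average_position",
    "average_momentum",
    "second_moment_position",
    "region_probability",
    "region_frequency",
    "phase_space_summary",
]


@dataclass
class ObservableSeries:
    """Per-sample position/momentum expectation values for one recording.

    Positions in cm; momenta in cm per sample interval (mass = 1); second
    moments in cm^2.
    """

    t: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    px_mean: np.ndarray
    py_mean: np.ndarray
    x2_mean: np.ndarray
    y2_mean: np.ndarray

    def as_table(self) -> dict[str, np.ndarray]:
        return {
            "t": self.t,
            "x_mean": self.x_mean,
            "y_mean": self.y_mean,
            "px_mean": self.px_mean,
            "py_mean": self.py_mean,
            "x2_mean": self.x2_mean,
            "y2_mean": self.y2_mean,
        }


@dataclass
class RegionSeries:
    """Per-region summed probability over time plus its time average f_G."""

    names: list[str]
    prob_G: np.ndarray  # groups x samples
    f_G: np.ndarray  # groups


@dataclass
class PhaseSpaceSummary:
    """Centroid and scatter of a (position, momentum) trajectory.

    The 1-SD ellipse comes from the eigendecomposition of the 2x2 sample
    covariance: semi-axes are the square roots of the eigenvalues, the angle
    orients the major axis.
    """

    centroid: tuple[float, float]
    cov: np.ndarray
    ellipse_axes: tuple[float, float]
    ellipse_angle: float  # radians, major axis vs. position axis


def time_derivative(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """d/dt per sample interval: central differences inside, one-sided at
    the ends.  The single scheme shared by every momentum computation."""
    a = np.asarray(a, dtype=float)
    if a.shape[axis] < 3:
        raise ValueError("need at least 3 samples for the derivative scheme")
    return np.gradient(a, axis=axis)


def _check_sizes(P: ProbabilityField, montage: Montage) -> None:
    if P.n_channels != len(montage):
        raise ValueError(
            f"probability field has {P.n_channels} channels but montage "
            f"has {len(montage)} electrodes"
        )


def average_position(P: ProbabilityField, montage: Montage):
    """Probability-weighted mean electrode coordinates, (<x>, <y>) per sample."""
    _check_sizes(P, montage)
    xy = montage.xy
    return xy[:, 0] @ P.P, xy[:, 1] @ P.P


def average_momentum(P: ProbabilityField, montage: Montage,
                     scheme=time_derivative):
    """Ehrenfest mean momentum: m sum_j x_j dP_j/dt with m = 1.

    Exactly the derivative of the mean-position series under the shared
    scheme (the sums commute); units cm per sample interval.
    """
    _check_sizes(P, montage)
    dP = scheme(P.P, axis=-1)
    xy = montage.xy
    return xy[:, 0] @ dP, xy[:, 1] @ dP


def second_moment_position(P: ProbabilityField, montage: Montage):
    """Probability-weighted mean squared coordinates (<x^2>, <y^2>)."""
    _check_sizes(P, montage)
    xy = montage.xy
    return (xy[:, 0] ** 2) @ P.P, (xy[:, 1] ** 2) @ P.P


def compute_observables(P: ProbabilityField, montage: Montage,
                        scheme=time_derivative) -> ObservableSeries:
    """All position-space observables for one recording in one pass."""
    x_mean, y_mean = average_position(P, montage)
    px_mean, py_mean = average_momentum(P, montage, scheme)
    x2_mean, y2_mean = second_moment_position(P, montage)
    t = np.arange(P.n_samples) / P.fs
    return ObservableSeries(t, x_mean, y_mean, px_mean, py_mean,
                            x2_mean, y2_mean)


def region_probability(P: ProbabilityField, montage: Montage,
                       grouping: RegionGrouping) -> np.ndarray:
    """Summed member-electrode probability per region, groups x samples."""
    _check_sizes(P, montage)
    grouping.validate(montage)
    rows = []
    for name in grouping.names:
        idx = [montage.index(lab) for lab in grouping.groups[name]]
        rows.append(P.P[idx].sum(axis=0) if idx else np.zeros(P.n_samples))
    return np.vstack(rows)


def region_frequency(prob_G: np.ndarray) -> np.ndarray:
    """Time average of each region's occupancy: f_G = (1/T) sum_t Prob_G(t)."""
    prob_G = np.asarray(prob_G, dtype=float)
    if prob_G.shape[-1] < 1:
        raise ValueError("need at least one sample")
    return prob_G.mean(axis=-1)


def compute_regions(P: ProbabilityField, montage: Montage,
                    grouping: RegionGrouping) -> RegionSeries:
    import logging

    prob_G = region_probability(P, montage, grouping)
    for name, members in grouping.groups.items():
        if not members:
            logging.getLogger(__name__).warning("empty region group %r", name)
    return RegionSeries(grouping.names, prob_G, region_frequency(prob_G))


def phase_space_summary(pos: np.ndarray, mom: np.ndarray) -> PhaseSpaceSummary:
    """Centroid, covariance and 1-SD ellipse of a phase-space trajectory."""
    pos = np.asarray(pos, dtype=float)
    mom = np.asarray(mom, dtype=float)
    if pos.shape != mom.shape:
        raise ValueError("position and momentum series differ in length")
    if pos.size < 2:
        raise ValueError("need at least 2 samples for a covariance")
    centroid = (float(pos.mean()), float(mom.mean()))
    cov = np.cov(np.vstack([pos, mom]), ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    # eigh sorts ascending: index 1 is the major axis
    axes = (float(np.sqrt(evals[1])), float(np.sqrt(evals[0])))
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    return PhaseSpaceSummary(centroid, cov, axes, angle)
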