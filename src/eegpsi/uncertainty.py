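"""Position-momentum uncertainty products and the K_Brain summary.

For each sample the position spread is Delta_x(t) = sqrt(<x^2> - <x>^2)
with both moments taken under the electrode-space probability P_j(t).  The
momentum spread mixes two constructions, mirroring how the uncertainty is
assembled in this framework:

  * <p_x>  — the Ehrenfest route, x-weighted dP/dt (observables module);
  * <p_x^2> — the momentum-basis route,
        m^2 sum_j (x_j^2 / Ptilde_j(t)) [dP_j(t)/dt]^2,
    with electrode index j paired one-to-one with momentum-grid index j
    under the two fixed orderings (montage file order; grid order).

Because the two estimators come from different constructions, samples with
<p^2> < <p>^2 can legitimately occur; they are flagged, excluded from
summaries, and counted — not clipped.

The product Delta_x(t) * Delta_p_x(t) (units cm^2 per sample interval;
cm^2 / 4 ms at 250 Hz) is summarized per recording by its min / max / mean /
SD over defined samples; the cohort mean of the per-recording minima is the
K estimate, the floor the product never goes below in this framework.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .montage import Montage
from .momentum_space import (MomentumGrid, MomentumProbability,
                             default_momentum_grid, momentum_probability,
                             to_momentum_basis)
from .observables import (ObservableSeries, compute_observables,
                          time_derivative)
from .wavefunction import (ProbabilityField, analytic_signal, normalize,
                           probability, trim_edges)

logger = logging.getLogger(__name__)

__all__ = [
    "UncertaintySeries",
    "RecordingSummary",
    "UncertaintySummary",
    "delta_x",
    "second_moment_momentum",
    "delta_p",
    "uncertainty_products",
    "summarize_k",
    "probability_map_at_min",
    "analyze_recording",
]

PTILDE_FLOOR = 1e-12  # floor on momentum probabilities before division
VAR_TOL = 1e-12  # negative-variance rounding tolerance


@dataclass
class UncertaintySeries:
    """Per-sample spreads and their products; flagged samples hold NaN."""

    t: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dpx: np.ndarray
    dpy: np.ndarray
    prod_x: np.ndarray
    prod_y: np.ndarray
    n_flagged_x: int = 0
    n_flagged_y: int = 0

    def as_table(self) -> dict[str, np.ndarray]:
        return {
            "t": self.t,
            "dx": self.dx,
            "dpx": self.dpx,
            "dx_dpx": self.prod_x,
            "dy": self.dy,
            "dpy": self.dpy,
            "dy_dpy": self.prod_y,
        }


@dataclass
class RecordingSummary:
    """min/max/mean/SD of the two uncertainty products for one recording."""

    min_x: float
    min_y: float
    max_x: float
    max_y: float
    mean_x: float
    mean_y: float
    std_x: float
    std_y: float
    argmin_x: int
    argmin_y: int
    n_flagged_x: int = 0
    n_flagged_y: int = 0
    tag: str = ""


@dataclass
class UncertaintySummary:
    """Cohort view: per-recording rows plus mean +/- SD aggregates.

    k_estimate is the cohort mean of per-recording minima pooled over the
    x and y products — the framework's uncertainty floor.
    """

    recordings: list[RecordingSummary]
    cohort_mean: dict[str, float]
    cohort_std: dict[str, float]
    k_estimate: float
    k_estimate_sd: float


def delta_x(x2_mean: np.ndarray, x_mean: np.ndarray) -> np.ndarray:
    """Position spread sqrt(<x^2> - <x>^2); tiny negative variances from
    rounding (>= -1e-12) are clipped to zero, anything worse raises."""
    var = np.asarray(x2_mean, float) - np.asarray(x_mean, float) ** 2
    if (var < -VAR_TOL).any():
        t = int(np.argmin(var))
        raise ValueError(
            f"position variance {var[t]} < 0 at sample {t}: "
            "inconsistent moments"
        )
    return np.sqrt(np.clip(var, 0.0, None))


def second_moment_momentum(P: ProbabilityField, Ptilde: MomentumProbability,
                           montage: Montage, scheme=time_derivative):
    """<p_x^2>(t) and <p_y^2>(t) via the momentum-basis expression.

    m^2 sum_j (x_j^2 / Ptilde_j(t)) [dP_j(t)/dt]^2 with m = 1, electrode j
    paired with momentum point j (equal counts required), and Ptilde floored
    at 1e-12 before the division.  Nonnegative by construction.
    """
    if P.n_channels != Ptilde.Ptilde.shape[0]:
        raise ValueError(
            f"index pairing needs equal counts: {P.n_channels} electrodes "
            f"vs {Ptilde.Ptilde.shape[0]} momentum points"
        )
    if not Ptilde.normalized:
        raise ValueError("Ptilde must be normalized")
    dP = scheme(P.P, axis=-1)
    Pt = np.clip(Ptilde.Ptilde, PTILDE_FLOOR, None)
    xy = montage.xy
    px2 = (xy[:, 0] ** 2) @ (dP**2 / Pt)
    py2 = (xy[:, 1] ** 2) @ (dP**2 / Pt)
    return px2, py2


def delta_p(p_mean: np.ndarray, p2_mean: np.ndarray):
    """Momentum spread sqrt(<p^2> - <p>^2) with mixed-estimator flagging.

    Returns (dp, n_flagged): samples where the variance is below -1e-12 are
    set to NaN and counted; values in [-1e-12, 0) are rounding and clip to 0.
    """
    var = np.asarray(p2_mean, float) - np.asarray(p_mean, float) ** 2
    flagged = var < -VAR_TOL
    n_flagged = int(flagged.sum())
    if n_flagged:
        logger.warning(
            "%d samples with <p^2> < <p>^2 flagged and excluded", n_flagged
        )
    dp = np.sqrt(np.clip(var, 0.0, None))
    dp[flagged] = np.nan
    return dp, n_flagged


def uncertainty_products(t: np.ndarray, dx: np.ndarray, dpx: np.ndarray,
                         dy: np.ndarray, dpy: np.ndarray,
                         n_flagged_x: int = 0,
                         n_flagged_y: int = 0) -> UncertaintySeries:
    """Elementwise Delta_x * Delta_p products; NaN (flagged) propagates."""
    series = [np.asarray(a, float) for a in (dx, dpx, dy, dpy)]
    if len({s.shape for s in series}) != 1:
        raise ValueError("uncertainty series length mismatch")
    dx, dpx, dy, dpy = series
    return UncertaintySeries(
        np.asarray(t, float), dx, dy, dpx, dpy, dx * dpx, dy * dpy,
        n_flagged_x=n_flagged_x, n_flagged_y=n_flagged_y,
    )


def _stats(prod: np.ndarray):
    defined = prod[np.isfinite(prod)]
    if defined.size == 0:
        raise ValueError("no defined samples in product series")
    return (float(defined.min()), float(defined.max()),
            float(defined.mean()), float(defined.std(ddof=0)))


def summarize_k(series_list: list[UncertaintySeries],
                tags: list[str] | None = None) -> UncertaintySummary:
    """Per-recording product statistics and the cohort K estimate.

    Minima use the first minimizing index (ties broken by earliest time),
    which also selects the probability-map sample.  Cohort aggregates are the
    across-recording mean and SD of each statistic; the K estimate pools the
    x and y minima.
    """
    if not series_list:
        raise ValueError("need at least one recording")
    if tags is None:
        tags = [""] * len(series_list)
    recs = []
    for us, tag in zip(series_list, tags):
        mn_x, mx_x, me_x, sd_x = _stats(us.prod_x)
        mn_y, mx_y, me_y, sd_y = _stats(us.prod_y)
        recs.append(RecordingSummary(
            min_x=mn_x, min_y=mn_y, max_x=mx_x, max_y=mx_y,
            mean_x=me_x, mean_y=me_y, std_x=sd_x, std_y=sd_y,
            argmin_x=int(np.nanargmin(us.prod_x)),
            argmin_y=int(np.nanargmin(us.prod_y)),
            n_flagged_x=us.n_flagged_x, n_flagged_y=us.n_flagged_y,
            tag=tag,
        ))
    stats = ("min_x", "min_y", "max_x", "max_y",
             "mean_x", "mean_y", "std_x", "std_y")
    cohort_mean = {s: float(np.mean([getattr(r, s) for r in recs]))
                   for s in stats}
    cohort_std = {s: float(np.std([getattr(r, s) for r in recs], ddof=0))
                  for s in stats}
    minima = np.array([[r.min_x, r.min_y] for r in recs]).ravel()
    return UncertaintySummary(
        recordings=recs,
        cohort_mean=cohort_mean,
        cohort_std=cohort_std,
        k_estimate=float(minima.mean()),
        k_estimate_sd=float(minima.std(ddof=0)),
    )


def probability_map_at_min(P: ProbabilityField, us: UncertaintySeries):
    """Electrode probability columns at the least-uncertain time points.

    Returns (map_x, map_y): the columns of P at the argmin of the x and y
    products respectively (first index wins ties).
    """
    if not (np.isfinite(us.prod_x).any() and np.isfinite(us.prod_y).any()):
        raise ValueError("product series has no defined minimum")
    ix = int(np.nanargmin(us.prod_x))
    iy = int(np.nanargmin(us.prod_y))
    return P.P[:, ix].copy(), P.P[:, iy].copy()


def analyze_recording(rec, montage: Montage,
                      grid: MomentumGrid | None = None,
                      n_edge: int = 0, nufft_tol: float = 1e-9):
    """Full single-recording pipeline.

    Hilbert -> normalize -> (optional edge trim) -> probabilities ->
    observables -> momentum basis -> spreads -> products.  Returns
    (ObservableSeries, UncertaintySeries, ProbabilityField).
    """
    if grid is None:
        grid = default_momentum_grid()
    if n_edge == 0:
        logger.warning("edge trim is 0; Hilbert edge artifacts retained")
    wf = normalize(analytic_signal(rec), rec.fs, rec.labels)
    wf = trim_edges(wf, n_edge)
    P = probability(wf)
    obs = compute_observables(P, montage)
    phi = to_momentum_basis(wf, montage, grid, tol=nufft_tol)
    Ptilde = momentum_probability(phi, rec.fs, normalize=True)
    dx = delta_x(obs.x2_mean, obs.x_mean)
    dy = delta_x(obs.y2_mean, obs.y_mean)
    px2, py2 = second_moment_momentum(P, Ptilde, montage)
    dpx, nfx = delta_p(obs.px_mean, px2)
    dpy, nfy = delta_p(obs.py_mean, py2)
    us = uncertainty_products(obs.t, dx, dpx, dy, dpy,
                              n_flagged_x=nfx, n_flagged_y=nfy)
    return obs, us, P
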