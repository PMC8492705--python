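"""Electrode geometry: montages, planar projection, and scalp region groupings.

Electrode positions live in head coordinates (cm) with the nose pointing in
the positive y direction.  All downstream observables use the 2-D projection
obtained by dropping the z coordinate ("removing the depth of the head"); the
electrode order in a montage is fixed and defines the channel index used by
every pipeline stage.

The bundled 92-channel montage and its eight-region grouping are *synthetic
stand-ins* for a high-density EGI-style net: they reproduce the canonical
per-region electrode counts (Occipital L/R 10/10, Parietal L/R 17/17,
Posterior L/R 10/11, Anterior L/R 8/9) with a plausible geometric split
(anterior = largest y, occipital = smallest y, left/right by sign of x), not
any manufacturer's actual layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Electrode",
    "Montage",
    "RegionGrouping",
    "REGION_NAMES",
    "load_montage",
    "project_to_plane",
    "load_grouping",
    "subset_montage",
    "default_montage",
    "default_grouping",
    "default_subset20_labels",
]

#: Canonical region names, paired left/right, front of head to back.
REGION_NAMES = (
    "Anterior L",
    "Anterior R",
    "Posterior L",
    "Posterior R",
    "Parietal L",
    "Parietal R",
    "Occipital L",
    "Occipital R",
)


@dataclass(frozen=True)
class Electrode:
    """A single sensor: label plus 3-D head position in cm."""

    label: str
    pos3d: tuple[float, float, float]

    @property
    def pos2d(self) -> tuple[float, float]:
        """Orthographic projection onto the horizontal plane (z dropped)."""
        return (self.pos3d[0], self.pos3d[1])


@dataclass(frozen=True)
class Montage:
    """An ordered set of electrodes; order defines the channel index.

    Lengths are centimetres.  At least two electrodes are required (a single
    sensor admits no spatial statistics).
    """

    electrodes: tuple[Electrode, ...]
    units: str = "cm"

    def __post_init__(self) -> None:
        if len(self.electrodes) < 2:
            raise ValueError("montage needs at least 2 electrodes")
        labels = [e.label for e in self.electrodes]
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise ValueError(f"duplicate electrode label: {lab!r}")
            seen.add(lab)

    def __len__(self) -> int:
        return len(self.electrodes)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    @property
    def xy(self) -> np.ndarray:
        """(N, 2) array of projected positions, montage order."""
        return np.array([e.pos2d for e in self.electrodes], dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in montage") from None


@dataclass(frozen=True)
class RegionGrouping:
    """Disjoint groups of electrode labels defining scalp regions."""

    groups: Mapping[str, tuple[str, ...]]

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(members) for g, members in self.groups.items()}

    def validate(self, montage: Montage) -> None:
        """Check disjointness and that every grouped label is in *montage*."""
        known = set(montage.labels)
        seen: dict[str, str] = {}
        for name, members in self.groups.items():
            for lab in members:
                if lab not in known:
                    raise ValueError(
                        f"group {name!r} lists unknown electrode {lab!r}"
                    )
                if lab in seen:
                    raise ValueError(
                        f"electrode {lab!r} appears in both "
                        f"{seen[lab]!r} and {name!r}"
                    )
                seen[lab] = name

    def is_partition(self, montage: Montage) -> bool:
        grouped = {lab for mem in self.groups.values() for lab in mem}
        return grouped == set(montage.labels)

    def restrict(self, montage: Montage) -> "RegionGrouping":
        """Drop labels absent from *montage* (for downsampled montages)."""
        known = set(montage.labels)
        return RegionGrouping(
            {
                name: tuple(lab for lab in mem if lab in known)
                for name, mem in self.groups.items()
            }
        )


def load_montage(path) -> Montage:
    """Read a delimited montage file with header columns label, x, y, z (cm).

    The planar projection is applied on load: each electrode's 2-D position is
    its (x, y) with z dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"label", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"montage file missing columns: {sorted(missing)}")
    electrodes = []
    for i, row in enumerate(df.itertuples(index=False)):
        coords = []
        for col in ("x", "y", "z"):
            v = getattr(row, col)
            try:
                coords.append(float(v))
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric coordinate {v!r} in column {col} "
                    f"at data line {i + 1}"
                ) from None
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"non-finite coordinate at data line {i + 1}")
        electrodes.append(Electrode(str(row.label), tuple(coords)))
    return Montage(tuple(electrodes))


def project_to_plane(montage: Montage) -> Montage:
    """Orthographic projection: zero the z coordinate of every electrode.

    Idempotent; electrode order is preserved.  The 2-D positions used by the
    observables are unchanged by this operation (they already drop z), but the
    returned montage makes the projection explicit in its stored coordinates.
    """
    return Montage(
        tuple(
            Electrode(e.label, (e.pos3d[0], e.pos3d[1], 0.0))
            for e in montage.electrodes
        ),
        units=montage.units,
    )


def load_grouping(path, montage: Montage) -> RegionGrouping:
    """Read a delimited grouping file with header columns label, group."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"label", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"grouping file missing columns: {sorted(missing)}")
    groups: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(str(row.group), []).append(str(row.label))
    grouping = RegionGrouping({g: tuple(m) for g, m in groups.items()})
    grouping.validate(montage)
    return grouping


def subset_montage(montage: Montage, labels: Sequence[str]) -> Montage:
    """Montage restricted to *labels*, preserving the given label order.

    Downstream normalization then runs over the reduced channel count — this
    is how 20-channel reanalyses of a 92-channel layout are built.
    """
    index = {e.label: e for e in montage.electrodes}
    missing = [lab for lab in labels if lab not in index]
    if missing:
        raise KeyError(f"labels not in montage: {missing}")
    return Montage(tuple(index[lab] for lab in labels), units=montage.units)


# ---------------------------------------------------------------------------
# Bundled synthetic EGI-92 stand-in layout
# ---------------------------------------------------------------------------

# (region base name, left count, right count, y band in cm, front to back)
_BANDS = (
    ("Anterior", 8, 9, (4.8, 8.0)),
    ("Posterior", 10, 11, (1.2, 4.2)),
    ("Parietal", 17, 17, (-3.6, 0.6)),
    ("Occipital", 10, 10, (-8.0, -4.2)),
)
_HEAD_RADIUS = 9.0  # cm, disc bounding the projected layout


def _side_points(n: int, y_lo: float, y_hi: float) -> list[tuple[float, float]]:
    """Deterministically spread n points over one side of a y band."""
    n_rows = max(2, round(math.sqrt(n)))
    base, extra = divmod(n, n_rows)
    pts: list[tuple[float, float]] = []
    for r in range(n_rows):
        n_in_row = base + (1 if r < extra else 0)
        y = y_hi - (r + 0.5) * (y_hi - y_lo) / n_rows
        half_width = 0.92 * math.sqrt(max(_HEAD_RADIUS**2 - y**2, 0.25))
        for c in range(n_in_row):
            x = 0.7 + (half_width - 0.7) * (c + 0.5) / n_in_row
            pts.append((x, y))
    return pts


def _default_layout() -> list[tuple[str, float, float, float, str]]:
    """Build the synthetic 92-channel layout: (label, x, y, z, region) rows.

    Anterior electrodes take the largest y, occipital the smallest; left/right
    by sign of x; z from a 9 cm sphere (dropped by the projection anyway).
    """
    rows = []
    k = 0
    for region, n_left, n_right, (y_lo, y_hi) in _BANDS:
        for side, n_side, sgn in (("L", n_left, -1.0), ("R", n_right, 1.0)):
            for x, y in _side_points(n_side, y_lo, y_hi):
                k += 1
                xs = sgn * x
                z = math.sqrt(max(_HEAD_RADIUS**2 - xs**2 - y**2, 0.0))
                rows.append(
                    (f"E{k}", round(xs, 3), round(y, 3), round(z, 3),
                     f"{region} {side}")
                )
    return rows


def _data_path(name: str):
    return resources.files("eegpsi.data").joinpath(name)


def default_montage() -> Montage:
    """The bundled synthetic 92-channel montage (see module docstring)."""
    with resources.as_file(_data_path("egi92_montage.csv")) as p:
        return load_montage(p)


def default_grouping(montage: Montage | None = None) -> RegionGrouping:
    """The bundled eight-region grouping of the synthetic 92-channel montage."""
    if montage is None:
        montage = default_montage()
    with resources.as_file(_data_path("egi92_grouping.csv")) as p:
        return load_grouping(p, montage)


def default_subset20_labels() -> list[str]:
    """Labels of the bundled 20-channel downsample (10–20-style coverage)."""
    text = _data_path("subset20_labels.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
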