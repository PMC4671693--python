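"""Pilot summary statistics of a (simulated) barrier assay.

One experimental condition with three replicates is summarised by the
15-vector ``L = (R(1), R(2), R(3), c1..c6, p1..p6)``:

* ``R(1) <= R(2) <= R(3)`` — ordered equivalent circular radii (µm) of the
  colony in each replicate, obtained by detecting the colony's leading edge
  on the occupancy grid and converting the enclosed area ``A`` to
  ``R = sqrt(A / pi)``;
* ``c_i`` — cell counts in six rectangular sub-regions along a transect
  through the colony centre, averaged over replicates;
* ``p_i`` — fractions of isolated cells in the same sub-regions (an agent is
  isolated if its four von Neumann neighbours are all empty), averaged over
  replicates.

Leading-edge detection mimics image segmentation of a micrograph: the sparse
boundary is bridged by a morphological closing (disc structuring element),
interior holes are filled, and the largest connected component defines the
enclosed area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import closing as _gray_closing
from skimage.morphology import disk

from .colony_model import ColonyState, LatticeConfig

__all__ = [
    "Window",
    "SubRegionLayout",
    "PilotSummary",
    "equivalent_radius",
    "default_layout",
    "count_cells",
    "isolated_fraction",
    "pilot_summary",
]


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangle in lattice coordinates (half-open ranges)."""

    row_start: int
    col_start: int
    height: int
    width: int

    @property
    def row_stop(self) -> int:
        return self.row_start + self.height

    @property
    def col_stop(self) -> int:
        return self.col_start + self.width


@dataclass(frozen=True)
class SubRegionLayout:
    """The transect sub-regions, indexed innermost (1) to outermost (6)."""

    windows: tuple[Window, ...]

    def __post_init__(self) -> None:
        if len(self.windows) == 0:
            raise ValueError("layout needs at least one window")

    def __len__(self) -> int:
        return len(self.windows)


def default_layout(
    cfg: LatticeConfig,
    n_windows: int = 6,
    window_width: int = 39,
    window_height: int = 28,
) -> SubRegionLayout:
    """Contiguous windows along the horizontal transect through the lattice
    centre, starting at the centre column and extending rightwards,
    vertically centred.  Defaults give the experimental 700 x 500 µm
    (39 x 28 site) sub-regions."""
    w = cfg.width_sites
    centre = (w - 1) // 2
    if centre + n_windows * window_width > w:
        raise ValueError(
            f"lattice width {w} too small for {n_windows} windows of width {window_width}"
        )
    row_start = centre - window_height // 2
    if row_start < 0 or row_start + window_height > w:
        raise ValueError("lattice too small for the window height")
    windows = tuple(
        Window(
            row_start=row_start,
            col_start=centre + i * window_width,
            height=window_height,
            width=window_width,
        )
        for i in range(n_windows)
    )
    return SubRegionLayout(windows)


def colony_mask(state: ColonyState, closing_radius: int = 3) -> np.ndarray:
    """Region enclosed by the colony's leading edge, as a boolean mask.

    Occupancy is closed with a disc structuring element (bridging gaps up to
    about twice the closing radius), holes are filled and the largest
    connected component is kept.
    """
    occ = state.occupancy.astype(bool)
    if not occ.any():
        raise ValueError("cannot detect a leading edge on an empty grid")
    if closing_radius > 0:
        closed = _gray_closing(occ.astype(np.uint8), disk(closing_radius)) > 0
    else:
        closed = occ
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        filled = labels == keep
    return filled


def equivalent_radius(
    state: ColonyState, cfg: LatticeConfig, closing_radius: int = 3
) -> float:
    """Equivalent circular radius R = sqrt(A/pi) (µm) of the area enclosed
    by the detected leading edge."""
    mask = colony_mask(state, closing_radius=closing_radius)
    area_um2 = mask.sum() * cfg.spacing_um**2
    return math.sqrt(area_um2 / math.pi)


def count_cells(state: ColonyState, window: Window) -> int:
    """Number of occupied sites inside the window."""
    _check_window(state, window)
    return int(
        state.occupancy[window.row_start : window.row_stop, window.col_start : window.col_stop].sum()
    )


def _check_window(state: ColonyState, window: Window) -> None:
    h, w = state.occupancy.shape
    if window.row_start < 0 or window.col_start < 0 or window.row_stop > h or window.col_stop > w:
        raise ValueError("window does not lie within the lattice")


def isolated_fraction(state: ColonyState, window: Window) -> float:
    """Fraction of in-window agents whose four nearest neighbours (looked up
    on the full lattice) are all unoccupied; 0.0 for an empty window."""
    _check_window(state, window)
    occ = state.occupancy
    padded = np.pad(occ, 1)
    # neighbour count of every site, computed on the full lattice
    neigh = (
        padded[:-2, 1:-1].astype(np.int16)
        + padded[2:, 1:-1]
        + padded[1:-1, :-2]
        + padded[1:-1, 2:]
    )
    sub = occ[window.row_start : window.row_stop, window.col_start : window.col_stop]
    sub_neigh = neigh[window.row_start : window.row_stop, window.col_start : window.col_stop]
    n_agents = int(sub.sum())
    if n_agents == 0:
        return 0.0
    n_isolated = int(((sub == 1) & (sub_neigh == 0)).sum())
    return n_isolated / n_agents


@dataclass(frozen=True)
class PilotSummary:
    """The 15-dimensional pilot summary L of one condition."""

    radii_sorted: tuple[float, ...]
    counts: tuple[float, ...]
    isolated_fracs: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.radii_sorted, self.radii_sorted[1:])):
            raise ValueError("radii must be sorted ascending")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")
        if any(not 0.0 <= p <= 1.0 for p in self.isolated_fracs):
            raise ValueError("isolated fractions must lie in [0, 1]")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.radii_sorted, self.counts, self.isolated_fracs])

    @property
    def dimension(self) -> int:
        return len(self.radii_sorted) + len(self.counts) + len(self.isolated_fracs)

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, n_replicates: int = 3, n_windows: int = 6
    ) -> "PilotSummary":
        vec = np.asarray(vec, dtype=float)
        r, c, p = (
            vec[:n_replicates],
            vec[n_replicates : n_replicates + n_windows],
            vec[n_replicates + n_windows :],
        )
        return cls(tuple(r), tuple(c), tuple(p))

    def column_names(self) -> list[str]:
        return (
            [f"R{i + 1}" for i in range(len(self.radii_sorted))]
            + [f"c{i + 1}" for i in range(len(self.counts))]
            + [f"p{i + 1}" for i in range(len(self.isolated_fracs))]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.as_vector()], columns=self.column_names())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PilotSummary":
        df = pd.read_csv(path)
        n_rep = sum(c.startswith("R") for c in df.columns)
        n_win = sum(c.startswith("c") for c in df.columns)
        return cls.from_vector(df.iloc[0].to_numpy(dtype=float), n_rep, n_win)


def pilot_summary(
    replicate_states: list[ColonyState],
    layout: SubRegionLayout,
    cfg: LatticeConfig,
    closing_radius: int = 3,
) -> PilotSummary:
    """Summarise replicate colonies: sorted radii plus sub-region counts and
    isolated-cell fractions averaged over replicates."""
    if not replicate_states:
        raise ValueError("need at least one replicate")
    shapes = {s.occupancy.shape for s in replicate_states}
    if len(shapes) > 1:
        raise ValueError("replicate lattice shapes differ")
    radii = sorted(
        equivalent_radius(s, cfg, closing_radius=closing_radius) for s in replicate_states
    )
    counts = [
        float(np.mean([count_cells(s, w) for s in replicate_states])) for w in layout.windows
    ]
    fracs = [
        float(np.mean([isolated_fraction(s, w) for s in replicate_states]))
        for w in layout.windows
    ]
    return PilotSummary(tuple(radii), tuple(counts), tuple(fracs))
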