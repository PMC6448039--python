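"""Spatial mapping of feature-learnability over the brainstem surface.

Per-electrode learnability values are interpolated onto a regular 7x7 grid
covering a generic 2 mm x 2 mm dorsal column nuclei (DCN) map with exact
thin-plate splines, and per-animal surfaces are aligned (translated by each
animal's measured array shift) before being averaged cell-wise across the
cohort ("z-stacking").

Coordinate convention: x is lateral in mm (positive = right of the midline),
y is rostro-caudal in mm (positive = rostral); the map extent is
[-1, 1] x [-1, 1] mm with the array centre electrode (e4) at the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator

__all__ = [
    "ElectrodeLayout",
    "DEFAULT_LAYOUT",
    "LearnabilityMap",
    "tps_surface",
    "align_and_stack",
    "MAP_EXTENT_MM",
    "GRID_SIZE",
    "grid_coordinates",
]

#: Half-extent of the square DCN map, mm.
MAP_EXTENT_MM = 1.0
#: Interpolation mesh is GRID_SIZE x GRID_SIZE.
GRID_SIZE = 7


@dataclass(frozen=True)
class ElectrodeLayout:
    """Positions of the 7 surface electrodes (e1..e7) on the DCN map.

    The default geometry places the three midline electrodes (e3, e4, e5) on
    x = 0 spaced 0.75 mm rostro-caudally with e4 at the map centre, and the
    lateral electrodes at x = +/-0.82 mm: a 470 um gap between the midline
    and the medial electrode edge plus a 350 um electrode radius
    (diameter 0.7 mm).  e1/e6 sit in the rostral half, e2/e7 caudal.
    """

    positions: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [-0.82, 0.375],   # e1 (left, rostral)
                [-0.82, -0.375],  # e2 (left, caudal)
                [0.0, 0.75],      # e3 (midline, rostral)
                [0.0, 0.0],       # e4 (midline, centre)
                [0.0, -0.75],     # e5 (midline, caudal)
                [0.82, 0.375],    # e6 (right, rostral)
                [0.82, -0.375],   # e7 (right, caudal)
            ]
        )
    )
    diameter_mm: float = 0.7

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (7, 2):
            raise ValueError("layout requires 7 electrode centres (x, y)")
        object.__setattr__(self, "positions", pos)

    def shifted(self, lateral_um: float, rostrocaudal_um: float) -> np.ndarray:
        """Electrode centres translated by an array shift given in um."""
        return self.positions + np.array([lateral_um, rostrocaudal_um]) / 1000.0


DEFAULT_LAYOUT = ElectrodeLayout()


def grid_coordinates(
    n: int = GRID_SIZE, extent: float = MAP_EXTENT_MM
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centred grid coordinates over the square map.

    Returns (x, y) 1-D arrays of length ``n``; the full mesh is their outer
    product with ``ij`` indexing (rows = x/lateral, cols = y/rostro-caudal).
    """
    step = 2.0 * extent / n
    centres = -extent + step * (np.arange(n) + 0.5)
    return centres, centres.copy()


@dataclass
class LearnabilityMap:
    """Interpolated learnability surfaces on the common 7x7 grid.

    ``mean_map`` averages the per-animal mean-learnability surfaces cell-wise,
    ``sem_map`` averages the per-animal SEM surfaces, and
    ``cross_animal_sem`` is the cell-wise SEM of the per-animal mean surfaces
    (between-animal variability of the map itself).
    """

    mean_map: np.ndarray
    sem_map: np.ndarray | None
    cross_animal_sem: np.ndarray | None
    grid_x: np.ndarray
    grid_y: np.ndarray
    n_animals: int

    def to_dict(self) -> dict:
        return {
            "mean_map": self.mean_map.tolist(),
            "sem_map": None if self.sem_map is None else self.sem_map.tolist(),
            "cross_animal_sem": (
                None
                if self.cross_animal_sem is None
                else self.cross_animal_sem.tolist()
            ),
            "grid_x_mm": self.grid_x.tolist(),
            "grid_y_mm": self.grid_y.tolist(),
            "n_animals": self.n_animals,
        }


def _check_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) mm")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a surface")
    # Duplicate nodes make the TPS system singular.
    if len(np.unique(pts.round(12), axis=0)) != len(pts):
        raise ValueError("duplicate electrode positions")
    # Collinear nodes: the affine part of the TPS system is rank-deficient.
    design = np.column_stack([np.ones(len(pts)), pts])
    if np.linalg.matrix_rank(design, tol=1e-9) < 3:
        raise ValueError("collinear electrode positions: TPS system singular")
    return pts


def tps_surface(
    points: np.ndarray,
    values: np.ndarray,
    smoothing: float = 0.0,
    grid_size: int = GRID_SIZE,
    extent: float = MAP_EXTENT_MM,
) -> np.ndarray:
    """Thin-plate-spline surface through per-electrode values on a regular grid.

    With ``smoothing=0`` (default) the spline interpolates exactly: it
    reproduces the input values at the electrode positions and any affine
    field a + b*x + c*y everywhere.

    Parameters
    ----------
    points : (n, 2) electrode centres in mm.
    values : (n,) learnability values (%).
    smoothing : TPS smoothing parameter; 0 gives exact interpolation.

    Returns
    -------
    (grid_size, grid_size) array; entry [i, j] is the surface at
    (x[i], y[j]) with cell-centred coordinates from :func:`grid_coordinates`.
    """
    pts = _check_points(points)
    vals = np.asarray(values, dtype=float)
    if vals.shape != (pts.shape[0],):
        raise ValueError("values must match the number of points")
    interp = RBFInterpolator(
        pts, vals, kernel="thin_plate_spline", degree=1, smoothing=smoothing
    )
    gx, gy = grid_coordinates(grid_size, extent)
    mesh = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    return interp(mesh).reshape(grid_size, grid_size)


def align_and_stack(
    per_animal: list[dict],
    smoothing: float = 0.0,
    grid_size: int = GRID_SIZE,
    extent: float = MAP_EXTENT_MM,
) -> LearnabilityMap:
    """Shift-align per-animal electrode maps and average them cell-wise.

    Each entry of ``per_animal`` is a dict with keys:

    - ``points``: (7, 2) unshifted electrode centres, mm;
    - ``mean``: (7,) per-electrode mean learnability (%);
    - ``sem``: (7,) per-electrode learnability SEM (optional);
    - ``shift_um``: (lateral, rostro-caudal) array shift of that animal, um.

    Electrode coordinates are translated by the animal's shift before
    interpolation so that all surfaces live in brain-fixed coordinates, then
    every surface is evaluated on the common grid and averaged per cell.
    Electrodes displaced beyond the map extent are clipped onto the boundary
    with a warning.
    """
    if not per_animal:
        raise ValueError("no animals to stack")
    mean_surfaces = []
    sem_surfaces = []
    for entry in per_animal:
        pts = np.asarray(entry["points"], dtype=float)
        shift = np.asarray(entry.get("shift_um", (0.0, 0.0)), dtype=float) / 1000.0
        shifted = pts + shift
        if np.any(np.abs(shifted) > extent):
            warnings.warn(
                "electrode shifted off the map extent; clipping to boundary",
                stacklevel=2,
            )
            shifted = np.clip(shifted, -extent, extent)
        mean_surfaces.append(
            tps_surface(shifted, entry["mean"], smoothing, grid_size, extent)
        )
        if entry.get("sem") is not None:
            sem_surfaces.append(
                tps_surface(shifted, entry["sem"], smoothing, grid_size, extent)
            )
    stack = np.stack(mean_surfaces)
    n = stack.shape[0]
    cross_sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(stack[0])
    )
    gx, gy = grid_coordinates(grid_size, extent)
    return LearnabilityMap(
        mean_map=stack.mean(axis=0),
        sem_map=np.stack(sem_surfaces).mean(axis=0) if sem_surfaces else None,
        cross_animal_sem=cross_sem,
        grid_x=gx,
        grid_y=gy,
        n_animals=n,
    )
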