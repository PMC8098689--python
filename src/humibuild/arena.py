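"""Arena occupancy: walls, deposited blocks, lid, gaps and termination.

The arena is a lattice of EMPTY / WALL / BLOCK cells.  Two parallel walls
form a short tunnel open at the front (+y); the agent extends or seals the
structure by attaching square blocks.  A lid covers the tunnel corridor up
to the furthest contiguous structure and suppresses ambient exchange
underneath (the 2D stand-in for roofed 3D construction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .conditions import FanSide

EMPTY, WALL, BLOCK = 0, 1, 2

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # 4-connectivity


class CollisionError(ValueError):
    """Block footprint overlaps existing structure."""


class UnattachedDepositionError(ValueError):
    """Block footprint touches no existing structure (no attachment)."""


class Termination(str, enum.Enum):
    NONE = "none"
    CLOSURE = "closure"
    BLOCK_LIMIT = "block_limit"
    ABORT = "abort"


@dataclass(frozen=True)
class Limits:
    """Stopping rules: seal gaps to ``gap_threshold`` cm or place ``max_blocks``."""

    gap_threshold: float = 5.0
    max_blocks: int = 14

    def __post_init__(self) -> None:
        if self.gap_threshold <= 0 or self.max_blocks < 0:
            raise ValueError("limits must be positive (max_blocks >= 0)")


@dataclass(frozen=True)
class ArenaSpec:
    """Construction parameters for the default arena layout (all cm)."""

    nx: int = 30
    ny: int = 45
    cell_size: float = 1.0
    wall_length: float = 20.0
    wall_gap: float = 10.0
    block_size: float = 3.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.cell_size <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.wall_length <= 0 or self.wall_gap <= 0 or self.block_size <= 0:
            raise ValueError("wall_length, wall_gap and block_size must be positive")
        h = self.cell_size
        if self.wall_gap + 2 * h > self.nx * h:
            raise ValueError("arena too narrow for the tunnel walls")
        if self.wall_length >= self.ny * h:
            raise ValueError("arena too short for the tunnel walls")


@dataclass
class Block:
    id: int
    footprint: frozenset
    cycle: int


@dataclass
class ArenaGeometry:
    """Occupancy grid plus lid state and tunnel reference geometry."""

    occupancy: np.ndarray
    cell_size: float
    lid_extent_y: float
    initial_wall_front_y: float
    supply_position: tuple[int, int]
    corridor_ix: tuple[int, int]  # inclusive column range spanned by the lid
    tunnel_center_x: float
    block_size: float
    blocks: list = field(default_factory=list)
    wall_seed_cell: tuple[int, int] = (0, 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    def covered_mask(self) -> np.ndarray:
        """Cells under the lid: corridor columns with center y < lid_extent_y."""
        nx, ny = self.shape
        ycenters = (np.arange(ny) + 0.5) * self.cell_size
        mask = np.zeros((nx, ny), dtype=bool)
        lo, hi = self.corridor_ix
        mask[lo : hi + 1, :] = ycenters[None, :] < self.lid_extent_y
        return mask

    def half_mask(self, side: FanSide) -> np.ndarray:
        """Cells on one lateral half of the arena (fan sweep region)."""
        nx, ny = self.shape
        mask = np.zeros((nx, ny), dtype=bool)
        mid = nx // 2
        if side is FanSide.LEFT:
            mask[:mid, :] = True
        else:
            mask[mid:, :] = True
        return mask

    def structure_mask(self) -> np.ndarray:
        return self.occupancy != EMPTY


def make_arena(spec: ArenaSpec = ArenaSpec()) -> ArenaGeometry:
    """Build the initial geometry: two parallel walls, lid over the tunnel.

    The tunnel axis is +y with the opening at the front; the supply point
    (where the agent collects blocks) sits at the rear of the tunnel.
    """
    h = spec.cell_size
    occ = np.full((spec.nx, spec.ny), EMPTY, dtype=np.int8)
    gap_cells = int(round(spec.wall_gap / h))
    wall_cells = int(round(spec.wall_length / h))
    ix_left = (spec.nx - gap_cells) // 2 - 1
    ix_right = ix_left + gap_cells + 1
    occ[ix_left, :wall_cells] = WALL
    occ[ix_right, :wall_cells] = WALL
    center_x = (ix_left + 1 + ix_right) / 2.0 * h  # midline between inner wall faces
    supply = ((ix_left + 1 + ix_right) // 2, 1)
    return ArenaGeometry(
        occupancy=occ,
        cell_size=h,
        lid_extent_y=wall_cells * h,
        initial_wall_front_y=wall_cells * h,
        supply_position=supply,
        corridor_ix=(ix_left, ix_right),
        tunnel_center_x=center_x,
        block_size=spec.block_size,
        wall_seed_cell=(ix_left, 0),
    )


def tunnel_interior_mask(geometry: ArenaGeometry) -> np.ndarray:
    """Cells strictly between the initial walls, over the walls' length."""
    nx, ny = geometry.shape
    lo, hi = geometry.corridor_ix
    wall_cells = int(round(geometry.initial_wall_front_y / geometry.cell_size))
    mask = np.zeros((nx, ny), dtype=bool)
    mask[lo + 1 : hi, :wall_cells] = True
    return mask


def place_block(geometry: ArenaGeometry, footprint, cycle: int = 0) -> Block:
    """Attach a block: cells must be empty and touch existing structure.

    Mirrors the attachment constraint on real deposition — material must be
    affixed to a wall or to previously deposited material, never floated in
    open space.
    """
    cells = sorted(set(map(tuple, footprint)))
    if not cells:
        raise ValueError("empty footprint")
    nx, ny = geometry.shape
    occ = geometry.occupancy
    for ix, iy in cells:
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise IndexError(f"footprint cell {(ix, iy)} outside the grid")
        if occ[ix, iy] != EMPTY:
            raise CollisionError(f"collision at cell {(ix, iy)}")
    fp_mask = np.zeros((nx, ny), dtype=bool)
    for ix, iy in cells:
        fp_mask[ix, iy] = True
    _, ncomp = ndimage.label(fp_mask, structure=_CROSS)
    if ncomp != 1:
        raise ValueError("footprint must be 4-connected")
    touching = ndimage.binary_dilation(fp_mask, structure=_CROSS) & geometry.structure_mask()
    if not touching.any():
        raise UnattachedDepositionError("unattached deposition: no adjacent wall or block")
    for ix, iy in cells:
        occ[ix, iy] = BLOCK
    block = Block(id=len(geometry.blocks), footprint=frozenset(cells), cycle=cycle)
    geometry.blocks.append(block)
    return block


def extend_lid(geometry: ArenaGeometry) -> ArenaGeometry:
    """Advance the lid to the furthest extent of any contiguous structure.

    Only structure 4-connected to the initial walls counts; the lid never
    retracts.  Called once per completed deposition cycle.
    """
    labels, _ = ndimage.label(geometry.structure_mask(), structure=_CROSS)
    root = labels[geometry.wall_seed_cell]
    ys = np.nonzero(labels == root)[1]
    extent = (ys.max() + 1) * geometry.cell_size
    geometry.lid_extent_y = max(geometry.lid_extent_y, float(extent))
    return geometry


def _clearance_grid(geometry: ArenaGeometry) -> tuple[np.ndarray, float]:
    """Distance from half-cell grid points to the nearest structure rectangle.

    Points sit at multiples of cell_size/2 in both coordinates (cell centers
    *and* corners), which makes the measure exact for axis-aligned slots of
    whole-cell width.
    """
    h = geometry.cell_size
    nx, ny = geometry.shape
    cells = np.argwhere(geometry.structure_mask())
    px = np.arange(2 * nx + 1) * (h / 2.0)
    py = np.arange(2 * ny + 1) * (h / 2.0)
    if len(cells) == 0:
        return np.full((px.size, py.size), np.inf), h
    x0 = cells[:, 0] * h
    y0 = cells[:, 1] * h
    clear = np.empty((px.size, py.size))
    # chunk over point rows to bound memory (points x rectangles)
    for i in range(px.size):
        dx = np.maximum(np.maximum(x0[None, :] - px[i], px[i] - (x0[None, :] + h)), 0.0)
        dy = np.maximum(np.maximum(y0[None, :] - py[:, None], py[:, None] - (y0[None, :] + h)), 0.0)
        clear[i, :] = np.sqrt(dx**2 + dy**2).min(axis=1)
    return clear, h


def max_gap_width(geometry: ArenaGeometry) -> float:
    """Widest opening connecting the tunnel interior to the outside, in cm.

    Defined as the diameter of the largest disc that can travel from deep
    inside the tunnel to the exterior without touching any wall or block:
    the maximin structure clearance over paths on a half-cell point grid.
    A fully sealed frontier gives 0.  The measure is exact for
    axis-aligned gaps and can only decrease as structure is added.
    """
    clear, h = _clearance_grid(geometry)
    nx, ny = geometry.shape
    # interior seed: on the tunnel midline just inside the rear; exterior
    # seed: the front-left arena corner, far from the structure
    si = (int(round(2 * geometry.tunnel_center_x / h)), 2)
    se = (0, 2 * ny)
    si = (min(max(si[0], 0), 2 * nx), min(max(si[1], 0), 2 * ny))
    passable = clear > 0
    if not (passable[si] and passable[se]):
        return 0.0
    labels, _ = ndimage.label(passable, structure=_CROSS)
    if labels[si] != labels[se]:
        return 0.0
    values = np.unique(clear[passable])
    lo, hi = 0, len(values) - 1  # connectivity holds at values[lo]
    while lo < hi:
        mid = (lo + hi + 1) // 2
        mask = clear >= values[mid]
        labels, _ = ndimage.label(mask, structure=_CROSS)
        if mask[si] and mask[se] and labels[si] == labels[se]:
            lo = mid
        else:
            hi = mid - 1
    return float(2.0 * values[lo])


def check_termination(
    geometry: ArenaGeometry, blocks_placed: int, limits: Limits
) -> Termination:
    """CLOSURE once no opening wider than the gap threshold remains,
    else BLOCK_LIMIT at the block budget, else NONE.  CLOSURE takes
    precedence when both hold."""
    if max_gap_width(geometry) <= limits.gap_threshold:
        return Termination.CLOSURE
    if blocks_placed >= limits.max_blocks:
        return Termination.BLOCK_LIMIT
    return Termination.NONE
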