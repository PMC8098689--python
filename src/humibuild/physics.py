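"""Humidity-field and substrate-moisture dynamics on the 2D arena lattice.

The simulator couples two scalar fields on the arena lattice: relative
humidity (RH, % of saturation) in the air layer just above the substrate,
and liquid water mass (g) held by the absorbent substrate in each cell.
One explicit time step applies, in order,

1. finite-difference diffusion of RH with no-flux boundaries at wall/block
   cells and at the arena edge,
2. linear relaxation toward ambient RH for cells exposed to outside air
   (covered cells exchange nothing; fan-swept cells relax much faster), and
3. evaporation from wet substrate into the local air cell, proportional to
   the local saturation deficit (100 - RH), capped by the available water
   and by the room left below saturation.

Evaporated water raises local RH through the coupling constant ``gamma``
(%RH per gram); the same constant converts RH removed by ambient exchange
back into grams, so a trial can keep an exact water ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .arena import EMPTY, ArenaGeometry
from .conditions import Condition, ConditionKind

RH_SAT = 100.0


class FieldConsistencyError(RuntimeError):
    """The humidity field left its physical range (instability or a bug)."""


def calibrate_evaporation(target_rate: float, ambient_rh: float) -> float:
    """Evaporation coefficient reproducing a measured steady drying rate.

    Given a saturated substrate cell that loses ``target_rate`` grams per
    hour while the local air is held at ``ambient_rh`` % RH, return the
    coefficient ``k_evap`` (g per second per %RH of deficit) such that the
    per-step law  ``mass_loss = k_evap * max(0, 100 - RH_local) * dt``
    integrates to exactly that hourly loss.

    Raises ``ValueError`` ("uncalibratable") when ``ambient_rh >= 100``,
    where the deficit vanishes and no finite coefficient exists.
    """
    if target_rate < 0:
        raise ValueError("target_rate must be >= 0")
    if ambient_rh < 0:
        raise ValueError("ambient_rh must be >= 0")
    if ambient_rh >= RH_SAT:
        raise ValueError("uncalibratable: zero saturation deficit at ambient_rh >= 100")
    return target_rate / 3600.0 / (RH_SAT - ambient_rh)


#: Measured drying rates (g/h at 40% ambient RH) for the two substrates:
#: unglazed ceramic tile as used in the arena, and the clay-heavy mound
#: soil it stands in for.
EVAP_RATE_TILE = 0.75
EVAP_RATE_SOIL = 0.6


@dataclass
class PhysicsParams:
    """Rates governing the humidity field.

    diffusivity : effective in-plane vapor diffusivity, cm^2/s.  Effective
        value for the thin air layer over the substrate (molecular diffusion
        plus weak convective mixing), not the molecular constant.
    ambient_rh : outside-air relative humidity, %.
    lambda_open : 1/s, relaxation rate toward ambient for uncovered cells
        in still air.  Slow in sheltered still air; together with 2D
        geometric dilution it sets how far the humid plume from the tunnel
        mouth reaches before dropping below the deposition threshold.
    lambda_fan : 1/s, relaxation rate for fan-swept cells; must be >=
        lambda_open.
    gamma : %RH rise per gram evaporated into one cell's air column.
    capacity : grams of water one substrate cell holds when saturated.
    evap_rate : calibration target, g/h lost by a saturated cell at
        ``ambient_rh`` (tile preset by default).
    k_evap : evaporation coefficient; derived from ``evap_rate`` unless
        given explicitly.
    """

    diffusivity: float = 1.0
    ambient_rh: float = 40.0
    lambda_open: float = 0.003
    lambda_fan: float = 1.0
    gamma: float = 1.2e5
    capacity: float = 0.15
    evap_rate: float = EVAP_RATE_TILE
    k_evap: float | None = None

    def __post_init__(self) -> None:
        if self.k_evap is None:
            self.k_evap = calibrate_evaporation(self.evap_rate, self.ambient_rh)
        for name in ("diffusivity", "lambda_open", "lambda_fan", "gamma", "capacity", "k_evap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ambient_rh < RH_SAT:
            raise ValueError("ambient_rh must lie in [0, 100)")
        if self.lambda_fan < self.lambda_open:
            raise ValueError("lambda_fan must be >= lambda_open")

    def stable_dt(self, cell_size: float, safety: float = 0.25) -> float:
        """Time step at ``safety`` times the explicit-scheme stability bound."""
        if self.diffusivity == 0:
            return safety  # diffusion-free: any dt is stable; pick something small
        return safety * cell_size**2 / (4.0 * self.diffusivity)


@dataclass
class HumidityField:
    """Lattice of relative-humidity values (%% RH) over the arena."""

    values: np.ndarray
    cell_size: float
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2D grid with nx, ny >= 1")
        if self.cell_size <= 0 or self.dt <= 0:
            raise ValueError("cell_size and dt must be positive")
        if self.values.min() < 0 or self.values.max() > RH_SAT:
            raise ValueError("RH values must lie in [0, 100]")

    @classmethod
    def uniform(
        cls,
        nx: int,
        ny: int,
        value: float,
        cell_size: float,
        params: PhysicsParams,
        dt_safety: float = 0.25,
    ) -> "HumidityField":
        """Uniform field with a stability-checked time step."""
        f = cls(np.full((nx, ny), float(value)), cell_size, params.stable_dt(cell_size, dt_safety))
        f.check_stability(params)
        return f

    def check_stability(self, params: PhysicsParams) -> None:
        if params.diffusivity > 0 and self.dt > self.cell_size**2 / (4.0 * params.diffusivity) * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt} violates the explicit stability bound "
                f"{self.cell_size ** 2 / (4 * params.diffusivity)} for D={params.diffusivity}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SubstrateMoisture:
    """Per-cell liquid water mass (g) in the absorbent substrate."""

    mass: np.ndarray
    capacity: float

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.capacity < 0:
            raise ValueError("capacity must be >= 0")
        if self.mass.min() < 0 or self.mass.max() > self.capacity * (1 + 1e-12):
            raise ValueError("mass must lie in [0, capacity] elementwise")

    def total(self) -> float:
        return float(self.mass.sum())


def deposit_water(
    moisture: SubstrateMoisture, position: tuple[int, int], amount: float
) -> tuple[SubstrateMoisture, float]:
    """Add ``amount`` grams at a cell, capped at capacity; return runoff.

    Models the agent passively dripping from its reservoir onto the
    substrate.  Water beyond saturation is discarded as runoff and
    reported so the trial's water ledger stays closed.
    """
    ix, iy = position
    nx, ny = moisture.mass.shape
    if not (0 <= ix < nx and 0 <= iy < ny):
        raise IndexError(f"position {position} outside the {nx}x{ny} grid")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    room = moisture.capacity - moisture.mass[ix, iy]
    absorbed = min(amount, room)
    moisture.mass[ix, iy] += absorbed
    return moisture, amount - absorbed


def sample_humidity(
    field: HumidityField,
    position: tuple[float, float],
    geometry: ArenaGeometry | None = None,
) -> float:
    """Bilinear interpolation of RH at a continuous position (cm).

    With ``geometry`` given, wall/block cells are masked out of the
    interpolation (the sensor reads air, not the inside of structure);
    the weights of the remaining open cells are renormalized.
    """
    x, y = position
    h = field.cell_size
    nx, ny = field.shape
    if not (0 <= x <= nx * h and 0 <= y <= ny * h):
        raise ValueError(f"position {position} outside arena bounds")
    # fractional cell-center coordinates, clamped so edge positions use edge cells
    gx = min(max(x / h - 0.5, 0.0), nx - 1.0)
    gy = min(max(y / h - 0.5, 0.0), ny - 1.0)
    ix0, iy0 = int(gx), int(gy)
    ix1, iy1 = min(ix0 + 1, nx - 1), min(iy0 + 1, ny - 1)
    fx, fy = gx - ix0, gy - iy0
    v = field.values
    corners = ((ix0, iy0), (ix1, iy0), (ix0, iy1), (ix1, iy1))
    weights = ((1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy)
    if geometry is not None:
        open_ = geometry.occupancy == EMPTY
        weights = tuple(w if open_[c] else 0.0 for w, c in zip(weights, corners))
    total = sum(weights)
    if total <= 0:
        raise ValueError(f"position {position} has no open cell in reach to sample")
    return float(sum(w * v[c] for w, c in zip(weights, corners)) / total)


def step_field(
    field: HumidityField,
    moisture: SubstrateMoisture,
    geometry: ArenaGeometry,
    params: PhysicsParams,
    condition: Condition,
) -> tuple[HumidityField, SubstrateMoisture, float]:
    """Advance the coupled field/moisture system by one explicit step.

    Returns the (mutated) field and moisture plus the water-equivalent mass
    (g) lost to ambient air this step, for ledger bookkeeping.
    """
    rh = field.values
    if rh.shape != geometry.occupancy.shape or rh.shape != moisture.mass.shape:
        raise ValueError("field, moisture and occupancy grids must share dimensions")
    field.check_stability(params)
    h, dt = field.cell_size, field.dt
    open_ = geometry.occupancy == EMPTY

    # 1. diffusion as antisymmetric pair fluxes between open neighbors:
    #    conserves total RH exactly on the closed no-flux domain
    alpha = params.diffusivity * dt / h**2
    lap = np.zeros_like(rh)
    both = open_[:-1, :] & open_[1:, :]
    d = (rh[1:, :] - rh[:-1, :]) * both
    lap[:-1, :] += d
    lap[1:, :] -= d
    both = open_[:, :-1] & open_[:, 1:]
    d = (rh[:, 1:] - rh[:, :-1]) * both
    lap[:, :-1] += d
    lap[:, 1:] -= d
    rh += alpha * lap

    # 2. ambient exchange: only open cells not under the lid; fan-swept
    #    cells (uncovered cells on the fan's half) relax at lambda_fan
    covered = geometry.covered_mask()
    exchanging = open_ & ~covered
    lam = np.where(exchanging, params.lambda_open, 0.0)
    if condition.kind is ConditionKind.FAN:
        lam = np.where(
            exchanging & geometry.half_mask(condition.fan_side), params.lambda_fan, lam
        )
    removed = lam * dt * (rh - params.ambient_rh)
    rh -= removed
    ambient_loss = float(removed.sum()) / params.gamma if params.gamma > 0 else 0.0

    # 3. evaporation: deficit-law transfer from substrate to air, capped by
    #    available water and by the room left below saturation so no
    #    clipping (and no ledger leak) is ever needed
    deficit = np.maximum(RH_SAT - rh, 0.0)
    desired = params.k_evap * deficit * dt
    if params.gamma > 0:
        desired = np.minimum(desired, deficit / params.gamma)
    actual = np.minimum(moisture.mass, desired)
    actual[~open_] = 0.0
    moisture.mass -= actual
    rh += params.gamma * actual

    if np.isnan(rh).any():
        raise FieldConsistencyError("NaN in humidity field after step")
    if rh.min() < -1e-9 or rh.max() > RH_SAT + 1e-9:
        raise FieldConsistencyError(
            f"RH left [0, 100]: min={rh.min():.3g}, max={rh.max():.3g}"
        )
    np.clip(rh, 0.0, RH_SAT, out=rh)
    return field, moisture, ambient_loss
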