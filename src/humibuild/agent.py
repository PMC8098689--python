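"""Behavioral state machine of the builder agent.

One loop (a deposition cycle) mirrors the robot's control program: collect
a block at the rear supply point, turn to face the tunnel front, advance in
small steps while passively dripping water and sampling the air ahead,
deposit the block attached to existing structure once the sampled relative
humidity falls strictly below the threshold, then return to the rear.
All stochasticity (heading noise) flows through the supplied RNG, so a
trial is bit-reproducible from its seed.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .arena import EMPTY, ArenaGeometry, place_block
from .physics import HumidityField, SubstrateMoisture, deposit_water, sample_humidity

log = logging.getLogger(__name__)

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class AgentState(str, enum.Enum):
    COLLECT_BLOCK = "collect_block"
    ORIENT_FORWARD = "orient_forward"
    ADVANCE_SAMPLE = "advance_sample"
    DEPOSIT = "deposit"
    RETURN_REAR = "return_rear"


class TrappedAgentError(RuntimeError):
    """No free path back to the supply point; the trial aborts."""


class NoAttachmentError(RuntimeError):
    """No valid attached footprint exists anywhere in the arena."""


@dataclass
class AgentParams:
    """Behavioral parameters.

    rh_threshold : % RH; deposition triggers when the sampled humidity
        falls strictly below this ("falls below", so an exact hit does not
        trigger).
    step_length : cm advanced per ADVANCE_SAMPLE action.
    drip_per_step : g of water dripped per outbound step (0 models an
        empty reservoir).
    drip_radius : cm; drops splash and soak into the absorbent substrate
        over this radius around the agent, so the drip is split evenly
        over the covered cells.
    sense_offset : cm ahead of the agent at which humidity is sampled (the
        sensor sits at the agent's front).
    heading_noise_sd : degrees of Gaussian noise applied when orienting,
        modeling imprecise navigation; 0 gives exact axial motion.
    max_forward_y : cm; travel cap forcing a deposition if the threshold is
        never crossed (no physical counterpart — prevents non-termination).
    reach_radius : cm within which the agent can place a block without
        first sidestepping toward the structure.
    """

    rh_threshold: float = 75.0
    step_length: float = 2.0
    drip_per_step: float = 0.1
    drip_radius: float = 1.5
    sense_offset: float = 3.0
    heading_noise_sd: float = 6.0
    max_forward_y: float = 42.0
    reach_radius: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.rh_threshold < 100:
            raise ValueError("rh_threshold must lie in (0, 100)")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.drip_per_step < 0:
            raise ValueError("drip_per_step must be >= 0")


@dataclass
class DepositionEvent:
    """One completed deposition: where the humidity cue fired and what was built."""

    cycle: int
    trigger_x: float
    trigger_y: float
    rh_at_trigger: float
    forced: bool
    block_id: int
    sim_time: float = math.nan


@dataclass
class Agent:
    position: tuple[float, float]
    heading: tuple[float, float] = (0.0, 1.0)
    state: AgentState = AgentState.COLLECT_BLOCK
    carrying: bool = False
    cycle: int = 0
    prev_sample: float | None = None
    trigger: tuple[float, float, float, bool] | None = None  # x, y, rh, forced
    total_dripped: float = 0.0
    total_runoff: float = 0.0
    trail: list = field(default_factory=list)


def _cell_of(pos: tuple[float, float], geometry: ArenaGeometry) -> tuple[int, int]:
    nx, ny = geometry.shape
    h = geometry.cell_size
    return (
        min(max(int(pos[0] / h), 0), nx - 1),
        min(max(int(pos[1] / h), 0), ny - 1),
    )


def _clamp(pos, geometry: ArenaGeometry, margin: float = 1e-6):
    nx, ny = geometry.shape
    h = geometry.cell_size
    return (
        min(max(pos[0], margin), nx * h - margin),
        min(max(pos[1], margin), ny * h - margin),
    )


def _supply_xy(geometry: ArenaGeometry) -> tuple[float, float]:
    ix, iy = geometry.supply_position
    h = geometry.cell_size
    return ((ix + 0.5) * h, (iy + 0.5) * h)


def _window_sum(a: np.ndarray, s: int) -> np.ndarray:
    """Sum of every s-by-s window; output indexed by the window's low corner."""
    c = np.cumsum(np.cumsum(a, axis=0), axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[s:, s:] - c[:-s, s:] - c[s:, :-s] + c[:-s, :-s]


def valid_footprints(geometry: ArenaGeometry):
    """All attachable square footprints: anchor cells, centroids (cm).

    A footprint is valid when every cell is empty and at least one cell is
    4-adjacent to a wall or block.  Returns (anchors, centroids, side).
    """
    h = geometry.cell_size
    s = max(int(round(geometry.block_size / h)), 1)
    empty = (geometry.occupancy == EMPTY).astype(np.int64)
    adjacent = (
        ndimage.binary_dilation(geometry.structure_mask(), structure=_CROSS)
        & (geometry.occupancy == EMPTY)
    ).astype(np.int64)
    ok = (_window_sum(empty, s) == s * s) & (_window_sum(adjacent, s) >= 1)
    anchors = np.argwhere(ok)
    centroids = (anchors + s / 2.0) * h
    return anchors, centroids, s


def select_deposition_site(agent: Agent, geometry: ArenaGeometry, params: AgentParams):
    """Footprint whose centroid is nearest the trigger point.

    Ties break toward smaller x, then smaller y.  If the nearest valid
    footprint lies beyond the agent's reach, the agent sidesteps toward it
    in step_length increments (abstracted as position updates) and places
    on arrival.  Raises NoAttachmentError when no valid footprint exists.
    """
    if agent.trigger is None:
        raise RuntimeError("select_deposition_site requires a recorded trigger")
    tx, ty, _, _ = agent.trigger
    anchors, centroids, s = valid_footprints(geometry)
    if len(anchors) == 0:
        raise NoAttachmentError("no attachment point")
    # never place a block on top of the agent itself
    ax, ay = _cell_of(agent.position, geometry)
    free = ~(
        (anchors[:, 0] <= ax)
        & (ax < anchors[:, 0] + s)
        & (anchors[:, 1] <= ay)
        & (ay < anchors[:, 1] + s)
    )
    if not free.any():
        raise NoAttachmentError("no attachment point clear of the agent")
    anchors, centroids = anchors[free], centroids[free]
    d2 = (centroids[:, 0] - tx) ** 2 + (centroids[:, 1] - ty) ** 2
    order = np.lexsort((centroids[:, 1], centroids[:, 0], np.round(d2, 9)))
    best = anchors[order[0]]
    cx, cy = centroids[order[0]]
    # sidestep toward the placement site until within reach
    guard = 0
    while math.hypot(cx - agent.position[0], cy - agent.position[1]) > params.reach_radius:
        px, py = agent.position
        d = math.hypot(cx - px, cy - py)
        step = min(params.step_length, d)
        agent.position = _clamp((px + step * (cx - px) / d, py + step * (cy - py) / d), geometry)
        guard += 1
        if guard > 500:
            raise NoAttachmentError("no attachment point reachable")
    ix0, iy0 = int(best[0]), int(best[1])
    return [(ix0 + i, iy0 + j) for i in range(s) for j in range(s)]


def _path_exists(geometry: ArenaGeometry, a: tuple[int, int], b: tuple[int, int]) -> bool:
    empty = geometry.occupancy == EMPTY
    if not (empty[a] and empty[b]):
        return False
    labels, _ = ndimage.label(empty, structure=_CROSS)
    return labels[a] == labels[b]


def step_state_machine(
    agent: Agent,
    geometry: ArenaGeometry,
    field_: HumidityField,
    moisture: SubstrateMoisture,
    params: AgentParams,
    rng: np.random.Generator,
    sim_time: float = math.nan,
):
    """Execute one action of the current state and transition.

    Returns (agent, moisture, event-or-None); an event is emitted only by
    the DEPOSIT action.
    """
    event = None
    state = agent.state

    if state is AgentState.COLLECT_BLOCK:
        agent.position = _supply_xy(geometry)
        agent.carrying = True
        agent.cycle += 1
        agent.prev_sample = None
        agent.trigger = None
        agent.state = AgentState.ORIENT_FORWARD

    elif state is AgentState.ORIENT_FORWARD:
        theta = math.radians(rng.normal(0.0, params.heading_noise_sd))
        agent.heading = (math.sin(theta), math.cos(theta))
        agent.state = AgentState.ADVANCE_SAMPLE

    elif state is AgentState.ADVANCE_SAMPLE:
        hx, hy = agent.heading
        # try the nominal heading first, then deflect up to +/-90 degrees to
        # flow around structure (the robot steers around obstacles); the
        # deflection side alternates by a seeded draw so paths stay
        # reproducible but unbiased
        sign = 1.0 if rng.random() < 0.5 else -1.0
        blocked = True
        for ddeg in (0.0, 30.0, -30.0, 60.0, -60.0):
            phi = math.radians(ddeg) * sign
            dx = hx * math.cos(phi) - hy * math.sin(phi)
            dy = hx * math.sin(phi) + hy * math.cos(phi)
            target = _clamp(
                (agent.position[0] + params.step_length * dx, agent.position[1] + params.step_length * dy),
                geometry,
            )
            if geometry.occupancy[_cell_of(target, geometry)] == EMPTY:
                agent.position = target
                hx, hy = dx, dy  # sample along the direction actually moved
                blocked = False
                break
        if params.drip_per_step > 0:
            cx, cy = _cell_of(agent.position, geometry)
            nx, ny = geometry.shape
            rad = max(int(params.drip_radius / geometry.cell_size), 0)
            patch = [
                (ix, iy)
                for ix in range(max(cx - rad, 0), min(cx + rad + 1, nx))
                for iy in range(max(cy - rad, 0), min(cy + rad + 1, ny))
            ]
            per_cell = params.drip_per_step / len(patch)
            for cell in patch:
                _, runoff = deposit_water(moisture, cell, per_cell)
                agent.total_runoff += runoff
            agent.total_dripped += params.drip_per_step
        sense = _clamp(
            (agent.position[0] + params.sense_offset * hx, agent.position[1] + params.sense_offset * hy),
            geometry,
        )
        try:
            rh = sample_humidity(field_, sense, geometry)
        except ValueError:
            # sense point buried in structure: read the air at the agent itself
            sense = agent.position
            rh = sample_humidity(field_, sense, geometry)
        agent.trail.append((sense[0], sense[1], rh))
        if rh < params.rh_threshold:
            agent.trigger = (sense[0], sense[1], rh, False)
            agent.state = AgentState.DEPOSIT
        elif agent.position[1] >= params.max_forward_y or blocked:
            agent.trigger = (sense[0], sense[1], rh, True)  # travel cap: forced deposition
            agent.state = AgentState.DEPOSIT
        else:
            agent.prev_sample = rh

    elif state is AgentState.DEPOSIT:
        footprint = select_deposition_site(agent, geometry, params)
        tx, ty, rh, forced = agent.trigger
        block = place_block(geometry, footprint, cycle=agent.cycle)
        event = DepositionEvent(
            cycle=agent.cycle,
            trigger_x=tx,
            trigger_y=ty,
            rh_at_trigger=rh,
            forced=forced,
            block_id=block.id,
            sim_time=sim_time,
        )
        agent.carrying = False
        agent.state = AgentState.RETURN_REAR

    elif state is AgentState.RETURN_REAR:
        here = _cell_of(agent.position, geometry)
        if not _path_exists(geometry, here, geometry.supply_position):
            raise TrappedAgentError(f"trapped agent at cell {here}")
        agent.position = _supply_xy(geometry)
        agent.state = AgentState.COLLECT_BLOCK

    else:  # pragma: no cover
        raise ValueError(f"unknown state {state}")

    if state is not agent.state:
        log.debug("agent cycle %d: %s -> %s", agent.cycle, state.value, agent.state.value)
    return agent, moisture, event
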