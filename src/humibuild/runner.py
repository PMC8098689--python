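"""Trial and batch orchestration for the three experimental treatments.

A trial initializes the arena with saturated tiles between the walls and a
dry exterior, burns in the humidity field so the moisture halo at the
tunnel mouth reaches quasi-steady state, then interleaves agent actions
with field substeps until a stopping rule fires: CLOSURE (no opening wider
than the gap threshold) or BLOCK_LIMIT (block budget spent).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__
from .agent import (
    Agent,
    AgentParams,
    DepositionEvent,
    NoAttachmentError,
    TrappedAgentError,
    step_state_machine,
)
from .arena import (
    ArenaGeometry,
    ArenaSpec,
    Limits,
    Termination,
    check_termination,
    extend_lid,
    make_arena,
    tunnel_interior_mask,
)
from .conditions import Condition, ConditionKind, FanSide
from .physics import (
    RH_SAT,
    FieldConsistencyError,
    HumidityField,
    PhysicsParams,
    SubstrateMoisture,
    step_field,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunSettings:
    """Numerical schedule: field substeps per agent action and burn-in."""

    steps_per_agent_action: int = 20
    burn_in_steps: int = 12000
    dt_safety: float = 0.25
    max_agent_actions: int = 5000

    def __post_init__(self) -> None:
        if self.steps_per_agent_action < 1 or self.burn_in_steps < 0:
            raise ValueError("invalid run settings")
        if not 0 < self.dt_safety <= 1:
            raise ValueError("dt_safety must lie in (0, 1]")


@dataclass(frozen=True)
class TrialConfig:
    seed: int
    condition: Condition
    arena: ArenaSpec = ArenaSpec()
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    agent: AgentParams = field(default_factory=AgentParams)
    limits: Limits = Limits()
    run: RunSettings = RunSettings()


def default_config(condition: Condition | str, seed: int = 0, **overrides) -> TrialConfig:
    if isinstance(condition, str):
        kind = ConditionKind(condition)
        condition = Condition(kind, FanSide.LEFT if kind is ConditionKind.FAN else None)
    return TrialConfig(seed=seed, condition=condition, **overrides)


@dataclass
class WaterLedger:
    """Running water balance of a trial (all grams)."""

    initial_substrate: float = 0.0
    dripped: float = 0.0
    runoff: float = 0.0
    ambient_loss: float = 0.0
    initial_field_rh: float = 0.0


@dataclass
class TrialResult:
    events: list
    termination: Termination
    final_occupancy: np.ndarray
    final_field: np.ndarray
    final_moisture: np.ndarray
    geometry: ArenaGeometry
    ledger: WaterLedger
    condition: Condition
    seed: int
    sim_time: float
    provenance: dict
    abort_reason: str | None = None

    @property
    def initial_wall_front_y(self) -> float:
        return self.geometry.initial_wall_front_y


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialize(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {k: _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    return obj


def config_provenance(config: TrialConfig) -> dict:
    return {"config": _serialize(config), "seed": config.seed, "version": __version__}


def initialize_trial(config: TrialConfig):
    """Geometry, field and moisture in the documented initial state.

    Tiles between the walls are saturated (RH 100 above them); everything
    beyond the tunnel's end starts dry at ambient RH.
    """
    geometry = make_arena(config.arena)
    params = config.physics
    nx, ny = geometry.shape
    field_ = HumidityField.uniform(
        nx, ny, params.ambient_rh, config.arena.cell_size, params, config.run.dt_safety
    )
    interior = tunnel_interior_mask(geometry)
    field_.values[interior] = RH_SAT
    mass = np.zeros((nx, ny))
    mass[interior] = params.capacity
    moisture = SubstrateMoisture(mass=mass, capacity=params.capacity)
    return geometry, field_, moisture


def effective_agent_params(config: TrialConfig) -> AgentParams:
    """Condition contract: the DRY treatment empties the reservoir."""
    if config.condition.kind is ConditionKind.DRY:
        return replace(config.agent, drip_per_step=0.0)
    return config.agent


def run_trial(config: TrialConfig) -> TrialResult:
    """Run one trial to termination; fully reproducible from (config, seed)."""
    geometry, field_, moisture = initialize_trial(config)
    params = config.physics
    agent_params = effective_agent_params(config)
    ledger = WaterLedger(
        initial_substrate=moisture.total(),
        initial_field_rh=float(field_.values.sum()),
    )
    rng = np.random.default_rng(config.seed)
    events: list[DepositionEvent] = []
    termination: Termination | None = None
    abort_reason = None
    sim_time = 0.0

    def substeps(n: int) -> None:
        nonlocal sim_time
        for _ in range(n):
            _, _, lost = step_field(field_, moisture, geometry, params, config.condition)
            ledger.ambient_loss += lost
            sim_time += field_.dt

    try:
        substeps(config.run.burn_in_steps)
    except FieldConsistencyError as exc:  # pragma: no cover - defensive
        return _aborted(config, geometry, field_, moisture, ledger, events, sim_time, str(exc))

    start = check_termination(geometry, 0, config.limits)
    if start is not Termination.NONE:
        termination = start

    sx, sy = geometry.supply_position
    h = geometry.cell_size
    agent = Agent(position=((sx + 0.5) * h, (sy + 0.5) * h))

    actions = 0
    while termination is None:
        try:
            agent, moisture, event = step_state_machine(
                agent, geometry, field_, moisture, agent_params, rng, sim_time=sim_time
            )
            substeps(config.run.steps_per_agent_action)
        except (TrappedAgentError, NoAttachmentError, FieldConsistencyError) as exc:
            termination = Termination.ABORT
            abort_reason = str(exc)
            break
        if event is not None:
            ledger.dripped = agent.total_dripped
            ledger.runoff = agent.total_runoff
            events.append(event)
            extend_lid(geometry)
            log.info(
                "trial seed=%d cycle=%d: deposition at (%.1f, %.1f) RH=%.1f forced=%s",
                config.seed, event.cycle, event.trigger_x, event.trigger_y,
                event.rh_at_trigger, event.forced,
            )
            outcome = check_termination(geometry, len(events), config.limits)
            if outcome is not Termination.NONE:
                termination = outcome
        actions += 1
        if actions >= config.run.max_agent_actions:
            termination = Termination.ABORT
            abort_reason = f"agent action budget ({config.run.max_agent_actions}) exhausted"

    ledger.dripped = agent.total_dripped
    ledger.runoff = agent.total_runoff
    return TrialResult(
        events=events,
        termination=termination,
        final_occupancy=geometry.occupancy.copy(),
        final_field=field_.values.copy(),
        final_moisture=moisture.mass.copy(),
        geometry=geometry,
        ledger=ledger,
        condition=config.condition,
        seed=config.seed,
        sim_time=sim_time,
        provenance=config_provenance(config),
        abort_reason=abort_reason,
    )


def _aborted(config, geometry, field_, moisture, ledger, events, sim_time, reason):
    return TrialResult(
        events=events,
        termination=Termination.ABORT,
        final_occupancy=geometry.occupancy.copy(),
        final_field=field_.values.copy(),
        final_moisture=moisture.mass.copy(),
        geometry=geometry,
        ledger=ledger,
        condition=config.condition,
        seed=config.seed,
        sim_time=sim_time,
        provenance=config_provenance(config),
        abort_reason=reason,
    )


def run_batch(base: TrialConfig, n: int, seeds: list[int]) -> list[TrialResult]:
    """n independent trials; FAN batches alternate the fan side (L, R, L, ...)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(seeds) != n:
        raise ValueError(f"need exactly {n} seeds, got {len(seeds)}")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds in batch")
    results = []
    for i, seed in enumerate(seeds):
        condition = base.condition
        if condition.kind is ConditionKind.FAN:
            condition = Condition(
                ConditionKind.FAN, FanSide.LEFT if i % 2 == 0 else FanSide.RIGHT
            )
        results.append(run_trial(replace(base, seed=seed, condition=condition)))
    return results
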