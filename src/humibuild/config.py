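"""Trial configuration files (TOML), output writers, and test fixtures.

One TOML file fully determines a trial: tables [arena], [physics],
[agent], [condition], [limits], [run].  Unknown keys are rejected, every
default is echoed into provenance, and each output directory embeds the
config hash and seed so a result can be re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np

from .agent import AgentParams
from .arena import ArenaGeometry, ArenaSpec, Limits, make_arena, place_block
from .conditions import Condition, ConditionKind, FanSide
from .physics import PhysicsParams
from .runner import RunSettings, TrialConfig, TrialResult, config_provenance


class ConfigError(ValueError):
    pass


_TABLES = {
    "arena": ArenaSpec,
    "physics": PhysicsParams,
    "agent": AgentParams,
    "limits": Limits,
    "run": RunSettings,
}
_CONDITION_KEYS = {"kind", "fan_side"}


def _build(cls, table: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in [{name}]")
    try:
        return cls(**table)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] table: {exc}") from exc


def config_from_dict(doc: dict) -> TrialConfig:
    unknown = set(doc) - set(_TABLES) - {"condition", "seed"}
    if unknown:
        raise ConfigError(f"unknown table(s)/key(s): {sorted(unknown)}")
    cond_table = dict(doc.get("condition", {}))
    bad = set(cond_table) - _CONDITION_KEYS
    if bad:
        raise ConfigError(f"unknown key(s) {sorted(bad)} in [condition]")
    if "kind" not in cond_table:
        raise ConfigError("[condition] table with a 'kind' key is required")
    try:
        kind = ConditionKind(cond_table["kind"])
        fan_side = cond_table.get("fan_side")
        if fan_side is None and kind is ConditionKind.FAN:
            fan_side = "left"
        condition = Condition(kind, FanSide(fan_side) if fan_side is not None else None)
    except ValueError as exc:
        raise ConfigError(f"invalid [condition]: {exc}") from exc
    parts = {name: _build(cls, dict(doc.get(name, {})), name) for name, cls in _TABLES.items()}
    return TrialConfig(
        seed=int(doc.get("seed", 0)),
        condition=condition,
        arena=parts["arena"],
        physics=parts["physics"],
        agent=parts["agent"],
        limits=parts["limits"],
        run=parts["run"],
    )


def load_config(path) -> TrialConfig:
    """Parse and validate a trial TOML file; defaults are filled in."""
    with open(path, "rb") as fh:
        try:
            doc = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"TOML parse error in {path}: {exc}") from exc
    return config_from_dict(doc)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v) + '"'


def dump_config(config: TrialConfig) -> str:
    """Render a config back to TOML; load(dump(c)) == c."""
    lines = [f"seed = {config.seed}", "", "[condition]", f'kind = "{config.condition.kind.value}"']
    if config.condition.fan_side is not None:
        lines.append(f'fan_side = "{config.condition.fan_side.value}"')
    for name in _TABLES:
        obj = getattr(config, name if name != "run" else "run")
        lines += ["", f"[{name}]"]
        for f in dataclasses.fields(obj):
            val = getattr(obj, f.name)
            if val is None:
                continue
            lines.append(f"{f.name} = {_toml_value(val)}")
    return "\n".join(lines) + "\n"


def config_hash(config: TrialConfig) -> str:
    doc = config_provenance(config)["config"]
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# output writers

def events_frame(result: TrialResult):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cycle": ev.cycle,
                "trigger_x": ev.trigger_x,
                "trigger_y": ev.trigger_y,
                "rh_at_trigger": ev.rh_at_trigger,
                "forced": ev.forced,
                "block_id": ev.block_id,
                "sim_time": ev.sim_time,
            }
            for ev in result.events
        ],
        columns=["cycle", "trigger_x", "trigger_y", "rh_at_trigger", "forced", "block_id", "sim_time"],
    )


def _to_png(path: Path, grid: np.ndarray, lo: float, hi: float) -> None:
    from PIL import Image

    scaled = np.clip((grid.T[::-1] - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(scaled, mode="L").save(path)


def write_trial_outputs(result: TrialResult, outdir) -> Path:
    """events.csv, summary.json, grids as CSV + 8-bit PNG, provenance.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(result.provenance["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    events_frame(result).to_csv(outdir / "events.csv", index=False)
    np.savetxt(outdir / "occupancy.csv", result.final_occupancy, fmt="%d", delimiter=",")
    np.savetxt(outdir / "field.csv", result.final_field, fmt="%.6f", delimiter=",")
    _to_png(outdir / "occupancy.png", result.final_occupancy.astype(float), 0, 2)
    _to_png(outdir / "field.png", result.final_field, 0, 100)

    summary = {
        "config_hash": cfg_hash,
        "seed": result.seed,
        "condition": result.condition.label,
        "termination": result.termination.value,
        "abort_reason": result.abort_reason,
        "n_events": len(result.events),
        "n_forced": sum(ev.forced for ev in result.events),
        "sim_time_s": result.sim_time,
        "lid_extent_y_cm": result.geometry.lid_extent_y,
        "water_g": {
            "initial_substrate": result.ledger.initial_substrate,
            "dripped": result.ledger.dripped,
            "runoff": result.ledger.runoff,
            "ambient_loss": result.ledger.ambient_loss,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    prov = dict(result.provenance)
    prov["config_hash"] = cfg_hash
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# deterministic fixtures for tests

def make_fixture(kind: str):
    """Small deterministic instances used by the test suite.

    toy_arena : 10 x 15 arena with short walls, passes all geometry
        invariants.
    prebuilt_closure : geometry whose widest remaining opening is exactly
        the default 5 cm gap threshold.
    threshold_trace : RH trace crossing the 75% threshold at a known index.
    """
    if kind == "toy_arena":
        return make_arena(ArenaSpec(nx=10, ny=15, wall_length=6.0, wall_gap=4.0, block_size=2.0))
    if kind == "prebuilt_closure":
        geometry = make_arena(ArenaSpec())
        # a row capping the left wall front leaves a 5 cm slot to the right wall
        place_block(geometry, [(ix, 20) for ix in range(9, 15)], cycle=1)
        return geometry
    if kind == "threshold_trace":
        return {"samples": [85.0, 80.0, 76.0, 74.0], "threshold": 75.0, "first_below": 3}
    raise ValueError(f"unknown fixture kind {kind!r}")
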