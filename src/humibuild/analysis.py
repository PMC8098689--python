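"""Trigger-point analyses: signed distances, condition comparison, maps.

The headline measurement is the signed axial (vertical) distance between
the front edge of the initial walls and each deposition trigger point:
positive distances mean the humidity cue fired beyond the original tunnel
(extension), negative ones inside it (retreat / sealing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .arena import BLOCK, WALL
from .runner import TrialResult


@dataclass(frozen=True)
class DistanceSample:
    condition: str
    distance: float
    cycle: int
    seed: int


def trigger_distances(result: TrialResult, include_forced: bool = False) -> list[DistanceSample]:
    """Signed axial distances of trigger points from the initial wall edge.

    Forced depositions (travel-cap fallback, no physical counterpart) are
    excluded by default.
    """
    samples = [
        DistanceSample(
            condition=result.condition.label,
            distance=ev.trigger_y - result.initial_wall_front_y,
            cycle=ev.cycle,
            seed=result.seed,
        )
        for ev in result.events
        if include_forced or not ev.forced
    ]
    if not samples:
        warnings.warn("trial has no usable (non-forced) deposition events")
    return samples


def pooled_distances(results: list[TrialResult], include_forced: bool = False) -> np.ndarray:
    return np.array(
        [s.distance for r in results for s in trigger_distances(r, include_forced)]
    )


def trigger_slope(result: TrialResult) -> float:
    """Least-squares slope of trigger distance vs. cycle index (cm/cycle)."""
    samples = trigger_distances(result)
    if len(samples) < 2:
        raise ValueError("need at least two non-forced events for a slope")
    cycles = np.array([s.cycle for s in samples], dtype=float)
    dist = np.array([s.distance for s in samples])
    if np.ptp(cycles) == 0:
        raise ValueError("all events share one cycle index")
    return float(np.polyfit(cycles, dist, 1)[0])


def compare_conditions(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test between distance samples (two-tailed).

    Pooled-variance Student's t by default (df = n_a + n_b - 2); Welch's
    unequal-variance form via ``welch=True``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate samples: zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def trigger_map(results: list[TrialResult], ax=None, save: str | None = None):
    """Trigger points of all trials on the arena raster, colored by cycle.

    Crosses mark where the sampled humidity first fell below threshold;
    the green line marks the initial wall front edge.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 6))
    else:
        fig = ax.figure
    if not results:
        warnings.warn("no results to map")
        ax.set_title("(empty)")
        return fig

    first = results[0]
    h = first.geometry.cell_size
    nx, ny = first.geometry.shape
    occ = first.final_occupancy
    base = np.zeros_like(occ, dtype=float)
    base[occ == WALL] = 1.0
    base[occ == BLOCK] = 0.6
    ax.imshow(
        base.T, origin="lower", cmap="gray_r", extent=(0, nx * h, 0, ny * h), alpha=0.6
    )
    ax.axhline(first.initial_wall_front_y, color="green", lw=1.5)
    max_cycle = max((ev.cycle for r in results for ev in r.events), default=1)
    sc = None
    for r in results:
        if not r.events:
            continue
        xs = [ev.trigger_x for ev in r.events]
        ys = [ev.trigger_y for ev in r.events]
        cs = [ev.cycle for ev in r.events]
        sc = ax.scatter(xs, ys, c=cs, cmap="viridis", vmin=1, vmax=max_cycle, marker="x", s=40)
    if sc is not None:
        fig.colorbar(sc, ax=ax, label="deposition cycle")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_title(f"trigger points: {first.condition.label} (n={len(results)})")
    if save:
        fig.savefig(save, dpi=150, bbox_inches="tight")
    return fig
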