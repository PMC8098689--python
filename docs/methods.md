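# Methods

## The mechanism being modeled

The simulator tests whether a single environmental cue — local relative
humidity — suffices to produce the two qualitative building patterns seen
in savannah termites and in a robophysical analogue: tunnel *extension*
when the outside air is still and the builder carries water, and tunnel
*closure* when the air is disturbed by wind or no water is transported.
Deposition is template-driven (the agent reacts to the humidity gradient,
not to the shapes of previous deposits), with a secondary stigmergic
constraint: every block must be attached to existing structure.

## Field physics

The arena is a 30 × 45 cm lattice of 1 cm cells. Two scalar fields live on
it: relative humidity *H* (% of saturation) in the air layer over the
substrate, and liquid water *m* (g) in the absorbent substrate. One
explicit step applies diffusion (no-flux at structure and arena edges),
linear relaxation toward ambient for cells open to outside air, and
deficit-law evaporation from wet substrate, in that order. The evaporation
transfer is capped by both the available water and the head-room below
saturation, so the water ledger closes exactly: water added by the agent
equals water still in the substrate, plus the field's RH excess divided by
the coupling constant γ, plus the cumulative loss to ambient air. The
explicit scheme requires Δt ≤ h²/4D; the default Δt is a quarter of that
bound (0.0625 s), checked at construction and again at every step.

No field equations were available for the physical arena this model
mirrors, so the physics here is the simplest law set that supports a
humidity bubble at a wet/dry boundary and its disruption by ventilation;
all of its rate constants are properties of this artifact, not measured
quantities, except the two drying rates below.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| D | 1.0 | cm²/s | effective in-plane vapor diffusivity of the thin air layer (molecular diffusion plus weak mixing); sets cm-scale spreading in seconds |
| ambient RH | 40 | % | the ambient humidity at which the substrate drying rates were measured |
| λ_open | 0.003 | 1/s | exchange with still outside air is slow (~5 min time constant) in a sheltered arena; with 2D geometric dilution it places the 75% contour a few cm beyond the tunnel mouth, where depositions must begin |
| λ_fan | 1.0 | 1/s | fan-swept air mixes to ambient within ~1 s; strong enough that even a wet surface cannot hold 75% RH under the fan |
| γ | 1.2 × 10⁵ | %RH/g | ~0.5 mg of vapor saturates one cell's air column (≈10 cm of air over 1 cm²); keeps the bubble persistent, with one saturated cell able to saturate its own air using ≪10% of its water |
| k_e | calibrated | g/(s·%RH) | from the measured drying rates: 0.75 g/h (unglazed tile) and 0.6 g/h (clay-heavy mound soil), both at 40% ambient RH, reproduced exactly by construction |
| capacity | 0.15 | g/cell | ~6 mm of porous tile under 1 cm² holds ≈0.15 g at saturation |
| RH threshold | 75 | % | the deposition trigger; strictly-below semantics, so a sample exactly at threshold does not trigger |
| step length / sense offset | 2 / 3 | cm | the sensor sits at the agent's front; sampling every 2 cm quantizes trigger positions by about one step |
| drip | 0.1 g over r = 1.5 cm | g, cm | drops splash and soak into the tile over a small patch; the patch, not a single cell, is what makes the dripped trail an effective vapor source |
| heading noise | 6 | ° (sd) | imprecise navigation; ±2 sd of lateral drift over the tunnel length stays within the corridor while spreading trigger points across its width |
| gap threshold / block budget | 5 / 14 | cm, blocks | stopping rules of the experimental protocol |
| block size | 3 | cm | square blocks somewhat smaller than the tunnel half-width, so single placements narrow but do not instantly choke the 10 cm corridor |
| substeps / burn-in | 20 / 12 000 | steps | 20 field substeps (1.25 s) per agent action keep the field near quasi-steady between moves; the burn-in (750 s) lets the mouth plume reach steady state before the first cycle |

The operating point (λ_open, block size, heading noise, drip patch) was
set so that the humidity-template mechanism can operate at all — i.e. so
the still/wet feedback loop of drip → local RH rise → outward trigger
drift is neither drowned by ambient exchange nor cut short by immediate
corridor choking. These are design choices of the artifact, reasoned from
the time and length scales above, and are all config-overridable.

## Geometry and structure rules

Attachment is 4-connectivity (diagonal contact is not physical
attachment). The lid covers the corridor columns spanned by the initial
walls up to the furthest extent of structure contiguous with them, and
never retracts. The gap measure is the diameter of the widest disc that
can pass from deep inside the tunnel to the exterior without touching
structure, computed as a maximin-clearance path on a half-cell point grid;
it is exact for axis-aligned openings (an untouched 10 cm tunnel measures
10.0, a sealed frontier 0.0) and can only decrease as blocks are added.
Closure takes precedence over the block budget when both stopping rules
hold at once.

## Agent

The state machine is collect → orient (+y with Gaussian heading noise) →
advance-and-sample → deposit → return. While advancing, the agent deflects
up to ±60° around occupied cells, choosing the direction closest to its
nominal heading with a seeded coin for ties. Deposition sites are chosen
as the valid footprint (all cells empty, at least one 4-adjacent to
structure, never covering the agent itself) whose centroid is nearest the
trigger point, ties broken toward smaller x then smaller y; if the site is
beyond the agent's reach it sidesteps toward it in step-length increments
before placing. If the threshold is never crossed, a travel cap forces a
deposition; such events are flagged and excluded from distance statistics,
since the physical experiment has no counterpart for them. A trial whose
agent loses all free paths back to the supply point aborts and is flagged.

All randomness (the heading noise and deflection ties) flows through one
`numpy` generator seeded per trial, so a configuration and seed reproduce
the event log byte-for-byte.

## Analyses

Per deposition event the signed axial distance between the trigger point
and the front edge of the initial walls is recorded (positive = beyond the
walls). Conditions are compared with a pooled-variance two-tailed Student
t-test on event distances pooled across trials (Welch's form available via
a flag; per-trial means can be compared by passing them instead). The
pooled-events default was chosen because the per-trial event counts are
small and uneven. Trigger maps render all trigger points over the arena
raster, colored by cycle.

## What the default conditions show — and what they do not

With the default configuration and seeds 1–6 per treatment: still/wet
trials show positive least-squares slopes of trigger distance versus
cycle (the tunnel front ratchets outward); fan and dry trials terminate in
closure with triggers near or behind the initial wall edge; and pooled
distances separate still/wet from both disturbed treatments at p < 0.05.
These are properties of the simulated twin, not of any animal data: the
model is 2D, has no temperature, CO₂ or true advection (the fan is an
enhanced-exchange region, not a flow field), a one-cell-thick wall
geometry, and an abstracted return path instead of landmark navigation.
Still/wet trials here usually end in closure after several extension
cycles rather than running out the full block budget, because the
extending columns eventually narrow the measured opening below the gap
threshold — a geometric consequence of blocks wider than the walls they
cap. The qualitative contrast between treatments, not the absolute trial
length, is the modeled result.

## Numerical details and degenerate inputs

RH is kept in [0, 100] by construction (the evaporation cap makes clipping
a no-op); a NaN or out-of-range value raises an internal-consistency error
and aborts the trial with a diagnostic. Calibration at ambient RH ≥ 100%
is rejected as uncalibratable (zero saturation deficit). A zero block
budget terminates a trial immediately; `D = 0` disables diffusion but
keeps the exchange and evaporation terms. Footprint ties in site selection
are resolved on squared distances rounded at 10⁻⁹ to make the lexicographic
tie-break robust to floating-point noise.
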