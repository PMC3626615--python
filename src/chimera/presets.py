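"""Desk-scale study conditions used by the bundled experiments.

These are the frozen configurations behind the package's headline
results: the phase-diagram sweep, the replica transition curve, the
colonization (ecosystem-engineering) replicates, and the well-fed
generalism-drift world.  They are ordinary :class:`RunConfig` objects --
everything is overridable -- but the values here are the documented
reference conditions at which the emergent sequence completes within a
few thousand steps on a desk machine.
"""

from __future__ import annotations

from .config import RunConfig, default_config
from .experiments import SweepSpec

__all__ = [
    "een_config",
    "wellfed_config",
    "no_grazer_config",
    "desk_sweep_spec",
    "TRANSITION_ETA",
    "TRANSITION_SIGMAS",
    "TRANSITION_STEPS",
    "EEN_STEPS",
]

# Colonization replicates: rich inflow, moderate noise (the EEN corner of
# the phase diagram).  Colonization typically completes within the first
# half of the run; the remainder covers the slower post-colonization
# consolidation of wall adhesion and detritivory (late colonizers need
# a few thousand steps of settled top-layer dynamics).
EEN_STEPS = 10000

# Transition curve: intermediate inflow where colonization is contested,
# scanned across the noise axis with ten replicas per point.
TRANSITION_ETA = 6
TRANSITION_SIGMAS = (0.2, 0.5, 0.8)
TRANSITION_STEPS = 3500


def een_config(steps: int = EEN_STEPS) -> RunConfig:
    """Reference condition where top-face colonization reliably evolves."""
    return default_config().replace(
        ecology={"eta": 8},
        run={"steps": steps, "log_events": False, "record_interval": 50},
    )


def wellfed_config(steps: int = 5000) -> RunConfig:
    """A well-fed world: rich inflow and no effective crowding limit.

    Used for the generalism-drift experiment, where the only relevant
    pressure is the diversity of nutrient classes.
    """
    return default_config().replace(
        ecology={"eta": 8},
        evolution={"rho_max": 10**6},
        run={"steps": steps, "log_events": False, "record_interval": 50},
    )


def no_grazer_config(eta: int, delta: float) -> RunConfig:
    """A cell-free world for the inflow-decay equilibrium check."""
    return default_config().replace(
        ecology={"eta": eta, "delta": delta, "delta_detritus": delta / 4.0},
        evolution={"n_founders": 0},
        run={"log_events": False},
    )


def desk_sweep_spec(seed_base: int = 0, replicas: int = 2, steps: int = 5000) -> SweepSpec:
    """The coarse (eta, sigma) grid of the desk-scale phase diagram.

    Inflow spans starvation (eta = 1) to the rich regime (eta = 8);
    noise spans near-still water to strong stirring.
    """
    return SweepSpec(
        eta_values=[1, 3, 6, 8],
        sigma_values=[0.1, 0.3, 0.5, 0.7],
        replicas=replicas,
        steps=steps,
        base_config=default_config(),
        seed_base=seed_base,
    )
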