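"""World state: a struct-of-arrays store for cells and particles.

Bodies (cells and nutrient/detritus particles) live in one set of aligned
numpy arrays so the physics kernels can act on everything at once.  Ids
are assigned in strictly increasing order and removals preserve array
order, so the ``ids`` array is always sorted and id -> index lookups are
a binary search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig

__all__ = ["CELL", "PARTICLE", "Body", "RngStreams", "Counters", "SimulationState", "init_state"]

CELL = 0
PARTICLE = 1


@dataclass
class Body:
    """Scalar view of a single body, for the per-pair operations and tests."""

    id: int
    kind: int
    position: np.ndarray
    velocity: np.ndarray
    mass: float
    radius: float


class RngStreams:
    """Independent named random substreams derived from one root seed.

    Each consumer (physics noise, ecology, mutation, offspring placement)
    owns a counter-based Philox stream spawned from the root seed, so
    adding draws to one consumer never perturbs the others.
    """

    NAMES = ("physics", "ecology", "mutation", "placement")

    def __init__(self, seed: int):
        self.seed = int(seed)
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(self.NAMES))
        for name, child in zip(self.NAMES, children):
            setattr(self, name, np.random.Generator(np.random.Philox(child)))


@dataclass
class Counters:
    """Cumulative bookkeeping; together with the live arrays these close
    the particle budget: injected = consumed + degraded + present."""

    injected: int = 0
    injected_by_class: np.ndarray = None  # nutrients only
    consumed_by_class: np.ndarray = None  # includes the detritus class
    degraded_nutrients: int = 0
    degraded_detritus: int = 0
    detritus_spawned: int = 0
    births: int = 0
    deaths: int = 0
    mass_consumed: float = 0.0
    mass_maintenance: float = 0.0
    mass_death: float = 0.0

    @classmethod
    def zeros(cls, n_sources: int) -> "Counters":
        return cls(
            injected_by_class=np.zeros(n_sources, dtype=np.int64),
            consumed_by_class=np.zeros(n_sources + 1, dtype=np.int64),
        )


class SpringSet:
    """Cell-cell adhesion springs, stored as id pairs (a < b)."""

    def __init__(self):
        self.a = np.empty(0, dtype=np.int64)
        self.b = np.empty(0, dtype=np.int64)
        self._members: set[tuple[int, int]] = set()

    def __len__(self) -> int:
        return self.a.size

    def has(self, ia: int, ib: int) -> bool:
        key = (ia, ib) if ia < ib else (ib, ia)
        return key in self._members

    def add_pairs(self, a_ids: np.ndarray, b_ids: np.ndarray) -> None:
        if len(a_ids) == 0:
            return
        lo = np.minimum(a_ids, b_ids)
        hi = np.maximum(a_ids, b_ids)
        keep = []
        for i, key in enumerate(zip(lo.tolist(), hi.tolist())):
            if key not in self._members:
                self._members.add(key)
                keep.append(i)
        if keep:
            self.a = np.concatenate([self.a, lo[keep]])
            self.b = np.concatenate([self.b, hi[keep]])

    def remove_mask(self, mask: np.ndarray) -> None:
        if not mask.any():
            return
        for ia, ib in zip(self.a[mask].tolist(), self.b[mask].tolist()):
            self._members.discard((ia, ib))
        self.a = self.a[~mask]
        self.b = self.b[~mask]

    def drop_ids(self, dead_ids: np.ndarray) -> int:
        """Remove every spring touching any of ``dead_ids``; returns count."""
        if len(self) == 0 or len(dead_ids) == 0:
            return 0
        dead = set(int(i) for i in dead_ids)
        mask = np.fromiter(
            ((int(x) in dead) or (int(y) in dead) for x, y in zip(self.a, self.b)),
            dtype=bool,
            count=len(self),
        )
        n = int(mask.sum())
        self.remove_mask(mask)
        return n


class SimulationState:
    """Full world at one instant plus cumulative counters and RNG streams."""

    def __init__(self, config: RunConfig, seed: int):
        self.config = config
        self.n_sources = config.ecology.n_sources
        self.n_classes = config.ecology.n_classes
        self.step = 0
        self.next_id = 0
        self.rng = RngStreams(seed)
        self.counters = Counters.zeros(self.n_sources)
        self.springs = SpringSet()
        self.events: list[dict] = []
        self.log_events = config.run.log_events
        self.last_diag: dict = {}

        n = 0
        self.ids = np.empty(n, dtype=np.int64)
        self.kind = np.empty(n, dtype=np.int8)
        self.pos = np.empty((n, 3), dtype=np.float64)
        self.vel = np.empty((n, 3), dtype=np.float64)
        self.mass = np.empty(n, dtype=np.float64)
        self.radius = np.empty(n, dtype=np.float64)
        self.pclass = np.empty(n, dtype=np.int16)  # -1 for cells
        self.eff = np.empty((n, self.n_classes), dtype=np.float64)
        self.wall_adh = np.empty(n, dtype=np.float64)
        self.cell_adh = np.empty(n, dtype=np.float64)
        self.wall_attached = np.empty(n, dtype=bool)
        self.wall_anchor = np.empty((n, 3), dtype=np.float64)
        self.wall_id = np.empty(n, dtype=np.int8)

    # -- array plumbing ------------------------------------------------

    _ARRAYS = (
        "ids", "kind", "pos", "vel", "mass", "radius", "pclass", "eff",
        "wall_adh", "cell_adh", "wall_attached", "wall_anchor", "wall_id",
    )

    @property
    def n_bodies(self) -> int:
        return self.ids.size

    @property
    def cell_mask(self) -> np.ndarray:
        return self.kind == CELL

    @property
    def particle_mask(self) -> np.ndarray:
        return self.kind == PARTICLE

    @property
    def n_cells(self) -> int:
        return int(self.cell_mask.sum())

    def index_of(self, ids: np.ndarray) -> np.ndarray:
        """Map body ids to current array indices (ids array is sorted)."""
        idx = np.searchsorted(self.ids, ids)
        if np.any(idx >= self.ids.size) or np.any(self.ids[np.minimum(idx, self.ids.size - 1)] != ids):
            raise KeyError("dangling body id reference")
        return idx

    def append(self, **fields) -> np.ndarray:
        """Append new bodies; returns their assigned ids."""
        k = len(fields["kind"])
        new_ids = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k
        fields["ids"] = new_ids
        for name in self._ARRAYS:
            cur = getattr(self, name)
            add = np.asarray(fields[name], dtype=cur.dtype)
            setattr(self, name, np.concatenate([cur, add]))
        return new_ids

    def remove_indices(self, idx: np.ndarray) -> None:
        if len(idx) == 0:
            return
        keep = np.ones(self.n_bodies, dtype=bool)
        keep[idx] = False
        for name in self._ARRAYS:
            setattr(self, name, getattr(self, name)[keep])

    def body(self, i: int) -> Body:
        return Body(
            id=int(self.ids[i]),
            kind=int(self.kind[i]),
            position=self.pos[i].copy(),
            velocity=self.vel[i].copy(),
            mass=float(self.mass[i]),
            radius=float(self.radius[i]),
        )

    def record_event(self, kind: str, **data) -> None:
        if self.log_events:
            self.events.append({"step": self.step, "event": kind, **data})

    # -- checks --------------------------------------------------------

    def check_containment(self) -> None:
        """Every body center must sit strictly inside the open box."""
        L = self.config.physics.box_side
        p = self.pos
        ok = (
            (p[:, 0] > 0) & (p[:, 0] < L)
            & (p[:, 1] > 0) & (p[:, 1] < L)
            & (p[:, 2] > -L) & (p[:, 2] < 0)
        )
        if not ok.all():
            bad = int(self.ids[np.flatnonzero(~ok)[0]])
            raise RuntimeError(f"containment violation: body {bad} left the box at step {self.step}")


def init_state(config: RunConfig, seed: int) -> SimulationState:
    """Create the founding world: identical specialist cells resting on the floor.

    Founders all metabolise a single nutrient class with maximal
    efficiency (zero on every other class and on detritus) and carry the
    configured initial adhesion traits.
    """
    state = SimulationState(config, seed)
    ev = config.evolution
    L = config.physics.box_side
    n = ev.n_founders
    if n == 0:
        return state
    rng = state.rng.placement
    r = ev.cell_radius
    xy = rng.uniform(r, L - r, size=(n, 2))
    pos = np.column_stack([xy, np.full(n, -L + r)])
    eff = np.zeros((n, config.ecology.n_classes))
    eff[:, ev.founder_class] = 1.0
    state.append(
        kind=np.full(n, CELL, dtype=np.int8),
        pos=pos,
        vel=np.zeros((n, 3)),
        mass=np.full(n, ev.m0),
        radius=np.full(n, r),
        pclass=np.full(n, -1, dtype=np.int16),
        eff=eff,
        wall_adh=np.full(n, ev.founder_wall_adhesion),
        cell_adh=np.full(n, ev.founder_cell_adhesion),
        wall_attached=np.zeros(n, dtype=bool),
        wall_anchor=np.zeros((n, 3)),
        wall_id=np.full(n, -1, dtype=np.int8),
    )
    return state
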