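"""Observables: diet entropy, mean efficiency, per-step summaries, and the
four-phase classification of finished runs.

The degree of generalism of a cell is its normalized diet entropy
H = -sum_k p_k ln p_k / ln C, where p_k is the relative efficiency on
class k and C the number of resource classes (detritus included by
default).  H is 0 for a pure specialist and 1 for a uniform generalist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .config import MetricsParams, RunConfig
from .state import SimulationState

__all__ = [
    "PHASES",
    "StepRecord",
    "cell_entropy",
    "mean_efficiency",
    "population_summary",
    "detect_top_layer",
    "detritivore_stats",
    "classify_phase",
]

# Severity-ordered phase labels (ties in modal voting fall to the left).
PHASES = ("extinction", "monolayer", "multilayer", "EEN")


@dataclass
class StepRecord:
    """One row of the per-step time series.

    Means over an empty population are recorded as NaN ("absent"), never
    as zero.  ``mean_height`` uses the normalized vertical coordinate:
    top face at 0, floor at -1.
    """

    step: int
    n_cells: int
    n_particles_by_class: list[int]  # nutrient classes then detritus
    free_nutrients: int
    mean_entropy: float
    mean_efficiency: float
    mean_wall_adhesion: float
    mean_cell_adhesion: float
    mean_height: float
    height_span: float
    n_detritivores: int
    mean_detritivore_efficiency: float
    top_layer_occupied: bool
    n_springs: int = 0
    total_cell_mass: float = 0.0

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def cell_entropy(efficiencies: np.ndarray) -> float:
    """Normalized diet entropy of one efficiency vector, in [0, 1].

    Zero iff exactly one entry is nonzero; one iff uniform.  Invariant
    under permutation and positive rescaling (entries are renormalized
    to relative efficiencies first).  The zero vector is a domain error.
    """
    e = np.asarray(efficiencies, dtype=float)
    if (e < 0).any():
        raise ValueError("efficiencies must be non-negative")
    s = e.sum()
    if s <= 0:
        raise ValueError("entropy of an all-zero efficiency vector is undefined")
    p = e / s
    nz = p[p > 0]
    h = -(nz * np.log(nz)).sum()
    return float(h / math.log(e.size)) if e.size > 1 else 0.0


def _entropies(eff: np.ndarray) -> np.ndarray:
    """Row-wise normalized entropy for a matrix of efficiency vectors."""
    s = eff.sum(axis=1, keepdims=True)
    p = eff / s
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t.sum(axis=1) / math.log(eff.shape[1])


def mean_efficiency(efficiencies: np.ndarray) -> float:
    """Average efficiency over the sources actually used: sum / n_used.

    Under the sum-to-one normalization this is exactly 1 / n_used, so a
    specialist scores 1 and a uniform generalist 1 / C.
    """
    e = np.asarray(efficiencies, dtype=float)
    n_used = int((e > 0).sum())
    if n_used == 0:
        raise ValueError("mean efficiency of an all-zero vector is undefined")
    return float(e.sum() / n_used)


def detect_top_layer(state: SimulationState, mp: MetricsParams | None = None) -> bool:
    """Whether a persistent cell population occupies the top of the box.

    True iff the fraction of cells whose center lies within ``band_depth``
    of the top face exceeds ``coverage_threshold`` and their number
    reaches ``min_top_count``.  Deterministic given the state.
    """
    if mp is None:
        mp = state.config.metrics
    cmask = state.cell_mask
    n = int(cmask.sum())
    if n == 0:
        return False
    in_band = int((state.pos[cmask, 2] >= -mp.band_depth).sum())
    return (in_band / n > mp.coverage_threshold) and (in_band >= mp.min_top_count)


def detritivore_stats(state: SimulationState, eps: float | None = None) -> tuple[int, float]:
    """Count of cells with detritus efficiency above ``eps`` and their mean
    detritus efficiency (NaN when there are none)."""
    if eps is None:
        eps = state.config.metrics.detritivore_eps
    if eps < 0:
        raise ValueError("eps must be non-negative")
    cmask = state.cell_mask
    det = state.eff[cmask, -1]
    sel = det > eps
    n = int(sel.sum())
    return n, (float(det[sel].mean()) if n else math.nan)


def population_summary(state: SimulationState) -> StepRecord:
    """Compute every StepRecord field from the current state."""
    cfg = state.config
    cmask = state.cell_mask
    n_cells = int(cmask.sum())
    counts = [
        int((state.pclass == k).sum()) for k in range(cfg.ecology.n_classes)
    ]
    free_nutrients = int(sum(counts[: cfg.ecology.n_sources]))
    if n_cells:
        eff = state.eff[cmask]
        entropies = _entropies(eff)
        n_used = (eff > 0).sum(axis=1)
        z = state.pos[cmask, 2] / cfg.physics.box_side
        mean_h = float(z.mean())
        span = float(z.max() - z.min())
        mean_H = float(entropies.mean())
        mean_E = float((eff.sum(axis=1) / n_used).mean())
        mean_wa = float(state.wall_adh[cmask].mean())
        mean_ca = float(state.cell_adh[cmask].mean())
        total_mass = float(state.mass[cmask].sum())
    else:
        mean_h = span = mean_H = mean_E = mean_wa = mean_ca = math.nan
        span = 0.0
        total_mass = 0.0
    n_det, det_mean = detritivore_stats(state)
    return StepRecord(
        step=state.step,
        n_cells=n_cells,
        n_particles_by_class=counts,
        free_nutrients=free_nutrients,
        mean_entropy=mean_H,
        mean_efficiency=mean_E,
        mean_wall_adhesion=mean_wa,
        mean_cell_adhesion=mean_ca,
        mean_height=mean_h,
        height_span=span,
        n_detritivores=n_det,
        mean_detritivore_efficiency=det_mean,
        top_layer_occupied=detect_top_layer(state),
        n_springs=len(state.springs),
        total_cell_mass=total_mass,
    )


def classify_phase(records: list[StepRecord], config: RunConfig) -> str:
    """Assign exactly one of the four phase labels to a finished run.

    extinction: no cells at the end.  EEN: the top-layer detector fires
    in at least half of the final-window records.  multilayer: the
    occupied vertical span of the population exceeds ``layer_k`` cell
    diameters (window mean).  monolayer otherwise.
    """
    if not records:
        raise ValueError("cannot classify an empty trajectory")
    mp = config.metrics
    window = records[-min(mp.phase_window, len(records)):]
    final = records[-1]
    if final.n_cells == 0:
        return "extinction"
    top_frac = sum(1 for r in window if r.top_layer_occupied) / len(window)
    if top_frac >= 0.5:
        return "EEN"
    spans = [r.height_span for r in window if r.n_cells > 0]
    mean_span = sum(spans) / len(spans) if spans else 0.0
    layer_height = 2.0 * config.evolution.cell_radius / config.physics.box_side
    if mean_span > mp.layer_k * layer_height:
        return "multilayer"
    return "monolayer"
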