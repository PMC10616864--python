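"""Synthetic longitudinal BOLD cohorts with a planted, time-shifting hub
structure.

The generator emulates the study conditions of an awake-mouse longitudinal
resting-state experiment: 244 atlas regions (122 per hemisphere), 600
volumes at TR = 1 s, 10 subjects scanned at pre-injury and 1, 3, 7 and 14
weeks post-injury. Region signals are drawn from a stationary multivariate
Gaussian process: innovations are shaped by the Cholesky factor of a
per-timepoint target correlation matrix and passed through an AR(1)
recursion (shared temporal autocorrelation), then white measurement noise
is added. Pearson correlations of the emitted series therefore converge to
the (noise-attenuated) target as the series lengthens. Hemodynamics,
motion and physiological noise are deliberately not modeled.

The planted structure drives the qualitative trajectories the analysis is
meant to recover: a transient global connectivity burst at 1 wpi (strength
rises, then falls below baseline by 14 wpi), a "motor cortex" hub set
whose correlation to the rest of the network declines over time, and a
"subcortical" hub set whose correlation rises — the cortical-to-subcortical
hub shift. Hub rows are elevated toward all nodes (entry(i, j) = max of
the background level and the hub levels of i and j), because degree
centrality counts edges to the whole network; within each hub block the
nodes are additionally coupled at ``within_hub_corr``, as homotopic
cortical and striatal regions are in vivo. Targets are projected to the
nearest positive semi-definite correlation matrix by eigenvalue clipping
and rescaling; the projection may not move any entry by more than
``psd_tolerance``.

Determinism: the scenario seed fully determines every emitted value.
Subject x timepoint streams are derived with
``numpy.random.SeedSequence(scenario.seed, spawn_key=(subject_index,
timepoint_index))`` — a documented, platform-stable hash.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .errors import ScenarioError
from .types import BOLDSession, DEFAULT_TIMEPOINTS, RegionAtlas

log = logging.getLogger(__name__)

#: hub-to-network correlation schedules over (pre, 1, 3, 7, 14 wpi).
#: The levels are bounded by the PSD geometry: with bulk equicorrelation b
#: and hub nodes mutually correlated at w, the block-mean eigenmode caps
#: hub-to-network correlation near sqrt((1+(m-1)w)(1+(k-1)b)/(m k)); the
#: defaults sit just inside that cone so eigenvalue repair is negligible.
MOTOR_SCHEDULE = (0.28, 0.25, 0.22, 0.13, 0.07)
SUBCORTICAL_SCHEDULE = (0.14, 0.16, 0.19, 0.22, 0.25)
WITHIN_HUB_CORR = 0.6

#: background connectivity over time: the matrix-wide picture is a transient
#: rise after injury (the 1 wpi burst on top of the 0.12/0.13 level) followed
#: by a global decline below baseline in the chronic phase
BACKGROUND_SCHEDULE = (0.12, 0.12, 0.13, 0.11, 0.095)


@dataclass(frozen=True)
class Scenario:
    """Full description of one synthetic cohort."""

    n_nodes: int = 244
    n_subjects: int = 10
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_volumes: int = 600
    sampling_interval: float = 1.0
    motor_hub_ids: tuple[int, ...] = ()
    subcortical_hub_ids: tuple[int, ...] = ()
    motor_hub_corr: tuple[float, ...] = MOTOR_SCHEDULE
    subcortical_hub_corr: tuple[float, ...] = SUBCORTICAL_SCHEDULE
    within_hub_corr: float = WITHIN_HUB_CORR
    background_corr: float = 0.12
    background_schedule: tuple[float, ...] | None = BACKGROUND_SCHEDULE
    global_burst: float = 0.08
    burst_timepoint: str = "1wpi"
    ar_coeff: float = 0.3
    noise_sd: float = 0.3
    psd_tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.n_subjects < 1 or self.n_volumes < 3:
            raise ScenarioError("degenerate scenario dimensions")
        motor, sub = set(self.motor_hub_ids), set(self.subcortical_hub_ids)
        if motor & sub:
            raise ScenarioError("motor and subcortical hub sets must be disjoint")
        for i in motor | sub:
            if not 0 <= i < self.n_nodes:
                raise ScenarioError(f"hub id {i} outside 0..{self.n_nodes - 1}")
        nt = len(self.timepoints)
        if motor and len(self.motor_hub_corr) != nt:
            raise ScenarioError("motor_hub_corr length must match timepoints")
        if sub and len(self.subcortical_hub_corr) != nt:
            raise ScenarioError("subcortical_hub_corr length must match timepoints")
        if self.background_schedule is not None and \
                len(self.background_schedule) != nt:
            raise ScenarioError("background_schedule length must match timepoints")
        bg_levels = self.background_schedule or (self.background_corr,)
        levels = (*bg_levels, max(bg_levels) + self.global_burst,
                  self.within_hub_corr,
                  *self.motor_hub_corr, *self.subcortical_hub_corr)
        if any(not -1 < c < 1 for c in levels):
            raise ScenarioError("all target correlation levels must lie in (-1, 1)")
        if not 0 <= abs(self.ar_coeff) < 1:
            raise ScenarioError("|ar_coeff| must be < 1")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be >= 0")


def default_scenario(seed: int = 0) -> Scenario:
    """Full study-scale scenario: 244 nodes x 600 volumes, 10 subjects."""
    return Scenario(
        motor_hub_ids=tuple(range(0, 12)),
        subcortical_hub_ids=tuple(range(12, 24)),
        seed=seed,
    )


def desk_scenario(seed: int = 0, n_nodes: int = 60, n_volumes: int = 300) -> Scenario:
    """Scaled-down profile (60 nodes x 300 volumes) for fast iteration."""
    n_hubs = max(2, n_nodes // 10)
    return Scenario(
        n_nodes=n_nodes, n_volumes=n_volumes,
        motor_hub_ids=tuple(range(0, n_hubs)),
        subcortical_hub_ids=tuple(range(n_hubs, 2 * n_hubs)),
        seed=seed,
    )


def null_scenario(seed: int = 0, n_nodes: int = 60, n_volumes: int = 300,
                  timepoints: tuple[str, ...] = ("pre", "14wpi")) -> Scenario:
    """No planted change: homogeneous background at every timepoint."""
    return Scenario(
        n_nodes=n_nodes, n_volumes=n_volumes, timepoints=timepoints,
        motor_hub_ids=(), subcortical_hub_ids=(),
        global_burst=0.0, background_schedule=None, seed=seed,
    )


# ---------------------------------------------------------------- targets

def nearest_psd_correlation(m: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to a PSD correlation matrix.

    Eigenvalues are clipped at ``min_eig`` and the result is rescaled to a
    unit diagonal.
    """
    sym = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= 0:
        return sym
    clipped = np.clip(vals, min_eig, None)
    b = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(b))
    out = b / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def build_target_matrix(scenario: Scenario, timepoint: str) -> np.ndarray:
    """Planted correlation target for one timepoint (PSD, unit diagonal)."""
    if timepoint not in scenario.timepoints:
        raise ScenarioError(f"timepoint {timepoint!r} not in scenario")
    ti = scenario.timepoints.index(timepoint)
    n = scenario.n_nodes
    if scenario.background_schedule is not None:
        bg = scenario.background_schedule[ti]
    else:
        bg = scenario.background_corr
    if timepoint == scenario.burst_timepoint:
        bg = bg + scenario.global_burst
    node_level = np.full(n, -np.inf)
    if scenario.motor_hub_ids:
        node_level[list(scenario.motor_hub_ids)] = scenario.motor_hub_corr[ti]
    if scenario.subcortical_hub_ids:
        node_level[list(scenario.subcortical_hub_ids)] = np.maximum(
            node_level[list(scenario.subcortical_hub_ids)],
            scenario.subcortical_hub_corr[ti],
        )
    target = np.maximum(bg, np.maximum(node_level[:, None], node_level[None, :]))
    # hub nodes are mutually coupled well above their hub-to-network level
    # (left/right homotopic cortex, striatal blocks); this is also what makes
    # high hub-to-network correlations PSD-feasible over the background
    for ids in (scenario.motor_hub_ids, scenario.subcortical_hub_ids):
        if ids:
            block = np.ix_(list(ids), list(ids))
            target[block] = np.maximum(target[block], scenario.within_hub_corr)
    np.fill_diagonal(target, 1.0)
    repaired = nearest_psd_correlation(target)
    off = ~np.eye(n, dtype=bool)
    shift = float(np.abs(repaired - target)[off].max())
    if shift > 0:
        log.info("PSD repair at %s moved entries by up to %.2e", timepoint, shift)
    if shift > scenario.psd_tolerance:
        raise ScenarioError(
            f"PSD repair at {timepoint} moved an entry by {shift:.3f} "
            f"(> tolerance {scenario.psd_tolerance})"
        )
    return repaired


# ---------------------------------------------------------------- simulation

def _cholesky(target: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(target)
    except np.linalg.LinAlgError:
        vals = np.linalg.eigvalsh(target)
        if vals.min() < -1e-10:
            raise ScenarioError(f"target is not PSD (min eigenvalue {vals.min():.2e})")
        return np.linalg.cholesky(target + 1e-10 * np.eye(target.shape[0]))


def simulate_session(
    target: np.ndarray,
    scenario: Scenario,
    subject_seed: int | np.random.SeedSequence,
    *,
    subject_id: str = "",
    timepoint: str = "",
    chol: np.ndarray | None = None,
) -> BOLDSession:
    """Draw one session from the stationary AR(1) Gaussian process.

    ``subject_seed`` may be an integer or a SeedSequence; identical seeds
    yield bit-identical sessions.
    """
    n, t_len = scenario.n_nodes, scenario.n_volumes
    if target.shape != (n, n):
        raise ScenarioError(f"target shape {target.shape} != ({n}, {n})")
    L = chol if chol is not None else _cholesky(target)
    rng = np.random.default_rng(subject_seed)
    phi = scenario.ar_coeff
    burn = 100 if phi != 0 else 0
    innovations = rng.standard_normal((burn + t_len, n)) @ L.T
    if phi != 0:
        x = sp_signal.lfilter([np.sqrt(1 - phi**2)], [1.0, -phi],
                              innovations, axis=0)[burn:]
    else:
        x = innovations
    if scenario.noise_sd > 0:
        x = x + scenario.noise_sd * rng.standard_normal(x.shape)
    return BOLDSession(subject_id=subject_id, timepoint=timepoint,
                       signals=x.T, sampling_interval=scenario.sampling_interval)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, sufficient to score recovery."""

    targets: dict[str, np.ndarray]          # timepoint -> repaired target
    motor_hub_ids: tuple[int, ...]
    subcortical_hub_ids: tuple[int, ...]
    strength_direction: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "motor_hub_ids": list(self.motor_hub_ids),
            "subcortical_hub_ids": list(self.subcortical_hub_ids),
            "strength_direction": self.strength_direction,
            "targets": {tp: m.tolist() for tp, m in self.targets.items()},
        }
        path = Path(path)
        path.write_text(json.dumps(payload, sort_keys=True))
        return path


def simulate_cohort(scenario: Scenario) -> tuple[list[BOLDSession], GroundTruth]:
    """All n_subjects x n_timepoints sessions plus the planted ground truth."""
    targets = {tp: build_target_matrix(scenario, tp) for tp in scenario.timepoints}
    chols = {tp: _cholesky(m) for tp, m in targets.items()}
    sessions: list[BOLDSession] = []
    for s in range(scenario.n_subjects):
        sid = f"sub-{s:02d}"
        for t, tp in enumerate(scenario.timepoints):
            ss = np.random.SeedSequence(scenario.seed, spawn_key=(s, t))
            sessions.append(simulate_session(
                targets[tp], scenario, ss, subject_id=sid, timepoint=tp,
                chol=chols[tp],
            ))
    # expected strength direction relative to the pre-injury target
    direction: dict[str, str] = {}
    if "pre" in targets:
        off = ~np.eye(scenario.n_nodes, dtype=bool)
        pre_sum = targets["pre"][off].sum()
        for tp, m in targets.items():
            if tp == "pre":
                continue
            diff = m[off].sum() - pre_sum
            direction[tp] = "up" if diff > 0 else ("down" if diff < 0 else "flat")
    truth = GroundTruth(
        targets=targets,
        motor_hub_ids=scenario.motor_hub_ids,
        subcortical_hub_ids=scenario.subcortical_hub_ids,
        strength_direction=direction,
    )
    return sessions, truth


# ---------------------------------------------------------------- atlas

def synthetic_atlas(n_nodes: int = 244, scenario: Scenario | None = None) -> RegionAtlas:
    """Deterministic atlas: even ids left, odd ids right (122/122 at n=244).

    When a scenario is given, its hub nodes get recognizable names (M1/M2
    for the motor seeds, CPu/cc-ec style names for the subcortical set).
    """
    rng = np.random.default_rng(987654321 + n_nodes)
    coords = np.column_stack([
        rng.uniform(-5.0, 5.0, n_nodes),    # medio-lateral, mm
        rng.uniform(-8.0, 4.0, n_nodes),    # rostro-caudal
        rng.uniform(-6.0, 1.0, n_nodes),    # dorso-ventral
    ])
    hemis = tuple("left" if i % 2 == 0 else "right" for i in range(n_nodes))
    names = [f"region_{i:03d}_{'L' if i % 2 == 0 else 'R'}" for i in range(n_nodes)]
    if scenario is not None:
        motor_labels = ["M1", "M2", "S1", "S2", "PMC", "SMA"]
        for j, i in enumerate(scenario.motor_hub_ids):
            base = motor_labels[j // 2 % len(motor_labels)]
            names[i] = f"{base}_{'L' if i % 2 == 0 else 'R'}"
        sub_labels = ["CPu", "cc-ec", "Tu", "GP", "Thal", "STN"]
        for j, i in enumerate(scenario.subcortical_hub_ids):
            base = sub_labels[j // 2 % len(sub_labels)]
            names[i] = f"{base}_{'L' if i % 2 == 0 else 'R'}"
    return RegionAtlas(node_ids=np.arange(n_nodes), names=tuple(names),
                       hemispheres=hemis, coords=coords)


def m1_seed_ids(scenario: Scenario) -> tuple[int, int]:
    """Left and right primary-motor seed nodes of a scenario's atlas."""
    if len(scenario.motor_hub_ids) < 2:
        raise ScenarioError("scenario has no M1 seed pair")
    return scenario.motor_hub_ids[0], scenario.motor_hub_ids[1]
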