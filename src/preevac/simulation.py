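"""Multi-zone fire-scene simulation of the pre-evacuation phase.

A scene is a set of rectangular zones connected by a node graph (origins and
exit destinations), with a fire source in one zone and a circular smoke front
spreading at constant speed (0.3 m/s by default).  Agents are placed at
random positions inside their origin zones according to a demand split and
then, period by period, evaluate their risk context and draw an escape
decision from the probit hazard.  Agents do not move before deciding — this
is the pre-evacuation phase only; locomotion to exits is out of scope.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import Point, box

from .model import CoefficientSet, default_coefficients, hazard_probability
from .population import (
    ATTR_FIELDS,
    AttributeDistributions,
    Pedestrian,
    default_distributions,
    sample_population,
)
from .risk import RiskContext, context_at, dfd_level, rnc_level, standardize_level

__all__ = [
    "Zone",
    "FireSource",
    "Scene",
    "SimulationConfig",
    "SimState",
    "build_scene",
    "default_scene",
    "default_layout",
    "scene_to_json",
    "largest_remainder_counts",
    "place_agents",
    "smoke_radius",
    "step",
    "run",
    "period_hazards",
    "summarize",
    "render_snapshot",
]

logger = logging.getLogger(__name__)

_OVERLAP_TOL = 1e-9


@dataclass(frozen=True)
class Zone:
    """Axis-aligned rectangular region with an integer identifier."""

    id: int
    rect: tuple[float, float, float, float]  # (x0, y0, x1, y1)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"zone {self.id}: rectangle {self.rect} has no area")

    @property
    def polygon(self):
        return box(*self.rect)

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)


@dataclass(frozen=True)
class FireSource:
    """Fire location (planar metres), its zone, and ordinal intensity level."""

    point: tuple[float, float]
    zone: int
    level: int = 4

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4):
            raise ValueError(f"fire level must be in 1..4, got {self.level!r}")


@dataclass(frozen=True)
class Scene:
    """Validated multi-zone layout with connection graph and fire event."""

    zones: tuple[Zone, ...]
    nodes: Mapping[int, tuple[float, float]]
    edges: tuple[tuple[int, int], ...]
    origins: tuple[int, ...]
    destinations: tuple[int, ...]
    fire: FireSource
    smoke_speed: float = 0.3

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs0, ys0, xs1, ys1 = zip(*(z.rect for z in self.zones))
        return (min(xs0), min(ys0), max(xs1), max(ys1))

    def zone_by_id(self, zone_id: int) -> Zone:
        for z in self.zones:
            if z.id == zone_id:
                return z
        raise KeyError(f"no zone with id {zone_id}")


def default_layout() -> dict:
    """Three-hall 100 m x 60 m layout: origins 1-3, exits at nodes 4 and 5.

    Dimensions are package defaults (the reference layout's metric sizes are
    not published); the topology — two front halls and a large rear hall,
    exits on the left and right, fire in zone 3 — is the documented scene.
    """
    return {
        "zones": [
            {"id": 1, "rect": [0.0, 0.0, 50.0, 30.0]},
            {"id": 2, "rect": [50.0, 0.0, 100.0, 30.0]},
            {"id": 3, "rect": [0.0, 30.0, 100.0, 60.0]},
        ],
        "nodes": {
            "1": [25.0, 15.0],
            "2": [75.0, 15.0],
            "3": [50.0, 45.0],
            "4": [0.0, 15.0],
            "5": [100.0, 15.0],
        },
        "edges": [[1, 2], [1, 3], [2, 3], [1, 4], [2, 5]],
        "origins": [1, 2, 3],
        "destinations": [4, 5],
        "fire": {"point": [50.0, 50.0], "zone": 3, "level": 4},
        "smoke_speed": 0.3,
    }


def build_scene(layout: Mapping | None = None) -> Scene:
    """Validate a layout description and return a :class:`Scene`.

    Checks: zones have positive area and do not overlap, the fire source
    lies inside its declared zone, and every origin reaches at least one
    destination through the connection graph.
    """
    if layout is None:
        layout = default_layout()
    zones = tuple(Zone(id=int(z["id"]), rect=tuple(map(float, z["rect"])))
                  for z in layout["zones"])
    ids = [z.id for z in zones]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate zone ids {ids}")
    for i, a in enumerate(zones):
        for b in zones[i + 1:]:
            if a.polygon.intersection(b.polygon).area > _OVERLAP_TOL:
                raise ValueError(f"zones {a.id} and {b.id} overlap")

    nodes = {int(k): tuple(map(float, v)) for k, v in layout["nodes"].items()}
    edges = tuple((int(a), int(b)) for a, b in layout["edges"])
    origins = tuple(int(o) for o in layout["origins"])
    destinations = tuple(int(d) for d in layout["destinations"])
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(edges)
    for o in origins:
        if not any(nx.has_path(graph, o, d) for d in destinations):
            raise ValueError(f"origin {o} is disconnected from every destination")

    f = layout["fire"]
    fire = FireSource(point=tuple(map(float, f["point"])), zone=int(f["zone"]),
                      level=int(f.get("level", 4)))
    scene = Scene(zones=zones, nodes=nodes, edges=edges, origins=origins,
                  destinations=destinations, fire=fire,
                  smoke_speed=float(layout.get("smoke_speed", 0.3)))
    if not scene.zone_by_id(fire.zone).polygon.covers(Point(*fire.point)):
        raise ValueError(f"fire source {fire.point} lies outside zone {fire.zone}")
    if scene.smoke_speed <= 0:
        raise ValueError(f"smoke speed must be > 0, got {scene.smoke_speed}")
    return scene


def default_scene() -> Scene:
    return build_scene(default_layout())


def scene_to_json(scene: Scene, path=None) -> str:
    payload = {
        "zones": [{"id": z.id, "rect": list(z.rect)} for z in scene.zones],
        "nodes": {str(k): list(v) for k, v in scene.nodes.items()},
        "edges": [list(e) for e in scene.edges],
        "origins": list(scene.origins),
        "destinations": list(scene.destinations),
        "fire": {"point": list(scene.fire.point), "zone": scene.fire.zone,
                 "level": scene.fire.level},
        "smoke_speed": scene.smoke_speed,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


@dataclass
class SimulationConfig:
    """Reproducible simulation run description.

    ``demand_split`` follows the published escape-demand distribution over
    the three origins (14.3 % / 28.6 % / 57.1 %); ``dt`` is the decision
    period in seconds and ``reporting_interval`` only controls summary
    granularity.  ``fixed_context`` pins every agent's risk context to one
    triple (used for simulator-versus-analytic equivalence checks);
    ``freeze_context`` evaluates each agent's context once at the first
    period and reuses it.
    """

    n_agents: int
    demand_split: tuple[float, ...] = (0.143, 0.286, 0.571)
    dt: float = 1.0
    horizon: int = 300
    seed: int | None = None
    reporting_interval: float = 36.0
    coeffs: CoefficientSet | None = None
    distributions: AttributeDistributions | None = None
    neighbor_radius: float = 10.0
    freeze_context: bool = False
    fixed_context: RiskContext | None = None
    awareness_delay: bool = False
    continuous_context: bool = False
    invert_fire_scale: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError(f"n_agents must be >= 1, got {self.n_agents}")
        if abs(sum(self.demand_split) - 1.0) > 1e-9:
            raise ValueError(f"demand split must sum to 1, got {self.demand_split}")
        if any(p < 0 for p in self.demand_split):
            raise ValueError("demand split proportions must be non-negative")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.horizon < 0:
            raise ValueError(f"horizon must be >= 0, got {self.horizon}")
        if self.coeffs is None:
            self.coeffs = default_coefficients()


@dataclass
class SimState:
    """Mutable per-run state: positions, wait/escaped status, clock."""

    agents: list[Pedestrian]
    positions: np.ndarray              # (n, 2) planar metres, static
    escaped: np.ndarray                # bool per agent; absorbing
    escape_period: np.ndarray          # int per agent; -1 while waiting
    clock: float = 0.0
    period: int = 0
    context_cache: np.ndarray | None = None  # (n,) cached linear predictors

    @property
    def n_waiting(self) -> int:
        return int((~self.escaped).sum())


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer allocation of ``n`` over proportions by largest remainder."""
    p = np.asarray(proportions, dtype=float)
    raw = n * p
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def place_agents(
    scene: Scene,
    config: SimulationConfig,
    population: Sequence[Pedestrian] | None = None,
    rng: np.random.Generator | None = None,
) -> SimState:
    """Place agents uniformly inside their origin zones per the demand split.

    Counts per origin follow largest-remainder rounding of the split; with a
    fixed seed both attribute draws and positions are reproducible.
    """
    if len(config.demand_split) != len(scene.origins):
        raise ValueError(
            f"demand split has {len(config.demand_split)} entries for "
            f"{len(scene.origins)} origins"
        )
    n_positive = sum(1 for p in config.demand_split if p > 0)
    if config.n_agents < n_positive:
        raise ValueError(
            f"n_agents={config.n_agents} is fewer than the {n_positive} "
            "origins with positive demand"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if population is None:
        dist = config.distributions or default_distributions(config.n_agents)
        dist = replace(dist, n=config.n_agents)
        population = sample_population(dist, rng=rng)
    if len(population) != config.n_agents:
        raise ValueError("population size does not match n_agents")

    counts = largest_remainder_counts(config.n_agents, config.demand_split)
    positions = np.empty((config.n_agents, 2))
    start = 0
    for origin, count in zip(scene.origins, counts):
        zone = scene.zone_by_id(origin)
        x0, y0, x1, y1 = zone.rect
        positions[start:start + count, 0] = rng.uniform(x0, x1, size=count)
        positions[start:start + count, 1] = rng.uniform(y0, y1, size=count)
        for ped in population[start:start + count]:
            ped.origin_zone = origin
            ped.position = None  # set below from the positions array
        start += count
    for i, ped in enumerate(population):
        ped.position = (float(positions[i, 0]), float(positions[i, 1]))

    return SimState(
        agents=list(population),
        positions=positions,
        escaped=np.zeros(config.n_agents, dtype=bool),
        escape_period=np.full(config.n_agents, -1, dtype=int),
    )


def smoke_radius(t: float, scene: Scene) -> float:
    """Radius (m) of the circular smoke front ``smoke_speed * t`` at time ``t`` s."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return scene.smoke_speed * float(t)


def _static_terms(state: SimState, scene: Scene, config: SimulationConfig):
    """Per-agent linear-predictor parts that never change: attributes, RCS, DFD."""
    coeffs = config.coeffs
    coded = pd.DataFrame([a.coded() for a in state.agents])
    attr = np.zeros(len(state.agents))
    for name, c in coeffs.attr_coeffs.items():
        attr += c * coded[name].to_numpy(float)
    fire = np.asarray(scene.fire.point)
    dist = np.hypot(*(state.positions - fire).T)
    rcs = standardize_level(scene.fire.level, invert=config.invert_fire_scale)
    if config.continuous_context:
        dfd = np.clip(1.0 - dist / 80.0, 0.0, 1.0)
    else:
        dfd = np.array([dfd_level(d).scale for d in dist])
    static = (coeffs.const + attr
              + coeffs.context_coeffs.get("rcs", 0.0) * rcs
              + coeffs.context_coeffs.get("dfd", 0.0) * dfd)
    return static, dist


def _reacting_fraction(state: SimState, radius: float) -> np.ndarray:
    """Fraction of already-reacting agents within ``radius`` of each agent."""
    d = cdist(state.positions, state.positions)
    neighbor = (d <= radius) & ~np.eye(len(d), dtype=bool)
    counts = neighbor.sum(axis=1)
    reacting = neighbor @ state.escaped.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, reacting / np.maximum(counts, 1), 0.0)
    return frac


def _agent_linear_predictors(state: SimState, scene: Scene, config: SimulationConfig) -> np.ndarray:
    coeffs = config.coeffs
    if config.fixed_context is not None:
        ctx = config.fixed_context
        coded = pd.DataFrame([a.coded() for a in state.agents])
        attr = np.zeros(len(state.agents))
        for name, c in coeffs.attr_coeffs.items():
            attr += c * coded[name].to_numpy(float)
        lp = (coeffs.const + attr
              + coeffs.context_coeffs.get("rcs", 0.0) * ctx.rcs
              + coeffs.context_coeffs.get("dfd", 0.0) * ctx.dfd
              + coeffs.context_coeffs.get("rnc", 0.0) * ctx.rnc)
        return np.broadcast_to(lp, (len(state.agents),)).astype(float)
    static, _ = _static_terms(state, scene, config)
    frac = _reacting_fraction(state, config.neighbor_radius)
    if config.continuous_context:
        rnc = frac
    else:
        rnc = np.array([rnc_level(f).scale for f in frac])
    return static + coeffs.context_coeffs.get("rnc", 0.0) * rnc


def _aware(state: SimState, scene: Scene, config: SimulationConfig) -> np.ndarray:
    """Awareness gate: with the delay enabled, agents start evaluating once the
    smoke front has entered their zone."""
    if not config.awareness_delay:
        return np.ones(len(state.agents), dtype=bool)
    radius = smoke_radius(state.clock + config.dt, scene)
    fire_pt = Point(*scene.fire.point)
    zone_reached = {
        z.id: fire_pt.distance(z.polygon) <= radius for z in scene.zones
    }
    return np.array([zone_reached[a.origin_zone] for a in state.agents])


def step(
    state: SimState,
    scene: Scene,
    coeffs: CoefficientSet,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> SimState:
    """Advance one decision period in place.

    Every waiting (and aware) agent re-evaluates its risk context, computes
    the probit hazard, and draws a Bernoulli escape decision; escape is
    absorbing.  The natural-response rate enters the first period only — it
    models the one-shot spontaneous-response fraction, not a per-second
    floor.  The clock advances by ``dt`` regardless of outcomes.
    """
    if config is None:
        config = SimulationConfig(n_agents=len(state.agents), coeffs=coeffs, seed=0)
    period = state.period + 1
    if config.freeze_context:
        if state.context_cache is None:
            state.context_cache = _agent_linear_predictors(state, scene, config)
        lp = state.context_cache
    else:
        lp = _agent_linear_predictors(state, scene, config)
    p = hazard_probability(lp, coeffs, include_natural=(period == 1))
    draws = rng.random(len(state.agents))
    newly = ~state.escaped & _aware(state, scene, config) & (draws < p)
    state.escaped |= newly
    state.escape_period[newly] = period
    state.period = period
    state.clock += config.dt
    return state


def period_hazards(ped: Pedestrian, scene: Scene, config: SimulationConfig,
                   n_periods: int, reacting_fraction: float = 0.0) -> np.ndarray:
    """Analytic per-period hazard sequence one agent faces under a frozen context.

    Mirrors the simulator's decision rule — natural response at the first
    period, probit-only afterwards — and is the reference for
    simulator-versus-first-passage equivalence checks.
    """
    coeffs = config.coeffs
    if config.fixed_context is not None:
        ctx = config.fixed_context
    else:
        ctx = context_at(ped, scene, 1, reacting_fraction=reacting_fraction,
                         continuous=config.continuous_context,
                         invert_fire_scale=config.invert_fire_scale)
    lp = coeffs.const
    coded = ped.coded()
    for name, c in coeffs.attr_coeffs.items():
        lp += c * coded[name]
    for name, c in coeffs.context_coeffs.items():
        lp += c * ctx.as_dict()[name]
    return np.array([
        float(hazard_probability(lp, coeffs, include_natural=(t == 1)))
        for t in range(1, n_periods + 1)
    ])


def run(scene: Scene, config: SimulationConfig) -> pd.DataFrame:
    """Run the full pre-evacuation experiment and return the event table.

    One row per agent: origin zone, position, coded attributes, ``response``
    (1 = escaped within the horizon), ``period`` (escape period, or the
    horizon for censored agents) and ``escape_time`` in seconds.
    Deterministic under the config seed: population sampling, placement and
    decision draws use independent named substreams of it.
    """
    ss = np.random.SeedSequence(config.seed)
    s_pop, s_place, s_sim = ss.spawn(3)
    dist = config.distributions or default_distributions(config.n_agents)
    dist = replace(dist, n=config.n_agents)
    population = sample_population(dist, rng=np.random.default_rng(s_pop))
    state = place_agents(scene, config, population=population,
                         rng=np.random.default_rng(s_place))
    rng = np.random.default_rng(s_sim)
    logger.info("simulation: %d agents, horizon %d periods (dt=%gs)",
                config.n_agents, config.horizon, config.dt)
    for _ in range(config.horizon):
        step(state, scene, config.coeffs, rng, config=config)
        if state.n_waiting == 0:
            break

    coded = pd.DataFrame([a.coded() for a in state.agents])
    escaped = state.escaped
    return pd.DataFrame({
        "agent": [a.id for a in state.agents],
        "origin": [a.origin_zone for a in state.agents],
        "x": state.positions[:, 0],
        "y": state.positions[:, 1],
        **{f: coded[f].to_numpy() for f in ATTR_FIELDS},
        "response": escaped.astype(int),
        "period": np.where(escaped, state.escape_period, config.horizon),
        "escape_time": np.where(escaped, state.escape_period * config.dt, np.nan),
    })


def summarize(events: pd.DataFrame, window: float, *, dt: float = 1.0,
              reporting_interval: float = 36.0) -> dict:
    """Response-rate summary of an event table.

    Reports the fraction escaped within ``window`` seconds, cumulative
    escaped / still-waiting counts at each reporting interval, and the
    spontaneous-response fraction (escapes in the first decision period).
    """
    if len(events) == 0:
        raise ValueError("event table is empty")
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    n = len(events)
    esc = events["response"] == 1
    times = events.loc[esc, "escape_time"]
    horizon_s = float(events["period"].max() * dt)
    marks = np.arange(reporting_interval, horizon_s + reporting_interval,
                      reporting_interval)
    intervals = [
        {"t": float(m),
         "escaped": int((times <= m).sum()),
         "waiting": int(n - (times <= m).sum())}
        for m in marks
    ]
    return {
        "n_agents": n,
        "escaped_total": int(esc.sum()),
        "censored": int(n - esc.sum()),
        "window_s": float(window),
        "fraction_within_window": float((times <= window).sum() / n),
        "spontaneous_fraction": float(((events["response"] == 1)
                                       & (events["period"] == 1)).mean()),
        "intervals": intervals,
    }


def render_snapshot(scene: Scene, state: SimState, path, t: float | None = None) -> None:
    """Plot zone outlines, agent status and the smoke front to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for z in scene.zones:
        x0, y0, x1, y1 = z.rect
        ax.add_patch(plt.Rectangle((x0, y0), x1 - x0, y1 - y0,
                                   fill=False, edgecolor="black"))
        ax.annotate(str(z.id), ((x0 + x1) / 2, (y0 + y1) / 2), color="grey")
    waiting = ~state.escaped
    ax.scatter(state.positions[waiting, 0], state.positions[waiting, 1],
               s=8, c="tab:blue", label="waiting")
    ax.scatter(state.positions[~waiting, 0], state.positions[~waiting, 1],
               s=8, c="tab:green", label="escaped")
    r = smoke_radius(state.clock if t is None else t, scene)
    ax.add_patch(plt.Circle(scene.fire.point, r, color="gold", alpha=0.4,
                            label="smoke"))
    ax.plot(*scene.fire.point, "r*", markersize=12)
    ax.set_xlim(scene.bounds[0] - 2, scene.bounds[2] + 2)
    ax.set_ylim(scene.bounds[1] - 2, scene.bounds[3] + 2)
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    fig.savefig(path, dpi=110)
    plt.close(fig)
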