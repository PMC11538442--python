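"""Individual-based automata (IBA) model of a three-level trophic chain.

Resources, primary consumers (PC) and secondary consumers (SC) move randomly
on a toroidal continuous square.  PCs eat resources within a small radius and
live or die step by step on what they catch; SCs hunt PCs within a much
larger radius but their survival and reproduction are governed by prey
encountered over a 500-step rolling window.  The two consumer levels
therefore operate on intrinsically different timescales: R and PC interact
every step, while the PC influence on SC only exists as a 500-step integral.

Model rules per step, in order:

1. every individual moves (per-axis uniform displacement in ``[-s, +s]``,
   toroidal wrap);
2. each PC, in seeded random order, consumes every still-available resource
   within ``radius_pc`` (a resource feeds exactly one PC);
3. each SC encounters all PCs within ``radius_sc``; each encountered PC is
   killed with probability ``sc_kill_prob`` (satiation-limited take) and
   removed at the end of the phase, while the full encounter count is
   credited to the SC's consumption window;
4. PC survival/reproduction: a PC killed by an SC is removed first; of the
   rest, a PC that ate nothing dies, one that ate at least one survives and
   one that ate at least two leaves one offspring, placed uniformly at
   random on the grid (newborns disperse);
5. SC survival/reproduction from the rolling window: an SC older than the
   window dies if it encountered fewer than ``sc_survival_threshold`` prey
   over the last ``sc_window`` steps, and reproduces (at most once per
   ``sc_repro_refractory`` steps) if it encountered at least
   ``sc_repro_threshold``; offspring start beside the parent with an empty
   window;
6. ``resource_influx`` new resources appear uniformly at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .series import UniformSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IBAConfig:
    """Full parameterization of the automata model."""

    grid_size: float = 1000.0
    n_resources0: int = 15000
    n_pc0: int = 1500
    n_sc0: int = 20
    speed_r: float = 10.0
    speed_pc: float = 10.0
    speed_sc: float = 25.0
    radius_pc: float = 10.0
    radius_sc: float = 100.0
    resource_influx: int = 500
    sc_window: int = 500
    sc_survival_threshold: int = 3000
    sc_repro_threshold: int = 5000
    sc_repro_refractory: int = 200
    sc_kill_prob: float = 0.15
    n_steps: int = 15000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_resources0, self.n_pc0, self.n_sc0) < 0:
            raise ValueError("initial counts must be >= 0")
        if min(self.speed_r, self.speed_pc, self.speed_sc) <= 0:
            raise ValueError("speeds must be > 0")
        if min(self.radius_pc, self.radius_sc) <= 0:
            raise ValueError("radii must be > 0")
        if self.sc_repro_threshold < self.sc_survival_threshold:
            raise ValueError(
                "sc_repro_threshold must be >= sc_survival_threshold"
            )
        if not 0.0 <= self.sc_kill_prob <= 1.0:
            raise ValueError("sc_kill_prob must lie in [0, 1]")


@dataclass
class WorldState:
    """Mutable state of one running simulation."""

    pos_r: np.ndarray
    pos_pc: np.ndarray
    pos_sc: np.ndarray
    sc_hist: np.ndarray          # ring buffer (n_sc, sc_window) of encounters
    sc_sum: np.ndarray           # rolling window sums, kept incrementally
    sc_birth_time: np.ndarray
    sc_last_repro_time: np.ndarray
    current_step: int
    rng: np.random.Generator
    # per-step ledger, for conservation checks and diagnostics
    last_resources_eaten: int = 0
    last_pc_killed: int = 0
    last_pc_starved: int = 0
    last_pc_born: int = 0
    last_sc_died: int = 0
    last_sc_born: int = 0

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.pos_r), len(self.pos_pc), len(self.pos_sc)


@dataclass(frozen=True)
class AbundanceRecord:
    t: int
    n_resources: int
    n_pc: int
    n_sc: int


def init_world(config: IBAConfig) -> WorldState:
    """Scatter the initial populations uniformly on the square."""
    rng = np.random.default_rng(config.seed)
    g = config.grid_size
    n_sc = config.n_sc0
    return WorldState(
        pos_r=rng.uniform(0, g, (config.n_resources0, 2)),
        pos_pc=rng.uniform(0, g, (config.n_pc0, 2)),
        pos_sc=rng.uniform(0, g, (n_sc, 2)),
        sc_hist=np.zeros((n_sc, config.sc_window), dtype=np.int32),
        sc_sum=np.zeros(n_sc, dtype=np.int64),
        sc_birth_time=np.zeros(n_sc, dtype=np.int64),
        sc_last_repro_time=np.zeros(n_sc, dtype=np.int64),
        current_step=0,
        rng=rng,
    )


def _move(pos: np.ndarray, speed: float, grid: float,
          rng: np.random.Generator) -> np.ndarray:
    if len(pos) == 0:
        return pos
    return np.mod(pos + rng.uniform(-speed, speed, pos.shape), grid)


def step(world: WorldState, config: IBAConfig) -> WorldState:
    """Advance the world by one timestep (in place) and return it."""
    rng = world.rng
    g = config.grid_size
    t = world.current_step

    world.pos_r = _move(world.pos_r, config.speed_r, g, rng)
    world.pos_pc = _move(world.pos_pc, config.speed_pc, g, rng)
    world.pos_sc = _move(world.pos_sc, config.speed_sc, g, rng)

    # --- PCs consume resources (exclusive, seeded random order) ---
    n_pc = len(world.pos_pc)
    eaten_per_pc = np.zeros(n_pc, dtype=np.int64)
    resources_eaten = 0
    if n_pc and len(world.pos_r):
        tree = cKDTree(world.pos_r, boxsize=g)
        order = rng.permutation(n_pc)
        balls = tree.query_ball_point(world.pos_pc[order], config.radius_pc)
        available = np.ones(len(world.pos_r), dtype=bool)
        for pc_idx, ball in zip(order, balls):
            if ball:
                idx = np.asarray(ball)
                mask = available[idx]
                c = int(mask.sum())
                if c:
                    available[idx[mask]] = False
                    eaten_per_pc[pc_idx] = c
        resources_eaten = int((~available).sum())
        world.pos_r = world.pos_r[available]

    # --- SCs encounter and (with satiation) kill PCs ---
    n_sc = len(world.pos_sc)
    encounters = np.zeros(n_sc, dtype=np.int64)
    pc_killed = np.zeros(n_pc, dtype=bool)
    if n_sc and n_pc:
        tree = cKDTree(world.pos_pc, boxsize=g)
        balls = tree.query_ball_point(world.pos_sc, config.radius_sc)
        for sc_idx, ball in enumerate(balls):
            if ball:
                idx = np.asarray(ball)
                encounters[sc_idx] = len(idx)
                kills = idx[rng.random(len(idx)) < config.sc_kill_prob]
                pc_killed[kills] = True

    # --- PC survival and reproduction (killed PCs removed first) ---
    survive = (~pc_killed) & (eaten_per_pc >= 1)
    reproduce = (~pc_killed) & (eaten_per_pc >= 2)
    n_born = int(reproduce.sum())
    offspring = rng.uniform(0, g, (n_born, 2))
    n_starved = int(((~pc_killed) & (eaten_per_pc == 0)).sum())
    world.pos_pc = np.concatenate([world.pos_pc[survive], offspring])

    # --- SC rolling window, survival, reproduction ---
    slot = t % config.sc_window
    world.sc_sum += encounters - world.sc_hist[:, slot]
    world.sc_hist[:, slot] = encounters
    age = t - world.sc_birth_time
    # grace: the window is undefined before an SC has existed sc_window steps
    alive = (age < config.sc_window) | (world.sc_sum >= config.sc_survival_threshold)
    can_reproduce = (
        alive
        & (world.sc_sum >= config.sc_repro_threshold)
        & (t - world.sc_last_repro_time >= config.sc_repro_refractory)
    )
    world.sc_last_repro_time[can_reproduce] = t
    n_sc_born = int(can_reproduce.sum())
    world.pos_sc = np.concatenate(
        [world.pos_sc[alive], world.pos_sc[can_reproduce]]
    )
    world.sc_birth_time = np.concatenate(
        [world.sc_birth_time[alive], np.full(n_sc_born, t + 1, dtype=np.int64)]
    )
    world.sc_last_repro_time = np.concatenate(
        [world.sc_last_repro_time[alive], np.full(n_sc_born, t + 1, dtype=np.int64)]
    )
    world.sc_hist = np.concatenate(
        [world.sc_hist[alive],
         np.zeros((n_sc_born, config.sc_window), dtype=np.int32)]
    )
    world.sc_sum = np.concatenate(
        [world.sc_sum[alive], np.zeros(n_sc_born, dtype=np.int64)]
    )

    # --- resource influx ---
    world.pos_r = np.concatenate(
        [world.pos_r, rng.uniform(0, g, (config.resource_influx, 2))]
    )

    world.last_resources_eaten = resources_eaten
    world.last_pc_killed = int(pc_killed.sum())
    world.last_pc_starved = n_starved
    world.last_pc_born = n_born
    world.last_sc_died = int((~alive).sum())
    world.last_sc_born = n_sc_born
    world.current_step = t + 1
    return world


def run_iba(config: IBAConfig) -> tuple[UniformSeries, UniformSeries, UniformSeries]:
    """Run the simulation and return the three abundance series (R, PC, SC)."""
    world = init_world(config)
    records = np.zeros((config.n_steps, 3), dtype=np.int64)
    log_every = max(config.n_steps // 10, 1)
    for t in range(config.n_steps):
        step(world, config)
        records[t] = world.counts
        if (t + 1) % log_every == 0:
            r, pc, sc = world.counts
            logger.info("step %d/%d: R=%d PC=%d SC=%d",
                        t + 1, config.n_steps, r, pc, sc)
    return (
        UniformSeries(records[:, 0].astype(float), name="resources"),
        UniformSeries(records[:, 1].astype(float), name="primary_consumers"),
        UniformSeries(records[:, 2].astype(float), name="secondary_consumers"),
    )


def iba_causal_webs(
    triple: tuple[UniformSeries, UniformSeries, UniformSeries],
    E_range=range(1, 11),
    fast: tuple[int, int] = (1, -1),
    slow: tuple[int, int] = (500, -500),
):
    """Construct the fast and slow causal webs from one simulated triple.

    Every ordered pair is tested at ``tau=1, tp=-1`` (high-resolution web)
    and ``tau=500, tp=-500`` (low-resolution web): a link is accepted when
    the best CCM skill over ``E_range`` exceeds the maximum absolute lagged
    cross-correlation and is positive.  Returns the two networks.
    """
    from .network import CausalNetwork, xcorr_link_test
    from .series import SeriesLengthError

    E_max = max(E_range)
    slow_tau = slow[0]
    n = len(triple[0])
    needed = (E_max - 1) * slow_tau + slow_tau + 2
    if n < needed:
        raise SeriesLengthError(
            f"series of length {n} too short for the tau={slow_tau} web; "
            f"need at least {needed} samples"
        )
    webs = []
    for tau, tp in (fast, slow):
        links = []
        for X in triple:
            for Y in triple:
                if X.name == Y.name:
                    continue
                links.append(xcorr_link_test(X, Y, E_range, tau, tp))
        webs.append(
            CausalNetwork(
                tuple(s.name for s in triple), tuple(links),
                scale_label=f"tau={tau}",
            )
        )
    return webs[0], webs[1]


def records_from_series(
    triple: tuple[UniformSeries, UniformSeries, UniformSeries],
) -> list[AbundanceRecord]:
    """Abundance records, one per step, from a simulated triple."""
    r, pc, sc = triple
    return [
        AbundanceRecord(int(t), int(a), int(b), int(c))
        for t, a, b, c in zip(r.time_index, r.values, pc.values, sc.values)
    ]
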