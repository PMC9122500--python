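"""Metropolis Monte Carlo with replica exchange over the mobile degrees of freedom.

One sweep proposes one move per mobile degree-of-freedom group: a random
rotation (axis uniform on the sphere, angle uniform up to ``rb_max_rot``,
composed via unit quaternions) plus translation for each mobile rigid body,
and a random translation for each free bead. Moves are accepted with the
Metropolis probability min(1, exp(-dS/T)). Replica exchange swaps adjacent
temperatures with probability min(1, exp((1/T_i - 1/T_j)(S_i - S_j))).

Configurations are saved from the lowest-temperature replica only, every
``save_every`` sweeps, so the saved ensemble approximates the target
distribution.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import random_rotation_small
from .topology import Topology

ScoreFn = Callable[[np.ndarray], tuple[float, dict]]


@dataclass
class MoveSet:
    rb_max_trans: float = 4.0   # A
    rb_max_rot: float = 0.5     # radians
    bead_max_trans: float = 4.0  # A

    def __post_init__(self) -> None:
        if min(self.rb_max_trans, self.rb_max_rot, self.bead_max_trans) < 0:
            raise ValueError("move bounds must be non-negative")


@dataclass
class SamplerConfig:
    n_replicas: int = 4
    t_min: float = 1.0
    t_max: float = 2.5
    n_steps: int = 1500          # sweeps per run
    save_every: int = 10
    exchange_every: int = 10
    seed: int = 0
    n_runs: int = 4

    def temperatures(self) -> np.ndarray:
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.n_replicas == 1:
            return np.array([self.t_min])
        return np.geomspace(self.t_min, self.t_max, self.n_replicas)


# Desk-scale defaults used by the synthetic stage scenarios, and the
# full-scale profile for production runs against real deposited data.
DESK_SCALE = SamplerConfig(n_replicas=4, n_steps=1500, n_runs=4)
FULL_SCALE = SamplerConfig(n_replicas=30, n_steps=300_000, n_runs=10)


@dataclass
class ModelConfiguration:
    """One sampled arrangement of all bead centers, with provenance."""
    coords: np.ndarray
    run: int
    replica: int
    step: int
    score: float
    terms: dict[str, float] = field(default_factory=dict)


@dataclass
class Ensemble:
    models: list[ModelConfiguration]

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def coords_stack(self) -> np.ndarray:
        return np.stack([m.coords for m in self.models])

    @property
    def scores(self) -> np.ndarray:
        return np.array([m.score for m in self.models])

    @property
    def run_labels(self) -> np.ndarray:
        return np.array([m.run for m in self.models])

    def provenance_table(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.models):
            row = {"model": i, "run": m.run, "replica": m.replica,
                   "step": m.step, "score": m.score}
            row.update(m.terms)
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        return Ensemble([self.models[i] for i in indices])

    def save(self, directory: str | Path) -> None:
        """Indexed trajectory directory: per-frame coordinates + score table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.provenance_table().to_csv(directory / "scores.csv", index=False)
        frames = []
        for i, m in enumerate(self.models):
            n = len(m.coords)
            frames.append(pd.DataFrame({
                "model": np.full(n, i), "bead": np.arange(n),
                "x": m.coords[:, 0], "y": m.coords[:, 1], "z": m.coords[:, 2],
            }))
        pd.concat(frames, ignore_index=True).to_csv(directory / "frames.csv", index=False)

    @staticmethod
    def load(directory: str | Path) -> "Ensemble":
        directory = Path(directory)
        scores = pd.read_csv(directory / "scores.csv")
        frames = pd.read_csv(directory / "frames.csv")
        models = []
        term_cols = [c for c in scores.columns
                     if c not in ("model", "run", "replica", "step", "score")]
        for _, r in scores.iterrows():
            sub = frames[frames["model"] == r["model"]].sort_values("bead")
            models.append(ModelConfiguration(
                coords=sub[["x", "y", "z"]].to_numpy(),
                run=int(r["run"]), replica=int(r["replica"]), step=int(r["step"]),
                score=float(r["score"]),
                terms={c: float(r[c]) for c in term_cols},
            ))
        return Ensemble(models)


# ---------------------------------------------------------------------------
# movers

class RigidBodyMover:
    """Rotate about the body centroid and translate, all members together."""

    def __init__(self, bead_ids: Sequence[int]):
        self.idx = np.asarray(bead_ids, int)

    def propose(self, coords: np.ndarray, moveset: MoveSet,
                rng: np.random.Generator) -> np.ndarray:
        sub = coords[self.idx]
        centroid = sub.mean(axis=0)
        R = random_rotation_small(moveset.rb_max_rot, rng)
        t = _random_in_ball(moveset.rb_max_trans, rng)
        new = coords.copy()
        new[self.idx] = (sub - centroid) @ R.T + centroid + t
        return new


class BeadMover:
    def __init__(self, bead_id: int):
        self.idx = int(bead_id)

    def propose(self, coords: np.ndarray, moveset: MoveSet,
                rng: np.random.Generator) -> np.ndarray:
        new = coords.copy()
        new[self.idx] = coords[self.idx] + _random_in_ball(moveset.bead_max_trans, rng)
        return new


def _random_in_ball(radius: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    if n == 0:
        return np.zeros(3)
    return v / n * rng.uniform(0.0, radius)


def make_movers(topology: Topology) -> list:
    """One mover per mobile rigid body and per free bead; fixed bodies get none."""
    movers: list = []
    for rb in topology.mobile_rigid_bodies():
        movers.append(RigidBodyMover(rb.bead_ids))
    for bid in topology.free_bead_ids():
        movers.append(BeadMover(bid))
    return movers


# ---------------------------------------------------------------------------
# Metropolis and replica exchange

def metropolis_accept(delta: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    if delta <= 0:
        return True
    return rng.random() < np.exp(-delta / temperature)


def mc_sweep(coords: np.ndarray, score: float, score_fn: ScoreFn, movers: Sequence,
             moveset: MoveSet, temperature: float,
             rng: np.random.Generator) -> tuple[np.ndarray, float, int]:
    """One proposal per mover; returns (coords, score, n_accepted)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    n_acc = 0
    for mover in movers:
        cand = mover.propose(coords, moveset, rng)
        s_new, _ = score_fn(cand)
        if metropolis_accept(s_new - score, temperature, rng):
            coords, score = cand, s_new
            n_acc += 1
    return coords, score, n_acc


def run_mc(score_fn: ScoreFn, coords0: np.ndarray, movers: Sequence,
           n_sweeps: int, temperature: float, save_every: int,
           rng: np.random.Generator, moveset: Optional[MoveSet] = None,
           run: int = 0, replica: int = 0) -> list[ModelConfiguration]:
    """Plain single-chain Metropolis; the degenerate one-replica ladder."""
    moveset = moveset or MoveSet()
    coords = np.array(coords0, float)
    score, terms = score_fn(coords)
    saved = []
    for sweep in range(1, n_sweeps + 1):
        coords, score, _ = mc_sweep(coords, score, score_fn, movers, moveset,
                                    temperature, rng)
        if sweep % save_every == 0:
            _, terms = score_fn(coords)
            saved.append(ModelConfiguration(coords.copy(), run, replica, sweep,
                                            score, dict(terms)))
    return saved


def run_replica_exchange(system, config: SamplerConfig,
                         moveset: Optional[MoveSet] = None,
                         init_fn: Optional[Callable[[np.random.Generator], np.ndarray]] = None,
                         movers: Optional[Sequence] = None) -> Ensemble:
    """Replica-exchange MC over ``system`` (anything with .score(coords)).

    ``init_fn(rng)`` supplies randomized initial coordinates per replica;
    by default the system topology's reference coordinates are used as-is.
    ``n_runs`` independent runs are executed with seeds derived from
    ``config.seed`` and labeled for later A/B ensemble splitting. Deterministic
    for a fixed seed.
    """
    moveset = moveset or MoveSet()
    if movers is None:
        movers = make_movers(system.topology)
    if config.n_steps % config.save_every != 0:
        warnings.warn("n_steps is not a multiple of save_every; trailing sweeps "
                      "are sampled but not saved", stacklevel=2)
    temps = config.temperatures()
    score_fn = system.score
    all_models: list[ModelConfiguration] = []
    run_seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    for run in range(config.n_runs):
        streams = run_seeds[run].spawn(config.n_replicas + 1)
        rngs = [np.random.default_rng(s) for s in streams[:-1]]
        xrng = np.random.default_rng(streams[-1])
        states = []
        for r in range(config.n_replicas):
            if init_fn is not None:
                c0 = np.array(init_fn(rngs[r]), float)
            else:
                c0 = system.topology.reference_coords()
            s0, _ = score_fn(c0)
            states.append([c0, s0])
        for sweep in range(1, config.n_steps + 1):
            for r in range(config.n_replicas):
                c, s, _ = mc_sweep(states[r][0], states[r][1], score_fn, movers,
                                   moveset, temps[r], rngs[r])
                states[r][0], states[r][1] = c, s
            if config.n_replicas > 1 and sweep % config.exchange_every == 0:
                for i in range(config.n_replicas - 1):
                    si, sj = states[i][1], states[i + 1][1]
                    log_p = (1.0 / temps[i] - 1.0 / temps[i + 1]) * (si - sj)
                    if log_p >= 0 or xrng.random() < np.exp(log_p):
                        states[i], states[i + 1] = states[i + 1], states[i]
            if sweep % config.save_every == 0:
                c = states[0][0]
                _, terms = score_fn(c)
                all_models.append(ModelConfiguration(
                    c.copy(), run, 0, sweep, states[0][1], dict(terms)))
    return Ensemble(all_models)


class FunctionSystem:
    """Adapter exposing a plain score function as a sampler 'system' (used by
    the calibration toys: harmonic well, double well)."""

    def __init__(self, fn: Callable[[np.ndarray], float], topology=None):
        self._fn = fn
        self.topology = topology

    def score(self, coords: np.ndarray) -> tuple[float, dict]:
        return float(self._fn(coords)), {}
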