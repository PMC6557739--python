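"""Annealed particle swarm search over gene subsets.

Particles live in a continuous D-dimensional box over the (level-3)
gene pool; each coordinate, rounded and clamped, is the pool slot of a
selected gene, and duplicate slots are repaired by advancing cyclically
to the nearest unused slot so every particle always decodes to D
distinct genes.

Velocities follow the inertia-weighted update

    v <- w(t) v + c1 Y1 (pbest - x) + c2 Y2 (gbest - x),   |v| <= v_max

with the inertia weight decreased linearly from ``w_ini`` to ``w_end``
over the run.  Two modifications target premature convergence:

* the swarm-best position ``p_g`` is updated through a Metropolis
  criterion under a linearly decreasing temperature — a candidate
  better by at least ``eps`` always replaces ``p_g``; a candidate
  within ``eps`` replaces it with probability exp(-|df| / T); a
  candidate worse by ``eps`` or more never does;
* when the best fitness ever seen stagnates for ``n_mu`` consecutive
  generations, a random half of the swarm is reinitialized.

Because the Metropolis rule may move ``p_g`` to a marginally worse
position, the best subset ever evaluated is tracked separately and
greedily; it is what the optimizer reports, and stagnation is measured
against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "IPSOConfig",
    "IPSOResult",
    "decode",
    "anneal",
    "inertia_weight",
    "metropolis_update",
    "run_ipso",
]


@dataclass
class IPSOConfig:
    """Swarm and annealing parameters.

    Defaults follow the established settings for this method family:
    swarm of 60 particles, 20 generations, c1 = c2 = 1.49445, inertia
    0.9 -> 0.4, half-swarm mutation after 3 stagnant generations.  The
    annealing scale (T0 = 0.1 -> T_end = 0.001) and the indifference
    threshold eps = 0.01 are on the accuracy scale [0, 1].
    """

    n_select: int  # D: genes per particle
    swarm_size: int = 60
    max_iter: int = 20
    c1: float = 1.49445
    c2: float = 1.49445
    w_ini: float = 0.9
    w_end: float = 0.4
    v_max: float | None = None  # default |pool| / 2
    t0: float = 0.1
    t_end: float = 0.001
    eps: float = 0.01
    n_mu: int = 3
    gbest_update: str = "metropolis"  # or "greedy"
    mutation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.w_ini < self.w_end:
            raise ValueError("w_ini must be >= w_end")
        if not (self.t0 >= self.t_end > 0):
            raise ValueError("temperatures must satisfy t0 >= t_end > 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.gbest_update not in ("metropolis", "greedy"):
            raise ValueError("gbest_update must be 'metropolis' or 'greedy'")

    def standard_pso(self) -> "IPSOConfig":
        """The plain inertia-weighted PSO baseline: greedy swarm-best
        updates, no mutation, same seeds and schedules."""
        from dataclasses import replace

        return replace(self, gbest_update="greedy", mutation=False)


@dataclass
class IPSOResult:
    """Best subset found plus a per-generation trace."""

    best_genes: tuple[int, ...]
    best_fitness: float
    trace: list[dict] = field(default_factory=list)
    evaluations: int = 0

    def trace_rows(self):
        """Trace as (iteration, T, w, best_ever, pg_fitness, mutated) rows."""
        return [
            (r["iteration"], r["T"], r["w"], r["best_ever"], r["pg_fitness"], int(r["mutated"]))
            for r in self.trace
        ]


def decode(position: np.ndarray, pool_size: int) -> np.ndarray:
    """Map a continuous position to distinct pool slots.

    Coordinates are rounded to the nearest integer and clamped to
    ``[0, pool_size - 1]``; duplicates are repaired by advancing
    (cyclically) to the nearest unused slot above.  Deterministic.
    """
    D = len(position)
    if D > pool_size:
        raise ValueError(f"cannot select {D} distinct genes from a pool of {pool_size}")
    slots = np.clip(np.rint(np.asarray(position, dtype=float)), 0, pool_size - 1).astype(int)
    used = np.zeros(pool_size, dtype=bool)
    out = np.empty(D, dtype=int)
    for i, s in enumerate(slots):
        while used[s]:
            s = (s + 1) % pool_size
        used[s] = True
        out[i] = s
    return out


def anneal(t0: float, t_end: float, max_iter: int, t: int) -> float:
    """Linearly decreasing annealing temperature T(t)."""
    if max_iter == 0:
        raise ValueError("max_iter must be > 0 for the annealing schedule")
    # interpolation form is endpoint-exact in floating point
    frac = t / max_iter
    return t0 * (1.0 - frac) + t_end * frac


def inertia_weight(w_ini: float, w_end: float, max_iter: int, t: int) -> float:
    """Linearly decreasing inertia weight w(t)."""
    if max_iter == 0:
        raise ValueError("max_iter must be > 0 for the inertia schedule")
    frac = t / max_iter
    return w_ini * (1.0 - frac) + w_end * frac


def metropolis_update(
    pg_fitness: float,
    candidate_fitness: float,
    temperature: float,
    eps: float,
    rng: np.random.Generator,
) -> bool:
    """Whether a candidate replaces the swarm-best position.

    Better by at least ``eps``: always.  Within ``eps`` of the
    incumbent: with probability exp(-|df| / T).  Worse by ``eps`` or
    more: never.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    df = candidate_fitness - pg_fitness
    if df >= eps:
        return True
    if abs(df) < eps:
        return rng.random() < np.exp(-abs(df) / temperature)
    return False


def _init_particles(rng, n, D, pool_size, v_max):
    positions = rng.uniform(0.0, pool_size - 1, size=(n, D))
    velocities = rng.uniform(-v_max, v_max, size=(n, D))
    return positions, velocities


def run_ipso(
    fitness: Callable[[tuple[int, ...]], float],
    pool_size: int,
    config: IPSOConfig,
) -> IPSOResult:
    """Run the annealed swarm search and return the best subset found.

    Parameters
    ----------
    fitness : callable
        Maps a tuple of pool-slot indices (sorted, distinct) to a
        fitness in [0, 1].  Evaluations are memoized per subset, so
        the callable must be deterministic within a run.
    pool_size : int
        Number of genes in the (level-3) pool being searched.
    config : IPSOConfig

    Returns
    -------
    IPSOResult
        ``best_genes`` holds pool-slot indices; translate through the
        pool's ``gene_indices`` for dataset coordinates.
    """
    cfg = config
    if cfg.n_select > pool_size:
        raise ValueError("n_select exceeds pool size")
    v_max = cfg.v_max if cfg.v_max is not None else pool_size / 2.0
    rng = np.random.default_rng(cfg.seed)
    # separate stream for Metropolis coin flips: its draws must not
    # perturb the swarm dynamics, which makes the greedy limit an
    # exact trajectory match
    met_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x4D45]))

    n, D = cfg.swarm_size, cfg.n_select
    if n < 2:
        warnings.warn("swarm of < 2 particles cannot mutate half the swarm")

    cache: dict[tuple[int, ...], float] = {}
    evals = 0

    def f_of(position: np.ndarray) -> tuple[tuple[int, ...], float]:
        nonlocal evals
        key = tuple(sorted(decode(position, pool_size).tolist()))
        if key not in cache:
            cache[key] = float(fitness(key))
            evals += 1
        return key, cache[key]

    positions, velocities = _init_particles(rng, n, D, pool_size, v_max)
    pbest_pos = positions.copy()
    pbest_fit = np.empty(n)
    for i in range(n):
        _, pbest_fit[i] = f_of(positions[i])
    g = int(np.argmax(pbest_fit))
    pg_pos = pbest_pos[g].copy()
    pg_fit = float(pbest_fit[g])
    best_genes, best_fit = f_of(pg_pos)

    trace: list[dict] = []
    stagnation = 0
    for t in range(1, cfg.max_iter + 1):
        w = inertia_weight(cfg.w_ini, cfg.w_end, cfg.max_iter, t)
        T = anneal(cfg.t0, cfg.t_end, cfg.max_iter, t)
        improved = False
        for i in range(n):
            y1 = rng.random(D)
            y2 = rng.random(D)
            velocities[i] = np.clip(
                w * velocities[i]
                + cfg.c1 * y1 * (pbest_pos[i] - positions[i])
                + cfg.c2 * y2 * (pg_pos - positions[i]),
                -v_max,
                v_max,
            )
            positions[i] = positions[i] + velocities[i]
            genes, fit = f_of(positions[i])
            if fit > pbest_fit[i]:
                pbest_fit[i] = fit
                pbest_pos[i] = positions[i].copy()
            if cfg.gbest_update == "metropolis":
                accept = metropolis_update(pg_fit, fit, T, cfg.eps, met_rng)
            else:
                accept = fit >= pg_fit
            if accept:
                pg_pos = positions[i].copy()
                pg_fit = fit
            if fit > best_fit:
                best_fit = fit
                best_genes = genes
                improved = True
        stagnation = 0 if improved else stagnation + 1
        mutated = False
        if cfg.mutation and stagnation >= cfg.n_mu:
            half = n // 2
            if half == 0:
                warnings.warn("swarm too small to mutate; skipping reinitialization")
            else:
                chosen = rng.choice(n, size=half, replace=False)
                new_pos, new_vel = _init_particles(rng, half, D, pool_size, v_max)
                positions[chosen] = new_pos
                velocities[chosen] = new_vel
                pbest_pos[chosen] = new_pos.copy()
                for j, idx in enumerate(chosen):
                    _, pbest_fit[idx] = f_of(new_pos[j])
                mutated = True
            stagnation = 0
        trace.append(
            {
                "iteration": t,
                "T": T,
                "w": w,
                "best_ever": best_fit,
                "pg_fitness": pg_fit,
                "mutated": mutated,
            }
        )
    return IPSOResult(
        best_genes=best_genes, best_fitness=best_fit, trace=trace, evaluations=evals
    )
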