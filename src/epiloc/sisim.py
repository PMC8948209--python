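"""Synchronous agent-based Susceptible-Infected simulation.

Every node is either susceptible or infected; at each discrete time step
all infected nodes simultaneously try to infect each susceptible neighbour
with per-edge probability ``beta`` (the infection rate). There is no
recovery, so on a connected graph the process runs to completion and every
node receives a finite infection time. The first-passage delay over a
single link is geometric with mean ``1/beta`` and variance
``(1 - beta)/beta**2`` — the moments the localisation methods plug in as
the per-link delay model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .netmodel import Graph

__all__ = ["SpreadConfig", "SpreadRealisation", "ObserverSet", "run_si", "observe"]

NEVER = -1  # sentinel for "never infected" in the times array


@dataclass(frozen=True)
class SpreadConfig:
    """Run configuration: infection rate, RNG seed, optional step cap."""

    beta: float
    seed: int = 0
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")

    @property
    def mean_delay(self) -> float:
        """Geometric per-link mean delay, 1/beta."""
        return 1.0 / self.beta

    @property
    def delay_variance(self) -> float:
        """Geometric per-link delay variance, (1-beta)/beta^2."""
        return (1.0 - self.beta) / self.beta**2


@dataclass
class SpreadRealisation:
    """One completed (or truncated) SI run: true source and infection times.

    ``infection_time[v]`` is the step at which ``v`` became infected
    (source at 0), or ``NEVER`` (-1) if the run was truncated before the
    infection reached ``v``.
    """

    source: int
    infection_time: np.ndarray
    graph_ref: str = ""

    @property
    def complete(self) -> bool:
        return bool(np.all(self.infection_time != NEVER))

    def to_table(self, beta: float | None = None, seed: int | None = None) -> str:
        """Serialise as tabular text with a metadata header."""
        buf = io.StringIO()
        buf.write(f"# source={self.source}")
        if beta is not None:
            buf.write(f" beta={beta}")
        if seed is not None:
            buf.write(f" seed={seed}")
        buf.write("\nnode\tinfection_time\n")
        for v, t in enumerate(self.infection_time):
            buf.write(f"{v}\t{int(t)}\n")
        return buf.getvalue()


@dataclass
class ObserverSet:
    """Ordered observer nodes with (optionally) their arrival times."""

    nodes: list[int]
    arrival_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("observer nodes must be distinct")
        if self.arrival_times is not None:
            self.arrival_times = np.asarray(self.arrival_times)
            if len(self.arrival_times) != len(self.nodes):
                raise ValueError("arrival_times must parallel nodes")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def reference_index(self) -> int:
        """Index of the reference observer: minimum arrival time, ties by
        observer node index."""
        if self.arrival_times is None:
            raise ValueError("arrival times not recorded")
        t = self.arrival_times
        best = min(range(len(self.nodes)), key=lambda i: (t[i], self.nodes[i]))
        return best


def run_si(g: Graph, cfg: SpreadConfig, source: int | str = "random") -> SpreadRealisation:
    """Run one synchronous SI realisation and record per-node infection times.

    ``source`` is a node id or ``"random"`` (uniform choice). At step ``t``
    each susceptible node with ``j`` infected neighbours becomes infected
    with probability ``1 - (1 - beta)**j`` — equivalent to independent
    per-edge trials, and free of any update order as the dynamics are
    simultaneous.
    """
    rng = np.random.default_rng(cfg.seed)
    n = g.node_count
    if source == "random":
        src = int(rng.integers(n))
    else:
        src = int(source)
        if not 0 <= src < n:
            raise ValueError(f"unknown source node {source!r}")

    times = np.full(n, NEVER, dtype=np.int64)
    times[src] = 0
    # pressure[v] = number of infected neighbours of susceptible v
    pressure = np.zeros(n, dtype=np.int64)
    boundary: set[int] = set()
    for w in g.neighbors(src):
        pressure[w] += 1
        boundary.add(w)

    t = 0
    n_infected = 1
    while boundary and n_infected < n:
        t += 1
        if cfg.max_steps is not None and t > cfg.max_steps:
            break
        cand = sorted(boundary)
        probs = 1.0 - (1.0 - cfg.beta) ** pressure[cand]
        hits = rng.random(len(cand)) < probs
        newly = [v for v, h in zip(cand, hits) if h]
        for v in newly:
            times[v] = t
            boundary.discard(v)
            n_infected += 1
        for v in newly:
            for w in g.neighbors(v):
                if times[w] == NEVER:
                    pressure[w] += 1
                    boundary.add(w)
    return SpreadRealisation(source=src, infection_time=times)


def observe(
    r: SpreadRealisation, observers: list[int], policy: str = "strict"
) -> ObserverSet:
    """Record the arrival times at the observer nodes.

    With ``policy="strict"`` an observer that was never infected raises an
    error; completed runs on connected graphs cannot trigger it. The
    benchmark layer reruns truncated realisations instead of observing them.
    """
    if not observers:
        raise ValueError("observers must be non-empty")
    n = len(r.infection_time)
    times = []
    for o in observers:
        if not 0 <= o < n:
            raise ValueError(f"observer {o} not in graph")
        t = int(r.infection_time[o])
        if t == NEVER:
            if policy == "strict":
                raise ValueError(f"observer {o} was never infected")
            t = NEVER
        times.append(t)
    return ObserverSet(nodes=list(observers), arrival_times=np.asarray(times))
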