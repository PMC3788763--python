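"""Structured-coalescent genealogy simulation under a demographic scenario.

Between demographic events the sampled populations are isolated, so each
population's coalescent runs independently: with ``k`` extant lineages in a
population of haploid size ``N``, the waiting time to the next coalescence is
exponential with rate ``k(k-1)/(2N)`` per generation (continuous-time
approximation).  At a merge event all lineages of the source population move
to the destination; at an admixture pulse each lineage of the target is
independently reassigned to the donor with the pulse's rate; at a resize the
population's size changes stepwise.  Simulation continues past the last event
until a single lineage (the grand MRCA) remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .scenarios import ParameterDraw, ScenarioSpec, validate_draw

__all__ = ["SampleConfig", "Genealogy", "simulate_genealogy", "genealogy_stats"]


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes per population and the locus length in sites."""

    sample_sizes: Tuple[Tuple[str, int], ...] = (("SAG", 249), ("NAG", 53), ("NC", 15))
    locus_length: int = 1752

    def __post_init__(self) -> None:
        sizes = dict(self.sample_sizes)
        if any(n < 0 for n in sizes.values()):
            raise ValueError("sample sizes must be nonnegative")
        if sum(sizes.values()) < 2:
            raise ValueError("need at least two sampled lineages in total")
        if self.locus_length < 1:
            raise ValueError("locus length must be >= 1")

    @property
    def sizes(self) -> Dict[str, int]:
        return dict(self.sample_sizes)

    @property
    def n_total(self) -> int:
        return sum(dict(self.sample_sizes).values())

    @classmethod
    def from_sizes(cls, sizes: Dict[str, int], locus_length: int = 1752) -> "SampleConfig":
        return cls(tuple(sizes.items()), locus_length)


@dataclass
class Genealogy:
    """A binary coalescent tree over the sampled lineages.

    Nodes ``0 .. n_leaves-1`` are the leaves (time 0); internal nodes follow
    in order of creation.  ``left``/``right`` are child indices (-1 for
    leaves); times are in generations before present.
    """

    n_leaves: int
    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_population: List[str]

    @property
    def n_nodes(self) -> int:
        return len(self.time)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_parent(self) -> np.ndarray:
        """Parent index per node (-1 for the root)."""
        parent = np.full(self.n_nodes, -1, dtype=np.int64)
        for v in range(self.n_leaves, self.n_nodes):
            parent[self.left[v]] = v
            parent[self.right[v]] = v
        return parent

    def branch_lengths(self) -> np.ndarray:
        """Duration of the branch above each node (0 for the root)."""
        parent = self.branch_parent()
        lengths = np.zeros(self.n_nodes)
        has_parent = parent >= 0
        lengths[has_parent] = self.time[parent[has_parent]] - self.time[has_parent]
        return lengths

    def mrca_time(self, a: int, b: int) -> float:
        """Time of the most recent common ancestor of two leaves."""
        parent = self.branch_parent()
        anc_a = set()
        v = a
        while v != -1:
            anc_a.add(v)
            v = parent[v]
        v = b
        while v not in anc_a:
            v = parent[v]
        return float(self.time[v])

    def to_newick(self, names: Optional[List[str]] = None) -> str:
        """Newick string with branch lengths in generations."""
        if names is None:
            names = [f"{pop}_{i}" for i, pop in enumerate(self.leaf_population)]
        lengths = self.branch_lengths()

        out: List[str] = []
        # iterative post-order to avoid recursion limits on large trees
        stack: List[Tuple[int, bool]] = [(self.root, False)]
        frags: Dict[int, str] = {}
        while stack:
            v, done = stack.pop()
            if v < self.n_leaves:
                frags[v] = f"{names[v]}:{lengths[v]:.10g}"
                continue
            if not done:
                stack.append((v, True))
                stack.append((int(self.left[v]), False))
                stack.append((int(self.right[v]), False))
            else:
                sub = f"({frags.pop(int(self.left[v]))},{frags.pop(int(self.right[v]))})"
                if v == self.root:
                    frags[v] = sub + ";"
                else:
                    frags[v] = f"{sub}:{lengths[v]:.10g}"
        return frags[self.root]


def simulate_genealogy(
    spec: ScenarioSpec,
    draw: ParameterDraw,
    cfg: SampleConfig,
    rng: np.random.Generator,
    check_draw: bool = True,
) -> Genealogy:
    """Simulate one genealogy under ``spec`` with parameter values ``draw``.

    Parameters
    ----------
    spec, draw
        Demographic scenario and a parameter draw satisfying its constraints.
    cfg
        Sample sizes per population (populations absent from ``spec`` are
        rejected) and locus length (unused here, carried for convenience).
    rng
        numpy Generator; a fixed state yields an identical genealogy.
    check_draw
        Validate the draw against the scenario first (disable in tight inner
        loops where draws come straight from :func:`sample_prior_draw`).
    """
    if check_draw:
        problems = validate_draw(spec, draw)
        if problems:
            raise ValueError(f"{spec.id}: invalid draw: " + "; ".join(problems))
    sample_sizes = cfg.sizes
    unknown = set(sample_sizes) - set(spec.populations)
    if unknown:
        raise ValueError(f"sampled populations not in scenario: {sorted(unknown)}")

    n_leaves = sum(sample_sizes.values())
    n_nodes = 2 * n_leaves - 1 if n_leaves >= 1 else 1
    time = np.zeros(n_nodes)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    leaf_population: List[str] = []

    # lineage pools per population, in the scenario's declared order
    pools: Dict[str, List[int]] = {}
    node = 0
    for pop in spec.populations:
        k = sample_sizes.get(pop, 0)
        pools[pop] = list(range(node, node + k))
        leaf_population.extend([pop] * k)
        node += k

    sizes: Dict[str, float] = {}
    for pop in spec.populations:
        sizes[pop] = draw[spec.initial_sizes[pop]] * spec.size_scaling
        if sizes[pop] <= 0:
            raise ValueError(f"{spec.id}: nonpositive size for {pop}")

    # events sorted by drawn time; stable, so listed order breaks ties
    order = sorted(range(len(spec.events)), key=lambda i: draw[spec.events[i].time])
    schedule = [(draw[spec.events[i].time], spec.events[i]) for i in order]
    schedule.append((np.inf, None))  # terminal epoch

    next_node = n_leaves
    t_now = 0.0

    def coalesce_pool(pop: str, t_start: float, t_end: float) -> None:
        nonlocal next_node
        pool = pools[pop]
        n_size = sizes[pop]
        t = t_start
        while len(pool) >= 2:
            k = len(pool)
            rate = k * (k - 1) / 2.0 / n_size
            t += rng.exponential(1.0 / rate)
            if t >= t_end:
                return
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            # remove the two (larger index first to keep positions valid)
            for idx in sorted((i, j), reverse=True):
                pool.pop(idx)
            time[next_node] = t
            left[next_node] = a
            right[next_node] = b
            pool.append(next_node)
            next_node += 1

    for t_event, event in schedule:
        for pop in list(pools):
            coalesce_pool(pop, t_now, t_event)
        if event is None:
            break
        t_now = t_event
        if event.kind == "merge":
            if event.source not in pools or event.dest not in pools:
                raise ValueError(
                    f"{spec.id}: merge {event.source}->{event.dest} at t={t_event:g} "
                    "involves an inactive population"
                )
            pools[event.dest].extend(pools.pop(event.source))
            del sizes[event.source]
        elif event.kind == "admix":
            if event.target not in pools or event.donor not in pools:
                raise ValueError(
                    f"{spec.id}: admixture at t={t_event:g} involves an inactive population"
                )
            r = draw[event.rate]
            tgt = pools[event.target]
            moving = rng.random(len(tgt)) < r
            pools[event.donor].extend(l for l, m in zip(tgt, moving) if m)
            pools[event.target] = [l for l, m in zip(tgt, moving) if not m]
        elif event.kind == "resize":
            if event.population not in pools:
                raise ValueError(
                    f"{spec.id}: resize of inactive population {event.population} "
                    f"at t={t_event:g}"
                )
            new_size = draw[event.size] * spec.size_scaling
            if new_size <= 0:
                raise ValueError(f"{spec.id}: nonpositive size for {event.population}")
            sizes[event.population] = new_size

    total = sum(len(p) for p in pools.values())
    if total != 1:
        raise RuntimeError(
            f"{spec.id}: simulation finished with {total} lineages in "
            f"{len(pools)} populations; scenario event list is inconsistent"
        )
    return Genealogy(n_leaves, time, left, right, leaf_population)


def genealogy_stats(g: Genealogy) -> Tuple[float, float]:
    """``(tmrca, total branch length)`` in generations."""
    if g.n_leaves == 1:
        return 0.0, 0.0
    return float(g.time[g.root]), float(g.branch_lengths().sum())
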