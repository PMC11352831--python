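"""Synchronous Boolean dynamics: steps, attractors, basins.

States are bit vectors over the core's sorted gene list, encoded as integers
(bit i = node i of the order).  The synchronous map applies every node's
rule simultaneously; its attractors are the recurrent cycles (fixed points
at period 1) and the basin of an attractor is the set of states whose
forward orbit enters it.  Exhaustive mode sweeps all 2^n states with a
memoized successor walk, guaranteeing completeness; sampled mode probes
random initial states and is flagged incomplete.  The finder is pluggable
so a constraint-solver backend can be slotted in for large networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rules import RuleSet

__all__ = [
    "Attractor", "AttractorSet", "BasinMap", "CompiledDynamics",
    "synchronous_step", "find_attractors", "basin_map",
    "EXHAUSTIVE_CAP",
]

EXHAUSTIVE_CAP = 22


@dataclass(frozen=True)
class Attractor:
    """A periodic orbit, canonicalized to start at its smallest state."""
    states: tuple[int, ...]

    @classmethod
    def from_cycle(cls, cycle: list[int]) -> "Attractor":
        if len(set(cycle)) != len(cycle):
            raise ValueError("attractor states must be distinct")
        i = cycle.index(min(cycle))
        return cls(states=tuple(cycle[i:] + cycle[:i]))

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def __contains__(self, state: int) -> bool:
        return state in self.states


@dataclass
class AttractorSet:
    attractors: list[Attractor]
    mode: str  # 'exhaustive' | 'sampled'
    n_nodes: int
    budget: int | None = None
    complete: bool = True

    def __post_init__(self):
        if len(set(self.attractors)) != len(self.attractors):
            raise ValueError("attractors must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.attractors)

    def index_of(self, a: Attractor) -> int:
        return self.attractors.index(a)


@dataclass
class BasinMap:
    """Exhaustive state -> attractor assignment with basin sizes."""
    attractor_of: np.ndarray  # index into attractors, length 2^n
    attractors: list[Attractor]
    n_nodes: int

    @property
    def basin_sizes(self) -> list[int]:
        counts = np.bincount(self.attractor_of, minlength=len(self.attractors))
        return counts.tolist()

    def basin_of(self, a: Attractor) -> int:
        return self.attractors.index(a)

    def attractor_of_state(self, state: int) -> Attractor:
        return self.attractors[int(self.attractor_of[state])]


class CompiledDynamics:
    """Rule set compiled to fast integer successor computation.

    Optionally clamps one node to a fixed value (transient perturbations).
    """

    def __init__(self, rules: RuleSet, clamp: tuple[str, int] | None = None):
        order = rules.node_order
        self.order = order
        self.index = {u: i for i, u in enumerate(order)}
        self.n = len(order)
        self._inputs = []
        self._tables = []
        self._clamp = None
        for u in order:
            r = rules.rules[u]
            self._inputs.append([self.index[src] for src, _ in r.inputs])
            self._tables.append(r.truth_table)
        if clamp is not None:
            node, value = clamp
            self._clamp = (self.index[node], int(value))
        self._succ_cache: dict[int, int] = {}
        self._full_succ: np.ndarray | None = None

    def step(self, state: int) -> int:
        """Successor of one state (memoized)."""
        if self._full_succ is not None:
            return int(self._full_succ[state])
        cached = self._succ_cache.get(state)
        if cached is not None:
            return cached
        nxt = 0
        for j in range(self.n):
            idx = 0
            for pos, i in enumerate(self._inputs[j]):
                idx |= ((state >> i) & 1) << pos
            nxt |= int(self._tables[j][idx]) << j
        if self._clamp is not None:
            i, v = self._clamp
            nxt = (nxt & ~(1 << i)) | (v << i)
        self._succ_cache[state] = nxt
        return nxt

    def successor_table(self) -> np.ndarray:
        """Vectorized successor for every state (exhaustive mode)."""
        if self._full_succ is None:
            states = np.arange(1 << self.n, dtype=np.int64)
            succ = np.zeros_like(states)
            for j in range(self.n):
                idx = np.zeros_like(states)
                for pos, i in enumerate(self._inputs[j]):
                    idx |= ((states >> i) & 1) << pos
                bit = self._tables[j][idx].astype(np.int64)
                succ |= bit << j
            if self._clamp is not None:
                i, v = self._clamp
                succ = (succ & ~(1 << i)) | (v << i)
            self._full_succ = succ
        return self._full_succ

    def state_to_dict(self, state: int) -> dict[str, int]:
        return {u: (state >> i) & 1 for u, i in self.index.items()}

    def dict_to_state(self, d: dict[str, int]) -> int:
        s = 0
        for u, i in self.index.items():
            s |= (d[u] & 1) << i
        return s


def synchronous_step(rules: RuleSet, state: dict[str, int] | int,
                     _compiled: CompiledDynamics | None = None):
    """One synchronous update; accepts a dict keyed by gene or an int state."""
    dyn = _compiled or CompiledDynamics(rules)
    if isinstance(state, dict):
        if set(state) != set(rules.node_order):
            raise ValueError("state keys must match the rule domain")
        return dyn.state_to_dict(dyn.step(dyn.dict_to_state(state)))
    if not 0 <= state < (1 << dyn.n):
        raise ValueError("integer state out of range for this network")
    return dyn.step(state)


def _walk_to_cycle(dyn: CompiledDynamics, start: int) -> tuple[list[int], list[int]]:
    """Follow successors until a repeat; return (transient path, cycle)."""
    seen: dict[int, int] = {}
    path: list[int] = []
    s = start
    while s not in seen:
        seen[s] = len(path)
        path.append(s)
        s = dyn.step(s)
    i = seen[s]
    return path[:i], path[i:]


def find_attractors(rules: RuleSet, mode: str = "exhaustive",
                    budget: int | None = None, seed: int = 0,
                    cap: int = EXHAUSTIVE_CAP) -> AttractorSet:
    """Identify attractors of the synchronous dynamics.

    exhaustive : complete sweep of all 2^n states (n <= cap).
    sampled : trajectories from `budget` random initial states, drawn
        without replacement when the state space allows; completeness is
        not guaranteed and the result is flagged accordingly.
    """
    dyn = CompiledDynamics(rules)
    n = dyn.n
    if mode == "exhaustive":
        if n > cap:
            raise ValueError(f"{n} nodes exceeds the exhaustive cap ({cap}); "
                             "use sampled mode")
        bm = _exhaustive_basins(dyn)
        return AttractorSet(attractors=bm.attractors, mode="exhaustive",
                            n_nodes=n, complete=True)
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    if budget is None:
        raise ValueError("sampled mode requires a budget")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 2]))
    size = 1 << n
    if budget >= size and n <= cap:
        starts = np.arange(size)
    elif n <= cap:
        starts = rng.choice(size, size=budget, replace=False)
    else:
        starts = rng.integers(0, 1 << n, size=budget)
    found: dict[Attractor, None] = {}
    for s in starts:
        _, cycle = _walk_to_cycle(dyn, int(s))
        found.setdefault(Attractor.from_cycle(cycle))
    atts = sorted(found, key=lambda a: a.states)
    return AttractorSet(attractors=atts, mode="sampled", n_nodes=n,
                        budget=int(len(starts)), complete=False)


def _exhaustive_basins(dyn: CompiledDynamics) -> BasinMap:
    succ = dyn.successor_table()
    n_states = 1 << dyn.n
    label = np.full(n_states, -1, dtype=np.int64)
    attractors: list[Attractor] = []
    for s0 in range(n_states):
        if label[s0] >= 0:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        s = s0
        while label[s] < 0 and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if label[s] >= 0:
            lab = int(label[s])
        else:
            cycle = path[pos[s]:]
            att = Attractor.from_cycle(cycle)
            lab = len(attractors)
            attractors.append(att)
        for s in path:
            label[s] = lab
    # canonical order: sort attractors, remap labels
    order = sorted(range(len(attractors)), key=lambda i: attractors[i].states)
    remap = np.empty(len(attractors), dtype=np.int64)
    for new, old in enumerate(order):
        remap[old] = new
    return BasinMap(attractor_of=remap[label],
                    attractors=[attractors[i] for i in order],
                    n_nodes=dyn.n)


def basin_map(rules: RuleSet, cap: int = EXHAUSTIVE_CAP) -> BasinMap:
    """Exhaustive state -> attractor map (basin sizes sum to 2^n)."""
    dyn = CompiledDynamics(rules)
    if dyn.n > cap:
        raise ValueError(f"{dyn.n} nodes exceeds the exhaustive cap ({cap})")
    return _exhaustive_basins(dyn)
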