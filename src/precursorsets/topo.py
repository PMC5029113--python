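"""Topological factories, hypergraph paths and the combinatorial enumerator.

A *topological factory* from sources X to the targets is a reaction set
F with ``targets ∪ Subs(F) ⊆ Prod(F) ∪ X`` — a purely set-theoretic
producibility notion that ignores quantities.  In the many-to-one
transformed network (every reaction has a single product) the minimal
topological factories have a crisp characterisation: every non-source
substrate has exactly one producer in F, and every product of F lies on
a path to a target inside F.  That characterisation drives both the
backward-branching enumerator of minimal factories and the
*combinatorial* precursor-set enumerator, which unions k-subsets of
those factories and asks the LP oracle whether the union is
stoichiometrically feasible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

from .feasibility import (
    Mode,
    SolverConfig,
    is_feasible_source_set,
    reduce_to_minimal,
)
from .milp_enum import EnumerationResult
from .netcore import Network, many_to_one, mto_parent_map

__all__ = [
    "HyperPath",
    "Factory",
    "is_topological_factory",
    "find_path",
    "validate_minimal_mto_factory",
    "enumerate_mto_factories",
    "enumerate_minimal_tps",
    "combi_enumerate",
    "FactoryExplosionError",
]


class FactoryExplosionError(RuntimeError):
    """Too many minimal topological factories to enumerate combinations of."""


@dataclass(frozen=True)
class HyperPath:
    """A simple path m_0 -r_1-> m_1 ... -r_n-> m_n through hyperarcs.

    Chain conditions: m_i is a substrate of r_{i+1} and a product of
    r_i; metabolites and reactions are pairwise distinct.
    """

    metabolites: tuple[str, ...]
    reactions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.metabolites) != len(self.reactions) + 1:
            raise ValueError("need exactly one more metabolite than reactions")
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ValueError("metabolites on a simple path must be distinct")
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError("reactions on a simple path must be distinct")


@dataclass(frozen=True)
class Factory:
    """A reaction set together with its source footprint."""

    reactions: frozenset[str]
    source_footprint: frozenset[str]
    kind: str = "topological"  # topological | stoichiometric | md

    def to_dict(self) -> dict:
        return {
            "reactions": sorted(self.reactions),
            "source_footprint": sorted(self.source_footprint),
            "kind": self.kind,
        }


def _subs_prod(network: Network, F: Iterable[str]) -> tuple[set[str], set[str]]:
    subs: set[str] = set()
    prod: set[str] = set()
    for rid in F:
        r = network.reaction(rid)
        subs |= set(r.substrates)
        prod |= set(r.products)
    return subs, prod


def is_topological_factory(
    network: Network, F: Iterable[str], X: Iterable[str]
) -> bool:
    """targets ∪ Subs(F) ⊆ Prod(F) ∪ X — quantities are ignored."""
    F = frozenset(F)
    X = frozenset(X)
    subs, prod = _subs_prod(network, F)
    return (set(network.targets) | subs) <= (prod | X)


def find_path(
    network: Network, F: Iterable[str], start: str, goal: str
) -> Optional[HyperPath]:
    """A simple hyperarc path from ``start`` to ``goal`` inside ``F``.

    Depth-first search keeping both the metabolite chain and the
    reaction chain duplicate-free; ``start == goal`` yields the empty
    path.
    """
    if start == goal:
        return HyperPath((start,), ())
    F = frozenset(F)
    reactions = [network.reaction(rid) for rid in sorted(F)]

    def dfs(
        m: str, seen_m: tuple[str, ...], seen_r: tuple[str, ...]
    ) -> Optional[HyperPath]:
        for r in reactions:
            if r.id in seen_r or m not in r.substrates:
                continue
            for nxt in r.products:
                if nxt in seen_m:
                    continue
                chain_m = seen_m + (nxt,)
                chain_r = seen_r + (r.id,)
                if nxt == goal:
                    return HyperPath(chain_m, chain_r)
                found = dfs(nxt, chain_m, chain_r)
                if found is not None:
                    return found
        return None

    return dfs(start, (start,), ())


def validate_minimal_mto_factory(mto_network: Network, H: Iterable[str]) -> bool:
    """Is ``H`` a minimal topological factory of a many-to-one network?

    With X inferred as ``Subs(H) ∩ sources``, checks (a) every target is
    produced or a source, (b) every non-source substrate *and every
    target* of H has exactly one producer within H, and (c) every
    product of H has a path to some target inside H.  For many-to-one
    networks of a normalized network (sources never produced), (a)-(c)
    are equivalent to H being an inclusion-minimal topological factory.
    Targets must be included in (b): a set producing a target twice
    contains a strictly smaller factory even when all its substrates
    have unique producers.
    """
    H = frozenset(H)
    net = mto_network
    for rid in H:
        if len(net.reaction(rid).products) > 1:
            raise ValueError(f"{rid!r} has several products; not a many-to-one network")
    subs, prod = _subs_prod(net, H)
    X = subs & set(net.sources)
    if not set(net.targets) <= (prod | X):
        return False
    needs_unique_producer = (subs | (set(net.targets) - set(net.sources))) - X
    for m in needs_unique_producer:
        producers = [rid for rid in H if m in net.reaction(rid).products]
        if len(producers) != 1:
            return False
    for m in prod:
        if not any(find_path(net, H, m, t) for t in sorted(net.targets)):
            return False
    return True


def enumerate_mto_factories(
    mto_network: Network, max_factories: int = 100_000
) -> list[Factory]:
    """All minimal topological factories (from any source subset) of a
    many-to-one network, by backward branching.

    Start from each choice of one producer per target; repeatedly take
    the lexicographically smallest substrate that is neither a source
    nor produced yet and branch over its producers.  Finished reaction
    sets are filtered through :func:`validate_minimal_mto_factory`
    (branches closing a cycle with no route to the target are dropped
    there) and deduplicated.
    """
    net = mto_network
    sources = set(net.sources)
    targets = sorted(set(net.targets) - sources)
    if not targets:
        return []

    producer_map: dict[str, list[str]] = {
        c.id: [r.id for r in net.producers_of(c.id)] for c in net.compounds
    }

    # seed states: one producer chosen for every target
    seeds: list[frozenset[str]] = [frozenset()]
    for t in targets:
        producers = producer_map[t]
        if not producers:
            return []
        seeds = [s | {rid} for s in seeds for rid in producers]

    done: set[frozenset[str]] = set()
    stack = list(dict.fromkeys(seeds))
    seen_states: set[frozenset[str]] = set(stack)
    while stack:
        R = stack.pop()
        subs, prod = _subs_prod(net, R)
        missing = sorted(subs - prod - sources)
        if not missing:
            done.add(R)
            if len(done) > max_factories:
                raise FactoryExplosionError(
                    f"more than {max_factories} candidate factories; "
                    "use the MILP enumerator instead"
                )
            continue
        m = missing[0]
        for rid in producer_map[m]:
            if rid in R:
                continue
            state = R | {rid}
            if state not in seen_states:
                seen_states.add(state)
                stack.append(state)

    factories = []
    for R in sorted(done, key=lambda s: (len(s), tuple(sorted(s)))):
        if not validate_minimal_mto_factory(net, R):
            continue
        subs, _ = _subs_prod(net, R)
        factories.append(
            Factory(
                reactions=R,
                source_footprint=frozenset(subs & sources),
                kind="topological",
            )
        )
    return factories


def enumerate_minimal_tps(
    network: Network, max_factories: int = 100_000
) -> set[frozenset[str]]:
    """All inclusion-minimal topological precursor sets of ``network``.

    Source footprints of the minimal topological factories of the
    many-to-one transform (which include, after retransformation, all
    minimal factories of the original network), reduced to the
    inclusion-minimal ones.
    """
    mto = many_to_one(network)
    footprints = {
        f.source_footprint for f in enumerate_mto_factories(mto, max_factories)
    }
    return _inclusion_minimal(footprints)


def _inclusion_minimal(sets: Iterable[frozenset[str]]) -> set[frozenset[str]]:
    sets = set(sets)
    return {s for s in sets if not any(o < s for o in sets)}


def combi_enumerate(
    network: Network,
    config: Optional[SolverConfig] = None,
    mode: Optional[Mode] = None,
    max_factories: int = 10_000,
) -> EnumerationResult:
    """Enumerate minimal precursor sets from combinations of topological
    factories of the many-to-one network.

    For k = 1, 2, ...: union each k-subset of the minimal topological
    factories, map it back to original reactions, and ask the LP/MILP
    oracle whether the union's source footprint is feasible; feasible
    footprints are reduced to minimality.  Supersets of already-found
    solutions are pruned.  Complete because every minimal
    stoichiometric factory decomposes into such topological factories —
    but intentionally naive, and exponential in the factory count.
    """
    config = config or SolverConfig()
    mode = mode or config.mode
    t0 = time.monotonic()
    mto = many_to_one(network)
    parent = mto_parent_map(mto)
    factories = enumerate_mto_factories(mto, max_factories)

    # Whether a combination union is stoichiometrically feasible depends
    # only on its source footprint, so distinct factories sharing a
    # footprint are interchangeable here: keep one representative each.
    reps: dict[frozenset[str], Factory] = {}
    for f in factories:
        reps.setdefault(f.source_footprint, f)
    footprints = sorted(reps, key=lambda s: (len(s), tuple(sorted(s))))

    # Rather than materialising every k-combination of factories, walk the
    # union-closure of the distinct footprints breadth-first: level k holds
    # exactly the unions achievable with k factories and not fewer.  A node
    # that tested feasible, or contains a found solution, never needs
    # extending — all of its supersets contain a found solution too.
    found: set[frozenset[str]] = set()
    solutions: list[dict] = []
    iterations = 0
    seen: set[frozenset[str]] = set()
    level: list[tuple[frozenset[str], frozenset[str]]] = [
        (fp, reps[fp].reactions) for fp in footprints
    ]
    k = 0
    while level and k < len(footprints):
        k += 1
        survivors: list[tuple[frozenset[str], frozenset[str]]] = []
        for X, union_mto in level:
            if X in seen:
                continue
            seen.add(X)
            if len(seen) > 100_000:
                raise FactoryExplosionError(
                    "union closure of factory footprints is too large; "
                    "use the MILP enumerator instead"
                )
            if any(sol <= X for sol in found):
                continue
            iterations += 1
            if not is_feasible_source_set(network, X, mode, config):
                survivors.append((X, union_mto))
                continue
            minimal = reduce_to_minimal(network, X, mode, config)
            found.add(minimal)
            solutions.append(
                {
                    "sources": sorted(minimal),
                    "flux": {},
                    # an original reaction is active as a whole if any of its
                    # single-product copies is
                    "support": sorted({parent[rid] for rid in union_mto}),
                    "k": k,
                }
            )
        level = [
            (X | fp, union_mto | reps[fp].reactions)
            for X, union_mto in survivors
            for fp in footprints
            if not fp <= X
        ]
    if mode is Mode.STEADY_STATE:
        # Factory combinations are provably complete for the accumulating
        # and machinery-duplicating models, but under strict steady state a
        # minimal factory may contain byproduct-draining cycles that have no
        # path to the target; the footprint of its path-connected skeleton
        # then undershoots the true solution.  Every solution still contains
        # the footprint of at least one minimal topological factory, so a
        # sweep over source supersets of those footprints restores
        # completeness without consulting the MILP route.
        seeds = {f.source_footprint for f in factories}
        source_list = sorted(network.sources)
        for k in range(1, len(source_list) + 1):
            for combo in combinations(source_list, k):
                X = frozenset(combo)
                if any(sol <= X for sol in found):
                    continue
                if not any(seed <= X for seed in seeds):
                    continue
                iterations += 1
                if not is_feasible_source_set(network, X, mode, config):
                    continue
                minimal = reduce_to_minimal(network, X, mode, config)
                if any(sol <= minimal for sol in found):
                    continue
                found.add(minimal)
                solutions.append(
                    {
                        "sources": sorted(minimal),
                        "flux": {},
                        "support": [],
                        "k": None,
                    }
                )

    # found sets are inclusion-minimal feasible sets, hence an antichain
    return EnumerationResult(
        solutions=solutions,
        mode=mode,
        config=config,
        iterations=iterations,
        terminated_reason="exhausted",
        algorithm="combi",
        wall_time=time.monotonic() - t0,
    )
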