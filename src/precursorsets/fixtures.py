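"""Programmatic construction of the benchmark toy networks.

Each builder returns a small, fully normalized network whose interesting
behaviour is known in advance; ``verify=True`` (the default is cheap
structural checking only where noted) re-derives that behaviour from the
LP oracles at build time, so a fixture can never silently drift from the
properties the test-suite relies on.

The networks:

* :func:`make_two_reaction` — two chained reactions with non-unit
  coefficients; exercises matrix assembly.
* :func:`make_regenerating_cycle` — a Krebs-like loop whose carrier
  compound is regenerated; a precursor set exists in the accumulating
  and steady-state models but not in the machinery-duplicating one.
* :func:`make_dual_route` — three sources, two routes to the target;
  the topological and stoichiometric minimal solutions differ.
* :func:`make_redundant_feeders` — n sources feeding a dead-end cycle;
  many topological factories, a single stoichiometric solution.
* :func:`make_coupled_outputs` — one reaction co-produces n coupled
  intermediates; the only stoichiometric solution needs all n sources.
* :func:`make_random` — seeded random networks for property tests.
"""

from __future__ import annotations

import random
from typing import Optional

from .feasibility import Mode, SolverConfig, brute_force_minimal_sets, check_s_factory
from .netcore import Compound, Network, Reaction, normalize
from .topo import enumerate_minimal_tps, is_topological_factory

__all__ = [
    "make_two_reaction",
    "make_regenerating_cycle",
    "make_dual_route",
    "make_redundant_feeders",
    "make_coupled_outputs",
    "make_random",
    "FixtureError",
]


class FixtureError(AssertionError):
    """A fixture failed its build-time property checklist."""


def _net(compounds, reactions, sources, targets) -> Network:
    comps = [
        Compound(c, role="source" if c in sources else "target" if c in targets else "internal")
        for c in compounds
    ]
    return Network(comps, reactions, set(sources), set(targets))


def make_two_reaction() -> Network:
    """c1 + 2 c2 -> c3 (r1); 3 c3 -> c4 (r2). Sources c1, c2; target c4."""
    return _net(
        ["c1", "c2", "c3", "c4"],
        [
            Reaction("r1", {"c1": 1.0, "c2": 2.0}, {"c3": 1.0}),
            Reaction("r2", {"c3": 3.0}, {"c4": 1.0}),
        ],
        {"c1", "c2"},
        {"c4"},
    )


def make_regenerating_cycle() -> Network:
    """p + a -> c -> b -> a + t: the carrier a is regenerated, not created.

    Unit flux on all three reactions leaves a, b, c at net zero and
    makes one unit of t, so {p} is a precursor set in the accumulating
    and steady-state models.  No flux can make a, b *and* c strictly
    positive simultaneously, so the machinery-duplicating model admits
    no precursor set at all.
    """
    return _net(
        ["p", "a", "b", "c", "t"],
        [
            Reaction("r1", {"p": 1.0, "a": 1.0}, {"c": 1.0}),
            Reaction("r2", {"c": 1.0}, {"b": 1.0}),
            Reaction("r3", {"b": 1.0}, {"a": 1.0, "t": 1.0}),
        ],
        {"p"},
        {"t"},
    )


def make_dual_route(verify: bool = True) -> Network:
    """Three-source network where topology and stoichiometry disagree.

    All coefficients are 1.  Route one runs p1 through a b/c/d loop that
    needs the a->b replenishment reaction r2 to balance; route two burns
    p2 + p3 directly (r8).  A third, deficient route (r5-r7) makes {p3}
    producible topologically but not stoichiometrically.  Minimal
    topological solutions: {p1}, {p3}; minimal stoichiometric solutions:
    {p1}, {p2, p3}.
    """
    net = _net(
        ["p1", "p2", "p3", "a", "b", "c", "d", "e", "f", "t"],
        [
            Reaction("r1", {"p1": 1.0, "b": 1.0}, {"c": 1.0}),
            Reaction("r2", {"a": 1.0}, {"b": 1.0}),
            Reaction("r3", {"b": 1.0, "c": 1.0}, {"a": 1.0, "d": 1.0}),
            Reaction("r4", {"d": 1.0}, {"b": 1.0, "t": 1.0}),
            Reaction("r5", {"e": 1.0}, {"t": 1.0}),
            Reaction("r6", {"e": 1.0}, {"f": 1.0}),
            Reaction("r7", {"f": 1.0, "p3": 1.0}, {"e": 1.0}),
            Reaction("r8", {"p2": 1.0, "p3": 1.0}, {"t": 1.0}),
        ],
        {"p1", "p2", "p3"},
        {"t"},
    )
    if verify:
        _check(
            enumerate_minimal_tps(net)
            == {frozenset({"p1"}), frozenset({"p3"})},
            "dual_route: minimal topological precursor sets",
        )
        _check(
            brute_force_minimal_sets(net, Mode.ACCUMULATE)
            == {frozenset({"p1"}), frozenset({"p2", "p3"})},
            "dual_route: minimal stoichiometric precursor sets",
        )
        _check(
            is_topological_factory(net, {"r1", "r3", "r4"}, {"p1"})
            and not check_s_factory(net, {"r1", "r3", "r4"}, {"p1"}).feasible,
            "dual_route: {r1,r3,r4} topological but not stoichiometric",
        )
        _check(
            check_s_factory(net, {"r1", "r2", "r3", "r4"}, {"p1"}).feasible,
            "dual_route: {r1,r2,r3,r4} is a factory from {p1}",
        )
        _check(
            is_topological_factory(net, {"r5", "r6", "r7"}, {"p3"}),
            "dual_route: {r5,r6,r7} is a topological factory from {p3}",
        )
        _check(
            check_s_factory(net, {"r8"}, {"p2", "p3"}).feasible,
            "dual_route: {r8} is a factory from {p2,p3}",
        )
        r2 = net.reaction("r2")
        _check(
            set(r2.substrates) == {"a"} and set(r2.products) == {"b"},
            "dual_route: r2 converts a to b",
        )
    return net


def make_redundant_feeders(n: int, verify: bool = True) -> Network:
    """One direct route p1 -> t plus n-1 feeders of a dead-end cycle.

    Sources p2..pn each feed compound c, which enters the deficient
    cycle c + b -> a, a -> b, a -> t: the cycle consumes one a per
    turn to make t but also needs one a to regenerate b, so it can never
    run.  There are n minimal topological factories but only one
    stoichiometric solution, {p1}.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    srcs = [f"p{i}" for i in range(1, n + 1)]
    reactions = [Reaction("r1", {"p1": 1.0}, {"t": 1.0})]
    reactions += [
        Reaction(f"r{i}", {f"p{i}": 1.0}, {"c": 1.0}) for i in range(2, n + 1)
    ]
    reactions += [
        Reaction("r_a", {"c": 1.0, "b": 1.0}, {"a": 1.0}),
        Reaction("r_b", {"a": 1.0}, {"b": 1.0}),
        Reaction("r_t", {"a": 1.0}, {"t": 1.0}),
    ]
    net = _net(srcs + ["a", "b", "c", "t"], reactions, set(srcs), {"t"})
    if verify:
        from .netcore import many_to_one
        from .topo import enumerate_mto_factories

        factories = enumerate_mto_factories(many_to_one(net))
        _check(len(factories) == n, "redundant_feeders: n minimal factories")
        _check(
            {frozenset({"r1"})}
            | {
                frozenset({"r_t", "r_a", "r_b", f"r{i}"})
                for i in range(2, n + 1)
            }
            == {f.reactions for f in factories},
            "redundant_feeders: factory composition",
        )
        _check(
            brute_force_minimal_sets(net, Mode.ACCUMULATE) == {frozenset({"p1"})},
            "redundant_feeders: unique stoichiometric solution {p1}",
        )
    return net


def make_coupled_outputs(n: int, verify: bool = True) -> Network:
    """Co-production couples all n sources into a single solution.

    Reaction r_prime turns (n-1) b into one of each c_1..c_n; each c_i
    plus source p_i yields the hub a, which either becomes the target or
    replenishes b.  Stoichiometric balance of the hub forces all n
    branches to run, so the only stoichiometric solution contains every
    source — although each singleton {p_i} is already a topological one.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    srcs = [f"p{i}" for i in range(1, n + 1)]
    cs = [f"c{i}" for i in range(1, n + 1)]
    reactions = [
        Reaction("r_a1", {"a": 1.0}, {"t": 1.0}),
        Reaction("r_a2", {"a": 1.0}, {"b": 1.0}),
        Reaction("r_prime", {"b": float(n - 1)}, {c: 1.0 for c in cs}),
    ]
    reactions += [
        Reaction(f"r{i}", {f"c{i}": 1.0, f"p{i}": 1.0}, {"a": 1.0})
        for i in range(1, n + 1)
    ]
    net = _net(["a", "b", "t"] + cs + srcs, reactions, set(srcs), {"t"})
    if verify:
        from .netcore import many_to_one
        from .topo import enumerate_mto_factories

        factories = enumerate_mto_factories(many_to_one(net))
        _check(len(factories) == n, "coupled_outputs: n minimal factories")
        _check(
            brute_force_minimal_sets(net, Mode.ACCUMULATE)
            == {frozenset(srcs)},
            "coupled_outputs: only solution uses every source",
        )
        _check(
            enumerate_minimal_tps(net)
            == {frozenset({p}) for p in srcs},
            "coupled_outputs: topological singletons",
        )
    return net


def make_random(
    n_compounds: int = 8,
    n_reactions: int = 12,
    max_subs: int = 2,
    max_prods: int = 2,
    coeff_choices: tuple[float, ...] = (1.0, 2.0),
    n_sources: int = 4,
    n_targets: int = 1,
    seed: int = 0,
    max_attempts: int = 200,
    max_mto_factories: Optional[int] = None,
) -> Network:
    """A seeded random hypergraph that provably admits a topological route.

    Rejection-samples networks until some source subset is a topological
    precursor set (checked with the factory enumerator), so property
    tests never waste time on trivially dead networks.  Deterministic
    for a given seed.  ``max_mto_factories`` additionally rejects
    networks whose many-to-one factory count exceeds the bound, keeping
    the exponential combinatorial enumerator usable in cross-checks.
    """
    if min(n_compounds, n_reactions, max_subs, max_prods, n_sources, n_targets) < 1:
        raise ValueError("all size parameters must be positive")
    if n_sources + n_targets > n_compounds:
        raise ValueError("more sources+targets than compounds")
    rng = random.Random(seed)
    for _ in range(max_attempts):
        ids = [f"m{i}" for i in range(n_compounds)]
        sources = set(ids[:n_sources])
        targets = set(ids[n_sources : n_sources + n_targets])
        internal = [c for c in ids if c not in sources]
        reactions = []
        for j in range(n_reactions):
            n_s = rng.randint(1, max_subs)
            subs = rng.sample(ids, n_s)
            pool = [c for c in internal if c not in subs]
            if not pool:
                continue
            n_p = rng.randint(1, min(max_prods, len(pool)))
            prods = rng.sample(pool, n_p)
            reactions.append(
                Reaction(
                    f"r{j}",
                    {c: rng.choice(coeff_choices) for c in subs},
                    {c: rng.choice(coeff_choices) for c in prods},
                )
            )
        try:
            net = normalize(_net(ids, reactions, sources, targets))
        except Exception:
            continue
        try:
            from .netcore import many_to_one
            from .topo import enumerate_mto_factories

            cap = 5000 if max_mto_factories is None else max_mto_factories
            factories = enumerate_mto_factories(many_to_one(net), max_factories=cap)
            if factories and (
                max_mto_factories is None or len(factories) <= max_mto_factories
            ):
                return net
        except Exception:
            continue
    raise FixtureError(
        f"could not draw a network with a topological route in {max_attempts} tries"
    )


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise FixtureError(f"fixture checklist failed: {message}")
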