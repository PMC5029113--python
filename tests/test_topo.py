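from itertools import chain, combinations

import pytest

from precursorsets import (
    Compound,
    Mode,
    Network,
    Reaction,
    check_s_factory,
    combi_enumerate,
    enumerate_minimal_sources,
    enumerate_minimal_tps,
    enumerate_mto_factories,
    find_path,
    is_topological_factory,
    many_to_one,
    validate_minimal_mto_factory,
)
from precursorsets.fixtures import (
    make_coupled_outputs,
    make_redundant_feeders,
)

from conftest import sets_of


def powerset(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, k) for k in range(len(items) + 1))


def brute_minimal_topo_factories(net):
    """Oracle: all minimal topological factories (footprint-inferred X)."""
    all_f = [frozenset(F) for F in powerset(net.reaction_ids)]

    def footprint_x(F):
        subs = set().union(*(set(net.reaction(r).substrates) for r in F)) if F else set()
        return frozenset(subs & net.sources)

    factories = {F for F in all_f if is_topological_factory(net, F, footprint_x(F))}
    minimal = set()
    for F in factories:
        X = footprint_x(F)
        if not any(
            G < F and is_topological_factory(net, G, X) for G in factories
        ):
            minimal.add(F)
    return minimal


class TestIsTopologicalFactory:
    def test_dual_route_examples(self, dual_route):
        assert is_topological_factory(dual_route, {"r1", "r3", "r4"}, {"p1"})
        assert not is_topological_factory(dual_route, {"r1", "r3"}, {"p1"})
        assert is_topological_factory(dual_route, {"r7", "r6", "r5"}, {"p3"})

    def test_empty_factory_when_targets_are_sources(self):
        net = Network(
            [Compound("s", role="source"), Compound("o")],
            [Reaction("r", {"s": 1.0}, {"o": 1.0})],
            {"s"},
            {"s"},
            allow_source_targets=True,
        )
        assert is_topological_factory(net, set(), {"s"})

    def test_empty_factory_fails_otherwise(self, cycle):
        assert not is_topological_factory(cycle, set(), {"p"})


class TestFindPath:
    def test_cycle_path(self, cycle):
        p = find_path(cycle, {"r1", "r2", "r3"}, "c", "t")
        assert p is not None
        assert p.metabolites == ("c", "b", "t")
        assert p.reactions == ("r2", "r3")

    def test_empty_path(self, cycle):
        p = find_path(cycle, {"r1"}, "t", "t")
        assert p.metabolites == ("t",) and p.reactions == ()

    def test_no_path(self, dual_route):
        assert find_path(dual_route, {"r8"}, "a", "t") is None

    def test_path_respects_restriction(self, dual_route):
        assert find_path(dual_route, {"r1", "r3"}, "p1", "t") is None
        assert find_path(dual_route, {"r1", "r3", "r4"}, "p1", "t") is not None


class TestValidateMinimalMtoFactory:
    def test_feeder_branch_is_minimal(self):
        net = many_to_one(make_redundant_feeders(4, verify=False))
        assert validate_minimal_mto_factory(net, {"r2", "r_a", "r_b", "r_t"})

    def test_missing_feeder_fails(self):
        net = many_to_one(make_redundant_feeders(4, verify=False))
        assert not validate_minimal_mto_factory(net, {"r_a", "r_b", "r_t"})

    def test_duplicate_producer_fails(self):
        net = many_to_one(make_redundant_feeders(4, verify=False))
        # both r2 and r3 produce c
        assert not validate_minimal_mto_factory(net, {"r2", "r3", "r_a", "r_b", "r_t"})

    def test_rejects_multi_product_input(self, dual_route):
        with pytest.raises(ValueError, match="many-to-one"):
            validate_minimal_mto_factory(dual_route, {"r3"})

    @pytest.mark.parametrize(
        "builder",
        [
            lambda: make_redundant_feeders(3, verify=False),
            lambda: make_coupled_outputs(3, verify=False),
        ],
    )
    def test_equivalent_to_brute_force_minimality(self, builder, cycle, dual_route):
        for base in (builder(), cycle, dual_route):
            net = many_to_one(base)
            oracle = brute_minimal_topo_factories(net)
            for F in powerset(net.reaction_ids):
                F = frozenset(F)
                assert validate_minimal_mto_factory(net, F) == (F in oracle), F


class TestEnumerateMtoFactories:
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_feeders_count(self, n):
        net = many_to_one(make_redundant_feeders(n, verify=False))
        factories = enumerate_mto_factories(net)
        assert len(factories) == n
        assert {f.reactions for f in factories} == {frozenset({"r1"})} | {
            frozenset({"r_t", "r_a", "r_b", f"r{i}"}) for i in range(2, n + 1)
        }

    @pytest.mark.parametrize("n", [2, 4])
    def test_coupled_count(self, n):
        net = many_to_one(make_coupled_outputs(n, verify=False))
        factories = enumerate_mto_factories(net)
        assert len(factories) == n
        for f in factories:
            assert {"r_a1", "r_a2"} <= f.reactions
            assert any(r.startswith("r_prime_") for r in f.reactions)

    def test_matches_brute_force_oracle(self, dual_route, cycle):
        for base in (dual_route, cycle):
            net = many_to_one(base)
            got = {f.reactions for f in enumerate_mto_factories(net)}
            assert got == brute_minimal_topo_factories(net)

    def test_footprints_are_recorded(self, dual_route):
        net = many_to_one(dual_route)
        for f in enumerate_mto_factories(net):
            subs = set().union(
                *(set(net.reaction(r).substrates) for r in f.reactions)
            )
            assert f.source_footprint == subs & net.sources


class TestEnumerateMinimalTps:
    def test_dual_route(self, dual_route):
        assert enumerate_minimal_tps(dual_route) == {
            frozenset({"p1"}),
            frozenset({"p3"}),
        }

    def test_cycle(self, cycle):
        assert enumerate_minimal_tps(cycle) == {frozenset({"p"})}

    @pytest.mark.parametrize("n", [2, 4])
    def test_coupled_singletons(self, n):
        net = make_coupled_outputs(n, verify=False)
        assert enumerate_minimal_tps(net) == {
            frozenset({f"p{i}"}) for i in range(1, n + 1)
        }

    def test_every_sps_is_a_tps(self, dual_route, cycle, feeders5):
        for net in (dual_route, cycle, feeders5):
            tps = enumerate_minimal_tps(net)
            for sps in sets_of(enumerate_minimal_sources(net)):
                assert any(t <= sps for t in tps)

    def test_tps_not_sps_witness(self, dual_route):
        # {p3} is producible topologically but not stoichiometrically
        assert frozenset({"p3"}) in enumerate_minimal_tps(dual_route)
        assert frozenset({"p3"}) not in sets_of(enumerate_minimal_sources(dual_route))


class TestCombiEnumerate:
    def test_dual_route(self, dual_route):
        res = combi_enumerate(dual_route)
        assert sets_of(res) == {frozenset({"p1"}), frozenset({"p2", "p3"})}

    def test_feeders_found_at_k1(self, feeders5):
        res = combi_enumerate(feeders5)
        assert sets_of(res) == {frozenset({"p1"})}
        assert [s["k"] for s in res.solutions] == [1]

    def test_coupled_found_only_at_kn(self, coupled4):
        res = combi_enumerate(coupled4)
        assert sets_of(res) == {frozenset({"p1", "p2", "p3", "p4"})}
        assert [s["k"] for s in res.solutions] == [4]

    def test_agrees_with_milp_on_fixtures(
        self, dual_route, cycle, feeders5, coupled4, any_mode
    ):
        for net in (dual_route, cycle, feeders5, coupled4):
            assert sets_of(combi_enumerate(net, mode=any_mode)) == sets_of(
                enumerate_minimal_sources(net, mode=any_mode)
            )


class TestDecomposition:
    """Every minimal stoichiometric factory is covered by minimal
    topological factories of the many-to-one network contained in its
    own image."""

    def brute_minimal_s_factories(self, net):
        out = set()
        feasible = {}
        for F in powerset(net.reaction_ids):
            F = frozenset(F)
            if not F:
                continue
            subs = set().union(*(set(net.reaction(r).substrates) for r in F))
            X = frozenset(subs & net.sources)
            feasible[F] = (X, check_s_factory(net, F, X).feasible)
        for F, (X, ok) in feasible.items():
            if not ok:
                continue
            if not any(
                G < F and check_s_factory(net, G, X).feasible
                for G in feasible
                if G < F
            ):
                out.add(F)
        return out

    @pytest.mark.parametrize(
        "builder",
        [
            lambda: make_redundant_feeders(3, verify=False),
            lambda: make_coupled_outputs(3, verify=False),
        ],
        ids=["feeders3", "coupled3"],
    )
    def test_exhaustive_on_parametric_fixtures(self, builder):
        self._check(builder())

    def test_exhaustive_on_cycle_and_dual_route(self, cycle, dual_route):
        self._check(cycle)
        self._check(dual_route)

    def _check(self, net):
        mto = many_to_one(net)
        psi = {}  # original reaction id -> its copies in the mto network
        for r in mto.reactions:
            parent = r.id
            if r.origin and r.origin.startswith("mto of "):
                parent = r.origin[len("mto of "):].split(" for product ")[0]
            psi.setdefault(parent, set()).add(r.id)
        topo_factories = [f.reactions for f in enumerate_mto_factories(mto)]
        checked = 0
        for H in self.brute_minimal_s_factories(net):
            image = set().union(*(psi[r] for r in H))
            inside = [F for F in topo_factories if F <= image]
            assert inside, f"no topological factory inside the image of {sorted(H)}"
            union = set().union(*inside)
            for r in H:
                assert union & psi[r], (
                    f"reaction {r} of factory {sorted(H)} uncovered"
                )
            checked += 1
        assert checked > 0
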