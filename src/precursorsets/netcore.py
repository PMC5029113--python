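"""Network data model and structural transformations.

A metabolic network is a directed hypergraph: compounds are vertices,
irreversible reactions are hyperarcs carrying positive stoichiometric
coefficients on both sides.  This module owns the data model plus the
purely structural transformations every other module builds on:

* :func:`normalize` — split reversible reactions and isolate sources so
  that no reaction produces a source compound;
* :func:`build_matrix` — assemble the sparse stoichiometric matrix
  (products positive, substrates negative);
* :func:`many_to_one` — replace each multi-product reaction by one
  single-product copy per product;
* :func:`augment` — add source-pool reactions and/or a pooled target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse

__all__ = [
    "Compound",
    "Reaction",
    "Network",
    "StoichiometricMatrix",
    "AugmentedNetwork",
    "NetworkError",
    "normalize",
    "build_matrix",
    "many_to_one",
    "augment",
]


class NetworkError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class Compound:
    """A metabolic compound (a vertex of the hypergraph)."""

    id: str
    name: Optional[str] = None
    role: str = "internal"  # internal | source | target

    def __post_init__(self) -> None:
        if self.role not in ("internal", "source", "target"):
            raise NetworkError(f"invalid compound role {self.role!r} for {self.id!r}")


@dataclass(frozen=True)
class Reaction:
    """An irreversible reaction (a hyperarc).

    ``substrates`` and ``products`` map compound id -> strictly positive
    coefficient and must be disjoint: a compound may not appear on both
    sides of one reaction.
    """

    id: str
    substrates: Mapping[str, float]
    products: Mapping[str, float]
    reversible: bool = False
    origin: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", dict(self.substrates))
        object.__setattr__(self, "products", dict(self.products))
        for side, coeffs in (("substrate", self.substrates), ("product", self.products)):
            for cid, coeff in coeffs.items():
                if not coeff > 0:
                    raise NetworkError(
                        f"reaction {self.id!r}: {side} coefficient of {cid!r} "
                        f"must be > 0, got {coeff!r}"
                    )
        both = set(self.substrates) & set(self.products)
        if both:
            raise NetworkError(
                f"reaction {self.id!r}: compounds {sorted(both)} appear on both sides"
            )


@dataclass
class Network:
    """A metabolic network with designated source and target compounds."""

    compounds: list[Compound]
    reactions: list[Reaction]
    sources: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    allow_source_targets: bool = False

    def __post_init__(self) -> None:
        self.sources = set(self.sources)
        self.targets = set(self.targets)
        self.validate()

    # -- introspection -------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def producers_of(self, cid: str) -> list[Reaction]:
        return [r for r in self.reactions if cid in r.products]

    def consumers_of(self, cid: str) -> list[Reaction]:
        return [r for r in self.reactions if cid in r.substrates]

    def validate(self) -> None:
        ids = self.compound_ids
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate compound ids: {dup}")
        rids = self.reaction_ids
        if len(rids) != len(set(rids)):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids: {dup}")
        known = set(ids)
        for r in self.reactions:
            unknown = (set(r.substrates) | set(r.products)) - known
            if unknown:
                raise NetworkError(
                    f"reaction {r.id!r} references unknown compounds: {sorted(unknown)}"
                )
            # zero-substrate reactions would make the empty set a trivial
            # precursor set; only pool reactions added by augment() may do that
            if not r.substrates and not (r.origin and "pool" in r.origin):
                raise NetworkError(
                    f"reaction {r.id!r} has no substrates; free production is "
                    "reserved for pool reactions created by augment()"
                )
        for cid in sorted(self.sources | self.targets):
            if cid not in known:
                raise NetworkError(f"source/target {cid!r} is not a compound")
        overlap = self.sources & self.targets
        if overlap and not self.allow_source_targets:
            raise NetworkError(
                f"compounds {sorted(overlap)} are both source and target "
                "(set allow_source_targets=True to permit)"
            )

    def copy(self) -> "Network":
        return Network(
            compounds=list(self.compounds),
            reactions=list(self.reactions),
            sources=set(self.sources),
            targets=set(self.targets),
            allow_source_targets=self.allow_source_targets,
        )


@dataclass
class StoichiometricMatrix:
    """Sparse compounds x reactions coefficient matrix.

    Entry (i, j) is the net coefficient of compound i in reaction j:
    positive for products, negative for substrates.  Row/column order is
    the stable input order of the network.
    """

    rows: list[str]
    cols: list[str]
    matrix: sparse.csc_matrix

    def row_index(self, cid: str) -> int:
        return self.rows.index(cid)

    def net_production(self, flux: Mapping[str, float]) -> dict[str, float]:
        """S @ v as a compound-id keyed dict; missing fluxes count as 0."""
        v = np.array([flux.get(rid, 0.0) for rid in self.cols])
        sv = self.matrix @ v
        return dict(zip(self.rows, sv.tolist()))

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class AugmentedNetwork:
    """A network plus source-pool reactions and/or a pooled target.

    ``source_pool_reactions`` maps each source id to the id of its pool
    reaction (no substrates, single unit product).  ``pooled_target``,
    when present, is the (new compound id, collector reaction id) pair
    where the collector consumes one unit of every target.
    """

    network: Network
    source_pool_reactions: dict[str, str] = field(default_factory=dict)
    pooled_target: Optional[tuple[str, str]] = None


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------


def _fresh_id(base: str, taken: set[str]) -> str:
    if base not in taken:
        return base
    k = 2
    while f"{base}_{k}" in taken:
        k += 1
    return f"{base}_{k}"


def normalize(network: Network) -> Network:
    """Return an equivalent network with only irreversible reactions and
    with no reaction producing a source compound.

    Reversible reactions are split into ``<id>_fwd`` / ``<id>_rev``.  A
    source ``x`` that is produced by some reaction is replaced as a
    source by a fresh compound ``x_src`` together with a unit reaction
    ``r_src_x: x_src -> x``; producing ``x`` internally then no longer
    short-circuits the availability of the source.  Idempotent.
    """
    compounds = list(network.compounds)
    reactions: list[Reaction] = []
    taken_r = set(network.reaction_ids)
    for r in network.reactions:
        if r.reversible:
            fwd = _fresh_id(f"{r.id}_fwd", taken_r)
            taken_r.add(fwd)
            rev = _fresh_id(f"{r.id}_rev", taken_r)
            taken_r.add(rev)
            reactions.append(
                Reaction(fwd, r.substrates, r.products, origin=f"fwd of {r.id}")
            )
            reactions.append(
                Reaction(rev, r.products, r.substrates, origin=f"rev of {r.id}")
            )
        else:
            reactions.append(r)

    sources = set(network.sources)
    produced = {cid for r in reactions for cid in r.products}
    taken_c = {c.id for c in compounds}
    for x in sorted(sources & produced):
        dummy = _fresh_id(f"{x}_src", taken_c)
        taken_c.add(dummy)
        rid = _fresh_id(f"r_src_{x}", taken_r)
        taken_r.add(rid)
        compounds.append(Compound(dummy, role="source"))
        reactions.append(
            Reaction(rid, {dummy: 1.0}, {x: 1.0}, origin=f"source isolation of {x}")
        )
        sources.discard(x)
        sources.add(dummy)

    return Network(
        compounds=compounds,
        reactions=reactions,
        sources=sources,
        targets=set(network.targets),
        allow_source_targets=network.allow_source_targets,
    )


def build_matrix(network: Network, extra_reactions: Iterable[Reaction] = ()) -> StoichiometricMatrix:
    """Assemble the sparse stoichiometric matrix of ``network``.

    ``extra_reactions`` (e.g. pool reactions referencing an extra
    compound appended to ``network.compounds``) are placed after the
    network's own columns in the given order.
    """
    rows = network.compound_ids
    ridx = {cid: i for i, cid in enumerate(rows)}
    all_reactions = list(network.reactions) + list(extra_reactions)
    cols = [r.id for r in all_reactions]
    data: list[float] = []
    ii: list[int] = []
    jj: list[int] = []
    for j, r in enumerate(all_reactions):
        for cid, coeff in r.substrates.items():
            ii.append(ridx[cid])
            jj.append(j)
            data.append(-coeff)
        for cid, coeff in r.products.items():
            ii.append(ridx[cid])
            jj.append(j)
            data.append(coeff)
    mat = sparse.csc_matrix(
        (data, (ii, jj)), shape=(len(rows), len(cols)), dtype=float
    )
    return StoichiometricMatrix(rows=rows, cols=cols, matrix=mat)


def many_to_one(network: Network) -> Network:
    """Split every multi-product reaction into one copy per product.

    A reaction ``r`` with products ``{a: ca, b: cb}`` becomes ``r_a``
    (same substrates, product ``a`` only) and ``r_b``; single-product
    reactions are kept unchanged, so the transform is idempotent.  The
    origin tag of each copy records the parent reaction id.
    """
    reactions: list[Reaction] = []
    taken = {r.id for r in network.reactions if len(r.products) <= 1}
    for r in network.reactions:
        if not r.products:
            warnings.warn(
                f"reaction {r.id!r} has no products; copied unchanged by many_to_one",
                stacklevel=2,
            )
        if len(r.products) <= 1:
            reactions.append(r)
            continue
        for a in r.products:  # dict order == input order
            rid = _fresh_id(f"{r.id}_{a}", taken)
            taken.add(rid)
            reactions.append(
                Reaction(
                    rid,
                    r.substrates,
                    {a: r.products[a]},
                    origin=f"mto of {r.id} for product {a}",
                )
            )
    return Network(
        compounds=list(network.compounds),
        reactions=reactions,
        sources=set(network.sources),
        targets=set(network.targets),
        allow_source_targets=network.allow_source_targets,
    )


def mto_parent(reaction: Reaction) -> Optional[str]:
    """Parent reaction id recorded by :func:`many_to_one`, if any."""
    if reaction.origin and reaction.origin.startswith("mto of "):
        return reaction.origin[len("mto of "):].split(" for product ")[0]
    return None


def mto_parent_map(transformed: Network) -> dict[str, str]:
    """Map each reaction id of a many-to-one network to its original id."""
    return {r.id: (mto_parent(r) or r.id) for r in transformed.reactions}


def augment(
    network: Network, pool_sources: bool = True, pool_target: bool = False
) -> AugmentedNetwork:
    """Add source-pool reactions and/or a pooled-target collector.

    Pool reaction for source ``x``: no substrates, one unit of ``x``
    (id ``pool_x``).  The pooled target is a fresh compound ``t_pool``
    plus the collector ``r_pool_t`` consuming one unit of every target.
    The input network is not modified.
    """
    net = network.copy()
    pools: dict[str, str] = {}
    pooled: Optional[tuple[str, str]] = None
    taken_r = set(net.reaction_ids)
    taken_c = set(net.compound_ids)
    if pool_sources:
        for x in sorted(net.sources):
            rid = _fresh_id(f"pool_{x}", taken_r)
            taken_r.add(rid)
            net.reactions.append(
                Reaction(rid, {}, {x: 1.0}, origin=f"source pool of {x}")
            )
            pools[x] = rid
    if pool_target:
        if not net.targets:
            raise NetworkError("cannot pool an empty target set")
        overlap = net.targets & net.sources
        if overlap and not net.allow_source_targets:
            raise NetworkError(
                f"targets {sorted(overlap)} are also sources; refusing to pool"
            )
        tbar = _fresh_id("t_pool", taken_c)
        rid = _fresh_id("r_pool_t", taken_r)
        net.compounds.append(Compound(tbar, role="target"))
        net.reactions.append(
            Reaction(
                rid,
                {t: 1.0 for t in sorted(net.targets)},
                {tbar: 1.0},
                origin="target pool",
            )
        )
        pooled = (tbar, rid)
    net.validate()
    return AugmentedNetwork(
        network=net, source_pool_reactions=pools, pooled_target=pooled
    )
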