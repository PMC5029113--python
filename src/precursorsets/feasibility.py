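"""LP/MILP decision oracles for precursor-set and factory feasibility.

The central question — "can source subset X drive a strictly positive
production of every target?" — reduces to a linear program: maximise the
net production of a pooled target subject to nonnegative (accumulating
mode) or zero (steady-state mode) net production of every non-source
compound.  X is a stoichiometric precursor set iff the optimum is
strictly positive.

The machinery-duplicating variant additionally requires strictly
positive net production of every consumed non-source compound, which is
disjunctive and therefore decided by a small MILP (delegated to
:mod:`precursorsets.milp_enum`).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .netcore import Network, augment, build_matrix

__all__ = [
    "Mode",
    "SolverConfig",
    "FluxAssignment",
    "Certificate",
    "SolverError",
    "InfeasibleInputError",
    "check_sps",
    "check_s_factory",
    "check_md_sps",
    "check_scs",
    "reduce_to_minimal",
    "brute_force_minimal_sets",
    "is_feasible_source_set",
]


class Mode(enum.Enum):
    """Feasibility model for intermediate compounds."""

    ACCUMULATE = "accumulate"
    STEADY_STATE = "steady-state"
    MACHINERY_DUPLICATING = "md"

    @classmethod
    def from_string(cls, s: str) -> "Mode":
        for m in cls:
            if m.value == s or m.name.lower() == s.lower():
                return m
        raise ValueError(f"unknown mode {s!r}")


@dataclass
class SolverConfig:
    """Numeric constants and limits shared by all solvers.

    ``epsilon`` is the strict-positivity surrogate for target
    production, ``eps_bar`` the one for the machinery-duplicating net
    production, ``U`` the per-flux upper bound, ``delta`` the minimum
    flux forced on declared factory members, ``support_tol`` the
    threshold above which a flux counts as active.
    """

    epsilon: float = 0.5
    eps_bar: float = 0.5
    U: float = 1000.0
    delta: float = 1e-3
    support_tol: float = 1e-6
    mode: Mode = Mode.ACCUMULATE
    time_limit: Optional[float] = None
    max_solutions: Optional[int] = None
    mip_gap: float = 1e-6
    seed: int = 0
    target_level_max: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.mode, str):
            self.mode = Mode.from_string(self.mode)
        if not (0 < self.epsilon <= self.U):
            raise ValueError("require 0 < epsilon <= U")
        if not (0 < self.eps_bar <= self.U):
            raise ValueError("require 0 < eps_bar <= U")
        if not self.U > 1:
            raise ValueError("require U > 1")

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "eps_bar": self.eps_bar,
            "U": self.U,
            "delta": self.delta,
            "support_tol": self.support_tol,
            "mode": self.mode.value,
            "time_limit": self.time_limit,
            "max_solutions": self.max_solutions,
            "seed": self.seed,
        }


@dataclass
class FluxAssignment:
    """A nonnegative flux vector keyed by reaction id."""

    values: dict[str, float]
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        bad = {r: v for r, v in self.values.items() if v < -self.tolerance}
        if bad:
            raise ValueError(f"negative fluxes: {bad}")
        self.values = {r: max(v, 0.0) for r, v in self.values.items()}

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, v in self.values.items() if v > self.tolerance)


@dataclass
class Certificate:
    """Outcome of a feasibility check, with witness when feasible."""

    feasible: bool
    flux: Optional[FluxAssignment] = None
    active_reactions: frozenset[str] = frozenset()
    objective: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "feasible": self.feasible,
                "flux": self.flux.values if self.flux else None,
                "active_reactions": sorted(self.active_reactions),
                "objective": self.objective,
            },
            sort_keys=True,
        )


class SolverError(RuntimeError):
    """LP/MILP backend failed in a way that is not plain infeasibility."""


class InfeasibleInputError(ValueError):
    """An operation requiring a feasible source set got an infeasible one."""


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------


def _mode_row_kinds(
    net: Network, X: frozenset[str], mode: Mode, extra_free: frozenset[str] = frozenset()
) -> dict[str, str]:
    """Classify each compound row: 'free', 'ge' (>=0) or 'eq' (=0).

    Source rows in X are unconstrained (drawn from the environment).
    Under STEADY_STATE the zero-accumulation equality applies to every
    compound that is neither in X nor a target; targets keep >=.
    """
    kinds: dict[str, str] = {}
    for cid in net.compound_ids:
        if cid in X or cid in extra_free:
            kinds[cid] = "free"
        elif mode is Mode.STEADY_STATE and cid not in net.targets:
            kinds[cid] = "eq"
        else:
            kinds[cid] = "ge"
    return kinds


def _solve_lp(
    c: np.ndarray,
    A_ub: Optional[sparse.spmatrix],
    b_ub: Optional[np.ndarray],
    A_eq: Optional[sparse.spmatrix],
    b_eq: Optional[np.ndarray],
    bounds: list[tuple[float, float]],
) -> tuple[bool, Optional[np.ndarray], Optional[float]]:
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    if res.status == 2:  # infeasible
        return False, None, None
    if res.status != 0:
        raise SolverError(f"linprog failed with status {res.status}: {res.message}")
    return True, res.x, res.fun


def check_sps(
    network: Network,
    X: Iterable[str],
    mode: Mode = Mode.ACCUMULATE,
    config: Optional[SolverConfig] = None,
) -> Certificate:
    """Decide whether source subset ``X`` is a (stoichiometric) precursor set.

    Builds the pooled-target augmentation and maximises the pooled
    target's net production subject to the mode's row constraints and
    ``0 <= v <= U``.  ``X`` is a precursor set iff the optimum exceeds
    the support tolerance; the witness flux and its support (an
    S-factory) are returned.  MACHINERY_DUPLICATING delegates to
    :func:`check_md_sps`.
    """
    config = config or SolverConfig()
    X = frozenset(X)
    unknown = X - set(network.sources)
    if unknown:
        raise ValueError(f"not source compounds: {sorted(unknown)}")
    if mode is Mode.MACHINERY_DUPLICATING:
        return check_md_sps(network, X, config)

    aug = augment(network, pool_sources=False, pool_target=True)
    net = aug.network
    tbar, _ = aug.pooled_target
    sm = build_matrix(net)
    S = sm.matrix
    n = S.shape[1]

    # pooled-target compound row stays 'ge' even under steady state: it is
    # the quantity being maximised, not an intermediate
    kinds = _mode_row_kinds(net, X, mode)
    kinds[tbar] = "ge"

    rows_ge = [i for i, cid in enumerate(sm.rows) if kinds[cid] == "ge"]
    rows_eq = [i for i, cid in enumerate(sm.rows) if kinds[cid] == "eq"]
    A_ub = (-S[rows_ge, :]).tocsr() if rows_ge else None
    b_ub = np.zeros(len(rows_ge)) if rows_ge else None
    A_eq = S[rows_eq, :].tocsr() if rows_eq else None
    b_eq = np.zeros(len(rows_eq)) if rows_eq else None

    c = np.zeros(n)
    t_row = sm.row_index(tbar)
    c -= np.asarray(S[t_row, :].todense()).ravel()  # maximise (Sv)_tbar
    bounds = [(0.0, config.U)] * n

    ok, x, fun = _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if not ok:
        # row constraints at v=0 are satisfiable, so this cannot happen
        raise SolverError("membership LP unexpectedly infeasible")
    objective = -fun
    if objective <= config.support_tol:
        return Certificate(feasible=False, objective=objective)
    flux = FluxAssignment(
        dict(zip(sm.cols, x.tolist())), tolerance=config.support_tol
    )
    _verify_flux(network, flux, X, mode, config)
    support = frozenset(flux.support) - {aug.pooled_target[1]}
    return Certificate(
        feasible=True, flux=flux, active_reactions=support, objective=objective
    )


def check_s_factory(
    network: Network,
    F: Iterable[str],
    X: Iterable[str],
    mode: Mode = Mode.ACCUMULATE,
    config: Optional[SolverConfig] = None,
) -> Certificate:
    """Decide whether reaction set ``F`` is a factory from ``X`` to the targets.

    Feasibility LP: ``delta <= v_i <= U`` for i in F, ``v_i = 0``
    otherwise, the mode's row constraints on non-source compounds, and
    net target production >= epsilon.
    """
    config = config or SolverConfig()
    F = frozenset(F)
    X = frozenset(X)
    unknown = F - set(network.reaction_ids)
    if unknown:
        raise ValueError(f"not reactions of the network: {sorted(unknown)}")
    sm = build_matrix(network)
    S = sm.matrix
    n = S.shape[1]
    kinds = _mode_row_kinds(network, X, mode)

    rows_ge, b_ge = [], []
    rows_eq = []
    for i, cid in enumerate(sm.rows):
        if kinds[cid] == "eq":
            rows_eq.append(i)
        elif kinds[cid] == "ge":
            rows_ge.append(i)
            b_ge.append(config.epsilon if cid in network.targets else 0.0)
    A_ub = (-S[rows_ge, :]).tocsr() if rows_ge else None
    b_ub = -np.array(b_ge) if rows_ge else None
    A_eq = S[rows_eq, :].tocsr() if rows_eq else None
    b_eq = np.zeros(len(rows_eq)) if rows_eq else None
    bounds = [
        (config.delta, config.U) if rid in F else (0.0, 0.0) for rid in sm.cols
    ]
    ok, x, _ = _solve_lp(np.zeros(n), A_ub, b_ub, A_eq, b_eq, bounds)
    if not ok:
        return Certificate(feasible=False)
    flux = FluxAssignment(dict(zip(sm.cols, x.tolist())), tolerance=config.support_tol)
    _verify_flux(network, flux, X, mode, config)
    return Certificate(feasible=True, flux=flux, active_reactions=frozenset(F))


def check_md_sps(
    network: Network,
    X: Iterable[str],
    config: Optional[SolverConfig] = None,
) -> Certificate:
    """Decide whether ``X`` admits a machinery-duplicating factory.

    Solved as the enumeration MILP restricted to sources within ``X``
    (the per-compound disjunction "positive net production or no
    consumption" needs binary variables).
    """
    from .milp_enum import solve_restricted  # deferred: avoids import cycle

    config = config or SolverConfig()
    X = frozenset(X)
    unknown = X - set(network.sources)
    if unknown:
        raise ValueError(f"not source compounds: {sorted(unknown)}")
    sol = solve_restricted(network, X, Mode.MACHINERY_DUPLICATING, config)
    if sol is None:
        return Certificate(feasible=False)
    _verify_flux(network, sol.flux, X, Mode.MACHINERY_DUPLICATING, config)
    return Certificate(
        feasible=True,
        flux=sol.flux,
        active_reactions=sol.flux.support & set(network.reaction_ids),
    )


def is_feasible_source_set(
    network: Network,
    X: Iterable[str],
    mode: Mode,
    config: Optional[SolverConfig] = None,
) -> bool:
    """Mode-dispatching convenience wrapper around the membership oracles."""
    if mode is Mode.MACHINERY_DUPLICATING:
        return check_md_sps(network, X, config).feasible
    return check_sps(network, X, mode, config).feasible


def check_scs(
    network: Network,
    X: Iterable[str],
    mode: Mode = Mode.ACCUMULATE,
    config: Optional[SolverConfig] = None,
) -> bool:
    """Is ``X`` a cut set, i.e. is the complement of ``X`` not a precursor set?"""
    complement = frozenset(network.sources) - frozenset(X)
    return not is_feasible_source_set(network, complement, mode, config)


def reduce_to_minimal(
    network: Network,
    X: Iterable[str],
    mode: Mode = Mode.ACCUMULATE,
    config: Optional[SolverConfig] = None,
) -> frozenset[str]:
    """Greedily shrink a feasible source set to an inclusion-minimal one.

    Candidates are dropped in lexicographic id order, so the result is
    deterministic.  Raises :class:`InfeasibleInputError` if ``X`` itself
    is not feasible.
    """
    X = frozenset(X)
    if not is_feasible_source_set(network, X, mode, config):
        raise InfeasibleInputError(f"{sorted(X)} is not a feasible source set")
    current = set(X)
    for x in sorted(X):
        trial = current - {x}
        if is_feasible_source_set(network, trial, mode, config):
            current = trial
    return frozenset(current)


def brute_force_minimal_sets(
    network: Network,
    mode: Mode = Mode.ACCUMULATE,
    config: Optional[SolverConfig] = None,
) -> set[frozenset[str]]:
    """All inclusion-minimal feasible source sets, by exhaustive search.

    Walks subsets of the source set in order of increasing cardinality;
    supersets of already-found solutions are skipped (feasibility is
    monotone, so they cannot be minimal).  Exponential — intended as an
    independent oracle for networks with few sources.
    """
    from itertools import combinations

    sources = sorted(network.sources)
    found: set[frozenset[str]] = set()
    for k in range(len(sources) + 1):
        for combo in combinations(sources, k):
            X = frozenset(combo)
            if any(sol <= X for sol in found):
                continue
            if is_feasible_source_set(network, X, mode, config):
                found.add(X)
    return found


# ---------------------------------------------------------------------------
# certificate verification
# ---------------------------------------------------------------------------


def _verify_flux(
    network: Network,
    flux: FluxAssignment,
    X: frozenset[str],
    mode: Mode,
    config: SolverConfig,
) -> None:
    """Re-check a witness flux against the raw constraint system.

    Guards against silently accepting a numerically drifted solver
    answer; tolerance is proportional to the flux scale.
    """
    sm = build_matrix(network)
    net_prod = sm.net_production(flux.values)
    scale = max(1.0, max(abs(v) for v in flux.values.values()) if flux.values else 1.0)
    tol = 1e-6 * scale
    support = flux.support & set(network.reaction_ids)
    consumed = {
        cid
        for rid in support
        for cid in network.reaction(rid).substrates
    }
    for cid in network.compound_ids:
        if cid in X:
            continue
        v = net_prod[cid]
        if mode is Mode.STEADY_STATE and cid not in network.targets:
            if abs(v) > tol:
                raise SolverError(
                    f"witness violates steady state at {cid!r}: net {v:g}"
                )
        elif v < -tol:
            raise SolverError(
                f"witness violates nonnegativity at {cid!r}: net {v:g}"
            )
        if (
            mode is Mode.MACHINERY_DUPLICATING
            and cid in consumed
            and v < config.eps_bar - tol
        ):
            raise SolverError(
                f"witness violates strict production of consumed compound {cid!r}"
            )
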