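"""Exhaustive enumeration of minimal precursor sets by iterated MILP.

One binary ``b_j`` per source marks whether its pool reaction is used;
the MILP minimises ``sum b_j`` subject to the mode's stoichiometric row
constraints and the linking rows ``b_j <= v_j <= U b_j`` (a chosen
source must supply at least one unit).  Each optimum is an
inclusion-minimal precursor set; an exclusion cut
``sum_{j in support} b_j <= |support| - 1`` removes it and all its
supersets, and the loop repeats until the MILP becomes infeasible, at
which point the antichain of all minimal solutions has been produced.

Machinery-duplicating runs add, per non-source compound ``j``, a binary
``E_j`` and the big-M rows encoding "net production of j >= eps_bar, or
every consumer of j carries zero flux".
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .feasibility import (
    Certificate,
    FluxAssignment,
    Mode,
    SolverConfig,
    SolverError,
    reduce_to_minimal,
)
from .netcore import Network, augment, build_matrix

__all__ = [
    "MilpSolution",
    "EnumerationResult",
    "solve_one",
    "solve_restricted",
    "enumerate_minimal_sources",
]


@dataclass
class MilpSolution:
    """One optimum of the source-selection MILP."""

    chosen_sources: frozenset[str]
    flux: FluxAssignment
    objective: int


@dataclass
class EnumerationResult:
    """The full antichain of minimal solutions plus run metadata."""

    solutions: list[dict]  # {"sources": [...], "flux": {...}, "support": [...]}
    mode: Mode
    config: SolverConfig
    iterations: int = 0
    terminated_reason: str = "exhausted"
    algorithm: str = "milp"
    wall_time: float = 0.0

    @property
    def source_sets(self) -> set[frozenset[str]]:
        return {frozenset(sol["sources"]) for sol in self.solutions}

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "algorithm": self.algorithm,
            "config": self.config.to_dict(),
            "solutions": self.solutions,
            "iterations": self.iterations,
            "terminated_reason": self.terminated_reason,
            "wall_time": self.wall_time,
        }

    def to_tsv(self) -> str:
        """One solution per line, sources comma-joined, canonically sorted."""
        lines = ["n_sources\tsources"]
        rows = sorted(
            (len(s["sources"]), ",".join(sorted(s["sources"]))) for s in self.solutions
        )
        for n, joined in rows:
            lines.append(f"{n}\t{joined}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


class _MilpModel:
    """Matrix-form MILP over variables [v (all reactions + pools), b, (E)]."""

    def __init__(self, network: Network, mode: Mode, config: SolverConfig):
        self.network = network
        self.mode = mode
        self.config = config
        aug = augment(network, pool_sources=True, pool_target=False)
        self.aug = aug
        self.sm = build_matrix(aug.network)
        self.n_flux = len(self.sm.cols)
        self.sources = sorted(network.sources)
        self.pool_col = {
            x: self.sm.cols.index(rid) for x, rid in aug.source_pool_reactions.items()
        }
        self.b_index = {x: self.n_flux + i for i, x in enumerate(self.sources)}
        self.n_b = len(self.sources)
        self.n_E = 0
        self.E_index: dict[str, int] = {}
        if mode is Mode.MACHINERY_DUPLICATING:
            non_sources = [c for c in network.compound_ids if c not in network.sources]
            self.E_index = {
                c: self.n_flux + self.n_b + i for i, c in enumerate(non_sources)
            }
            self.n_E = len(non_sources)
        self.n_var = self.n_flux + self.n_b + self.n_E
        self.constraints: list[LinearConstraint] = []
        self._build_rows()

    def _row(self) -> np.ndarray:
        return np.zeros(self.n_var)

    def _build_rows(self) -> None:
        net = self.aug.network
        base = self.network
        S = self.sm.matrix
        U = self.config.U
        eps = self.config.epsilon
        lb = []
        ub = []
        rows = []
        for i, cid in enumerate(self.sm.rows):
            srow = self._row()
            srow[: self.n_flux] = S[i, :].toarray().ravel()
            rows.append(srow)
            if cid in base.targets:
                lb.append(eps)
                ub.append(np.inf)
            elif (
                self.mode is Mode.STEADY_STATE
                and cid not in base.sources
            ):
                lb.append(0.0)
                ub.append(0.0)
            else:
                # accumulate rows, and source rows in pooled form
                lb.append(0.0)
                ub.append(np.inf)
        self.constraints.append(
            LinearConstraint(np.vstack(rows), np.array(lb), np.array(ub))
        )

        # linking rows: b_j <= v_poolj  and  v_poolj <= U * b_j
        link_rows: list[np.ndarray] = []
        for x in self.sources:
            r1 = self._row()
            r1[self.b_index[x]] = 1.0
            r1[self.pool_col[x]] = -1.0
            link_rows.append(r1)  # b - v <= 0
            r2 = self._row()
            r2[self.pool_col[x]] = 1.0
            r2[self.b_index[x]] = -U
            link_rows.append(r2)  # v - U b <= 0
        if link_rows:
            self.constraints.append(
                LinearConstraint(np.vstack(link_rows), -np.inf, 0.0)
            )

        if self.mode is Mode.MACHINERY_DUPLICATING:
            self._add_md_rows()

    def _add_md_rows(self) -> None:
        """Big-M rows for the per-compound disjunction.

        For non-source j with consumers Q_j (pool reactions have no
        substrates, so only real reactions appear):
            (Sv)_j >= eps_bar - D_j * E_j
            sum_{i in Q_j} v_i <= D_j * (1 - E_j)
        with D_j = U * |Q_j| (or eps_bar when Q_j is empty, in which case
        the first row is vacuously relaxable via E_j = 1).
        """
        S = self.sm.matrix
        U = self.config.U
        eps_bar = self.config.eps_bar
        rows = []
        lbs = []
        ubs = []
        for cid, eidx in self.E_index.items():
            i = self.sm.row_index(cid)
            consumers = [
                j
                for j, rid in enumerate(self.sm.cols)
                if rid in {r.id for r in self.network.consumers_of(cid)}
            ]
            D = U * len(consumers) if consumers else eps_bar
            r1 = self._row()
            r1[: self.n_flux] = S[i, :].toarray().ravel()
            r1[eidx] = D
            rows.append(r1)  # (Sv)_j + D E_j >= eps_bar
            lbs.append(eps_bar)
            ubs.append(np.inf)
            if consumers:
                r2 = self._row()
                for j in consumers:
                    r2[j] = 1.0
                r2[eidx] = D
                rows.append(r2)  # sum v_i + D E_j <= D
                lbs.append(-np.inf)
                ubs.append(D)
        self.constraints.append(
            LinearConstraint(np.vstack(rows), np.array(lbs), np.array(ubs))
        )

    def add_exclusion_cut(self, chosen: Iterable[str]) -> None:
        """Forbid ``chosen`` and every superset of it."""
        chosen = sorted(chosen)
        row = self._row()
        for x in chosen:
            row[self.b_index[x]] = 1.0
        self.constraints.append(LinearConstraint(row, -np.inf, len(chosen) - 1))

    def solve(
        self, fixed_sources: Optional[frozenset[str]] = None
    ) -> Optional[MilpSolution]:
        """Minimise sum(b); ``fixed_sources`` restricts b to a subset of it."""
        cfg = self.config
        c = self._row()
        for x in self.sources:
            c[self.b_index[x]] = 1.0
        integrality = np.zeros(self.n_var)
        lo = np.zeros(self.n_var)
        hi = np.full(self.n_var, cfg.U)
        for x in self.sources:
            j = self.b_index[x]
            integrality[j] = 1
            hi[j] = 1.0
            if fixed_sources is not None and x not in fixed_sources:
                hi[j] = 0.0
        for eidx in self.E_index.values():
            integrality[eidx] = 1
            hi[eidx] = 1.0
        options: dict = {"mip_rel_gap": 0.0}
        if cfg.time_limit:
            options["time_limit"] = cfg.time_limit
        res = milp(
            c=c,
            constraints=self.constraints,
            integrality=integrality,
            bounds=Bounds(lo, hi),
            options=options,
        )
        if res.status == 2:  # infeasible
            return None
        if res.status == 1:
            raise SolverError("MILP hit iteration/time limit")
        if res.status != 0 or res.x is None:
            raise SolverError(f"MILP failed with status {res.status}: {res.message}")
        x = res.x
        chosen = frozenset(
            s for s in self.sources if x[self.b_index[s]] > 0.5
        )
        flux_vals = {
            rid: float(x[j]) for j, rid in enumerate(self.sm.cols)
        }
        if any(
            v > cfg.U * 0.99 for v in flux_vals.values()
        ):  # pragma: no cover - diagnostic only
            import warnings

            warnings.warn("a flux is within 1% of the upper bound U", stacklevel=2)
        flux = FluxAssignment(flux_vals, tolerance=cfg.support_tol)
        return MilpSolution(
            chosen_sources=chosen, flux=flux, objective=len(chosen)
        )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def solve_one(
    network: Network,
    excluded: Iterable[Iterable[str]] = (),
    config: Optional[SolverConfig] = None,
    mode: Optional[Mode] = None,
) -> Optional[MilpSolution]:
    """Find one minimum-cardinality precursor set avoiding ``excluded``.

    Returns ``None`` iff the MILP is infeasible, i.e. every precursor
    set contains one of the excluded sets.
    """
    config = config or SolverConfig()
    mode = mode or config.mode
    model = _MilpModel(network, mode, config)
    for chosen in excluded:
        model.add_exclusion_cut(chosen)
    return model.solve()


def solve_restricted(
    network: Network,
    allowed_sources: frozenset[str],
    mode: Mode,
    config: Optional[SolverConfig] = None,
) -> Optional[MilpSolution]:
    """Solve the selection MILP with sources restricted to a given subset.

    Used as the membership oracle for the machinery-duplicating model:
    the subset is feasible iff some sub-selection of it supports a
    factory (feasibility is monotone in the source set).
    """
    config = config or SolverConfig()
    model = _MilpModel(network, mode, config)
    return model.solve(fixed_sources=frozenset(allowed_sources))


def enumerate_minimal_sources(
    network: Network,
    config: Optional[SolverConfig] = None,
    mode: Optional[Mode] = None,
) -> EnumerationResult:
    """Enumerate every inclusion-minimal precursor set of the targets.

    Iterates :func:`solve_one`, appending one exclusion cut per found
    solution, until infeasibility proves completeness.  Each solution is
    double-checked to be inclusion-minimal via the independent LP oracle
    (:func:`precursorsets.feasibility.reduce_to_minimal` must be a
    no-op); a failure aborts loudly since it would mean the MILP model
    and the LP oracle disagree.
    """
    config = config or SolverConfig()
    mode = mode or config.mode
    t0 = time.monotonic()
    model = _MilpModel(network, mode, config)
    solutions: list[dict] = []
    iterations = 0
    reason = "exhausted"
    last_cardinality = 0
    while True:
        if config.max_solutions is not None and len(solutions) >= config.max_solutions:
            reason = "max_solutions"
            break
        try:
            sol = model.solve()
        except SolverError as exc:
            if "time" in str(exc).lower():
                reason = "time_limit"
                break
            raise
        iterations += 1
        if sol is None:
            break
        if sol.objective < last_cardinality:
            raise SolverError(
                "MILP returned a smaller solution after a larger one; "
                "exclusion cuts must be wrong"
            )
        last_cardinality = sol.objective
        verified = reduce_to_minimal(network, sol.chosen_sources, mode, config)
        if verified != sol.chosen_sources:
            raise SolverError(
                f"MILP solution {sorted(sol.chosen_sources)} is not minimal "
                f"(reduces to {sorted(verified)}); model inconsistent"
            )
        solutions.append(
            {
                "sources": sorted(sol.chosen_sources),
                "flux": {
                    r: v for r, v in sol.flux.values.items() if v > config.support_tol
                },
                "support": sorted(sol.flux.support & set(network.reaction_ids)),
            }
        )
        model.add_exclusion_cut(sol.chosen_sources)
    return EnumerationResult(
        solutions=solutions,
        mode=mode,
        config=config,
        iterations=iterations,
        terminated_reason=reason,
        algorithm="milp",
        wall_time=time.monotonic() - t0,
    )
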