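# precursorsets

Exhaustive enumeration of **minimal precursor sets** in metabolic
networks: given a network of (irreversible) stoichiometric reactions, a
set of candidate *source* compounds and a set of *target* compounds,
find every inclusion-minimal subset of sources from which all targets
can be produced in strictly positive amount. Applied to a genome-scale
model with a biomass target, the solutions are predicted minimal growth
media.

Three stoichiometric models are supported:

| mode | intermediate compounds | notes |
|---|---|---|
| `accumulate` | net production ≥ 0 | default |
| `steady-state` | net production = 0 (targets keep ≥) | strict balancing |
| `md` | consumed non-source compounds must have strictly positive net production | "machinery-duplicating"; rejects regenerating cycles |

Three independent algorithms cross-check each other:

* **milp** — iterated mixed-integer programming (HiGHS via
  `scipy.optimize.milp`): one binary per source, minimise the number of
  sources used, then add an exclusion cut per found solution until
  infeasibility proves the enumeration complete.
* **combi** — enumerate minimal *topological* factories of the
  many-to-one transformed network, combine their source footprints
  breadth-first over the union closure, and test each candidate with
  the LP membership oracle. Complete, but exponential in the factory
  count (it refuses pathological inputs and points you to `milp`).
* **brute** — exhaustive subset search with the LP/MILP membership
  oracle; the ground truth for small networks.

## CLI

```bash
precursorsets \
    --network net.txt --sources sources.txt --targets targets.txt \
    --mode accumulate --algorithm milp --output results/run1
```

writes `run1.json` (authoritative), `run1.tsv` (one solution per line)
and `run1.manifest.json` (input hashes, config echo, solver backend,
wall time). Exit code 0 = complete enumeration, 3 = partial
(`--max-solutions` / `--time-limit` hit), 1 = error.

Network files are plain text, one reaction per line (`#` comments,
coefficient defaults to 1.0, `<=>` marks a reversible reaction that is
split on normalization):

```text
r1: 1.0 c1 + 2.0 c2 -> 1.0 c3
r2: 3.0 c3 -> 1.0 c4
r5: a <=> b
```

Source/target files hold one compound id per line; `--autosources`
instead takes every compound that is never produced (or produced only
reversibly). SBML level-3 files are accepted via `--format sbml`.

## Library

```python
from precursorsets import (
    Mode, check_sps, enumerate_minimal_sources, combi_enumerate,
    enumerate_minimal_tps,
)
from precursorsets.io_cli import read_network

net = read_network("net.txt", sources={"g", "nh3"}, targets={"biomass"})
print(check_sps(net, {"g"}).feasible)                 # LP membership oracle
result = enumerate_minimal_sources(net, mode=Mode.STEADY_STATE)
for sol in result.solutions:
    print(sol["sources"], sol["support"])
```

`precursorsets.fixtures` builds the small benchmark networks used
throughout the test suite (a regenerating Krebs-like cycle, a network
whose topological and stoichiometric solutions differ, two parametric
worst cases for the combinatorial approach, and seeded random
networks); every builder re-derives its advertised properties with the
LP oracles at construction time.

## Numerics

Strict inequalities are encoded with configurable surrogates
(`SolverConfig`): target production ≥ ε (default 0.5), per-flux upper
bound U (default 1000), machinery-duplicating strictness ε̄ (default
0.5) with big-M rows D_j = U·|consumers(j)|. Every witness flux is
re-verified against the raw constraint system before a certificate is
returned, and every MILP solution is re-proved inclusion-minimal with
the independent LP oracle.
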