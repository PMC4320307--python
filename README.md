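# retiform

A small research tool modeling behavior-mode command in an n-valued
permutation system. It implements:

- **`permutation_core`** — permutations of `1..n`, 1-based lexicographic
  rank/unrank, and the `n-1` *negation operators* `N_1..N_{n-1}` (adjacent
  value exchanges by default; adjacent position exchanges as a config
  option — the two give isomorphic structures via the inverse map).
- **`permutograph`** — the operator-labeled graph on all `n!` permutations
  (the Cayley graph of the symmetric group under adjacent transpositions),
  with DOT/GraphML/CSV export and re-import.
- **`hamilton`** — Hamilton loops through the permutograph: verification
  with first-violation reporting, deterministic construction by plain
  changes, exhaustive enumeration for `n ≤ 4` (the quadrivalent system has
  **44** undirected loops, **88** directed; enumeration at `n ≥ 5` is
  deliberately refused), rotation/reversal canonicalization, and the
  visit-order (Günther) matrix over all start choices.
- **`plaque`** — a gap-junctional plaque as a container of loop programs
  closed under reversal, with stochastic channel turnover: exponential
  decay at a configurable half-life (default 2.5 h), balancing renewal
  that holds the functional fraction at a target (default 10 %), and
  scheduled dissolution/reassembly (default every 4 h) that preserves the
  loop repertoire.
- **`reticular_sim`** — a 20-mode behavior repertoire (shares summing to
  100 % over a ~4-week cycle), abductive winner-take-all program selection
  with prior/name tie-breaks, step-by-step program execution under a
  timing clock, priority interrupts that preempt and reprioritize, a
  six-way outcome classification per program attempt (including imprinting
  as a simple learning counter), and a seeded stochastic scheduler whose
  long-run shares recover the configured percentages.
- **`io_cli` / `cli`** — JSON-lines loop files, CSV matrices/traces, YAML
  config and scenario scripts, and a `retiform` command-line entry point.

## CLI

```bash
retiform build-graph --n 4 --format graphml --out graph.graphml
retiform find-loop --n 5 --out loop.jsonl
retiform verify-loop loop.jsonl
retiform enumerate-loops --n 4 --counting undirected     # prints 44
retiform enumerate-loops --n 5                           # refuses, exit code 3
retiform guenther-matrix --loop loop.jsonl --out matrix.csv
retiform build-plaque --channels 10000 --duration 8 --out turnover.csv
retiform simulate-rf --steps 100000 --seed 7 --out shares.csv \
    --scenario scenario.yaml --trace-out trace.csv
```

Global flags `--config cfg.yaml --seed S --log-level LEVEL` precede the
subcommand. Exit codes: 0 success, 2 validation failure, 3 refusal.

Config keys (YAML): `semantics` (`value`|`position`), `max_n`, `counting`,
`half_life_h`, `functional_fraction`, `plaque_lifetime_h`,
`channel_count`, `imprint_threshold`, `seed`, `log_level`.

A scenario script is a YAML list of timed signals:

```yaml
- {time: 0, evidence: {Works: 1.0}, priority: 1}
- {time: 5, evidence: {Escapes: 2.0}, priority: 9}   # preempts Works
```

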