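# emcut

Minimal cut set design for metabolic networks by binary linear programming
over elementary modes.

## The problem

Elementary mode (EM) analysis decomposes a metabolic network's steady-state
flux space into minimal, indivisible pathways: knocking out any single
reaction of a mode disables the whole mode. Rational strain design can
therefore be phrased over the *binary supports* of the EMs. Partition the
modes into three classes:

* **goal** modes `G` — desired functionality, kept in full,
* **kill** modes `K` — unwanted functionality, each must lose a reaction,
* **helper** modes `H` — indifferent to the design.

With `x ∈ {0,1}^n` indicating which reactions remain in the engineered
network and `‖e‖` the support size of mode `e`, the design problem is the
binary linear program

```
max  Σᵢ wᵢ xᵢ
s.t. eᵀx  =  ‖e‖      for every goal mode e      (kept in full)
     eᵀx  ≤  ‖e‖ − 1  for every kill mode e      (at least one knockout)
     xᵢ ∈ {0,1}
```

The unweighted optimum gives the minimum number of interventions
`Δmin = n − ‖x‖`; re-solving after adding the exclusion pair
`Σ_{i∈B} xᵢ ≤ |B|−1`, `Σ_{i∈N} xᵢ ≥ 1` (B = kept, N = deleted) enumerates
**all** minimal cut sets, each exactly once, in non-increasing objective
order. Weights `wᵢ` encode experimental feasibility (cheap uptake reactions,
isoenzyme counts, prohibitively expensive non-annotated reactions), so
implementable designs are enumerated first without losing completeness.
Boolean gene–protein–reaction and regulatory rules (`AND` complexes, `OR`
isoenzymes, `NOT` inhibition) are compiled into exact linear constraints
over binary gene variables `y`, moving the interventions to the gene level.
Binary survivor indicators `p` per helper mode (`eᵀx ≥ p‖e‖`,
`eᵀx ≤ p + ‖e‖ − 1`) let the residual functionality `Σ pᵢ` itself be
minimized or maximized.

The package is aimed at metabolic engineers and modelers who already have an
EM matrix (from efmtool or similar tools; supplied as TSV — SBML is out of
scope) and want exhaustive, experimentally prioritized knockout strategies.

## Worked example

The package embeds a 12-reaction, 9-mode example network (substrate A is to
be converted efficiently into product P; one goal mode, five kill modes,
three helpers) together with its reaction metadata, feasibility weights and
regulatory rules:

```sh
emcut fixture --dir demo && cd demo
emcut mcs --em toy_em_binary.tsv --partition toy_partition.tsv \
          --meta toy_meta.tsv --rules toy_rules.txt --weights toy_weights.tsv
```

prints (abridged):

```json
{
  "delta_min": 2,
  "exhausted": true,
  "solutions": [
    {"rank": 1, "objective": 407.2, "reaction_deletions": [],
     "gene_deletions": ["GR11", "GR2"], "regulation_forced_off": ["R10"],
     "n_surviving_helpers": 1, "feasible_flag": true},
    {"rank": 2, "objective": 407.2, "gene_deletions": ["GR2", "GR5b"], "...": "..."},
    {"rank": 3, "objective": 407.2, "gene_deletions": ["GR2", "GR5a"], "...": "..."},
    {"rank": 4, "objective": 310.2, "reaction_deletions": ["R9"],
     "gene_deletions": ["GR2"], "regulation_forced_off": ["R10"],
     "feasible_flag": false}
  ]
}
```

Reading: the design needs at least two interventions (`delta_min`). Three
equally cheap solutions exist purely at the gene level (delete GR2 plus one
of GR11/GR5a/GR5b — the R5 enzyme complex dies with either of its genes);
R10 is switched off by regulation in every solution (its inhibitor GR1 must
stay expressed for the goal mode), not by any deletion. The fourth solution
needs a direct knockout of the non-annotated reaction R9 and is flagged
infeasible. Without regulation the same partition yields five reaction-level
cut sets ({R2,R9}, {R2,R5,R6}, {R2,R5,R10}, {R2,R6,R11}, {R2,R10,R11}).

Survivor optimization on the embedded 6-reaction example:

```sh
emcut survivors --em survivor_em_binary.tsv --partition survivor_partition.tsv --sense min
# survivors: 0   deletions: R4
emcut survivors --em survivor_em_binary.tsv --partition survivor_partition.tsv --sense max
# survivors: 1   deletions: R6
```

Both single deletions realize the goal mode, but deleting R4 strips the
network down to exactly the desired functionality while deleting R6 keeps
the harmless side pathway alive.

The same operations are available as library functions
(`emcut.enumerate_mcs`, `emcut.optimize_survivors`, `emcut.suggest_weights`,
`emcut.brute_force_mcs`, …); see the docstrings and `docs/methods.md`.

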