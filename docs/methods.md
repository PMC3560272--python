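# Methods

## Model

`emcut` designs *networks of minimal functionality*: engineered metabolic
networks that retain a specified set of elementary modes (EMs) and lose a
specified set, with every other mode free to stay or go. All reasoning
happens on binary supports. A flux vector is binarized by
`support_i = 1 iff |flux_i| > tol`; forward and backward flux both count as
active, so a reversible reaction contributes a single binary variable and
its direction is irrelevant after binarization. Mode containment is the
inner-product test `eᵀv = ‖e‖`.

The modes are partitioned into goal (`G`, kept in full), kill (`K`, each
must lose at least one reaction) and helper (`H`, indifferent) classes, and
the design becomes a binary linear program over reaction-presence variables
`x`:

* one equality `eᵀx = ‖e‖` per goal row,
* one inequality `eᵀx ≤ ‖e‖ − 1` per kill row,
* maximize `Σ wᵢxᵢ` with strictly positive weights.

Helper rows (`eᵀx ≤ ‖e‖`) are tautological for binary `x`; they are skipped
by default and only emitted under a flag for completeness audits.

**Assumptions.** Steady-state, stoichiometry-only reasoning: no kinetics,
thermodynamics or flux magnitudes. A mode dies iff one of its reactions is
removed; regulation is static boolean (dynamic or cyclic regulation is out
of scope). The EM list supplied by the user is taken as complete for the
classes it covers — modes absent from the input are invisible to the
design.

## Enumeration and minimality

After each optimum with kept set `B` and deleted set `N`, the exclusion pair
`Σ_{i∈B} zᵢ ≤ |B| − 1` and `Σ_{i∈N} zᵢ ≥ 1` is added and the program
re-solved until infeasibility. The second cut forbids supersets of an
earlier deletion pattern, the first forbids subsets; together with strictly
positive weights this makes every emitted pattern inclusion-minimal and the
whole family an antichain (checked property-wise in the tests). The
exclusion cuts act on the *deletion-decision vector* `z`: gene variables for
GPR-mapped reactions plus reaction variables for unmapped reactions. This
matters because two distinct gene-level interventions (e.g. deleting either
gene of an enzyme complex) can share one reaction pattern and must both be
enumerated.

`Δmin` is reported as the minimum intervention count over the enumerated
solutions; for uniform weights this equals `n − ‖x‖` of the first solution.

An infeasible design (some kill support contained in the union of goal
supports) is reported, not raised: the result carries the irreducible
conflicts from the hitting-set reduction, and the remedy is to move modes
out of the goal class.

## Hitting-set preprocessing

The feasible set of the base program has a transparent combinatorial core:
goal-support reactions are fixed on, and the deleted set must hit every kill
support stripped of goal reactions. `reduce_to_hitting_set` performs exactly
this reduction — goal fixing, row stripping, removal of rows already hit by
externally forced zeros, dominance removal (a row that contains another row
is redundant), and fixing of reactions that occur in no surviving row. The
equivalence of the reduced form with the BLP's feasible set is verified
exhaustively on small random instances, and dominance removal is verified
never to change the minimal hitting sets. The reduction is this package's
own; MILP solvers apply their own presolve on top of whatever they receive.

## Regulation

Rules use a single-operator grammar (`[NOT] G {AND|OR [NOT] G}* -> R`);
mixed or nested expressions are rejected rather than silently converted —
users can introduce intermediate pseudo-genes. With each literal
contributing `y` (plain) or `1 − y` (negated) and `k` literals:

* IDENTITY: `Σt − x = 0`,
* OR: `−(k−1) ≤ Σt − kx ≤ 0`,
* AND: `0 ≤ Σt − kx ≤ k − 1`,

constants from negations folded into the bounds. Every compiled form is
*exact* — it admits precisely the assignments where the reaction equals the
boolean value of the expression — and `truth_table_check` re-verifies this
by exhaustion for any rule; the test suite runs it over all two-literal
forms, all negation patterns, and random rules up to four literals. (For
`(NOT Ga) OR Gb` the correct bounds are `−2 ≤ −y_a + y_b − 2x ≤ −1`,
derived from the truth table.)

Only genes referenced by some rule receive variables. The objective becomes
`Σ wᵢxᵢ + Σ uⱼyⱼ` with default gene weights of 1, so maximization keeps
genes expressed unless a deletion pays for itself; gene-weight design beyond
this default is deliberately left open. In each solution, a reaction that is
off is classified as: a direct deletion (no rule), a gene-deletion effect (a
plain literal of its rule is a deleted gene), or *regulation-forced* (all
plain literals expressed; an inhibitor keeps it off). Regulatory couplings
between reactions (e.g. mutual exclusion of two reactions) are accepted as
raw linear side constraints via `constraint:` lines.

## Survivor optimization

Helper mode survival is linearized with one binary `p` per mode:
`eᵀx ≥ p‖e‖` forces `p = 0` once any support reaction is deleted, and
`eᵀx ≤ p + ‖e‖ − 1` forces `p = 1` when the support is intact. `Σ pᵢ` is
then minimized or maximized subject to the base constraints. The objective
is lexicographic — survivor count first, then the weighted reaction/gene
objective to break ties toward cheap interventions — implemented as two
solves with the first optimum pinned by a constraint, since the trade-off
between the two criteria is genuinely open and this choice keeps both
interpretable. An optional budget constraint pins the intervention count for
comparisons between equal-size cut sets. With an empty goal class the same
construction yields `max_preservable`: the largest number of pool modes that
can survive while every kill mode is cut, an upper bound for formulations
that require "at least n desired modes kept". (Note the bound is computed
*without* any goal fixing; holding a mode as goal can only lower the
achievable count.)

## Solver

The built-in solver is a depth-first branch-and-bound over binaries:

* variable order = declaration (input file) order; branch value 1 first,
  which favors keeping reactions and makes the returned optimum — and hence
  the enumeration order — deterministic;
* unit propagation on the two-sided rows (activity-interval reasoning
  forces variables whose alternative value would violate a row);
* pruning by the additive optimistic bound `current + Σ max(0, cᵢ)` over
  unassigned variables;
* feasibility tolerance 1e-7 on row activities, 1e-6 when comparing
  objective values between solutions.

It is exact and adequate for desk-scale instances (tens of variables after
reduction). The relative order of equal-objective optima follows the
branching order and is explicitly non-contractual; the enumerated *set* is
the contract. An external backend (HiGHS via `scipy.optimize.milp`) sits
behind the same solve contract and is required by the tests to return
identical solution sets on all fixtures; it is the independent cross-check,
never the primary path.

## Weights

`suggest_weights` encodes the feasibility guidelines: uptake reactions
default to 0.1 (the sum of uptake weights must stay below the smallest
non-uptake weight — substrates are removed from the medium, not
engineered); annotated reactions get `max(1, n_isoenzymes)` (an enzyme
complex counts once regardless of gene count); non-annotated reactions get
a weight strictly above the sum of all deletable weights, by default
`ceil(deletable sum) × factor`, so that any solution touching them ranks
below every fully implementable one. The fixture reproduces its published
weight vector through an explicit override (99) because that value is an
instance choice — the inequality is the rule, which `validate_weights`
checks. `jitter_weights` multiplies each weight by seeded
`Uniform(1−rel, 1+rel)` for robustness experiments; on the embedded example
the top-ranked pair of designs is stable under ±20% jitter in every trial
the acceptance script runs.

## Oracles and synthetic data

Three independent references back the tests:

* `brute_force_mcs` — exhaustive subset search (bitmask sets, increasing
  size) for minimal hitting sets; never touches the BLP machinery;
* `simulate_deletion` — direct support-disjointness survival check;
* `enumerate_ems_bruteforce` — exact EM enumeration for tiny networks
  (n ≤ 12): a support is elementary iff the rational nullspace of the
  restricted stoichiometric matrix is one-dimensional with a zero-free,
  sign-feasible generator. All arithmetic is exact (sympy rationals);
  reversible modes are canonicalized to first-nonzero-positive and reported
  once. Futile two-cycles formed by a reaction and its separate reverse
  reaction are reported as modes, as they must be.

`generate_random_instance` draws distinct random supports (sizes 2–6 by
default), designates one random mode as goal and a random nonempty subset
as kill. These sizes match the regime where exhaustive oracles are exact,
which is the point of the generator; it emulates the combinatorial
structure of EM supports but not their stoichiometric consistency, flux
correlations, or the heavy-tailed support-size distributions of genome-scale
mode sets — agreement on these instances validates the optimization and
enumeration logic, not biological realism. Instances whose kill supports
are contained in the goal support are flagged infeasible rather than
redrawn, so the infeasible path is exercised too.

The acceptance batch runs 200 instances with up to 15 reactions and 30
modes — sized so the brute-force oracle stays exact and the whole batch
completes in seconds.

## Numerical and degenerate-case choices

* Constraint bounds are exact integers/rationals; objectives are floats
  with a 1e-6 ranking tolerance (weight ratios in practice are ≥ 0.1, far
  above it).
* Binarization tolerance defaults to 1e-9 and is a CLI flag; magnitudes
  within a decade of the tolerance trigger a warning.
* Duplicate supports within a class are collapsed (merged mode ids); the
  same support in two classes is a reported diagnostic, not a construction
  error, as is an empty goal+kill partition.
* A kill mode with empty support can never be cut and is rejected at
  problem build time.
* An enumeration whose first optimum deletes nothing (empty kill class)
  returns that single empty cut set.
* Caps (`max_solutions`, `min_objective`) mark the result as not exhausted.

## Limitations

* EM enumeration is deliberately brute-force and capped at 12 reactions;
  genome-scale mode sets must come from external enumerators via the TSV
  pathway.
* The built-in solver targets desk-scale (reduced) problems; very large
  instances should use the HiGHS backend, and wall-clock performance is not
  a goal.
* Published genome-scale validation numbers depend on a supplementary model
  and an external EM enumerator; the package validates the identical
  pathway on synthetic matrices instead and runs such models only when the
  user supplies them.
* Printed per-solution objective values in the original desk example are
  internally inconsistent with its own constraint set; the enumerated cut
  sets and their relative order are the reproduced contract, objective
  column values are not.
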