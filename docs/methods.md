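# Methods

## Model

`boolpath` treats a pathway as a set of biochemical reactions over typed
entities (proteins, small molecules, complexes, entity sets). Compilation
to a Boolean network follows three rules:

1. **Reactions.** Inputs, catalysts and activators are necessary jointly
   (AND); inhibitors veto (negated AND term); any one activator suffices
   and any one inhibitor acts, so multi-member activator/inhibitor roles OR
   into accessory variables. A reaction with several products drives an
   output accessory that is assigned to each product. A role with exactly
   one member is wired directly — accessory nodes exist only to keep rules
   readable, and the single-member shortcut is semantically identical
   (verified by truth-table enumeration in the test suite).
2. **Complexes** are ANDs over subunits; **entity sets** are ORs over
   members. These component relations are emitted only for containers not
   produced by any reaction: a produced complex's formation is already
   modeled by its producing reaction, and an unconditional subunit relation
   would override the reaction-driven dynamics (the producing reaction and
   the subunit rule would race through the OR combiner).
3. **Multiple producers.** An entity output by several reactions has one
   relation per reaction; they combine by OR at evaluation time, since any
   producing reaction suffices.

The simulation relaxes {0,1} to [0,1] with Goedel fuzzy operators (min,
max, 1−x). This choice of t-norm keeps Boolean corners exact: with binary
initial states and identity transfers the fuzzy trajectory reproduces the
two-state synchronous dynamics bit for bit, a property the suite checks
against an independently written Boolean simulator on 100 random networks.
Updates are synchronous because the iteration-count stopping rule
presupposes a global step.

### Assumptions

- Reactions have at least one input and one output; the schema forbids
  input-less reactions rather than guessing a convention for them.
- An entity appearing twice in one rule contributes one literal per
  polarity (AND/OR are idempotent); an entity that is both input and
  inhibitor of the same reaction yields x AND ¬x, constant 0 at the
  Boolean corners.
- Initial-value defaults encode "upstream is fully available": 1.0 for
  entities that feed loop-forming reactions or are never produced, 0.0
  elsewhere. "Feeds" counts every upstream role (input, catalyst,
  activator, inhibitor) — catalysts and regulators must be available for
  anything downstream to fire. The 1.0 rule extends transitively to the
  components of clamped containers (`root_components`): a clamped complex
  that is not produced by a reaction carries a subunit-AND relation, and
  zero-initialized subunits would erase the clamp at the first step.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `convergence_tol` | 1e-6 | activity | max state change treated as converged |
| `max_iterations` | max(100, ⌈1.2·\|V\|⌉) | steps | synchronous update bound |
| `expansion_step` | 20 | steps | attractor replay block size |
| `expansion_tol` | 0.01 | score | score change below which expansion stops |
| `expansion_cap` | 1000 | steps | hard bound on expanded trace length |
| `hill_n` | 3.0 | — | Hill exponent (cooperativity) |
| `hill_k` | 0.5 | activity | Hill half-maximal point |
| strength map | fixed | — | 0.999 / 0.99 / 0.99−0.196·(log₁₀v−1) / 0 |

Identity transfers are the shipped default; the normalized Hill form
f(x) = xⁿ(1+kⁿ)/(xⁿ+kⁿ) (f(0)=0, f(1)=1, monotone) is available per
variable. The strength map's log base is 10: only log₁₀ makes the third
branch continuous with the 0.99 branch at 10 nM (natural log would jump by
about 0.25). Enrichment's background size defaults to 20,000 — a common
but arbitrary stand-in for the human protein-coding gene count — and is an
explicit parameter because every p-value depends on it.

## Attractors and trace expansion

A cycle attractor is the earliest start s and smallest period p such that
trace rows repeat with period p from s onward, matched at tolerance 1e-9 —
below the convergence tolerance, above accumulated float noise. Converged
runs record the final row as a period-1 attractor directly, since the last
two rows may still differ by up to the convergence tolerance, which is
larger than the attractor-matching tolerance.

Impact scores compare areas under the activity-vs-step curve (rectangle
rule, unit step). Because a finite trace weights the transient against the
attractor arbitrarily, both traces are extended by replaying their
attractor cycles in lockstep blocks of 20 steps until every entity's score
moves by less than 0.01 between consecutive expansions, or the traces reach
1000 rows; the pair is first brought to a common length so the score's AUCs
always span identical step counts. The quantity monitored between
expansions is the score itself — the expansion exists to stabilize it. For
a single trace expanded without a partner (`expand_trace`), the monitored
quantity is the per-variable mean activity (AUC per step), the natural
single-trace analog; this is a package design choice where the underlying
convention is open.

Drug effects compose after the target's own transfer function at every
step: inhibition v·(1−s), activation v + s·(1−v). Both preserve [0,1] and
vanish at s=0. A targeted variable with no relations (a clamped input) is
never re-derived by the update loop, so the drug is applied to its initial
value instead; this is exactly the fixed point the per-step rule would
reach for a constant drive. A drug targeting a protein inside complexes
perturbs the protein-level variable; containers feel it through their
AND/OR relations.

## Synthetic data

The `fixtures` module generates every input format deterministically.

- `make_typical_reaction` is the maximal single-reaction shape (2 inputs, 1
  catalyst, 2 activators, 2 inhibitors, 2 outputs), exercising every
  accessory rule.
- `make_feedback_loop_pathway(m)` emulates a receptor-kinase module with a
  product-recycling loop: ligand and kinase upstream, a two-reaction
  negative feedback (active kinase forms a complex with its regulator,
  which inhibits kinase activation) that makes activity oscillate, and an
  m-reaction loop whose final reaction regenerates the entry complex while
  emitting the output dimer. Under defaults the output oscillates between
  0 and 1; halving the regulator's initial value lifts the oscillation
  floor to 0.5 (the inhibitory complex can never exceed the regulator's
  level); inhibiting the kinase gates the loop's entry and regeneration and
  collapses the output toward 1 − strength. These are the qualitative
  behaviors the perturbation workflow is designed to expose — entry-gated
  loops, attractor floors set by partial inhibition, and drug-induced
  collapse.
- `make_drug_table` produces multi-assay interaction tables log-uniform
  over [0.1, 10⁶] nM with four pinned rows spanning all strength branches;
  `make_multikinase_genesets` builds 12 gene sets with fixed sizes and
  fixed memberships of a 12-kinase query, padded with unique synthetic
  fillers; `make_fi_fixture` encodes a hub pattern (14 of 18 drugs on one
  gene, one drug bridging two others).

What passing tests on these fixtures show: the compiler, simulator, scorer
and filters implement their stated semantics exactly. What they do not
show: behavior on real curated pathways (hundreds of entities, deeply
nested complexes, annotation noise), realistic affinity or mutation
distributions, or biological validity of any particular prediction.

## Numerical choices

- All iteration orders are lexicographic in ids; compilation and
  simulation are fully deterministic, and serialized networks are
  byte-identical across runs.
- Binomial tails use `scipy.stats.binom.sf` (stable for large n);
  Benjamini-Hochberg uses `statsmodels`; both are cross-checked in the
  suite against exhaustive enumeration and the closed-form step-up.
- Histogram bins are half-open [lo, hi) with the final bin closed; assay
  thresholds are inclusive (≤). The p-scale conversion for activity values
  recorded as −log₁₀ molar (10^(9−p) nM) sits behind an explicit flag and
  is never auto-detected.
- Degenerate inputs: empty pathways compile to empty networks and simulate
  to a two-row converged trace; 0/0 impact scores are defined as 0; an
  absent drug or an empty query returns an explicit warning or error, never
  a silent empty result.
- Problem sizes in the test suite (networks of ≤ ~20 variables, 100-seed
  oracle sweeps, 1000-pair score checks) were chosen as the smallest sizes
  that still exercise every code path and invariant; all are generated at
  run time.

## Known limitations

- Synchronous updates only; asynchronous or stochastic update schemes can
  reach different attractors on the same network.
- The AND/OR logic ignores stoichiometry, kinetics and consumption; a
  recycled complex is never depleted.
- The relative impact score is unstable when the reference AUC is near 0 —
  a tiny absolute change then saturates the score at ±1.
- Drug strength is a static map from the minimum assay value; no dose,
  pharmacokinetics, or mutation effects on binding.
- Enrichment treats gene sets as flat and independent; no hierarchy-aware
  correction.
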