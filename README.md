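# boolpath

Boolean-network modeling of drug action on biochemical pathways.

Curated pathway databases describe signaling as networks of biochemical
reactions — each with inputs, catalysts, activators, inhibitors and
outputs — but a static diagram cannot tell you what an inhibitor does to a
pathway that contains feedback loops. `boolpath` is a library and CLI for
researchers in systems pharmacology who want to go from a reaction-level
pathway description plus a drug-target binding table to a quantitative,
dynamic prediction of which pathway entities a drug perturbs, and by how
much.

## What it computes

**Compilation.** A reaction becomes a logic rule: inputs, catalysts and
activators combine by AND, inhibitors enter negated
(`input1 · input2 · catalyst · activator_acc · !inhibitor_acc = output_acc`),
with accessory variables introduced when a role has multiple members
(activators/inhibitors OR into their accessory; a multi-output reaction
fans out through an output accessory). Complexes become ANDs over subunits,
entity sets become ORs over members. The result is a Boolean network.

**Simulation.** The two-state logic is relaxed to constrained fuzzy logic:
activities x ∈ [0, 1] with AND = min, OR = max, NOT = 1 − x, updated
synchronously through per-variable transfer functions (identity, or a
normalized Hill curve f(x) = xⁿ(1+kⁿ)/(xⁿ+kⁿ)). Simulation runs until the
maximum change between consecutive states is < 10⁻⁶ or the iteration count
reaches max(100, ⌈1.2·|V|⌉). Entities that feed loop-forming reactions, or
that are never produced by any reaction, start at 1.0; everything else at
0.0. Feedback loops settle into cycle attractors, which are detected and
replayed to extend traces.

**Drug perturbation.** A drug-target interaction's minimum supporting assay
value v (nM, across KD/Ki/IC50/EC50) maps to a strength

    s(v) = 0.999                        v < 1 nM
           0.99                         v < 10 nM
           0.99 − 0.196·(log₁₀ v − 1)   v < 10⁶ nM
           0                            otherwise

Inhibition multiplies the target's post-transfer value by (1 − s) each
step; activation moves it toward 1 by v + s·(1 − v). Impact on each entity
is the relative impact score

    score = (AUC_perturbed − AUC_reference) / (AUC_perturbed + AUC_reference)

where AUC sums the entity's activity over the attractor-expanded trace
(expanded in lockstep blocks of 20 steps until scores stabilize below 0.01
or 1000 steps). Scores lie in [−1, 1]; negative means the drug suppresses
the entity.

**Companions.** `evidence` reads and filters drug-target tables (two TSV
dialects, strict nM semantics, inclusive thresholds); `enrichment` ranks
gene sets by the upper-tail binomial test P(X ≥ k), X ~ Binomial(n, s/N),
with Benjamini-Hochberg FDR; `fi_network` builds mutation-filtered
functional-interaction subnetworks and overlays drugs binding network genes
at ≤ 100 nM.

## Worked example

The bundled synthetic pathway mirrors a receptor-kinase module with a
product-recycling loop: ligand SCF and kinase KIT upstream, a negative
feedback through the kinase:regulator complex IC = pKIT:PKC, and a
4-reaction loop that recycles its entry complex while emitting an output
dimer OUT. With the regulator PKC at half activity the loop's floor sits at
0.5; a 16 nM kinase inhibitor (strength 0.95) collapses it:

```python
from boolpath import run_perturbation_study
from boolpath.fixtures import make_feedback_loop_pathway, make_kinase_inhibitor_table

pathway = make_feedback_loop_pathway(loop_reactions=4)
drugs = make_kinase_inhibitor_table()
study = run_perturbation_study(
    pathway, drugs, "KINI", mechanism="inhibition",
    initial_overrides={"PKC": 0.5},
)
action = study.actions[0]
print(f"drug {action.drug} -> {action.targets[0]}, strength {action.strength:.4f}")
s_ref, _ = study.reference.attractor
s_per, _ = study.perturbed.attractor
print(f"reference OUT attractor min: {study.reference.column('OUT')[s_ref:].min():.4f}")
print(f"perturbed OUT attractor min: {study.perturbed.column('OUT')[s_per:].min():.4f}")
out = study.score_for("OUT")
print(f"OUT relative impact score: {out.score:.4f} "
      f"(reference AUC {out.reference_auc:.1f}, perturbation AUC {out.perturbation_auc:.1f})")
```

prints

```
drug KINI -> KIT, strength 0.9500
reference OUT attractor min: 0.5000
perturbed OUT attractor min: 0.0500
OUT relative impact score: -0.8035 (reference AUC 95.0, perturbation AUC 10.4)
```

The inhibitor's strength comes from its 16 nM KD (third branch of s(v));
the output complex's cycle floor drops from 0.5 to 1 − s ≈ 0.05, and the
strongly negative score quantifies the suppression. The same workflow is
available from the shell:

```sh
boolpath fixtures --out-dir fx
boolpath perturb fx/feedback_loop.json fx/kinase_inhibitors.tsv KINI \
    --init PKC=0.5 --out scores.tsv
```

The other subcommands — `convert`, `simulate`, `enrich`, `fi` — expose the
compilation, plain simulation, enrichment and FI-overlay workflows; see
`boolpath --help`.

## Documentation

`docs/methods.md` describes the model, its parameters and defaults, the
synthetic-data generators and their limits, and the numerical choices made
where the underlying conventions were open.
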