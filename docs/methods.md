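# Methods

`traitpaths` implements a comparative analysis of the joint evolution of
two binary traits on a time-calibrated phylogeny. The motivating system
is caterpillar antipredator strategy — colouration (cryptic vs
aposematic) crossed with aggregation (solitary vs group-living) — but
nothing in the machinery is specific to that system beyond naming.

## The model

The two traits are combined into a four-state composite character

| index | code | meaning |
|---|---|---|
| 0 | SC | solitary-cryptic |
| 1 | SA | solitary-aposematic |
| 2 | GC | group-cryptic |
| 3 | GA | group-aposematic |

which evolves along the tree as a continuous-time Markov chain. The
correlated-evolution assumption (Pagel-style pathway modelling) is that
both traits never change in the same instant: the generator Q has zero
entries at SC↔GA and SA↔GC, leaving eight single-trait transition
rates q1..q8. The canonical numbering is

    q1: GC→SC   q2: SA→SC   q3: SC→GC   q4: GA→GC
    q5: SC→SA   q6: GA→SA   q7: GC→GA   q8: SA→GA

This numbering is not arbitrary: it is the unique assignment consistent
with the model-naming scheme used throughout (symmetric pairs eq13,
eq25, eq47, eq68; context-independence pairs eq16, eq24, eq38, eq57;
the 7→6→2→3 directed cycle; and q3 = SC→GC as anchor). A unit test
re-derives it by brute force over all 8! assignments.

Rates are in expected events per unit branch length. Because rescaling
all rates by c and all branch lengths by 1/c leaves the likelihood
unchanged (rate–time confounding), simulated trees are scaled to unit
root-to-tip depth by default and rates read as expected events per tree
depth. Only products q·t are ever identifiable.

## Likelihood

`prune_loglik` computes the probability of the observed tip states by
the standard postorder partial-likelihood recursion (Felsenstein
pruning). Branch transition matrices are P(t) = expm(Qt). Two numerical
choices matter:

- **Per-node rescaling.** Each internal node's partial-likelihood
  vector is divided by its maximum and the log-scaler accumulated, so
  trees with many hundreds of tips do not underflow.
- **Matrix exponentials.** Single calls use scipy's scaling-and-squaring
  Padé `expm`, which is robust for the near-defective generators that
  arise under zero constraints. Inside the optimizer, P(t) over all
  branches of a fixed Q is computed through an eigendecomposition fast
  path, used only when the eigenvector matrix has condition number
  below 1e8; otherwise every branch falls back to `expm`. Entries are
  clipped to [0, 1] and rows renormalized to remove float dust.

The root partial likelihoods are combined using a **root policy**: FLAT
(weight 1/4 per state; the default, mirroring corDISC-style equal root
weighting), STATIONARY (the stationary distribution of Q), or FITZJOHN
(weights proportional to the root partials themselves). The choice is
reported with every result and is deliberately exposed as a sensitivity
axis rather than fixed.

An exhaustive oracle, `enumerate_assignments_loglik`, sums over all
4^(n internal) joint ancestral assignments (capped at 10 internal
nodes). The pruning implementation is required to agree with it to
1e-9; the vectorized "wave" engine used inside the optimizer is in turn
checked against the reference pruning.

Unknown tip states are supported (partial-likelihood vector of ones);
setting a tip to unknown can never decrease the likelihood, which is
asserted as a property test.

## The model space and AIC selection

Candidate models constrain the eight rates:

- **general** — no constraints, K = 8.
- **nX.. models** — the listed rates fixed to zero (transition
  impossible). All nonempty proper subsets of {1..8} give 2^8 − 2 = 254
  models, named by ascending digits (n3, n34, ...). Subsets that make
  the chain reducible are still fitted — the likelihood remains defined
  — and a reducibility flag is carried into the output table, because
  dropping them would change the weight normalization.
- **eqXY models** — rates X and Y share one free parameter, K = 7.
  Eight are included: the four symmetric pairs and the four
  context-independence pairs listed above.

Each model is fitted by maximizing the pruning log-likelihood over its
free parameters in log space with Nelder–Mead (derivative-free:
gradients of expm through the pruning recursion are awkward, and the
surfaces under zero constraints are multimodal, so multi-start is used
instead). Defaults: 10 random restarts drawn log-uniformly from
[1e-2, 10] (draws over the full box [1e-9, 100] would pin most starts
to a flat likelihood plateau at the lower bound), plus one warm start
at the general-model MLE projected onto the constraint; bounds
q ∈ [1e-9, 100] enforced by clipping, with boundary hits flagged;
convergence tolerance 1e-8 on the log-likelihood. Fits are
deterministic given (data, model, seed, settings).

Models are compared by AIC = 2K − 2 logLik, with ΔAIC relative to the
minimum, evidence ratio exp((AICmin − AIC)/2), and Akaike weights
normalized over the **entire fitted set** (not a displayed top-10) —
the published top-10 weights summing to ≈0.979 indicates full-set
normalization. AIC ties are broken lexicographically by model name for
determinism.

Because a nested model's maximized likelihood can never exceed its
parent's, the sweep finishes with a repair pass: nested pairs are
enumerated through the constraint lattice, and any parent beaten by its
own restriction is refit warm-started from the winning nested solution
(a few rounds; violations only ever arise from finite optimization).
Sweeps are resumable — per-model fits are serialized and skipped on
re-run.

## Ancestral states

`marginal_ancestral_states` computes, for every node, the marginal
posterior P(node = s | all tip data) by combining downward partials
with an "outside" quantity propagated root-to-tip:

    G_root = root-policy weights
    G_child(s') = Σ_s G_node(s) · Π_siblings (P L)(s) · P_child[s, s']

and normalizing G·L per node (per-node normalization cancels all
rescaling constants). This is marginal — not joint/MAP —
reconstruction, matching the per-node relative-likelihood pie-chart
convention of plotRECON-style displays. Against exact enumeration the
marginals agree to 1e-9 on small trees.

Nodes in serialized output are identified by postorder rank plus the
sorted list of subtended tip labels, since Newick child order is not
canonical.

## Synthetic data

There is no bundled empirical dataset; generators produce data with the
structure the analysis assumes.

- **Trees**: pure-birth (Yule) simulation conditioned on the number of
  tips, frozen one extra exponential waiting time after the n-th
  lineage appears so terminal branches are positive; optionally
  rescaled to unit depth. Ultrametricity is exact by construction.
- **Traits**: forward CTMC simulation along every branch (exponential
  waiting times + jump chain), returning both tip states and the
  latent internal states so recovery tests can score reconstructions.
- **Study emulation** (`emulate_study_dataset`): a 676-tip unit-depth
  tree with tip-state composition targeting 80.0 / 12.1 / 3.1 / 4.7 %
  for SC / SA / GC / GA. Rates are found by a deterministic search —
  a detailed-balance initial guess refined by Nelder–Mead so that the
  stationary distribution of Q equals the target composition, under
  the constraint q1 = 0 (the best-supported pathway, in which
  group-living can be lost only by aposematic lineages). Root states
  are drawn from that stationary distribution, so expected tip
  frequencies equal the target exactly; the solved rates are then
  rescaled so the slowest relaxation mode of Q decays ~5 e-folds per
  unit depth. That mixing level keeps the realized SC fraction within
  roughly ±7 points of its 80% target across seeds while leaving
  phylogenetic signal in the data. Tuning acts on rates, not on
  rejection-sampling trees: rejecting on a 676-tip joint composition
  would be infeasible.

What the generators do **not** emulate: diversification-rate variation
or extinction (no birth–death), trait-dependent diversification,
sampling bias in which species get measured, and phylogenetic error
(the tree is known without uncertainty). Passing recovery tests
therefore demonstrate correctness of the machinery under the model's
own assumptions, not robustness of the biological conclusions to
violations of them.

## Recovery benchmarks

`recovery_experiment` simulates under known truth, refits candidate
models, and summarizes rate errors and the AIC rank of the true model,
with an independent seed stream per replicate. The benchmark truth
`BENCHMARK_RATES = (1.0, 1.2, 1.5, 0.9, 1.1, 1.6, 0.8, 1.4)` was chosen
once: moderate, well-separated rates whose stationary distribution is
roughly balanced (~23/24/30/23 %), so all four states are visited and
all eight rates are identifiable on a unit-depth tree of a few hundred
tips. (A composition as skewed as the empirical 80/12/3/5 leaves the
group-cryptic exits nearly unidentifiable at these sample sizes, which
is a property of the design, not a bug in the fitter.)

Standard runs use 500-tip trees and 20 replicates with 2 optimizer
restarts per fit — enough for each rate's median relative error to sit
well under 50% and for an n1 truth to be preferred over the general
model by AIC in well over 70% of replicates, while keeping a full
harness run in minutes on one CPU. The acceptance script's full
263-model sweep uses 64-tip data for the same reason; the sweep's
combinatorics and bookkeeping are identical at any size.

## Known limitations

- Nelder–Mead with a handful of restarts can stop short of the global
  optimum on near-flat likelihood surfaces; the nesting repair pass
  removes the visible symptom (nested-pair inversions) but cannot
  certify global optimality.
- Rates at the 1e-9 lower bound are reported as boundary hits rather
  than rounded to exact zero; models with structural zeros should be
  expressed as n-models, not inferred from tiny estimates.
- The equality-model list is the eight two-rate patterns used in the
  motivating analysis, not all 28 pairs; other patterns can be built
  directly with `ModelSpec`.
- No confidence intervals on rate estimates, no AICc/BIC, no hidden
  (rate-heterogeneity) states, no stochastic character mapping.
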