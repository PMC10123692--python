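# Methods

This note documents the models and procedures implemented in `imatpipe`,
the assumptions behind them, the parameters that matter, and the design
choices made where the methodology left room.

## Model preparation

**Lipid boundary expansion.** Whole-cell lipidomics measures the pooled
abundance of a lipid across all compartments. To impose such a measurement
as a flux bound, the model gains a boundary compartment (`bd`): for a
measured lipid present in several intracellular compartments, one boundary
metabolite is created, with one transport reaction per intracellular
instance and a sink on the pool; a lipid confined to one compartment gets a
sink directly on its instance. All added reactions are reversible
([−1000, 1000]) so that measured net changes of either sign can be imposed
later, and carry a provenance annotation so they can be identified and, if
needed, excluded from reports.

**Reduction.** Blocked reactions are found by flux variability analysis run
with *no* objective-optimality constraint (`fraction_of_optimum = 0`):
blocked status is a property of the whole feasible space, and constraining
to an optimal objective face would misclassify reactions. A reaction is
blocked when |min flux| and |max flux| are both below 1e−9 (solver-noise
floor). Dead-end metabolites (participating in no remaining reaction) are
then stripped iteratively together with reactions whose stoichiometry has
become empty, to a fixed point. The pipeline default is
expand-then-reduce, so that sinks added for measured lipids can unblock
otherwise dead lipid pools; the order is a config switch
(`expand_before_reduce`). Reversible reactions are kept as single signed
flux variables throughout (no direction splitting).

## Transcriptome integration

Per-gene summary = arithmetic mean over replicates. Classification
thresholds are the lower/upper percentiles (linear interpolation between
order statistics — one of several common percentile definitions; the choice
is recorded in `GeneClassMap` for provenance) of the distribution of means
over the *metabolic* genes (those appearing in GPRs) by default; a config
flag switches to the full transcriptome distribution. Comparison is strict,
so a gene exactly at a threshold is moderate. GPR folding uses AND = min,
OR = max over {−1, 0, +1}: a complex is limited by its scarcest subunit,
isozymes by their most expressed member. Genes missing from the data count
as moderate (0) — conservative: they never push a reaction into R_H or R_L
on their own. Reactions with empty GPRs are never members of R_H/R_L.

## Metabolomic bounds

The measured net change window per species is
`ub = (c5 + Sd5) − (c0 − Sd0)`, `lb = (c5 − Sd5) − (c0 + Sd0)`
(width 2(Sd0 + Sd5) ≥ 0 by construction). Exchange fluxes are rates, so the
window is divided by the 5 h sampling interval by default; `as_rate=False`
gives the raw concentration differences for strict replication of the
formulas. Sign convention: positive = secretion/accumulation. Medium
measurements map to exchange reactions, whole-cell measurements to the
sinks created by the lipid expansion.

Measurement noise can produce a window that forces net production or
consumption of a species the network cannot balance; the strict
`apply_exchange_bounds` raises a diagnostic listing the applied bounds,
while the pipeline uses `relax_infeasible_bounds`, which widens sign-forcing
intervals to include zero — narrowest interval first, since it carries the
least information — until the model is feasible, and reports every
relaxation in `exchange_bounds.tsv`.

## iMAT and activity calls

The MILP (see README for the formulation) is assembled over the reduced,
bounded model and solved with HiGHS via `scipy.optimize.milp` at zero MIP
gap; the solve is deterministic for a fixed problem, and the backend and
tolerances are recorded in the run manifest. Infinite declared bounds are
boxed at ±1000 (standard iMAT scaling), and ε defaults to 1.0 — an
undocumented constant in this class of analyses; both are configurable.

The reverse-activity constraint is implemented as
`v_i + y⁻_i (v_max,i + ε) ≤ v_max,i`, so that y⁻ = 1 forces v_i ≤ −ε. The
inequality is sometimes printed with "≥" in the literature; in that
direction y⁻ = 0 pins v_i at its upper bound and y⁻ = 1 merely demands
v_i ≥ −ε, so reverse activity cannot be expressed (the package exposes the
printed variant behind `printed_eq5=True` for comparison, and the test
suite demonstrates the defect on a reversible pathway).

**Sensitivity.** For every reaction two forced MILPs are solved: active
(|v_i| ≥ ε, direction-agnostic via one auxiliary binary) and inactive
(v_i = 0). With objective-equality tolerance 1e−6 (safe — the objective is
integer valued): active ⟺ only the forced-active problem attains the
unconstrained optimum; inactive ⟺ only the forced-inactive one; otherwise
undetermined. An infeasible forced problem counts as −∞. Note a reaction
whose optimal flux lies strictly between 0 and ε in every optimum can have
both forced objectives below the optimum; it is reported undetermined.

**Robustness.** Sensitivity calls are computed at the percentile pairs
(30, 70), (33, 66), (40, 60); the consensus keeps a call only when all
pairs agree on a determined state. Pathways whose per-pair Fisher tests
disagree are flagged (`threshold_consistent` reporting) rather than
dropped.

## Pathway and reaction comparison

Pathway activity = #active / #reactions per GEM subsystem (undetermined
counts as not active; unlabeled reactions pool under "unassigned").
Between conditions, each subsystem and threshold pair gives a 2×2 table
active vs not-active (undetermined pooled with inactive — the natural
reading of comparing activity-state counts), tested with Fisher's exact
test and Bonferroni-corrected by the number of subsystems tested.
A pathway is differentially activated when |mean ratio difference| > 0.10
and the maximum corrected p across pairs < 0.05. Transport subsystems are
flagged so reports can exclude them from distortion-prone summaries.
Differential reactions require an active consensus in exactly one condition
and inactive in the other; undetermined anywhere excludes the reaction.

## Hold-out validation

A fraction of measured species (default 20%) is excluded from the bounds
and used as a test set: the predicted sign of each held-out exchange flux
(positive = secreted) is compared with the sign of its measured rate.
Predictions default to the flux vector of the optimal solution at the
middle threshold pair, abstaining when the consensus is undetermined or
|flux| < ε/100; `validation_mode="fva"` instead predicts only when the
flux-variability interval of the held-out exchange excludes zero (mass
balance against the constrained remainder of the network pins the flux).
Agreement is tested with Fisher's exact test on the predicted×observed sign
table (a binomial test against a fair coin is available), abstentions are
excluded and reported, and per-condition plus pooled figures are emitted.

## GSEA

Genes are ranked by Pearson correlation with the phenotype (binary 0/1 for
two-condition runs; an explicit ordinal vector, e.g. tumor stage, may be
supplied). Constant genes score 0; ties break by gene id for determinism.
The running sum increments by |score|^p / Σ_hits |score|^p at set members
(p = 1, the weighted scheme) and decrements by 1/(N − N_hits) elsewhere;
ES is the signed maximum excursion. The null re-ranks the genes for each of
n_perm phenotype-label permutations (default 1000). NES divides ES by the
mean |null ES| of matching sign; the nominal p is the same-signed tail
fraction (floored at 1/n_perm); the FDR q compares each observed NES with
the pooled sign-matched normalized null. Two significance rules are
reported as flags: FDR ≤ 0.1 ∧ NES > 1.5 ∧ leading-edge signal > 50%
(cell-line comparisons) and FDR ≤ 0.25 (tumor-stage panels). "Leading-edge
signal" is interpreted as the fraction of the set's in-list genes at or
before the running-sum extremum — the term has no standard printed
definition, so this interpretation is a documented choice.

With few samples per class (e.g. 4 vs 4) the permutation space is small
(70 distinct label assignments): p-values are granular and strongly
inter-correlated gene blocks inflate the null ES, depressing NES. The
calibration tests therefore use panels with individually noisy signal
genes; uniformity of null p-values is checked at 10 samples per class.

## PLS-DA / VIP

PLS regression of the dummy-coded class (A = 1, B = 0) on autoscaled
expression (unit variance — the conventional default), 2 components unless
configured otherwise. With unit-norm X-weights w_a and SS_a the class
variance explained by component a,

    VIP_j = sqrt( p · Σ_a w_ja² SS_a / Σ_a SS_a ),    Σ_j VIP_j² = p.

The signature is every gene with VIP ≥ 1.5 (inclusive). Note that label
flips in noisy data are genuinely discriminative patterns: they dilute the
VIP of the planted genes, so small all-signal panels can legitimately yield
an empty signature at the 1.5 cutoff.

## Synthetic data

The generator defines the study conditions and is itself tested code.

*Network*: a shared uptake hub feeds one irreversible linear chain per
pathway (subsystem), each ending in its own secretion exchange; dangling
reactions with consumer-less products are planted as blocked. *Roles*: one
differential pathway (flux only in the exposed condition; genes high there,
low in control), the rest cycling inactive / moderate / moderate / active.
The moderate pathways carry flux but sit mid-distribution in expression,
keeping each percentile stratum populated so that strict classification
recovers the planted high/low classes; roles are arranged so the high
stratum stays below one third of genes. *GPRs*: 1–3 genes per reaction
(all sharing the reaction's stratum, so AND/OR mixes propagate it).
*Expression*: stratum means 4 / 8 / 12 with within-stratum SD 0.3,
multiplicative replicate noise at 5% CV, 4 replicates per condition, and a
configurable fraction of genes mislabeled to another stratum
(default 0.1). *Metabolomics*: c5 = c0 + rate × duration with
multiplicative log-normal replicate noise (default 10% CV, triplicates,
5 h); chain fluxes are drawn from [1.5, 3.0], above ε, and the baseline
concentration (10, plus |rate|·duration for consumed species) is sized so
that rate × duration dominates replicate noise — with a noisier baseline a
spurious 3-replicate interval around a zero rate can clear ε and flip a
call. One caveat the tests make explicit: the mean ± replicate-SD window of
triplicates is not a 95% interval — its coverage of the true rate is ≈ 88%
regardless of noise scale.

What the generator does *not* emulate: genome-scale network topology
(cycles, cofactor coupling, thermodynamically infeasible loops), shared
genes between reactions, probe-level microarray artifacts, or compartment
ambiguity of real lipidomics. Passing tests therefore show the machinery is
correct and calibrated on well-posed inputs, not that real-data inference
is error-free.

## Problem sizes and defaults

End-to-end tests run the default study (4 pathways × 6 reactions, flip 0.1,
cv 0.1, ε = 1) over 20 seeds. The acceptance script uses a 12 × 6 study for
the pathway statistics (small pathways cannot reach Bonferroni significance
once a dozen subsystems are tested — with 4-reaction pathways the best
achievable corrected p exceeds 0.05), and pools hold-out comparisons over
eight independent 6 × 6 studies: small networks keep mass balance
informative for held-out exchanges, while a wide measured panel accumulates
enough interval slack that a single large network pins little.

## Known limitations

- Sensitivity analysis solves 2 MILPs per reaction per threshold pair;
  at genome scale this demands a commercial solver or heavy parallelism.
  The scipy/HiGHS backend is exact but single-threaded here.
- No thermodynamic (loop-law) constraints; flux directions in loops are
  only bounded by the declared reaction bounds.
- The Fisher 2×2 construction for pathway comparison (active vs not-active)
  treats undetermined as inactive; pathways dominated by undetermined calls
  are compared on little information.
- GSEA FDR follows the pooled sign-matched convention; with very few gene
  sets the q-values are coarse.
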