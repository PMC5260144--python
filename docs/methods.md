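# Methods

## The model in one paragraph

`macpol` couples two scales.  At the microscopic scale every macrophage
carries an 18-node signed Boolean network of the M1/M2 polarization
circuitry (inputs IFN-γ, IL-10, IL-4, LPS; receptors TLR4, IFNγR, IL-4Rα,
IL-10R; transducers/targets NF-κB, STAT1, SOCS3, NOS2, STAT6, PPARγ, SOCS1,
KLF4, Arg1, STAT3) updated synchronously:
a node becomes active iff at least one activating parent is active and no
inhibiting parent is.  At the mesoscopic scale, macrophages, B cells and
three helper T-cell classes (Th1, Th2, Treg) diffuse with antigen, antibody
and cytokine tokens on a periodic L×L×L lattice and interact through 15
local stochastic reaction rules (activation, phagocytosis/presentation,
helper priming, cytokine release, B-cell proliferation with antibody
secretion, antibody–antigen neutralization).  The two scales meet in the
differentiation rule: each step, every active or presenting M0 macrophage
clamps the locally sensed input vector onto its network, advances it k
synchronous updates (default k = 1), and terminally differentiates if the
state lands on a committed attractor — a fixed point of the clamped
dynamics expressing NOS2 (M1) or Arg1 (M2).

## Commitment semantics

The committed attractor depends on the input regime (e.g. the IL-4-driven
and IL-10-driven M2 fixed points differ in their IL-10R/STAT3 bits), so
commitment is defined by attractor *class*, not by one hard-coded state: a
state commits iff it is a fixed point under its own input bits and its
marker gene is on.  Network validation enumerates all 2^18 states and
checks, for each of the 16 input regimes, that at most one NOS2-marked and
at most one Arg1-marked fixed point exists and that no fixed point carries
both markers; for the bundled network every (IFN-γ or LPS) regime without
IL-4/IL-10 has exactly one M1 attractor and every (IL-4 or IL-10) regime
exactly one M2 attractor, so the two committed labels are mutually
exclusive by construction (f1 + f2 ≤ 1 in the differentiation rule).  The
mixed IFN-γ+IL-10 regimes are bistable (one attractor of each class) with
large cyclic transients; trajectories that do not converge never commit and
are reported as non-converging by the attractor report, never silently
classified.

## Within-step reaction semantics

One rule order is drawn per step and applied at every site (rules are
strictly local; a per-site reshuffle would only permute independent
events).  Matching is greedy over disjoint reactant sets; every
participating entity — including catalytic ones that reappear among the
products — takes part in at most one firing per step, which also implements
"once per pair per step" for the presentation/secretion reactions.  Tokens
produced during the reaction phase are staged and become reactive the next
step, though they are already visible to the same step's differentiation
phase.  With all rule probabilities at 1 (the default), the deactivation
rules (presenting→active, active→resting, helper active→resting) fire on
every entity not already engaged that step, so activation states are
short-lived unless continuously re-stimulated — activity has to be paid for
with contact or cytokine every step.

## Rule-table choices (all configurable flags)

* **IFN-γ is catalytic in macrophage activation.**  The activation rule is
  written with IFN-γ on both sides: one token can activate at most one
  resting macrophage per step and is removed by decay, not by signalling.
  With strict consumption, one token buys roughly three macrophage-active
  steps, which regenerate far less than one token through downstream
  secretion, so macrophage activation could never reach the population
  scale at which polarization and dampening are observable.  The flag
  `ifng_consumed_on_activation` restores the strictly consuming form.
* **Phenotype gating.**  M2-committed macrophages neither release IFN-γ on
  Th1 contact nor prime resting helpers (they remain phagocytic and still
  release IL-4/IL-10 on Th2/Treg contact); M1-committed macrophages do not
  release IL-4 on Th2 contact.  This encodes the M2 phenotype's
  IL-12-low, immunoregulatory, poor-Th1-priming character and is the causal
  pathway by which IL-10-driven M2 commitment weakens antigen control.
  Disable with `phenotype_gated_secretion`.
* **Helper activation is macrophage-borne.**  Only presenting macrophages
  prime resting helpers (the literal form of the priming rule).  An
  optional variant (`bcell_activates_helpers`) lets presenting B cells
  prime helpers too; it is off by default because it makes the B-cell arm
  self-igniting and independent of macrophages, which removes any effect of
  macrophage polarization on the outcome of an infection.
* **Th2-driven B proliferation duplicates the Th2 helper**
  (`r11_duplicates_h2`); the literal variant converts the engaged Th2 cell
  into two active Th1 cells.

## Engine-level processes outside the rule table

* **Innate helper stimulation** (`helper_innate_activation`, default 0.001
  per resting helper per step): a low-rate, antigen-independent activation
  of helper cells.  Without it the printed rule set is inert — every IFN-γ
  source requires an active helper and every helper activation requires a
  presenting macrophage, which requires IFN-γ.  The transiently active
  helpers seed the first IFN-γ through contacts with presenting B cells;
  the macrophage loop then amplifies.  The rate also sets the ignition-time
  distribution of the response (see calibration).
* **Antigen replication**: each antigen token divides with probability
  `ag_replication_prob` (default 0.1) per step, logistically damped by a
  per-site carrying capacity (`ag_site_capacity`, default 50) so an
  uncontrolled infection saturates instead of growing without bound.
* **Molecule decay**: cytokines decay with a 20-step half-life, antibodies
  with a 40-step half-life; antigen does not decay.
* **Homeostatic lymphocyte cap** (`lymphocyte_expansion_limit`, default 8×
  the initial B+helper count): proliferation products beyond the cap are
  not created (the reaction still fires and still secretes).  There is no
  cell death in the model, so clonal contraction is replaced by this
  saturation.

## Default study conditions and why

A 9×9×9 periodic lattice carries 500 macrophages and 2 500 lymphocytes
(625 B, 625 of each helper class — the ≈5:1 lymphocyte:monocyte ratio of a
normal differential white-cell count), about four cells per site.  This
dense packing is deliberate: reaction gains are products of local contact
probabilities, and below roughly two cells per site no interaction loop is
supercritical — the system stays inert no matter how long it runs.  Runs
last 800 steps at 24 steps per simulated day (33 days), placing the
day-3-to-day-10 cytokine injection window of the challenge scenarios over
the period in which the response ignites and macrophages commit.
A replicate is fully determined by one seed, split into independent named
streams (init/rules/differentiation/diffusion/injection/decay), so adding
draws to one component does not perturb another.

Scenario stimuli: the bacterial scenarios inject 8 000 LPS-bearing antigen
tokens at step 0 (large enough to establish against baseline phagocytic
consumption); the vaccine scenario injects a 36 000-token non-replicating
bolus (it must persist into the IL-4 window on consumption alone) plus
16 000 IL-4 tokens daily on days 3–9; the dampening scenario adds IL-10
daily on days 3–9 at the calibrated dose below.

## Calibration of the IL-10 dose

The IL-10 dose is the one quantitatively calibrated parameter.  Procedure
(`macpol calibrate-dampening`, a grid of at most 10 dose levels): run an
ensemble of the bacterium-then-IL-10 scenario per dose level with a
disjoint seed block, label each replicate *dampened* iff its final antigen
count is at least the inoculum (the infection was not controlled), and
select the dose whose dampened fraction is closest to the target.  On the
development grid (2–96 k tokens/day, 24 replicates per level) the
dose–response rises steeply from 0 at dose 0 to a plateau of ≈0.7 above
≈24 k/day; 8 000 tokens/day sits at ≈0.4 and is the frozen default.
The dampened fraction is an ignition-timing race: replicates whose response
ignites before the IL-10 window commit enough M1 macrophages to control
the infection; replicates that ignite inside the window commit
predominantly M2, lose macrophage IFN-γ secretion and Th1 priming, and the
bacterium persists at carrying capacity.

## What the synthetic scenarios do and do not emulate

The scenarios are self-contained simulations; nothing is fitted to wet-lab
data.  They capture the *logic* of polarized responses — stimulus-dependent
attractor selection inside each cell, cytokine-mediated crosstalk between
cells, population-level bimodality of outcomes — under deliberately crude
physics: unit-token molecules, equal diffusion speeds for cells and
molecules, no chemotaxis, no antigen specificity or clonal selection, no
cell death or aging, one generic antigen.  Passing tests therefore
demonstrate internal coherence of the multiscale logic, not quantitative
agreement with any experimental system.

## Numerical and implementation notes

* The Boolean dynamics is compiled to bitmask operations over packed
  integer states with a full 2^n transition table for n ≤ 22 nodes (1 MiB
  for the default 18-node network); fixed-point enumeration is `T == id`
  and per-agent iteration is a table lookup.
* Census audit is always on: every census change is attributed to a rule
  firing, commitment, injection, replication or decay event, and the
  predicted per-step delta must match the observed delta exactly; any
  discrepancy raises immediately with a dump.
* Random selection of which agents react uses per-step i.i.d. priorities,
  so the choice among co-located matching agents is uniform; newborn agents
  are marked used and cannot react in their birth step.
* Degenerate inputs: an empty lattice or zero-step run yields the initial
  census only; a network too large to enumerate is refused explicitly with
  its size; configs with unknown keys, negative counts or injections beyond
  the horizon are rejected at load.

## Known limitations

* Qualitative scenario behaviour depends on the dense default packing;
  halving densities puts every loop below threshold (by design of the
  contact physics, not a bug).
* The homeostatic caps (lymphocyte expansion, antigen carrying capacity)
  are the only stand-ins for death/contraction; census totals therefore
  saturate rather than decline after clearance.
* The mixed IFN-γ+IL-10 input regimes put the network in large limit
  cycles; macrophages under sustained mixed stimulus may wander without
  committing, which is biologically plausible but untestable here.
* The dampened fraction is calibration-dependent by construction: dose,
  schedule and the classification threshold are explicit configuration,
  and only the dose was calibrated against the target fraction.
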