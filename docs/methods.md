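# Methods

## The model

`synapsim` generates and simulates kinetic (QSP-style) models of
multispecific T-cell engagers in closed in vitro systems.  The reference
model describes a trispecific CD3xCD28xCD38 antibody acting on a sample of
multiple-myeloma (MM) patient blood: naive, effector-memory (EM) and active
T cells of CD4 and CD8 lineage, MM cells, and a lumped CD38+ PBMC
population.  T cells carry CD3 and CD28; MM cells carry CD38 and CD28;
PBMCs carry CD38 only.  CD38 on T cells is deliberately omitted: its
expression is well below that of CD28 on T cells and of CD38 on PBMCs, and
representing it would inflate the state space without adding predictive
value.

The drug has one binding site per arm.  Each arm is parameterised by an
association rate `kon` (nM^-1 h^-1) and an equilibrium constant `KD` (nM);
the dissociation rate is always the derived quantity `koff = KD * kon`.
Monovalently bound receptors on two different cells can be crosslinked into
*bridges*; `b` bridges (the bridges-per-synapse factor) constitute one
cell--cell synapse.  A synapse between cells A and B exists for every
admissible pairing (A carries receptor rA, B carries rB, and rA, rB are
targeted by *different* arms — one arm cannot bridge two copies of its own
target).  All cell behaviour is zero- or first-order except synapse
formation and naive T-cell activation:

* **Synapse formation.**  For the direction in which drug is pre-bound on
  rA and bridges a free rB, the synapse-formation rate is
  `c_AB * kon(rB) * Bound(rA@A) * Free(rB@B) / (b * N_A * V)` where `c_AB`
  is the dimensionless collision factor of the pool pair, `N_A` Avogadro's
  number in molecules/(nM mL), and `V` the experiment volume in mL — i.e.
  a mass-action crosslinking law scaled so that cells in smaller volumes
  collide more often (the collision factor is referenced to `ref_volume`,
  the volume at which it was calibrated; combining `c * ref_volume/V` with
  the nM-to-molecule conversion at `ref_volume` reduces to the `1/V` law
  above).  The symmetric direction (drug pre-bound on rB) is generated as a
  second term with `kon(rA)`.  Each formation event moves one cell from
  each free pool into the synapse, carries the cells' per-cell average
  receptor states along, and sequesters `b` receptors of each bridging type
  per synapse; bridged receptors can neither bind nor release drug.
* **Dissociation.**  Each bond direction breaks at its arm's `koff` per
  synapse; the bridging drug stays monovalently bound on the member whose
  bond did not break, both cells return to their free pools, and their
  tracked receptor states return proportionally.  (The alternative reading
  in which dissociation clears drug would violate mass conservation on a
  benign unbinding event; drug is cleared only with killed or degraded
  cells and by soluble-antigen complexation.)
* **Activation.**  An EM T cell bridged in synapse *through its CD3
  receptor* converts to the corresponding active-T synapse at the constant
  rate `k_act,EM`.  A naive T cell with the same topology converts at
  `k_act,naive * [B3/(Km_CD3+B3)] * [B28/(Km_CD28+B28)]` — an AND gate of
  Michaelis–Menten terms in the per-cell drug-bound CD3 and CD28 (`B3`
  includes the `b` bridged, hence drug-bound, CD3 copies).  With no
  drug-bound CD28 the gate is closed and naive cells never activate; this
  is what removes naive T cells from the bispecific variant's repertoire.
  A conversion whose product would be a homotypic synapse (e.g. an
  EM_CD4–active_CD4 pair converting to active_CD4–active_CD4) is
  suppressed because homotypic species are outside the enumeration; the
  affected flux is negligible.
* **Killing.**  Active-T–MM and active-T–PBMC synapses are destroyed at a
  killer-lineage-specific rate (`k_kill`, CD8 > CD4 enforced as a
  calibration bound).  The killer returns to its free active pool with its
  bridged receptors freed; the victim, its receptors and all drug engaged
  on the victim (monovalent and bridge) are routed to degradation fluxes.
  T–T synapses never kill.
* **Resistance.**  Active-T–MM synapses convert at `k_res` into a
  dissociated state in which the MM cell escapes to a distinct resistant
  pool that re-forms synapses but is never killed.  This bounds maximum
  killing below 100%.
* **Lifecycle.**  First-order proliferation and death per free pool
  (synapsed cells neither divide nor die); newborn cells carry fresh free
  receptors at the expression level.  Registered as synthesis/degradation
  fluxes.
* **Cytokines.**  Active T cells secrete TNF-a, IFN-g and IL-6 at constant
  per-cell rates wherever they are; PBMCs secrete IL-6 and IL-10 only while
  in synapse.  Cytokines are not degraded in vitro.
* **Soluble CD38.**  Shed at a constant per-cell rate from MM-lineage free
  pools, absent initially, and binds drug reversibly into an inert complex
  (a drug sink).
* **Drug.**  A fixed amount is present from t=0; there is no PK layer.

## Enumeration convention and structural counts

State species are: free drug, soluble CD38, the drug–sCD38 complex, the
four cytokines; one free pool per cell type plus one resistant pool per
killable tumor type; one synapse species per admissible pairing of two
*distinct* pools; and free/drug-bound receptor copy-number species for each
receptor on each context (a context being a free pool or a synapse
membership).  Bridged receptors are not separate states: a synapse holds
exactly `b` bridged copies of each of its two bridging receptors per
synapse unit, so the bridged amount equals `b x` the synapse copy number
and adding an ODE for it would be redundant; occupancy and audit
calculations account for it implicitly.  Flux accumulators are audit
variables, not model states, and are excluded from all species counts.

For the full model this enumerates 9 pools, 82 synapses, 17 free-pool
receptor contexts and 314 synapse-membership receptor contexts (x2 states),
plus 7 well-mixed species: 760 state variables.  The parameter manifest
lists kon/KD/koff per arm (9), the bridges-per-synapse factor, one
collision factor per interacting pool pair (36, all initialised from the
definition's single collision factor — encounter rates are physically
pair-specific, and calibration ties them to one value), dose, volume and
reference volume, two activation rates and two half-saturation constants,
four killing rates, the resistance rate, proliferation and death rates per
pool (18), eight cytokine production rates, four soluble-CD38 constants,
17 expression levels and 9 initial pool counts: 114 parameters.  These
counts are convention-dependent; the convention above is part of the
package contract and the minimal two-cell model's hand enumeration is the
companion structural check.

## Units and numerics

Counts (cells, receptors, molecules) are the internal state unit; doses in
nM are converted via Avogadro's number and the experiment volume at setup.
Time is hours, volume mL.  The solver is stiff-capable (BDF) with the
Jacobian sparsity pattern derived from the rule structure; defaults are
`rtol 1e-8`, `atol 1e-6` (calibration loops use `rtol 1e-6`, `atol 1e-2`,
which moves endpoint observables by well under 0.01% and roughly halves run
time).  Rate evaluation clips states at zero, and per-cell shares
`X/(N + eps)` use `eps = 1e-12` to remain defined as pools empty.  The
flux audit integrates one synthesis and one degradation accumulator per
conserved lineage (cells per lineage; receptors per receptor-lineage
pair; drug; sCD38; each cytokine) and checks
`total(t) = total(0) + synthesis(t) - degradation(t)` to a relative
tolerance of 1e-6 at every reported time (default reporting grid: 97
evenly spaced points).  Killing is reported control-normalised at matched
time, `100 * (1 - N(t)/N_control(t))`, the standard convention for
proliferating target lines.

## Stand-in parameterisation

No public dataset accompanies the study design, so the shipped default
parameters are order-of-magnitude, literature-plausible stand-ins chosen
once: arm affinities in the sub-nM to few-nM range typical of engineered
TCE arms (CD38 0.3 nM, CD3 1 nM, CD28 5 nM, with kon 0.5/0.2/0.1
nM^-1 h^-1), expression levels of 6e4 CD3 and 3e4 CD28 per T cell, 1e4
CD28 per MM cell, 1e4 CD38 per PBMC, and tumor-line CD38 of 1.29e5
(high) or 2.5e3 (low) copies per cell; lifecycle rates giving ~23 h active
T-cell doubling, ~35 h tumor doubling and day-scale death times;
`b = 5` bridges per synapse; a collision factor of 2e-3 at the 0.2 mL
reference volume placing the killing EC50 in the low-nM-fraction range; and
an MM-patient blood composition of ~1.2e6 T cells, 6e5 CD38+ PBMC and 5e4
circulating MM cells per mL.  With these values the model reproduces the
qualitative study conditions — killing rises steeply over sub-nM doses and
plateaus for the trispecific, while the bispecific variant's effective
receptor occupancy on MM cells follows a bell — but absolute killing
percentages at specific doses are not transferable to the published
calibrated model, whose fitted parameter values are not public.

## Synthetic experiments and staged calibration

The synthetic-data module emulates five assays: PBMC activation
(% activated T cells), pre-activated CD8 cytotoxicity for the CD38-high and
CD38-low lines (% killing), a MIMIC-style cytokine-range assay (per-cytokine
min/max bands over 10 simulated replicates with 30% lognormal spread),
a 6-day sorted-T-cell (1e5) proliferation time course, and a 24-h
qualification cytotoxicity at 2e5 PBMC : 2e4 MM (10:1 E:T).  Point
observations carry 5% multiplicative lognormal noise; assays are read in
triplicate at several times within the incubation (4/12/24 h for
activation, 6/24/48 h for cytotoxicity) — kinetic, replicated readouts are
standard practice and are what makes the synapse-formation/activation rate
product identifiable, which endpoint-only data are not.  Every generated
dataset records its generating truth and seed so parameter-recovery
closes the loop automatically.  The generator does not attempt to
reproduce donor-to-donor variability structure; bands are envelopes of
replicate noise around a single truth.

Calibration proceeds in stages with earlier stages frozen: activation and
synapse parameters (kon_CD3, k_act,EM, k_act,naive, collision factor)
against the tumor-free activation assay; killing and resistance against
the two cytotoxicity lines; cytokine production rates against the range
data, where the loss is zero inside a band and quadratic in the distance
to the nearest edge outside (scales are per-observable medians, so %
observables and molecule-scale cytokines mix on equal footing).  The
optimiser is differential evolution in log10 space (seeded, population
based, Sobol initialisation, followed by a local polish), with search
ranges set a priori to literature-plausible windows (e.g. kon_CD3 in
[0.05, 1] nM^-1 h^-1, collision factor in [5e-4, 8e-3]).  A flat final
population triggers an unidentifiability warning rather than an error.
The range-fit stage also returns its final optimiser population filtered
by band coverage (>= 90% of points inside the bands) — these members form
the virtual population, with initial T-subset counts rescaled to a
requested total while preserving composition ratios.  Two traditional
point fits to the band minima and maxima bracket the population envelope.
At the shipped study conditions the staged fit recovers all six target
parameters within 20% relative error; the resistance rate is the weakest
(its 2-fold profile moves high-dose killing by only a few points, close
to the noise floor — hence the denser 8-dose, 3-time design for the
cytotoxicity stage).

## Sensitivity analysis

Latin-hypercube sampling perturbs every strictly positive parameter
uniformly within +/-10% of baseline (one sample per quantile stratum;
zero-baseline parameters such as a disabled arm's kon are reported fixed),
the model is run at a low (8.4e-4 nM) and a high (0.672 nM) dose for 24 h,
and each output of interest — tumor killing, total active T cells, free
active T cells, ineffective tumor synapses — is reduced to its trapezoidal
AUC.  PRCC is computed via the precision matrix of the pooled
rank-correlation matrix (equivalent to correlating double-regression rank
residuals, which an independent brute-force implementation cross-checks to
1e-10), with t-statistic p-values at `n - 2 - (p - 1)` degrees of freedom.
Parameters are retained at p < 0.01 and the heatmap subset at |PRCC| >
0.80.  The default sample size n = 200 is a desk-scale choice (it is not
stated in the underlying study design) and is reported with every result.
Population-scale runs use a CD8-only blood-composition variant (321
species) so that 200-sample studies complete in tens of seconds; the full
760-species model is used for single trajectories and audits.

## Bispecific comparator and curve shapes

The bispecific comparator is the same definition with the CD28 arm's kon
set to zero (koff follows as zero); nothing else changes.  This removes
every T–T, MM–MM and MM–PBMC bridge and closes the naive-activation gate.
Synapse effectiveness follows the tumor-centric rule: a synapse is
effective if it joins an MM cell and can lead to T-cell activation or
killing — active-T–MM always; naive/EM-T–MM when the T cell is bridged
through CD3 and carries drug on both CD3 and CD28 at the assessed time;
MM–MM and MM–PBMC never; and under the bispecific, naive-T synapses never.
Dose–response studies run 12 log-spaced doses from 1e-5 to 10 nM over 3
days (the grid used in the underlying analysis is not printed; this one
covers its printed 8.4e-4–0.672 nM window with margin).  Shape calls are
made by two detectors: *plateau* — the final third of the grid stays
within 10% of the grid maximum; *bell* — an interior maximum exceeds both
endpoint values by more than 10%.

## Limitations

No antigen-presenting cells, no cytokine feedback on proliferation or
secretion, no PBMC activation, no spatial structure or stochasticity, no
in vivo PK or clinical dose projection.  Homotypic (same-pool) synapses
are not enumerated.  Synapse dissociation is modelled as a single
synapse-level event per bond direction at the arm's koff rather than as
sequential failure of all `b` bridges.  Passing tests demonstrate internal
consistency and recovery of the generator's own truth under the stated
noise model — not agreement with any particular wet-lab dataset.
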