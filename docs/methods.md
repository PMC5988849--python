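# Methods

## Scope and model structure

`angiotriad` implements a deterministic, multi-compartment kinetic model of
VEGF signaling through VEGFR2 to Akt and eNOS in an endothelial cell, and of
its inhibition by thrombospondin-1 (TSP1) acting through CD47. The model has
two layers:

1. **A rule-based receptor layer.** Six molecule types (VEGF, VEGFR2,
   VEGFR1, NRP1, CD47, TSP1) carry binding sites and one lumped VEGFR2
   phosphosite (`Y1175 ∈ {u, p}`). Thirty-odd reaction rules describe ligand
   binding, VEGF-mediated dimerization (homo- and heterodimers),
   constitutive VEGFR2–CD47 coupling, TSP1 binding to VEGFR2-coupled CD47,
   VEGFR1–NRP1 coupling, ligand-independent receptor coupling,
   autophosphorylation in VEGF-bridged VEGFR2 homodimers, trafficking
   through two signaling endosomes (SE1, SE2) and a recycling endosome (RE),
   NRP1-gated exit from SE2 to RE, degradation from the signaling endosomes,
   recycling of unphosphorylated receptors, and VEGFR2 synthesis. The rule
   engine (`rulegraph`) expands these rules into the full reaction network
   (418 species, ~1.8k elementary reactions with the nominal rule set) by
   fixed-point application with canonical graph labeling; mass-action
   statistical factors are embedding counts divided by rule-pattern
   automorphisms, with a 1/2 factor for self-reactions.

2. **An explicit downstream cascade.** Total phosphorylated VEGFR2 over
   PM+SE1+SE2 is the single driver of two arms: TSAd/Src → Axl-1 (two
   ordered phosphosites) → PI3K → PIP3 → membrane Akt (S473 by mTOR, then
   T308 by PDK1 — T308 strictly requires prior S473), and PLCγ → IP3 →
   ER Ca release/CRAC/SERCA/PMCA → Ca/CaM → eNOS. eNOS activates in two
   steps: Ca/CaM displaces caveolin-1 (partial activation), then doubly
   phosphorylated Akt phosphorylates S1177 (full, Ca-insensitive
   activation). Receptors resident in RE do not signal.

## Units and doses

Membrane and endosomal species are in molecules/cell; cytosolic cascade
species in µM; extracellular VEGF and TSP1 are clamped bath species in nM
whose value is set by protocol events (a fixed-dose bath without ligand
depletion). 50 ng/ml VEGF is converted at an assumed 45 kDa dimer mass to
≈1.1 nM. The canonical protocol adds 2.2 nM TSP1 ten minutes before VEGF
and observes the following hour; "maximum" readouts are peaks over the
post-VEGF window on a 1 s output grid.

## TSP1 mechanism hooks

Three multipliers act only on complexes that contain TSP1-bound CD47:

- `fTSP1_i2r ∈ [0,1]` scales SE2→RE transport (trafficking block),
- `fTSP1_deg ≥ 1` scales degradation from SE1/SE2,
- `fTSP1_dp ≥ 1` scales the plasma-membrane dephosphorylation rate
  (phosphatase recruitment).

Each hook is realized as a filtered rule pair (base rule excluding, scaled
rule including the TSP1-bound pattern), so neutral hooks with zero TSP1 are
*exactly* the control model. Interventions: TSP1/CD47 depletion scale the
dose/seed amounts before pre-equilibration; Kd scaling multiplies the
TSP1–CD47 off-rate with the on-rate fixed; cycloheximide zeroes the
synthesis rate constant; NRP1 knockout zeroes the NRP1 seed.

## Nominal parameterization

The original model's full fitted parameter table is not available to this
package; the shipped nominal set (see `PARAMETER_TABLE` in `model.py`, with units and
descriptions) was chosen once to reproduce the qualitative fitted behavior:
a transient total-pR2 peak within ~4 min relaxing to a lower quasi-steady
level; the majority of the pR2 signal carried by internalized receptors
(endosome/surface signal-integral ratio ≈ 12); Akt and eNOS peaking after
pR2; receptor synthesis `ksingleR2_syn = 1.4e-4 s⁻¹ × 6000 receptors ≈
0.84 receptors/s` balancing constitutive turnover at rest. Receptor totals
are 6000 VEGFR2, 10000 CD47, 1800 VEGFR1, 20000 NRP1 per cell (HUVEC-scale
surface numbers). TSP1–CD47 affinity is picomolar (Kd ≈ 25 pM), so a 2.2 nM
dose saturates CD47 ≈ 99%.

Three structural choices make the two signaling arms respond differently to
the TSP1 mechanisms, which is the scientific core of the mechanism scans:

- Autophosphorylation occurs at the plasma membrane; internalized dimers
  inherit their surface phospho-state. Endosomal dephosphorylation is slow
  (τ ≈ 28 min) while surface dephosphorylation is fast, so the endosomal
  pool dominates the signal and the surface phospho-fraction propagates
  into the endosomes. Phosphatase recruitment (`fTSP1_dp`) therefore scales
  the *whole* drive, while enhanced degradation (`fTSP1_deg`) removes only
  the endosomal component.
- TSAd/Src activation is threshold-like (Hill 2 in the drive), so Akt stays
  on while the surface-derived component persists (the degradation-only
  plateau) but collapses when both mechanisms act together.
- The PLCγ→IP3 arm is a slow sub-saturated integrator, and ER release is a
  cubic Hill function of IP3 with half-activation above the early IP3
  transient; sustained Ca elevation is carried by store-operated (CRAC)
  entry after ER depletion. Enhanced degradation alone removes the
  sustained drive, keeps the store full and thereby ablates Ca/CaM and
  eNOS — reproducing the near-linear relation between peak pS1177 and peak
  Ca/CaM across the degradation scan.

## Calcium module forms

`d[Ca]/dt = J_IP3R + J_leak,ER + J_CRAC + J_in − J_SERCA − J_PMCA` with
`J_IP3R = Iip3R_amp · (IP3/(km_ip3+IP3))³ · ([Ca]_ER − [Ca])`,
`J_CRAC = ICRAC_amp · max(0, 1 − ([Ca]_ER/[Ca]_ER,max)²)`, Hill-2 SERCA and
Hill-1 PMCA pumps; the ER balance is the negative of the exchange terms
scaled by an effective cytosol/ER volume ratio (β = 5). The ER leak and the
plasma-membrane influx are calibrated in closed form so the stated resting
point (0.1 µM cytosolic, 400 µM ER, 0.05 µM IP3) is a steady state. These
are standard store-operated forms matched to the named amplitude
parameters; the package claims structural, not equation-level, fidelity for
this module.

## Numerics

The network compiles to a sparse mass-action system (stoichiometry matrix ×
rate vector) with an analytic sparse Jacobian; the cascade block has a
hand-derived dense Jacobian (checked against finite differences in the test
suite). Integration uses BDF with stop-modify-restart at event times (all
events are at known times; no root finding). Default tolerances are
rtol 1e-8 / atol 1e-10; scans use rtol 1e-6 / atol 1e-8, under which every
reported peak is stable to halving the tolerances within 0.1%. States are
clipped at zero only below −100·atol·scale; larger negativity raises a
structured error naming the worst state. Pre-stimulus steady states are
found by a short transient integration followed by pseudo-transient
Newton continuation, which preserves the conserved totals exactly (the
shifted iteration is regular despite the singular Jacobian directions) and
agrees with long integration to ≈1e-8 relative; the result is cached per
(parameters, seed amounts).

## Synthetic time-course fixtures

`fitting.make_fixture` emulates the Western-blot-derived fitted panel:
receptor totals/surface levels under control, no-VEGF, CHX, CHX+VEGF and
NRP1-absent conditions, plus the signaling time courses (pR2, pPLCγ, Ca,
pSrc, pAxl, pS473, pT308, pS1177) under control stimulation, sampled at
sparse 2–15 min time points, max-normalized, with multiplicative lognormal
noise of configurable CV. What the fixtures do *not* emulate: saturation
and background of film densitometry, biological replicate scatter,
condition-to-condition loading differences, and digitization error — so
passing recovery tests demonstrate identifiability of the pipeline under
idealized relative measurements, not expected accuracy on real blots.
Fitting normalizes simulated series over the dataset's own time points
(exactly as densitometry normalizes observed maxima), fits log10 parameters
inside ±2-decade box bounds with a generalized pattern search (fixed
coordinate poll order, + before −, expand ×2 / contract ×0.5), and returns
a `FitResult` with the iteration and mesh history.

## Sensitivity analysis

Latin hypercube sampling (scipy's stratified sampler) draws log-uniform
multipliers ×[0.1, 10] around nominal values, with an influence-free dummy
parameter appended as a significance yardstick. PRCC rank-transforms
parameters and readout, removes the other parameters by linear regression
on ranks, and correlates the residuals; significance uses the t transform
with N−2−p degrees of freedom. The default full-model design varies the 32
kinetic/amplitude parameters of the receptor, cascade and calcium layers
(structural receptor totals are fixed by measurement); the acceptance runs
use a scaled-down N = 80 design, which is sufficient for stable signs of
the leading parameters.

## Problem sizes used by tests and the acceptance script

Network generation runs to its true fixed point (418 species). Mechanism
scans use the grid {1,2,4,8,16,32}; rescue curves use 5–8 point grids; PRCC
uses N = 80 samples over 32 parameters + dummy; parameter recovery fits 3
parameters (`ksingleR2_syn`, `kp_SrcAxl`, `kcat_PLCgDAG`) against a
7-readout control-condition fixture panel over 5 noise seeds. These sizes
are the package's defaults for its own validation workloads; all are
configurable upward through the library and CLI.

## Known limitations

- The reconstructed rule inventory is leaner than the original published
  network (418 vs 824 species): ligand-independent coupling is restricted
  to VEGFR2 pairs, NRP1 binds only receptor-bound VEGF, and complex growth
  is capped at two receptors per complex (the engine's `max_stoich`
  mechanism). The original model's complete rule file is not among this
  package's inputs, so exact structural equality is not expected.
- The SBML export covers the mass-action reaction network (with clamped
  bath species as boundary conditions); the explicit cascade block is not
  encoded in SBML.
- Ring closures (intramolecular binding) are not supported by the engine;
  no rule in the shipped model requires them.
- CD36/LRP1 TSP1 receptors, VEGF sequestration by TSP1, NO production
  downstream of eNOS and apoptotic signaling are out of scope.
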