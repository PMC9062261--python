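# Methods

## The model

`cardiomyosim` integrates a deterministic kinetic model of energy metabolism
in a cardiac muscle cell.  Five well-mixed compartments are resolved — the
supplying vessel, the extracellular space, the cytosol, the mitochondrial
intermembrane space (IMS) and the mitochondrial matrix — with relative
volumes 0.06842 : 0.24063 : 1 : 0.0715 : 0.6435 liters (cytosol ≡ 1 l).
The registry holds 63 species; 44 are integrated as ODEs, 8 are algebraic
assignments and 11 are clamped constants.  Concentrations are in mM, time in
s, the inner-membrane potential ΔΨ in mV, free energies in kJ/mol.

The reaction network has four blocks:

* **Cytosol** — glycolysis from a clamped glucose supply (HK → PK, reversible
  Michaelis–Menten forms with a shared binding denominator), glycogen
  synthesis and phosphorolysis with AMP-relief of inhibition
  (1 + (K_AMP/[AMP])^1.5), a pentose-phosphate sink proportional to the
  isomerase flux (J_G6PDH = V_f·J_PGI/v_ss), a glucose-1,6-bisphosphate shunt
  that bypasses phosphoglycerate kinase, lactate production/export/
  association, the creatine-kinase and adenylate-kinase buffers (mass action,
  near equilibrium), a load-sensitive ATP consumption
  J_ATPase = X/(1 + R·[Pi][ADP]/[ATP]), and myoglobin–oxygen binding.
* **Matrix** — a single phenomenological dehydrogenase flux standing in for
  pyruvate oxidation plus the whole TCA cycle (reduces NAD⁺ at a rate set by
  the redox ratio and phosphate), and thermodynamically balanced rate laws
  for complexes I, III, IV and the F₁F₀-ATP synthase.  Each carrier flux is
  X·(e^(−ΔG/RT)·substrate − product) with ΔG combining the redox span, the
  pH term, and the proton-motive energy ΔG_H = F·ΔΨ + RT·ln([H]i/[H]x).
* **Inner-membrane transport** — the adenine nucleotide translocase (ANT)
  with the standard 0.35/0.65 electrical partition of ΔΨ across the two
  half-reactions, the phosphate–proton cotransporter operating on the H₂PO₄⁻
  fraction (pKa 6.75), a passive phosphate path, K⁺/H⁺ antiport, Mg²⁺
  binding to ADP/ATP in both mitochondrial compartments, and a Goldman-type
  proton leak.
* **Oxygen chain** — two serial linear conductances (vessel → extracellular
  → cytosol); the vessel concentration is the protocol boundary condition
  (0.1326 mM ≡ 100%).

ΔΨ obeys C_IM·dΔΨ/dt = 4J_C1 + 2J_C3 + 4J_C4 − 3J_F1 − J_ANT − J_Hle; matrix
pH obeys a buffered proton equation with prefactor [H]x/r_buff.  Every other
ODE is the signed flux sum of its species divided by its compartment volume
(fluxes are referenced to the cytosolic volume).

## Nucleotide pools and the mitochondria–cytosol coupling

Free and Mg-bound ADP/ATP are separate states in the matrix; the translocase
acts on free and the synthase on Mg-bound forms, so the total-pool equations
d[ADP]x = (J_ANT − J_F1)/V and d[ATP]x = (J_F1 − J_ANT)/V hold as identities
and matrix adenine and Mg are conserved exactly.  The IMS adenine pool is
slaved to the cytosol (porin exchange across the outer membrane is much
faster than any inner-membrane process): [ADP]i ≡ [ADP]c, [ATP]i ≡ [ATP]c,
with the IMS Mg-binding ODEs partitioning those totals into free and bound
forms.  Consequently the ANT flux is booked against the cytosolic ATP/ADP
pools — outward transport is the cell's oxidative ATP supply, and inward
transport during severe hypoxia is the mitochondrial drain on cytosolic ATP
that accompanies reverse operation of the synthase.  Cytosolic Mg-bound ADP
follows the standard binding quadratic in total ADP (total Mg 5 mM).

## Parameter provenance and completed constants

Kinetic constants for the cytosolic reactions follow the perfused-rat-heart
glycolysis parameterization; the mitochondrial block descends from the
Beard-type biophysical model of oxidative phosphorylation, with its
degree-dependent M→mM rescalings applied (e.g. the K⁺/H⁺ constant 2.9802e4
and the Mg-binding constant 1e3 are the molar-unit values divided by 1000,
and the synthase law carries an explicit 1000-mM factor from the same
conversion).  The full set lives in `src/cardiomyosim/data/model.yaml`,
which is schema-validated on load; `Model.to_yaml()` round-trips it
byte-identically.

A few constants required completion or repair, documented inline in the
model file:

* **X_F1 = 1.0 s⁻¹** (near-equilibrium synthase).  This is the Beard-model
  value in mM units; with the tabulated matrix composition, the synthase
  stall potential then sits at 169.7 mV — exactly the tabulated resting ΔΨ.
* **X_Hle = 60 (s·mV)⁻¹**.  The isolated-mitochondrion leak constant (250)
  would dissipate ~3.4 mM/s of proton flux at 170 mV, beyond what the
  oxygen-transport chain (max ≈ 0.27 mM/s of respiration, so ≈ 2.7 mM/s of
  pumping) can sustain; no polarized rest state would exist.  The default
  was calibrated once against the model's reported operating regime
  (polarized rest near 170–180 mV; deep ATP depletion only at ischemic
  oxygen ≤ 1%; late-ischemia plateau of ΔΨ in the tens of mV).
* **C_IM = 6.75e-3 mM/mV** and **r_buff = 10.857 mM** (β/ln10 with matrix
  buffer capacity β = 25 mM per pH unit) are not part of the printed rate
  tables; they take Beard-class values.
* **Phosphate–proton cotransport** pairs H⁺ and H₂PO₄⁻ on the same membrane
  side (cotransport); the crossed-subscript exchange form would push
  phosphate out of the alkaline matrix and silence the synthase.
* **α_DH = V_matrix/V_cytosol** scales the pyruvate consumed by the lumped
  dehydrogenase; **K_MgATP = 0.024 mM** is used globally (the alternative
  0.0245 mM pair is available as the override preset
  `f1_table_mg_constants`); the saturation factor s1(·) on the
  phosphoglycerate branch is a pluggable unary callable defaulting to
  identity, since cytosolic pH is clamped at 7.1.

## Protocols, integration and steady states

Ischemia/reperfusion experiments are piecewise-constant vessel-oxygen
schedules (fractions of 0.1326 mM).  The canonical single-step protocol is
1000 s physiological, 1000 s ischemic, 1000 s reperfused; the graded
(two-step) protocol inserts an intermediate oxygen level for 1000 s before
full restoration.  Oxygen switches instantaneously, so the integrator
restarts at each boundary with state handoff.

The system is stiff (Mg-binding and acid–base relaxation at 10³–10⁴ s⁻¹
against 10²–10³-s pool dynamics); the default solver is BDF with
rtol = 1e-8, atol = 1e-10 mM (1e-6 mV for ΔΨ).  A full 3000-s protocol
integrates in ~3 s on one core.  Output is reported on a 1-s grid, refined
to 0.05 s for 30 s after every oxygen step-up so the seconds-scale
reperfusion transients of complex III are resolved.  Logarithm and
fractional-power arguments are floored at 1e-15 mM so transient solver
probes outside the positive orthant cannot produce NaNs; the Goldman leak
uses a three-term series for |FΔΨ/RT| < 1e-4.  Concentrations that
undershoot zero by more than 2e-3 mM abort the run with the species named
(small undershoots occur legitimately in the first milliseconds while the
tabulated initial values relax onto the fast-equilibrium manifold).

Two model features preclude a strict fixed point: the lactic-acid reservoir
only accumulates (its association reaction has no outflow), and the printed
cytosolic phosphate bookkeeping is not globally conservative (the
bisphosphate shunt and the sink reactions inject phosphate), so [Pi]c
creeps on a 10⁴-s scale.  `find_steady_state` therefore accepts a state when
the scaled residual falls below 2e-5 s⁻¹, and protocol work uses the
1000-s physiological pre-phase — not a deep relax, which would let the
phosphate drift distort the baseline — as the operational resting state.
At that state ATP is 6.99 mM, CrP 19.7 mM, ΔΨ 180.9 mV, free cytosolic ADP
14 µM, and the glycolytic intermediates sit within a factor of ~2 of the
perfused-heart values used as initial conditions.

## Sensitivity analysis

Relative sensitivities s_ij = (d[C_i]/dX_j)·(X_j/[C_i]) are estimated by
central differences: each enzyme's activity (its maximal-rate constants,
forward and reverse jointly, preserving equilibrium constants) is scaled by
1 ± δ (δ = 1%) and the full protocol re-simulated — two stiff solves per
enzyme, 77 for the 38-activity registry, cached so the three evaluation
timepoints (end of pre-phase, end of ischemia, end of reperfusion; standard
1% protocol) share one sweep.  Control strength is the L1 norm over the 44
dynamic species (ΔΨ included; the relative form is unitless so mixing is
valid), ranked descending with lexicographic tie-breaks.  Species with
near-zero baseline are excluded and logged.  Hexokinase carries the largest
control at the physiological and post-reperfusion timepoints (S ≈ 15.4 and
15.5), with phosphofructokinase second — the classical flux-controlling
pattern of cardiac glycolysis.

## Injury surrogates

`metrics` extracts, with linear interpolation on the output grid: ATP
depletion time (first crossing below 5% — configurable — of the preischemic
value after ischemia onset); recovery/settling times (first time after the
final oxygen step-up that a trace enters and remains within 5% of its final
value; a trace still moving in the last 2% of the window reports "not
settled"); the late-ischemia ΔΨ plateau (last pre-reperfusion sample); the
reperfusion ΔΨ spike ratio and its duration above 1.1× baseline; the
maximal contiguous interval of negative complex-I flux after reperfusion
(reverse electron transport, the ROS surrogate); and the complex-III
overshoot ratio within 60 s of reperfusion.

## What the defaults do and do not reproduce

With the completed constants the model reproduces: a polarized,
oxidative-dominant resting state at the tabulated concentrations; severity-
ordered ischemic energy collapse (cytosolic ATP falls 6.99 → 1.0 mM at 1%
oxygen, is maintained near baseline at 10%); fast creatine-phosphate
discharge at ischemia onset and its recovery ~60 s after reperfusion in the
150-s protocol, with the ATP:ADP ratio settling in ~90 s; a late-ischemia
membrane-potential plateau of ≈67 mV sustained by residual synthase
reversal against the leak; and a complex-III overshoot (≈1.6×) at
reperfusion.

It does **not** reproduce a complete ATP crash below 5% of baseline, a
≈200-s recovery, a twofold ΔΨ spike, or sustained reverse electron
transport.  The structural reason is documented by the test suite's budget
analysis: with glucose, cytosolic NAD/NADH and pH clamped, glycolysis plus
the load-feedback on consumption always find a low-turnover balance
("hibernation") near 1 mM ATP, and a synthase near equilibrium clamps ΔΨ to
its sliding stall potential, absorbing the reperfusion pumping burst before
the potential can overshoot.  Reproducing those phenomena would require
dynamics outside this rate-law set (glucose washout, pH excursions, or a
different consumption law).  The corresponding acceptance tests are left
failing rather than re-tuned.

The synthetic experiments here emulate perfused-heart oxygen-switch
preparations with an instantaneously mixed vasculature; they omit vascular
transport delays, oxygen diffusion gradients, calcium and contraction
coupling, fatty-acid oxidation, explicit complex II, ROS chemistry and any
injury/cell-death mechanism.  Passing tests therefore certify the kinetic
and thermodynamic consistency of the implementation and the listed
reproductions — not predictive validity for tissue.
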