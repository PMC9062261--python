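# cardiomyosim

Kinetic simulation of energy metabolism in a cardiac muscle cell through
ischemia and reperfusion.

When a coronary vessel is occluded, the cardiomyocyte loses its oxygen
supply: oxidative phosphorylation stalls, creatine phosphate and glycogen
buffer the ATP pool for a while, and the mitochondrial membrane potential
collapses.  Restoring oxygen restarts the electron transport chain against
fully reduced ubiquinone and cytochrome-c pools — the conditions suspected
of driving reactive-oxygen damage at reperfusion.  `cardiomyosim` is a tool
for simulating exactly these transitions: it integrates a five-compartment
ODE model (vessel, extracellular space, cytosol, mitochondrial
intermembrane space, matrix; 63 species, 44 of them dynamic) of glycolysis,
glycogen handling, lactate dynamics, creatine/adenylate buffering,
oxidative phosphorylation and oxygen transport, and extracts the scalar
readouts used to reason about reperfusion injury: ATP depletion and
recovery times, the membrane-potential plateau and spike, reverse electron
transport at complex I, and the complex-III rate overshoot.  It is aimed at
systems-biology and cardiac-physiology researchers who want a reproducible,
scriptable platform for testing reperfusion protocols in silico.

## The model in brief

Each species obeys d[C]/dt = (ΣJ_production − ΣJ_consumption ± ΣJ_transport)/V,
with fluxes from reversible Michaelis–Menten kinetics (glycolysis), mass
action (buffers, Mg binding), and thermodynamically balanced carrier laws
for the respiratory chain, e.g. complex I

    J_C1 = X_C1 · ( e^(−(ΔG_C1 + 4ΔG_H)/RT) · [NADH]x − [NAD]x ),

driven by the proton-motive energy ΔG_H = F·ΔΨ + RT·ln([H]i/[H]x).  The
membrane potential integrates the pumped and consumed charge,

    C_IM · dΔΨ/dt = 4J_C1 + 2J_C3 + 4J_C4 − 3J_F1 − J_ANT − J_Hle,

and ischemia/reperfusion experiments are piecewise-constant vessel-oxygen
schedules (fractions of the physiological 0.1326 mM).  `docs/methods.md`
describes the rate laws, the nucleotide-pool bookkeeping, the parameter
provenance, and exactly which published operating points the default
parameterization does and does not reproduce.

## Worked example

```python
from cardiomyosim import (default_model, standard_protocol, simulate,
                          SolverSettings, ir_metrics)

model = default_model()
protocol = standard_protocol(ischemic_fraction=0.01)   # 1% of physiological O2
result = simulate(model, protocol, SolverSettings(method="BDF"))

m = ir_metrics(result)
print(f"preischemic ATP      : {result.value_at('ATP_c', 999.0):.2f} mM")
print(f"end-ischemia ATP     : {result.value_at('ATP_c', 1999.0):.2f} mM")
print(f"membrane potential   : {result.value_at('DPSI', 999.0):.1f} -> "
      f"{m.dpsi_ischemic_plateau:.1f} mV during ischemia")
print(f"ATP recovery time    : {m.atp_recovery_time:.0f} s after reperfusion")
print(f"CrP recovery time    : {m.crp_recovery_time:.0f} s after reperfusion")
print(f"complex III overshoot: {m.c3_spike_ratio:.2f} x preischemic")
```

prints

    preischemic ATP      : 6.99 mM
    end-ischemia ATP     : 1.00 mM
    membrane potential   : 180.9 -> 67.4 mV during ischemia
    ATP recovery time    : 37 s after reperfusion
    CrP recovery time    : 403 s after reperfusion
    complex III overshoot: 1.58 x preischemic

Reading: during the 1000-s physiological pre-phase the cell settles into a
polarized, oxidative resting state (ATP ≈ 7 mM, ΔΨ ≈ 181 mV).  Cutting
vessel oxygen to 1% stops respiration; creatine phosphate discharges within
the first minute, ATP falls to ~1 mM (about 86% depletion — the residual is
sustained by glycolysis running against the throttled consumption), and the
membrane potential decays to a ~67 mV plateau held by partial reversal of
the ATP synthase.  On reperfusion the ATP pool refills within ~40 s, the
creatine store over several minutes, and complex III transiently overshoots
its resting rate.

A command-line interface wraps the same pipeline:

    cardiomyosim simulate --protocol standard --o2-fraction 0.01 --out traj.csv
    cardiomyosim sensitivity --timepoint physiol --out control_table.csv
    cardiomyosim metrics --o2-fraction 0.005 --out metrics.json
    cardiomyosim export-sbml --out model.xml

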