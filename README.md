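# dendrhythm

Cortical pyramidal neurons receive inhibition at two distinct membrane
domains: parvalbumin-like basket cells contact the soma and proximal
dendrites (the *perisomatic* zone), while somatostatin-like interneurons
target the *distal* dendrites. These populations also pace different local
rhythms — gamma (40–80 Hz) and beta (12–35 Hz) respectively. `dendrhythm`
is a simulation and analysis pipeline for asking how the **location** and
**rhythmicity** of inhibition interact to shape dendritic integration in a
layer-5 (L5) pyramidal neuron whose dendrites support Na⁺, NMDA, and Ca²⁺
spikes.

The pipeline has four stages, each usable on its own:

1. **Synthetic presynaptic drive** (`dendrhythm.inputs`) — inhomogeneous
   Poisson spike trains for thousands of presynaptic nodes. Excitatory
   nodes are organised into functional groups of 100 that share a 1/f-
   spectrum rate modulator normalized to [0.5, 1.5]; feedforward inhibition
   is a lagged (4 ms), rescaled copy of the excitatory modulation.
   Rhythmic inhibition modulates the inhibitory rate as
   r(t) = A·sin(2πft + φ) + off with A = off/(1/d − 1) for modulation depth
   d (beta: 16 Hz, d = 0.2; gamma: 64 Hz, d = 0.4), optionally under a
   Gaussian burst envelope (σ = two cycles). Clustered inputs are 40
   ±2 ms-jittered copies of one Poisson process.
2. **Conductance-based simulation** (`dendrhythm.cell`, `.synapses`,
   `.channels`, `.morphology`) — a reduced multicompartment L5-like cell
   (soma, axon stub, branched basal dendrites, apical trunk with obliques,
   Ca²⁺ hot zone at the nexus, tuft) with ten Hodgkin–Huxley conductances,
   AMPA/NMDA/GABA_A synapses with Mg²⁺ block
   s(V) = [1 + 0.33·exp(−0.06 V)]⁻¹ and two-factor short-term depression
   (D = D₁·D₂, each factor recovering exponentially and multiplied by its
   d ≤ 1 per presynaptic event). The branched cable equation is solved
   implicitly (backward Euler with Hines-ordered elimination) at
   dt = 0.1 ms in a numba-compiled kernel.
3. **Event detection** (`dendrhythm.events`) — somatic APs (upward
   crossings of −10 mV), dendritic Na⁺ spikes (NaT conductance density
   > 0.3 mS/cm², excluding a window after each somatic AP), and NMDA/Ca²⁺
   plateaus (V > −40 mV for ≥ 26 ms jointly with the relevant inward
   current exceeding 130 % of its value at the crossing, ending at 115 %).
4. **Rhythm/phase analytics** (`dendrhythm.analysis`) — spike-triggered
   averages of binary event-presence series, 8-bin phase histograms,
   pairwise phase consistency (PPC), peak/trough stratification,
   rhythm-corrected cross-correlograms, f–I curves, AP voltage thresholds,
   and phase-binned membrane-potential fluctuation bias.

`dendrhythm.experiments` wires the stages into configurable scenarios
(tonic baseline, doubled perisomatic/distal inhibition, E/I-lag, rhythmic,
bursty, and clustered-input regimes) at a reduced desk scale.

## Worked example

```python
from dendrhythm import ScenarioConfig, run_scenario, event_rates

res = run_scenario(ScenarioConfig(regime="baseline", duration=10000.0, seed=1))
for k, v in event_rates(res).items():
    print(f"{k:>14s}: {v:7.2f} Hz")
```

prints

```
            AP:    6.63 Hz
            Na:  114.84 Hz
     Na_apical:   70.63 Hz
      Na_basal:   44.21 Hz
          NMDA:  163.58 Hz
   NMDA_apical:  163.47 Hz
    NMDA_basal:    0.11 Hz
            Ca:   24.63 Hz
     Ca_apical:   24.63 Hz
      Ca_basal:    0.00 Hz
```

`AP` is the somatic firing rate under naturalistic 1/f-modulated drive with
balanced feedforward inhibition — a fluctuation-driven ~5–7 Hz operating
point. The dendritic event rates are summed over all recorded compartments
(an NMDA plateau spanning several electrical compartments is counted in
each, so these are presence rates, not distinct-event counts); Ca²⁺ spikes
are counted in the apical nexus hot zone, which basal dendrites lack.
Doubling the distal inhibitory drive
(`ScenarioConfig(regime="tonic_2x_distal", ...)`) roughly halves the firing
rate and suppresses Ca²⁺ spikes, while doubling perisomatic drive leaves
the dendritic events untouched — the central location-specificity result.

A command-line interface mirrors the library
(`dendrhythm budget | generate-inputs | run | detect-events | analyze |
fixtures`); see `dendrhythm --help`.

## What this is not

The package does not reproduce the source study's exact reconstructed
morphology or tuned per-compartment channel densities (those live in the
original model deposit); the synthetic cell is calibrated for qualitative
event competence at reduced scale. See `docs/methods.md` for the model
description, calibration choices, and known limitations.
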