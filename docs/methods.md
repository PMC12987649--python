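# Methods

This note documents the model, the synthetic-data generator, the numerical
choices, and the calibration decisions behind `dendrhythm`, in the spirit
of a simulator's model documentation. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The scientific question and the shape of the pipeline

The package studies how inhibition that differs in *where* it lands on a
layer-5 pyramidal neuron (perisomatic, i.e. soma plus dendrites within
100 µm path distance, versus distal dendritic) and in *how it varies in
time* (tonic, slowly balanced with excitation, or rhythmic at beta/gamma
frequencies) regulates dendritic integration: the generation of dendritic
Na⁺ spikes, NMDA plateaus and apical Ca²⁺ spikes, and their conversion
into somatic action potentials. Every experiment is in silico: synthetic
presynaptic drive → compartmental simulation → event detection → phase
analytics.

## Presynaptic drive

**Per-node rates.** Excitatory presynaptic nodes draw their mean rate from
a gamma distribution moment-matched to 4.43 ± 2.9 Hz (mean ± SD), floored
at 0.1 Hz. A gamma is used because the empirical distribution is only
available as two moments and cortical rate distributions are positive and
right-skewed. Inhibitory node rates are drawn the same way from
16.9 ± 14.3 Hz (perisomatic) and 3.9 ± 4.9 Hz (dendritic).

**Functional groups.** Excitatory nodes form groups of 100 sharing one
slow modulator: seeded white noise shaped in the frequency domain by a
1/√f amplitude mask (power ∝ 1/f), then min–max normalized to
[0.5, 1.5]. Min–max normalization (rather than a clipped z-transform) is
the simplest reading of "normalized from 0.5 to 1.5" and makes the range
endpoints exact, which the tests assert. Group membership is also spatial:
each node's 2–8 contacts (uniform divergence) lie within a 5–10 µm cluster
on one branch, and a group's clusters fall within a 100 µm span of a
common anchor.

**Feedforward inhibition.** The inhibitory modulator is the average of the
group modulators delayed by 4 ms (circularly, so length and moments are
preserved) and rescaled multiplicatively; the E/I-lag experiments extend
the delay per population (4/125/250/500 ms) and sharpen the excitatory
modulator by raising it to the fourth power with the mean renormalized.

**Rhythms.** Rhythmic inhibition multiplies the target population's rates
by 1 + (d/(1−d))·sin(2πft + φ), i.e. a sinusoid of amplitude
A = off/(1/d − 1) around the offset rate. The phase convention used
everywhere is that **phase 0 is the inhibition maximum and ±π the
minimum**; `analysis.phase_of` is the single source of this mapping. The
phase φ enters *inside* the sine argument — an additive φ outside the sine
would be dimensionally a rate offset, not a phase. Bursts multiply the
sine term by a Gaussian envelope with σ = 2 cycles, repeated at a
configurable period (default 1 s); the offset rate is untouched outside
the burst.

**Sampling.** Spike trains are Bernoulli-per-bin approximations of
inhomogeneous Poisson processes on a 1 ms grid (a spike iff
x[t] ≤ r[t]·dt, x ~ U(0,1)); the generator rejects configurations with
r·dt ≥ 1. Synaptic delivery times are rounded to the 0.1 ms membrane
integration step. Clustered inputs are 40 copies of one Poisson process,
each spike independently jittered by ±2 ms.

## The cell

**Morphology.** A deterministic template stands in for a reconstructed
cell: a lumped soma (25 µm), an axon stub, eight basal dendrites with two
branch orders, an apical trunk (600 µm) carrying oblique branches, a nexus
(the first major apical bifurcation, which together with the first-order
tuft branches forms the Ca²⁺ hot zone) and a binary tuft. Default cable
totals are 7440 µm apical and 4649 µm basal — the values the synapse
budget assumes — and sections are compartmentalized into ≤ 20 µm segments.
A `scale` parameter shrinks all cable lengths for desk-scale runs while
the terminal subtrees (basal, tuft) also thin their diameters by √scale
(floor 0.3 µm) so distal branches keep a realistic local input impedance;
the trunk and nexus keep their calibre so the hot zone stays coupled to
the soma. Optional seeded length jitter is renormalized to preserve
subtree totals. I/O is standard 7-column SWC with a sidecar table for the
region subtags.

**Channels.** Ten Hodgkin–Huxley conductances with gating kinetics from
the widely used L5 pyramidal model family: transient and persistent Na⁺
(NaT, NaP), h-current, muscarinic K⁺ (Im), slow and fast inactivating K⁺
(KPst, KTst), Kv3.1, high- and low-voltage-activated Ca²⁺, and
Ca²⁺-activated K⁺ (SK) driven by a single-pool Ca²⁺ model
(d[Ca]/dt = −k·I_Ca − ([Ca] − 10⁻⁴ mM)/τ, depth 0.1 µm, τ = 120 ms,
Nernst Ca²⁺ reversal). The soma carries the full roster minus Im; the
dendrites carry exactly {NaT, SKv3.1, Im, Ih, CaHVA, CaLVA, SK}; the
roster is validated at assembly. Passive parameters: Cm 1 µF/cm² at
soma/axon and 2 µF/cm² in the dendrites (spine correction), Ra 100 Ω·cm,
leak reversal −90 mV, leak density 0.1 mS/cm² (configuration).

**Densities** (mS/cm², defaults in `channels.default_densities`) are
deliberately simple per-region constants tuned once for qualitative event
competence, since no published per-compartment tables apply to the
synthetic tree: somatic NaT 2040 with strong KTst/SK for spiking and
adaptation; dendritic NaT 30 so local Na⁺ transients cross the 0.3 mS/cm²
detection threshold while backpropagating spikes still attenuate into the
tuft; dendritic Im 1.0 as the main slow subthreshold brake; a nexus hot
zone with CaLVA 60 / CaHVA 10 that supports ≥ 26 ms Ca²⁺ plateaus which
convert single somatic spikes into bursts. The competence tests in
`tests/test_cell.py` assert exactly these behaviours with the module-level
detectors.

## Synapses

Excitatory contacts carry AMPA (τ_rise/τ_decay 0.6/6.9 ms) plus NMDA
(3.7/125 ms, Mg²⁺ unblock s(V) = [1 + 0.33·e^(−0.06V)]⁻¹), reversal 0 mV;
inhibitory contacts carry GABA_A (0.5/6.8 ms), reversal −75 mV. Each
receptor is a two-state gate r' = α·Tmax·ON·(1−r) − β·r with
α = 1/τ_rise − 1/τ_decay and β = 1/τ_decay; the transmitter pulse ON lasts
the analytic dual-exponential time-to-peak
t_peak = τ_r·τ_d/(τ_d−τ_r)·ln(τ_d/τ_r) (AMPA 1.60 ms, GABA_A 1.41 ms,
NMDA 13.42 ms), which makes a single activation rise with τ_rise, decay
with τ_decay, and peak exactly at the dual-exponential time — a property
the tests check to within one integration step. A fixed 1 ms pulse cannot
have this property (a square-pulse response always peaks at the end of the
pulse), which is why the pulse duration is receptor-specific.

Maximal excitatory conductances are log-normal with distribution mean
0.2 nS and SD 0.345 nS (moments of the log-normal itself, matched
analytically); NMDA g_max equals AMPA g_max times a configurable ratio
(default 1:1 — note that plateau incidence and the PSC-based train
induction both depend on this ratio). Inhibitory conductances are fixed at
1 nS. Release is Bernoulli per presynaptic event per contact, with
per-node probabilities uniform on [0.16, 0.9] for excitation and normal
(clipped) per inhibitory population: 0.88 ± 0.05 perisomatic, 0.72 ± 0.10
basal, 0.30 ± 0.08 apical.

**Short-term depression** uses two factors D₁, D₂ per synapse, each
recovering as D ← 1 − (1−D)·e^(−Δt/τ) and multiplied by its d ≤ 1 *after*
every presynaptic stimulus (released or not); a released event's PSC is
scaled by the product at the post-recovery, pre-multiplication point.
Parameter sets (τ₁, d₁, τ₂, d₂): excitatory (35 ms, 0.95, 250 ms, 0.8),
perisomatic inhibitory (40 ms, 0.7, 500 ms, 0.7), dendritic inhibitory
(200 ms, 0.8, —, 1), the last being single-factor since d₂ = 1 disables
the slow factor. The constraint on the product is read as D ≤ 1
(depression factors cannot exceed one). The 8-pulse/50 Hz voltage-clamp
train-induction protocol, (mean(P₆..P₈) − P₁)/max(P), is implemented both
on simulated PSCs and as a depression-only amplitude model; the latter is
the calibration reference because the holding potential and receptor mix
of the original PSC calibrations are unknown. Under the depression-only
model the class ordering |perisomatic| > |excitatory| > |dendritic| holds
(≈ −0.86, −0.61, −0.56), which the tests assert; the absolute values are
not matched to any external calibration.

## Numerics

The cable equation is integrated by backward Euler at dt = 0.1 ms: gates
advance by exponential Euler on precomputed lookup tables (0.05 mV grid),
channel and synaptic conductances are assembled with reversal-weighted
right-hand sides (NMDA's s(V) and the Ca²⁺ Nernst potential use the
previous step's state), and the symmetric tree system is solved exactly by
two-sweep Hines elimination in compartment order. The whole step loop is
one numba kernel (compiled once, cached); fastmath is restricted to flags
that preserve NaN semantics so a non-finite state is detected and raised
as `NumericalFailure` with the failure time. Halving dt changes somatic
voltage by < 0.5 mV RMS over an actively spiking second, and the passive
cell matches an independent frequency-domain sparse impedance solve (the
same solve implements the 20 Hz electrotonic-distance measurement) to
better than 1 %.

Depression factors are updated in-kernel with per-step recovery multipliers
(exact for the linear recovery ODE); synaptic event lists (delivery step,
contact, release flag) are precomputed before integration, so the kernel
is deterministic given its inputs. Recording defaults to every dendritic
compartment at 0.2 ms (V, NaT conductance density, NMDA current, summed
Ca²⁺ current) plus soma voltage at the full step.

## Detection and analytics conventions

Plateau detection applies the voltage criterion (contiguous excursion
above −40 mV lasting ≥ 26 ms; sub-threshold dips can be bridged by a
configurable tolerance, default 0) and the current-ratio criterion (onset
at 130 % of the inward current at the −40 mV crossing, offset at 115 %)
jointly; the same detector serves NMDA spikes (NMDA current) and Ca²⁺
spikes (summed HVA+LVA current). Because the ratio rule is scale-free, a
depolarized excursion anywhere raises the small local Ca²⁺ current
proportionally; Ca²⁺ spikes are therefore *attributed to the nexus hot
zone* in the scenario statistics, which is where they are generated and
where the summary analyses evaluate them. The Na⁺-spike
backpropagation-exclusion window defaults to 2 ms (configurable; a 5 ms
variant is selectable), and the AP peak time for threshold analysis is the
voltage maximum between threshold crossings, with the threshold read 1 ms
before the peak.

The corrected cross-correlogram is computed on windowed (±max_lag, 1 ms
bins) correlograms: the CC between stratum-restricted presynaptic spikes
and all APs plus both autocorrelations are Fourier-transformed, the
coefficients at the modulation frequency (nearest bin ± one neighbour)
are zeroed, and the CC spectrum is divided element-wise by the square root
of the product of the autospectra before inverse transform. Working on
the windowed correlograms (coarse spectral resolution) rather than
full-length spectra matters: full-resolution whitening amplifies
bin-level noise and buries the transmission peak. The peak-area summary
integrates the positive lobe nearest zero lag between its surrounding sign
changes. PPC is the mean cosine of all pairwise phase differences,
algebraically equal to (nR²−1)/(n−1).

## Desk-scale calibration

The study conditions are reproduced at reduced scale (default
morphology scale 0.3, 10–14 s per condition, ~10⁴ synapses), chosen so the
full qualitative suite runs in minutes on one CPU; densities, per-node
rates and all kinetic parameters are the full-scale values. Three
calibration decisions close the remaining freedom:

- **Synaptic weight w.** The synaptic current is I = w·G·(V−E); the
  unitless w is not pinned by any published value. With w = 1 the printed
  input statistics alone set the synaptic mixing potential near −40 mV and
  the cell is mean-driven at tens of Hz, where inhibition contrasts
  vanish. Excitatory w = 0.55 with inhibitory w = 4 places the desk-scale
  cell in a fluctuation-driven ~5–7 Hz regime in which doubling distal
  inhibition suppresses NMDA/Ca²⁺ events and firing, as the full-scale
  study reports.
- **Fixed anatomical counts.** The 150 somatic contacts and the
  187-contact/140 µm clustered-input patch are fixed structures and do not
  scale with the cable; the perisomatic zone radius and functional-group
  span scale with the morphology so zone proportions are preserved.
- **Statistics.** Stochastic suite assertions use three drive seeds on one
  shared cell/placement realization, with medians (rates, thresholds) or
  seed-pooled spike trains (PPC, corrected CC).

## What the generator does and does not emulate

The drive emulates correlated cell assemblies (shared 1/f modulators),
E/I balance with a feedforward lag, realistic rate and release-probability
distributions, imposed (not emergent) rhythms, and co-activated clustered
inputs. It does not emulate: interacting interneuron networks (rhythms
are imposed by construction), synaptic facilitation or receptor
desensitization, conduction delays, or non-stationarities beyond the 1/f
modulation. Passing the suite therefore demonstrates the *mechanistic*
claims (location- and frequency-specific gating of dendritic events) in a
self-consistent model, not a fit to any recorded dataset.

## Known limitations

- Basal NMDA plateaus are essentially absent at desk scale (the shortened
  basal tree is too strongly clamped by the soma); NMDA statistics are
  carried by the apical tree.
- Doubling the perisomatic presynaptic rate barely changes the standing
  perisomatic conductance because the perisomatic depression parameters
  are saturated at the 16.9 Hz operating rate (steady-state efficacy
  ≈ 1/rate); the subtractive f–I threshold shift of perisomatic
  inhibition is therefore at or below detection at desk scale, while its
  divisive (slope) effect and the distal threshold shift do reproduce.
- Absolute event rates, percent modulations, and train-induction values
  are calibration-dependent and are not matched to any published numbers;
  all suite assertions are directions, not magnitudes.
- The depression-only train-induction values differ from PSC-based ones
  whenever kinetic summation is non-negligible (NMDA at 50 Hz).
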