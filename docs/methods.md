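# Methods

`aiseap` simulates how the axon initial segment (AIS) shapes the
extracellular action potential (EAP) of a simplified neuron, using three
layers: a compartmental cable model with Hodgkin–Huxley-type channels, a
line-source-approximation (LSA) forward model for extracellular
potentials, and waveform/spatial metrics with experiment pipelines built
on top. This note records the model, its assumptions, the parameters
that matter, and the design choices made where more than one reasonable
option existed.

## The reduced neuron

The model is a cylindrical soma (20 μm diameter × 30 μm length,
6 segments) joined to a thin unmyelinated axon (1 μm × 50 μm,
10 segments), laid out colinearly along the x axis with the soma centred
at the origin and the axon extending in −x. A 5-μm stretch of the axon
is labelled the AIS; its proximal edge sits `ais_start` μm from the soma
surface (0–45 μm). If the AIS edges do not coincide with the nominal
5-μm segment grid the axon is re-segmented so that they do; if the AIS
would overhang the 50-μm axon, the axon is extended distally. An
optional passive dendrite (2 μm × 400 μm, 10 segments) attaches on the
+x side.

Two channel configurations express the two initiation modes:

* **ais_initiation** — all Na and K channels on the AIS
  (gNa = 96 000 pS/μm², gK = 3 000 pS/μm²; about 1.5 μS and 47 nS total
  over the 5-μm AIS). These are effective lumped densities chosen so the
  spiking AIS behaves as a near-voltage-source driving the soma through
  the axial resistance — the critical-resistive-coupling regime of
  axonal spike initiation — and so that a single AP with a somatic peak
  above 0 mV occurs at *every* AIS position 0–45 μm under the default
  stimulus. Much weaker AIS conductances fail both requirements at
  large soma–AIS distances: the axial charge cannot lift the
  0.019-nF soma above 0 mV through ~90 MΩ of axon.
* **somatic_initiation** — all Na and K on the soma
  (gNa = 500 pS/μm², gK = 100 pS/μm²), the control in which the AP
  arises somatically and the soma and AIS remain nearly isopotential.

Passive properties are textbook cortical values: Ra = 150 Ω·cm,
Cm = 1 μF/cm², g_leak = 0.3 pS/μm² (0.03 mS/cm², τ_m ≈ 33 ms),
E_leak = −70 mV, E_Na = +50 mV, E_K = −90 mV. All are
config-overridable.

## Channel kinetics

Gating follows m³h (Na) and n⁴ (K) with forward/backward rates declared
once in a single parameter table (`aiseap.channels.RATE_TABLE`) using
three primitive forms (exp-linear, exponential, sigmoid). The voltage
dependence is the classical squid parameterisation shifted so rest sits
at −70 mV, with two deliberate modifications:

* **Na activation (m) is 20× faster and its midpoint is shifted +7 mV**
  (half-activation −45 mV, threshold ≈ −60 mV). Fast, low-threshold
  activation is the defining property of axonal sodium channels; without
  it the soma tracks the AIS quasi-statically, no appreciable soma–AIS
  voltage gradient forms, and the axial-current-versus-distance law
  degenerates. The midpoint shift also suppresses the resting window
  current that would otherwise make a strong AIS self-excitable.
* **h and n keep the classical millisecond time scale**, giving the AIS
  spike a 2–3 ms depolarised plateau. The plateau is what allows the
  axial current to deliver enough charge to pull the soma above 0 mV
  even at 45 μm separation; it also makes all APs in this model slower
  and wider than cortical APs in absolute terms. The laws studied here
  (dipole formation, far-field decay exponents, monotone width growth)
  are structural and do not depend on the absolute time scale.

Alternative kinetics can be dropped in as a mapping or YAML file via
`aiseap.channels.load_rate_table` and the `rate_table` argument of
`simulate`, without touching the solver.

## Numerical integration

The cable equation
`C_i dV_i/dt = −I_ion,i + Σ_j g_c(i,j)(V_j − V_i) + I_inj,i`
is integrated with Crank–Nicolson on the tridiagonal chain system
(axial conductances from the two half-segments in series), with gating
variables advanced by exact exponential updates using rates frozen at
the current voltage. The scheme is unconditionally stable; dt defaults
to 0.005 ms (dt > 0.025 ms is rejected) and halving dt moves the somatic
peak by < 1 sample and < 0.01 mV. The initial state (V = E_leak, gates
at steady state) is not an exact equilibrium of the coupled system; the
model settles by a few mV over tens of ms, a slow drift that the
baseline subtraction removes from all field metrics.

The reported per-segment net transmembrane current is the axial influx
Σ_j g_c (V_j − V_i), i.e. capacitive + ionic − injected current with the
injected current's return assigned to its target segment. This makes
the source set monopole-free — Σ_i I_membrane,i = 0 to machine
precision — which is required for the far field to be dipolar (decay
≈ r⁻², never r⁻¹).

## Stimulus protocol and analysis windows

The default stimulus is a weak somatic step: 0.08 nA from t = 2 ms for
13 ms (the somatic-initiation control uses 1.5 nA, as its soma+dendrite
load is ~30× the AIS's). The weak step has three deliberate
consequences: the AP latency exceeds 2 ms, so the baseline window lies
inside the constant-stimulus epoch; the soma sits near threshold (not
depolarised far above it) when the AIS fires, preserving the soma–AIS
driving force; and the stimulus on/off field steps fall outside the
analysis window.

All field metrics reference the **AP initiation event** — the AIS AP
peak when an active AIS exists, else the somatic AP peak (identical at
`ais_start = 0`; the somatic peak lags the AIS spike by up to ~2.4 ms at
45 μm). Baseline is the mean potential 2–1 ms before that reference;
metrics are evaluated on the window [−1, +8] ms around it. The window
exists because, with every channel confined to the AIS and a 33-ms leak
time constant, the soma holds residual AP charge long after the AIS K
conductance deactivates, producing a slowly decaying standing-dipole
tail that is not part of the AP transient.

An "action potential" requires Vm to cross 0 mV at the site in
question; operations needing a somatic AP raise `NoActionPotentialError`
otherwise.

## Extracellular forward model

Each segment is a line of uniformly distributed current along its axis
in an infinite, homogeneous, isotropic, purely resistive medium
(quasi-static), with conductivity σ = 0.3 S/m by default:

    V(x) = I / (4πσL) ∫₀^L ds / |x − p(s)|

evaluated with the arcsinh closed form (machine-precision agreement with
adaptive quadrature; the on-axis-beyond-ends case uses the exact
logarithmic limit). The soma cylinder is represented by its axis line
segments, with no disk correction. Electrodes on a source segment raise
an error rather than being clamped — silent clamps corrupt power-law
fits — and experiment electrode layouts enforce ≥ 2 μm clearance from
every segment. The far-field dipole reference is
V = I·d·cosθ/(4πσr²), valid for r ≫ d.

## Metrics

* **Peak-to-peak amplitude**: max − min over the analysis window.
* **Width at half peak-to-peak amplitude**: dominant extremum = largest
  |value|; threshold half the peak-to-peak amplitude from that extremum
  toward baseline; width = interval between the two threshold crossings
  bracketing the extremum, linearly interpolated between samples. An
  uncrossed side is an error, never a truncated width.
* **Initial positivity**: a positive local maximum exceeding 5%
  (configurable) of the peak-to-peak amplitude before the global trough.
* **Power-law exponent**: OLS of log10(amplitude) on log10(distance)
  inside the fit range, default 200–1000 μm — comfortably far-field for
  source extents ≤ 75 μm. Distances are measured from the soma centre
  (the coordinate origin).
* **Phase plot**: central-difference dV/dt against Vm. Under axonal
  initiation the somatic dV/dt peaks while Vm is still ~15 mV below
  threshold (external axial drive — the "kink" signature); under somatic
  initiation it peaks near the spike maximum.

## Experiments

* **Exponent fit** — AIS at 0/20/45 μm; 20 log-spaced electrodes from
  65 μm (50 μm beyond the soma surface) to 1000 μm along the axis
  opposite the axon, and from 50 to 1000 μm perpendicular through the
  soma centre. Horizontal exponents come out at −1.99…−1.87 (k ≈ −2,
  slightly shallow because the dipole centre sits 10–30 μm axonward of
  the distance origin); vertical exponents ≈ −3, i.e. ≤ −2, because on
  the perpendicular line the leading dipole term vanishes and the
  off-centre dipole plus higher moments dominate.
* **Axial-current scan** — peak axon→soma axial current at the junction
  for AIS proximal-edge distances l = 5…45 μm. The idealised
  resistive-coupling prediction is I ∝ 1/l. In the discretised model
  the 5-μm AIS is one compartment whose node sits at l + 2.5 μm, so even
  a perfect voltage-source AIS gives I ∝ 1/(l + 2.5), whose log–log OLS
  slope over 5–45 μm is −0.85, not −1; the default model measures
  −0.77 (the remaining gap is the residual soma–AIS driving-force
  variation across l). The product I_max·l — the dipole moment that
  sets the far-field amplitude — varies by < 2× while l varies 9×,
  which is the substance of the law: amplitude depends only weakly on
  AIS position. The scan also reports the fixed-slope constant c of
  I = c/l (≈ 44 nA·μm under the default conditions; this constant is
  kinetics- and Ra-dependent).
* **Width scan** — EAP width at half peak-to-peak amplitude at
  electrodes 30 and 100 μm above the soma centre and 30 and 100 μm along
  the axis opposite the axon, for 10 AIS positions 0–45 μm. Width grows
  monotonically with soma–AIS distance at every site (0.13 → 1.8 ms)
  while the somatic intracellular half-width varies by 17%.
* **Dipole maps** — extracellular polarity probes 25 μm above the AIS,
  soma and dendrite at three moments: 0.15 ms before the reference peak,
  at the peak, and during repolarization (located per run as the time
  the reference-site Vm has fallen two-thirds back toward rest, rather
  than at a fixed offset, so the snapshot tracks the model's own time
  scale). Axonal initiation gives AIS-sink/soma-source at the peak,
  reversing during repolarization; somatic initiation gives
  soma-sink/dendrite-source, with soma–AIS axial current at AP onset
  ~3 × 10⁻⁵ of the axonal-initiation peak (the two compartments are
  near-isopotential).

All experiments are deterministic given their configuration; nothing in
the simulation path draws random numbers.

## Synthetic fixtures

Every downstream stage is testable without the solver:

* `make_dipole_currents` — two ≤ 1-μm segments carrying ±I·w(t),
  summing to zero at every instant; its far field has the closed form
  above. Pushed through the full forward-model + amplitude + fit
  pipeline along rays from the dipole centre it recovers k = −2.000.
* `make_biphasic_waveform` — a difference-of-Gaussians trough-then-peak
  trace, rescaled so its *continuous-function* peak-to-peak amplitude
  and half-amplitude width (located by root finding on the analytic
  expression, independent of the sampled-metric implementation) equal
  the requested values; optional leading positive bump of a requested
  fraction of the amplitude.
* `make_powerlaw_profile` — log-spaced distances with amplitudes c·rᵏ
  and seed-deterministic multiplicative lognormal noise (a seed is
  mandatory whenever noise is requested).

The generators emulate the amplitude, width, decay and polarity
structure of EAP-like data, not the statistics of in vivo recordings (no
electrode drift, spike overlap, or correlated noise); tests passing on
them validate the numerics of the metrics, not robustness to real
recording artefacts.

## Known limitations

* The reduced morphology and lumped AIS are caricatures: no
  reconstructed dendritic tree, no Na_v1.2/1.6 density gradients, no
  myelin or nodes. Absolute EAP amplitudes and widths are therefore not
  comparable to experimental values; the spatial laws and contrasts are
  the object of study.
* With all channels in the AIS and a small leak, somatic repolarization
  is slow and AP time scales are 3–10× those of cortical neurons; see
  the kinetics section.
* The axial-current exponent is bounded by the compartmentalisation of
  the AIS (see the scan above); finer AIS segmentation would steepen it
  toward −1 but departs from the canonical 16-segment model.
* The medium is infinite and homogeneous; no electrode filtering,
  boundaries, or anisotropy.
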