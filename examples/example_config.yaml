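# Example run configuration: every key is optional and defaults to the
# package's study conditions.  Unknown keys are rejected.
model:
  ais_start: 45.0        # μm, soma surface -> proximal AIS edge
  ais_length: 5.0        # μm
  channel_config: ais_initiation   # or somatic_initiation
  include_dendrite: false
passive:
  Ra: 150.0              # Ω·cm
  Cm: 1.0                # μF/cm²
stimulus:
  amplitude: 0.08        # nA
  onset: 2.0             # ms
  duration: 13.0         # ms
solver:
  dt: 0.005              # ms
  t_stop: 20.0           # ms
ais_positions: [0.0, 20.0, 45.0]
fit_range: [200.0, 1000.0]   # μm, far-field window for exponent fits
n_electrodes: 20
sigma: 0.3               # S/m, extracellular conductivity
output_dir: results
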