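"""Far-field decay of EAP amplitude: the inverse-square law of the dipole.

For AIS positions 0, 20 and 45 μm from the soma, fits the power-law
exponent k of peak-to-peak EAP amplitude versus distance (log–log OLS,
200–1000 μm) along the soma–AIS axis and perpendicular to it.
"""

from aiseap import exp_exponent_fit
from aiseap.cli_io import ExperimentConfig

res = exp_exponent_fit(ExperimentConfig())
print(res.table.to_string(index=False, float_format="%.4f"))
print(f"\nvertical exponent range: [{res.vertical_k_min:.3f}, "
      f"{res.vertical_k_max:.3f}]")
# Along the axis the amplitude decays as ~r^-2 for every AIS position —
# the far field of the soma-AIS current dipole.  Perpendicular to the
# axis the dipolar cos(θ) factor makes the decay steeper than -2.
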