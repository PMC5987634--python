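"""EAP width grows with the soma–AIS distance.

Scans 10 AIS positions (0–45 μm) and measures the EAP width at half
peak-to-peak amplitude at electrodes 30 and 100 μm above the soma and 30
and 100 μm along the axis opposite the axon, plus the somatic
intracellular AP half-width for comparison.
"""

from aiseap import exp_width_scan
from aiseap.cli_io import ExperimentConfig

res = exp_width_scan(ExperimentConfig())
pivot = res.table.pivot(index="l_um", columns="site", values="width_ms")
print(pivot.to_string(float_format="%.3f"))
print(f"\nwidth non-decreasing with distance: {res.monotone_by_site}")
print(f"somatic intracellular half-width varies "
      f"{res.intracellular_variation:.1%} across the scan")
# The extracellular width tracks how long the axial current flows, which
# grows with the soma-AIS coupling resistance; the intracellular somatic
# waveform changes comparatively little.  Monitoring EAP width over days
# could therefore report AIS relocation in chronic recordings.
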