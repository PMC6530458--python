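"""Sweep wall stiffness and thickness: the study grid as one tidy table.

Reproduces, at desk scale, the structure of the parameter study: peak
flow rises and choke-point compliance falls as the wall stiffens (E
series) or thickens (h series), and every configuration obeys the
wave-speed flow limit to within a fraction of a percent.
"""

from starlingflow.pipeline import run_sweep
from starlingflow.synthetic import R_UP_OPEN, default_parameter_grid

spec = default_parameter_grid(resistances=(R_UP_OPEN,))
table = run_sweep(spec)
print(table.drop(columns="error").to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# VImax should increase monotonically down each series while C_choke
# decreases, and 'agreement (%)' stays well below 10.
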