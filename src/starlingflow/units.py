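"""Unit conversion constants.

Everything inside the package is SI (Pa, m², m³/s).  Clinical interfaces
accept/emit cmH₂O, cm² and L/min.
"""

#: Pascals per centimetre of water column.
CMH2O_PA: float = 98.0665

#: Cubic metres per second in one litre per minute.
LMIN_M3S: float = 1.0 / 60000.0


def lmin_to_m3s(q_lmin: float) -> float:
    """Convert a flowrate from L/min to m³/s."""
    return q_lmin * LMIN_M3S


def m3s_to_lmin(q_m3s: float) -> float:
    """Convert a flowrate from m³/s to L/min."""
    return q_m3s / LMIN_M3S


def cmh2o_to_pa(p: float) -> float:
    """Convert a pressure from cmH₂O to Pa."""
    return p * CMH2O_PA


def pa_to_cmh2o(p: float) -> float:
    """Convert a pressure from Pa to cmH₂O."""
    return p / CMH2O_PA


def compliance_cm2cmh2o_to_si(c: float) -> float:
    """Convert a compliance from cm²/cmH₂O to m²/Pa."""
    return c * 1e-4 / CMH2O_PA


def compliance_si_to_cm2cmh2o(c: float) -> float:
    """Convert a compliance from m²/Pa to cm²/cmH₂O."""
    return c * CMH2O_PA / 1e-4
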