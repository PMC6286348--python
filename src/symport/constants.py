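"""Physical constants shared across the kinetics and stoichiometry modules."""

GAS_CONSTANT = 8.314       # J mol^-1 K^-1
FARADAY = 96485.0          # C mol^-1
TEMPERATURE_K = 295.15     # 22 degC, the oocyte recording temperature


def rt_over_f_mv(temperature_k: float = TEMPERATURE_K) -> float:
    """RT/F in millivolts (~25.4 mV at 22 degC)."""
    return 1000.0 * GAS_CONSTANT * temperature_k / FARADAY
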