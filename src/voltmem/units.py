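"""Internal unit conventions and physical constants.

All quantities inside the package use a single consistent unit system:

* voltage            mV
* time               ms
* conductance        mS/cm^2
* capacitance        uF/cm^2
* current density    uA/cm^2
* concentration      mM
* temperature        degrees Celsius at the API surface, Kelvin internally

With these units, ``dV/dt = -I / C`` comes out directly in mV/ms, and a
capacitance of 1 uF/cm^2 over a leak of 0.2 mS/cm^2 gives a membrane time
constant of 5 ms.
"""

GAS_CONSTANT_R = 8.314  # J / (mol K)
FARADAY_F = 96485.0  # C / mol
ZERO_CELSIUS_K = 273.15


def celsius_to_kelvin(temperature_c: float) -> float:
    return temperature_c + ZERO_CELSIUS_K
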