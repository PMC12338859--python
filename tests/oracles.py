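"""Independent numerical oracles used by the test suite.

The equilibrium weak-acid accumulation oracle never uses the closed-form
accumulation expression: it solves the speciation mass balance numerically
at fixed proton activity in each compartment (root-finding on
HA + HA*Ka/[H+] = total) and then finds the intracellular total whose
protonated-species concentration equals the extracellular one.
"""

from __future__ import annotations

from scipy.optimize import brentq


def speciate_protonated(total_mM: float, pH: float, pKa: float) -> float:
    """Protonated-species concentration by root-finding on the mass balance."""
    if total_mM == 0:
        return 0.0
    Ka = 10.0**-pKa
    H = 10.0**-pH

    def balance(HA: float) -> float:
        return HA + HA * Ka / H - total_mM

    return brentq(balance, 0.0, total_mM, xtol=1e-300, rtol=1e-14)


def equilibrium_conc_I(pH_E: float, pH_I: float, pKa: float, conc_E_mM: float) -> float:
    """Total intracellular concentration equating protonated species across the membrane."""
    if conc_E_mM == 0:
        return 0.0
    HA_target = speciate_protonated(conc_E_mM, pH_E, pKa)
    hi = conc_E_mM * 10.0 ** (abs(pH_I - pH_E) + 2.0) + 1.0

    def mismatch(total: float) -> float:
        return speciate_protonated(total, pH_I, pKa) - HA_target

    return brentq(mismatch, 0.0, hi, xtol=1e-300, rtol=1e-14)
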