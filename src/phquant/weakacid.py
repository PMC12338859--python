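"""Equilibrium weak-acid partitioning across the plasma membrane.

Short-chain fatty acids (SCFAs) such as butyrate are weak acids: only the
protonated (neutral) species crosses lipid membranes freely.  At a given pH
the protonated fraction follows the Henderson-Hasselbalch relation

    f_HA(pH) = 1 / (1 + 10**(pH - pKa)).

If the extracellular compartment is effectively infinite and the protonated
species equilibrates across the membrane, the total intracellular
concentration at equilibrium is

    [SCFA]_I = [SCFA]_E * (10**(pH_I - pKa) + 1) / (10**(pH_E - pKa) + 1),

so an acid bathing a more basic cytosol (pH_I > pH_E) is trapped and
accumulates; the ratio [SCFA]_I/[SCFA]_E is the accumulation factor.

This module computes that pure equilibrium bound.  It deliberately ignores
metabolism, export transporters and cytosolic buffering, which in live cells
keep the realised concentration below the bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "WeakAcidSpecies",
    "PartitionQuery",
    "PartitionResult",
    "BUILTIN_SPECIES",
    "protonated_fraction",
    "protonated_concentration",
    "intracellular_total",
    "scan_table",
]


def _check_finite(name: str, value: float) -> float:
    if value is None or not math.isfinite(value):
        raise ValueError(f"{name} must be a finite number, got {value!r}")
    return float(value)


def _check_pH(name: str, value: float) -> float:
    value = _check_finite(name, value)
    if not 0.0 < value < 14.0:
        raise ValueError(f"{name} must lie in the open interval (0, 14), got {value}")
    return value


@dataclass(frozen=True)
class WeakAcidSpecies:
    """A weak acid with its dissociation constant (pKa, assumed at 37 degC)."""

    name: str
    pKa: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        pKa = _check_finite("pKa", self.pKa)
        if not 0.0 < pKa < 14.0:
            raise ValueError(f"pKa must lie in (0, 14), got {pKa}")


#: Only species whose pKa is sourced; anything else needs a user-supplied value.
BUILTIN_SPECIES: dict[str, WeakAcidSpecies] = {
    "butyrate": WeakAcidSpecies("butyrate", 4.82, "butyric acid, 37 degC"),
    "lactate": WeakAcidSpecies("lactate", 3.86, "lactic acid"),
}


@dataclass(frozen=True)
class PartitionQuery:
    """One partition-model evaluation: species + compartment pH values + dose.

    ``pH_I`` may be omitted for fraction-only queries (no equilibrium
    assumption needed); ``conc_E`` is the total extracellular concentration
    in millimolar.
    """

    species: WeakAcidSpecies
    pH_E: float
    conc_E: float
    pH_I: Optional[float] = None

    def __post_init__(self) -> None:
        _check_pH("pH_E", self.pH_E)
        if self.pH_I is not None:
            _check_pH("pH_I", self.pH_I)
        conc = _check_finite("conc_E", self.conc_E)
        if conc < 0:
            raise ValueError(f"conc_E must be non-negative, got {conc}")


@dataclass(frozen=True)
class PartitionResult:
    """Speciation and accumulation outputs for one query (mM)."""

    frac_protonated: float
    conc_HA: float
    conc_I: float
    accumulation_factor: float


def protonated_fraction(pH: float, pKa: float) -> float:
    """Fraction of a weak acid in the protonated (membrane-permeable) form.

    ``1 / (1 + 10**(pH - pKa))``; strictly decreasing in pH, equal to 0.5 at
    pH == pKa.  Butyrate (pKa 4.82) at colonic pH 5.7 is ~11.6% protonated.
    """
    pH = _check_pH("pH", pH)
    pKa = _check_finite("pKa", pKa)
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def protonated_concentration(q: PartitionQuery) -> float:
    """Concentration (mM) of the protonated species at extracellular pH.

    ``conc_E / (10**(pH_E - pKa) + 1)``, i.e. the protonated fraction times
    the total dose.
    """
    return q.conc_E / (10.0 ** (q.pH_E - q.species.pKa) + 1.0)


def intracellular_total(q: PartitionQuery) -> PartitionResult:
    """Equilibrium total intracellular concentration and accumulation factor.

    Assumes the extracellular reservoir is infinite and that at equilibrium
    the protonated-species concentration is equal on both sides of the
    membrane; the total intracellular concentration then follows from
    Henderson-Hasselbalch speciation at the cytosolic pH.

    Raises ``ValueError`` if ``pH_I`` is absent, because without it the
    equal-protonated-species equilibrium assumption cannot be applied.
    """
    if q.pH_I is None:
        raise ValueError(
            "pH_I is required: the equilibrium assumption equates protonated-species "
            "concentrations across the membrane and needs the intracellular pH"
        )
    pKa = q.species.pKa
    factor = (10.0 ** (q.pH_I - pKa) + 1.0) / (10.0 ** (q.pH_E - pKa) + 1.0)
    frac = protonated_fraction(q.pH_E, pKa)
    return PartitionResult(
        frac_protonated=frac,
        conc_HA=frac * q.conc_E,
        conc_I=factor * q.conc_E,
        accumulation_factor=factor,
    )


def scan_table(
    species_list: Sequence[WeakAcidSpecies],
    pH_E_grid: Sequence[float],
    pH_I: float,
    conc_E: float,
) -> pd.DataFrame:
    """Partition-model scan over species and extracellular pH values.

    Returns one row per (species, pH_E) pair with full speciation columns,
    useful for tabulating expected accumulation across a pH gradient (e.g.
    proximal-to-distal colon).
    """
    if len(species_list) == 0:
        raise ValueError("species_list must be non-empty")
    if len(pH_E_grid) == 0:
        raise ValueError("pH_E_grid must be non-empty")
    rows = []
    for sp in species_list:
        for pH_E in pH_E_grid:
            q = PartitionQuery(species=sp, pH_E=pH_E, pH_I=pH_I, conc_E=conc_E)
            r = intracellular_total(q)
            rows.append(
                {
                    "species": sp.name,
                    "pKa": sp.pKa,
                    "pH_E": float(pH_E),
                    "pH_I": float(pH_I),
                    "conc_E_mM": float(conc_E),
                    "frac_protonated": r.frac_protonated,
                    "conc_HA_mM": r.conc_HA,
                    "conc_I_mM": r.conc_I,
                    "accumulation_factor": r.accumulation_factor,
                }
            )
    return pd.DataFrame(rows)
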