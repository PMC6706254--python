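"""Electrochemical energetics of H⁺/K⁺ exchange across the parietal-cell membrane.

An electroneutral H⁺,K⁺ pump exports n_H protons (cytoplasm → gastric lumen)
and imports n_K potassium ions per ATP hydrolysed. Moving one ion against
its electrochemical gradient costs

    Δμ = RT·ln(c_to / c_from) + z·F·Δψ        [kcal/mol]

and a stoichiometry is thermodynamically feasible when the summed uphill
work does not exceed the free energy released by ATP hydrolysis, |ΔG_ATP|.
Rearranging the feasibility boundary for the proton term gives the maximum
sustainable pH gradient for a given stoichiometry.

Defaults describe the parietal cell at body temperature: cytoplasm pH 7,
120 mM K⁺; gastric juice pH 1.0, 10 mM K⁺; Δψ = 0 (the transport cycle is
electroneutral); ΔG_ATP ≈ −13 kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_KCAL",
    "F_KCAL_PER_VOLT",
    "TransportConditions",
    "Stoichiometry",
    "EnergyReport",
    "chemical_potential",
    "transport_work",
    "feasibility",
    "max_pH_gradient",
]

#: Gas constant, kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.9872e-3
#: Faraday constant, kcal·mol⁻¹·V⁻¹.
F_KCAL_PER_VOLT = 23.061


@dataclass(frozen=True)
class TransportConditions:
    """Ion concentrations on both membrane sides, temperature and potential.

    ``membrane_potential`` is the luminal-minus-cytoplasmic potential in mV;
    the default 0 encodes electroneutral operation.
    """

    temperature: float = 310.0  # K
    pH_in: float = 7.0
    pH_out: float = 1.0
    K_in: float = 120.0  # mM
    K_out: float = 10.0  # mM
    membrane_potential: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.K_in <= 0 or self.K_out <= 0:
            raise ValueError("K+ concentrations must be positive")

    @property
    def RT(self) -> float:
        return R_KCAL * self.temperature


@dataclass(frozen=True)
class Stoichiometry:
    """Ions moved per ATP: ``n_H`` protons out, ``n_K`` potassium in."""

    n_H: float = 1
    n_K: float = 1

    def __post_init__(self) -> None:
        if self.n_H < 0 or self.n_K < 0:
            raise ValueError("stoichiometric coefficients must be non-negative")


@dataclass(frozen=True)
class EnergyReport:
    """Per-ion potentials and totals, both sign conventions.

    ``total_work`` is positive uphill work; ``paper_sign_total`` is its
    negative (chemical potentials quoted as the negative of the work the
    pump must perform). ``feasible``/``max_pH_gradient`` are filled by
    :func:`feasibility` and :func:`max_pH_gradient`.
    """

    dmu_H: float
    dmu_K: float
    total_work: float
    paper_sign_total: float
    stoichiometry: Stoichiometry
    conditions: TransportConditions
    dG_ATP: float | None = None
    feasible: bool | None = None
    max_pH_gradient: float | None = None


def chemical_potential(
    c_from: float,
    c_to: float,
    z: float,
    conditions: TransportConditions,
    delta_psi_mV: float | None = None,
) -> float:
    """Electrochemical potential difference for moving one ion, kcal/mol.

    RT·ln(c_to/c_from) + z·F·Δψ, positive when the move is uphill.
    """
    if c_from <= 0 or c_to <= 0:
        raise ValueError("concentrations must be positive")
    dpsi = conditions.membrane_potential if delta_psi_mV is None else delta_psi_mV
    return conditions.RT * math.log(c_to / c_from) + z * F_KCAL_PER_VOLT * dpsi / 1000.0


def transport_work(
    conditions: TransportConditions, stoichiometry: Stoichiometry
) -> EnergyReport:
    """Uphill work per ATP for the given stoichiometry.

    H⁺ moves cytoplasm (pH_in) → lumen (pH_out); K⁺ moves lumen → cytoplasm.
    Proton concentrations are 10^(−pH) (activities taken as concentrations).
    """
    h_in = 10.0 ** (-conditions.pH_in)
    h_out = 10.0 ** (-conditions.pH_out)
    # H+ export: outward movement sees +Δψ for z=+1; K+ import sees −Δψ.
    dmu_H = chemical_potential(h_in, h_out, +1, conditions)
    dmu_K = chemical_potential(
        conditions.K_out, conditions.K_in, +1, conditions,
        delta_psi_mV=-conditions.membrane_potential,
    )
    total = stoichiometry.n_H * dmu_H + stoichiometry.n_K * dmu_K
    return EnergyReport(
        dmu_H=dmu_H,
        dmu_K=dmu_K,
        total_work=total,
        paper_sign_total=-total,
        stoichiometry=stoichiometry,
        conditions=conditions,
    )


def feasibility(
    conditions: TransportConditions, stoichiometry: Stoichiometry, dG_ATP: float
) -> EnergyReport:
    """Is the stoichiometry thermodynamically allowed against ``dG_ATP``?

    Feasible when total uphill work ≤ |ΔG_ATP| (closed boundary).
    ``dG_ATP`` must be negative (energy released).
    """
    if dG_ATP >= 0:
        raise ValueError("dG_ATP must be negative (kcal/mol released)")
    report = transport_work(conditions, stoichiometry)
    return EnergyReport(
        dmu_H=report.dmu_H,
        dmu_K=report.dmu_K,
        total_work=report.total_work,
        paper_sign_total=report.paper_sign_total,
        stoichiometry=stoichiometry,
        conditions=conditions,
        dG_ATP=dG_ATP,
        feasible=bool(report.total_work <= abs(dG_ATP)),
    )


def max_pH_gradient(
    conditions: TransportConditions, stoichiometry: Stoichiometry, dG_ATP: float
) -> float:
    """Largest pH gradient the pump can sustain, in pH units.

    Solves the feasibility boundary for the proton term:
    ΔpH_max = (|ΔG_ATP| − n_K·Δμ_K − n_H·F·Δψ) / (n_H · ln10 · RT),
    clipped at 0. The K⁺ term and any electrical term are evaluated at the
    given conditions; pH_out in ``conditions`` is ignored (it is the free
    variable).
    """
    if stoichiometry.n_H < 1:
        raise ValueError("max_pH_gradient requires n_H >= 1")
    if dG_ATP >= 0:
        raise ValueError("dG_ATP must be negative (kcal/mol released)")
    dmu_K = chemical_potential(
        conditions.K_out, conditions.K_in, +1, conditions,
        delta_psi_mV=-conditions.membrane_potential,
    )
    electrical_H = F_KCAL_PER_VOLT * conditions.membrane_potential / 1000.0
    numerator = abs(dG_ATP) - stoichiometry.n_K * dmu_K - stoichiometry.n_H * electrical_H
    dpH = numerator / (stoichiometry.n_H * math.log(10.0) * conditions.RT)
    return max(0.0, dpH)
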