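"""Can the pump acidify the stomach to pH 1?

Computes the electrochemical work of exporting H⁺ (cytoplasm pH 7 → lumen
pH 1, a 10⁶-fold gradient) and importing K⁺ (10 → 120 mM, 12-fold) for the
1H⁺:1K⁺ and 2H⁺:2K⁺ stoichiometries, compares the total against the free
energy of ATP hydrolysis in the parietal cell (≈ −13 kcal/mol), and reports
the maximum pH gradient each stoichiometry could sustain. Only the 1:1 mode
can reach the observed gradient of ~6 pH units.
"""

from ionsite import thermo
from ionsite.thermo import Stoichiometry, TransportConditions

cond = TransportConditions()  # pH 7 / 120 mM K+ in; pH 1 / 10 mM K+ out; 310 K
dG_ATP = -13.0  # kcal/mol

for n in (1, 2):
    stoich = Stoichiometry(n, n)
    rep = thermo.feasibility(cond, stoich, dG_ATP)
    dpH = thermo.max_pH_gradient(cond, stoich, dG_ATP)
    print(f"{n}H+:{n}K+ per ATP:")
    print(f"  dmu_H = {rep.dmu_H:.2f} kcal/mol/ion, dmu_K = {rep.dmu_K:.2f}")
    print(f"  sum of chemical potentials = {rep.paper_sign_total:.1f} kcal/mol")
    print(f"  feasible against dG_ATP = {dG_ATP}: {rep.feasible}")
    print(f"  maximum sustainable pH gradient: {dpH:.1f} units")
    print()
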