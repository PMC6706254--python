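"""Bond-valence sums for the gastric proton-pump cation site.

Builds a synthetic coordination site realising the published crystallographic
ion–oxygen distances of the K⁺-occluded E2-P state, computes per-ligand
partial valences and their total with the classic K⁺–O power law, then
calibrates Rb⁺–O parameters from the published Rb⁺ columns and applies them
to the luminal-open structure. A total near 1.0 means the ion is almost
ideally coordinated for a monovalent cation; the luminal-open state's much
smaller total shows a far looser site.
"""

from ionsite import bvs, refdata, synth
from ionsite.bvs import K_O_POWER


def site_from(column, ion="K"):
    return synth.make_coordination_site(
        synth.SiteSpec(
            ion_element=ion,
            ligands=tuple(zip(refdata.LIGAND_LABELS, [d for d, _ in column])),
        )
    )


site = site_from(refdata.K_E2_MGF)
shell = bvs.coordination_shell(site, "element K", cutoff=4.0)
report = bvs.valence_report(shell, K_O_POWER)
print("K+ site, occluded state (8 oxygens within 4 A):")
print(report.as_table())
print()

shell3 = bvs.coordination_shell(site, "element K", cutoff=3.0)
print(f"strong coordinators within 3 A: {len(shell3)}")
print()

rb_params, rms = bvs.calibrate_bv(
    refdata.rb_calibration_pairs(), form="power", cation="Rb+"
)
print(
    f"calibrated Rb-O power law: r0 = {rb_params.r0:.3f} A, "
    f"N = {rb_params.exponent:.2f} (RMS log-residual {rms:.3f})"
)
for name, column in [
    ("occluded Rb-MgFx", refdata.RB_E2_MGF),
    ("occluded Rb-AlFx", refdata.RB_E2_ALF),
    ("luminal-open Rb-BeFx", refdata.RB_SCH_E2_BEF),
]:
    s = site_from(column, ion="Rb")
    sh = bvs.coordination_shell(s, "element RB", cutoff=4.0)
    total = bvs.valence_report(sh, rb_params).total
    print(f"  {name}: total valence {total:.2f} over {len(sh)} oxygens")
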