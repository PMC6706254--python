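"""Published coordination geometry of the gastric proton-pump cation site.

Crystallographic ion–oxygen distances and partial valences for the K⁺/Rb⁺
site of the gastric H⁺,K⁺-ATPase in four E2-P analogue states (PDB 6JXH,
6JXI, 6JXJ and the earlier luminal-open Rb⁺·(SCH)E2BeFx structure). Only
oxygen atoms within 4 Å of the bound cation enter the valence sums; dashes
in the published table (contacts beyond 4 Å) are stored as valence ``None``.

These tables are package inputs: they let every bond-valence routine be
exercised and cross-checked against published totals without downloading
the deposited coordinates.
"""

from __future__ import annotations

__all__ = [
    "LIGAND_LABELS",
    "K_E2_MGF",
    "RB_E2_MGF",
    "RB_E2_ALF",
    "RB_SCH_E2_BEF",
    "TOTAL_VALENCE",
    "rb_calibration_pairs",
]

#: Coordinating oxygen atoms of the α-subunit cation site, in table order.
LIGAND_LABELS = [
    "V338 O",
    "A339 O",
    "V341 O",
    "E343 OE1",
    "E343 OE2",
    "E795 OE1",
    "E820 OE1",
    "E820 OE2",
]

# (distance Å, published partial valence or None when the contact is > 4 Å)
#: Y799W(K⁺)E2-MgFx — the 2.5 Å K⁺-occluded structure.
K_E2_MGF = [
    (2.90, 0.11),
    (2.62, 0.28),
    (2.56, 0.34),
    (2.93, 0.10),
    (3.74, 0.01),
    (2.77, 0.17),
    (3.32, 0.03),
    (3.90, 0.01),
]

#: Y799W(Rb⁺)E2-MgFx.
RB_E2_MGF = [
    (3.00, 0.12),
    (2.68, 0.27),
    (2.56, 0.37),
    (2.96, 0.13),
    (3.63, 0.03),
    (2.99, 0.12),
    (3.21, 0.08),
    (3.98, 0.02),
]

#: Y799W(Rb⁺)E2-AlFx.
RB_E2_ALF = [
    (3.09, 0.10),
    (2.63, 0.31),
    (2.63, 0.31),
    (3.07, 0.10),
    (3.72, 0.03),
    (2.88, 0.16),
    (3.38, 0.05),
    (3.95, 0.02),
]

#: Rb⁺·(SCH)E2BeFx — luminal-open, inhibitor-bound state; two contacts
#: exceed the 4 Å inclusion rule.
RB_SCH_E2_BEF = [
    (4.57, None),
    (3.23, 0.07),
    (2.89, 0.16),
    (3.41, 0.05),
    (3.42, 0.05),
    (4.05, None),
    (3.56, 0.04),
    (3.68, 0.03),
]

#: Published bond-valence sums for each state.
TOTAL_VALENCE = {
    "K_E2_MGF": 1.05,
    "RB_E2_MGF": 1.14,
    "RB_E2_ALF": 1.07,
    "RB_SCH_E2_BEF": 0.39,
}


def rb_calibration_pairs() -> list[tuple[float, float]]:
    """The 16 (distance, valence) pairs of the two Y799W Rb⁺ columns.

    These are the published values used to calibrate Rb⁺–O bond-valence
    parameters (the original parameter source for Rb⁺ is not printed).
    """
    return [(d, v) for d, v in RB_E2_MGF + RB_E2_ALF if v is not None]
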