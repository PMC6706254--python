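import numpy as np
import pytest

from ionsite import refdata, synth
from ionsite.structio import AtomRecord, Structure


@pytest.fixture(scope="session")
def k_site():
    """Synthetic coordination site realising the published K⁺–O distances."""
    spec = synth.SiteSpec(
        ligands=tuple(
            zip(refdata.LIGAND_LABELS, [d for d, _ in refdata.K_E2_MGF])
        )
    )
    return synth.make_coordination_site(spec)


@pytest.fixture
def three_waters():
    """Three water oxygens plus one potassium, hand-placed."""
    atoms = [
        AtomRecord(1, "K", "K", "K", 1, "A", 0.0, 0.0, 0.0),
        AtomRecord(2, "O", "O", "HOH", 101, "W", 2.8, 0.0, 0.0),
        AtomRecord(3, "O", "O", "HOH", 102, "W", 0.0, 3.1, 0.0),
        AtomRecord(4, "O", "O", "HOH", 103, "W", 0.0, 0.0, 3.4),
    ]
    return Structure(atoms, source="fixture")


@pytest.fixture
def saltbridge_topology():
    """N plus a carboxylate O pair laid out so N–COM distances are exact.

    O1 at the origin and O2 at (−0.5, 0, 0) put the O-pair centre of mass at
    (−0.25, 0, 0); a two-state N hopping along +x relative to O1 then sits at
    d_bound + 0.25 or d_unbound + 0.25 from the COM.
    """
    atoms = [
        AtomRecord(1, "NZ", "N", "LYS", 791, "A", 3.0, 0.0, 0.0),
        AtomRecord(2, "OE1", "O", "GLU", 820, "A", 0.0, 0.0, 0.0),
        AtomRecord(3, "OE2", "O", "GLU", 820, "A", -0.5, 0.0, 0.0),
    ]
    return Structure(atoms, source="fixture")
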