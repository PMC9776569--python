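import numpy as np
import pytest

from constph.sites import AtomRecord, SiteState, Structure, TitratableSite

TOY_LIBRARY = """\
# toy diprotic carboxylate-like site
SITE TOY
STATE prot x=1 taut=0 pkmod=4.5 ref=0
ATOM CX 0.20
ATOM OX -0.20
STATE deprot x=0 taut=0 pkmod=4.5 ref=1
ATOM CX -0.30
ATOM OX -0.70

SITE BAS
STATE prot x=1 taut=0 pkmod=10.0 ref=0
ATOM NZ 1.00
STATE deprot x=0 taut=0 pkmod=10.0 ref=1
ATOM NZ 0.00
"""


@pytest.fixture
def toy_library_file(tmp_path):
    path = tmp_path / "toy.sites"
    path.write_text(TOY_LIBRARY)
    return path


@pytest.fixture
def toy_structure():
    """Two residues, both matching the TOY template."""
    atoms = [
        AtomRecord(1, "CX", "TOY", 1, [0.0, 0.0, 0.0], -0.30, 0.17),
        AtomRecord(2, "OX", "TOY", 1, [0.12, 0.0, 0.0], -0.70, 0.15),
        AtomRecord(3, "CA", "TOY", 1, [0.0, 0.15, 0.0], 0.10, 0.2),
        AtomRecord(4, "CX", "TOY", 2, [0.8, 0.0, 0.0], -0.30, 0.17),
        AtomRecord(5, "OX", "TOY", 2, [0.92, 0.0, 0.0], -0.70, 0.15),
        AtomRecord(6, "CA", "TOY", 2, [0.8, 0.15, 0.0], 0.10, 0.2),
    ]
    return Structure(atoms)


def two_state_site(site_id=1, pkmod=7.0, q_prot=1.0, q_deprot=0.0,
                   atom="SC", index=0, residue_type="BAS"):
    states = [
        SiteState("prot", 1, 0, {atom: q_prot}, pkmod),
        SiteState("deprot", 0, 0, {atom: q_deprot}, pkmod, is_reference=True),
    ]
    return TitratableSite(site_id, residue_type, [atom], [atom], states,
                          atom_index={atom: index})
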