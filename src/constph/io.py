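"""Structure I/O: PQR (whitespace, charge then radius) and PDB via gemmi.

Disk coordinates follow the field convention (angstrom); internal units are
nm.  PQR atoms are whitespace-separated:

    ATOM  serial  name  resName  resSeq  x  y  z  charge  radius
"""

from __future__ import annotations

import gemmi

from constph.sites import AtomRecord, Structure

_A_TO_NM = 0.1


def read_pqr(path) -> Structure:
    atoms = []
    with open(path) as fh:
        for raw in fh:
            if not raw.startswith(("ATOM", "HETATM")):
                continue
            tok = raw.split()
            # chain id is optional in PQR; detect by testing token 5
            try:
                float(tok[5]); float(tok[6]); float(tok[7]); float(tok[8])
                has_chain = len(tok) >= 10 and not _is_float(tok[4])
            except (ValueError, IndexError):
                has_chain = True
            off = 1 if has_chain else 0
            atoms.append(AtomRecord(
                atom_id=int(tok[1]),
                name=tok[2],
                residue_name=tok[3],
                residue_index=int(tok[4 + off]),
                position=[float(tok[5 + off]) * _A_TO_NM,
                          float(tok[6 + off]) * _A_TO_NM,
                          float(tok[7 + off]) * _A_TO_NM],
                charge=float(tok[8 + off]),
                radius=float(tok[9 + off]) * _A_TO_NM,
            ))
    return Structure(atoms)


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_pqr(structure: Structure, path) -> None:
    with open(path, "w") as fh:
        for a in structure:
            x, y, z = a.position / _A_TO_NM
            fh.write(f"ATOM  {a.atom_id:5d} {a.name:<4s} {a.residue_name:<4s}"
                     f"{a.residue_index:5d}    "
                     f"{x:10.4f}{y:10.4f}{z:10.4f} "
                     f"{a.charge:9.5f} {a.radius / _A_TO_NM:8.4f}\n")
        fh.write("END\n")


def read_pdb(path) -> list[Structure]:
    """Read a (possibly multi-model) PDB file into one Structure per model.

    Charges and radii are not part of PDB and are left at zero; assign them
    from a site library / LJ table afterwards.
    """
    st = gemmi.read_structure(str(path))
    models = []
    for model in st:
        atoms = []
        serial = 0
        for chain in model:
            for residue in chain:
                for atom in residue:
                    serial += 1
                    atoms.append(AtomRecord(
                        atom_id=serial,
                        name=atom.name,
                        residue_name=residue.name,
                        residue_index=residue.seqid.num,
                        position=[atom.pos.x * _A_TO_NM,
                                  atom.pos.y * _A_TO_NM,
                                  atom.pos.z * _A_TO_NM],
                    ))
        models.append(Structure(atoms))
    return models
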