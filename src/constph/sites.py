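"""Titratable sites, protonation/tautomer state charge sets, and LJ-derived radii.

A titratable site is a group of atoms (usually a side chain) that exchanges a
proton with the solvent.  Each site carries two or more states: at least one
protonated and one deprotonated, possibly several tautomers of each.  A state
is a named set of atomic partial charges plus a reference pKa of the isolated
model compound (pKmod).  Exactly one state per site is the *reference* state,
against which the continuum-electrostatics energies are measured.

Atomic radii for the dielectric boundary are derived from the force field's
Lennard-Jones parameters: the radius is the distance at which the atom-water
pair potential crosses +2 RT on the repulsive wall, optionally minus the water
probe's own contact radius so that radii stay pairwise additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from constph.constants import R_KJ_MOL_K


class SiteDefinitionError(ValueError):
    """Raised when a site/state definition violates an invariant."""


class RadiusError(ValueError):
    """Raised when no 2RT crossing exists on the LJ repulsive wall."""


# --------------------------------------------------------------------------
# atoms and structures
# --------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom: identity, position (nm), partial charge (e), radius (nm)."""

    atom_id: int
    name: str
    residue_name: str
    residue_index: int
    position: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    lj_sigma: float | None = None
    lj_epsilon: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not math.isfinite(self.charge):
            raise ValueError(f"atom {self.name}: non-finite charge")
        if self.radius and self.radius < 0:
            raise ValueError(f"atom {self.name}: negative radius")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.atom_id, self.name, self.residue_name,
                          self.residue_index, self.position.copy(),
                          self.charge, self.radius,
                          self.lj_sigma, self.lj_epsilon)


class Structure:
    """A list of atoms with array views for the numerical kernels."""

    def __init__(self, atoms: Iterable[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @positions.setter
    def positions(self, value):
        value = np.asarray(value, dtype=float).reshape(-1, 3)
        if len(value) != len(self.atoms):
            raise ValueError("position array length mismatch")
        for a, p in zip(self.atoms, value):
            a.position = p.copy()

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def copy(self) -> "Structure":
        return Structure(a.copy() for a in self.atoms)

    def residue_indices(self) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if a.residue_index not in seen:
                seen.append(a.residue_index)
        return seen

    def atoms_of_residue(self, residue_index: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms)
                if a.residue_index == residue_index]

    def subset(self, indices: Sequence[int]) -> "Structure":
        return Structure(self.atoms[i].copy() for i in indices)


# --------------------------------------------------------------------------
# LJ-derived radii (2 RT water-interaction criterion)
# --------------------------------------------------------------------------

def _combine(lj_sigma, lj_epsilon, probe_sigma, probe_epsilon, combine_rule):
    if combine_rule == "lorentz_berthelot":
        sigma = 0.5 * (lj_sigma + probe_sigma)
    elif combine_rule == "geometric":
        sigma = math.sqrt(lj_sigma * probe_sigma)
    else:
        raise ValueError(f"unknown combination rule {combine_rule!r}")
    eps = math.sqrt(lj_epsilon * probe_epsilon)
    return sigma, eps


def _contact_distance(sigma: float, eps: float, energy: float) -> float:
    """Distance where 4*eps*[(s/r)^12 - (s/r)^6] = +energy on the repulsive wall.

    Substituting u = (sigma/r)^6 turns the condition into a quadratic,
    u^2 - u = energy/(4 eps), whose positive root lies on r < sigma*2^(1/6).
    """
    u = 0.5 * (1.0 + math.sqrt(1.0 + energy / eps))
    return sigma * u ** (-1.0 / 6.0)


def derive_atomic_radius(lj_sigma: float, lj_epsilon: float,
                         probe_sigma: float, probe_epsilon: float,
                         temperature: float = 310.0,
                         combine_rule: str = "lorentz_berthelot",
                         subtract_probe: bool = True) -> float:
    """Atomic radius (nm) from the 2 RT atom-water interaction criterion.

    The combined 12-6 pair potential of the atom with a water probe is solved
    for the distance r* where it crosses +2 RT on the repulsive branch.  When
    ``subtract_probe`` is on (default), the probe's own contact radius
    r*(probe, probe)/2 is subtracted so that radii of two atoms remain
    approximately pairwise additive and the probe's self-radius is consistent.

    Parameters are in nm (sigma), kJ/mol (epsilon) and K.
    """
    for name, v in (("lj_sigma", lj_sigma), ("lj_epsilon", lj_epsilon),
                    ("probe_sigma", probe_sigma),
                    ("probe_epsilon", probe_epsilon),
                    ("temperature", temperature)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite {name}")
    if lj_epsilon <= 0 or probe_epsilon <= 0:
        raise RadiusError("no repulsive-wall solution: epsilon must be > 0")
    if lj_sigma <= 0 or probe_sigma <= 0 or temperature <= 0:
        raise ValueError("sigma and temperature must be positive")

    two_rt = 2.0 * R_KJ_MOL_K * temperature
    sigma, eps = _combine(lj_sigma, lj_epsilon, probe_sigma, probe_epsilon,
                          combine_rule)
    rstar = _contact_distance(sigma, eps, two_rt)
    if not subtract_probe:
        return rstar
    r_probe = 0.5 * _contact_distance(probe_sigma, probe_epsilon, two_rt)
    radius = rstar - r_probe
    if radius <= 0:
        raise RadiusError("probe subtraction left a non-positive radius")
    return radius


def assign_radii(structure: Structure, probe_sigma: float, probe_epsilon: float,
                 temperature: float = 310.0,
                 combine_rule: str = "lorentz_berthelot",
                 subtract_probe: bool = True,
                 hydrogen_radius: float = 0.05) -> Structure:
    """Set every atom's radius from its LJ parameters (in place).

    Atoms with epsilon == 0 (typically hydrogens in all-atom force fields)
    get the fixed ``hydrogen_radius`` instead of failing.
    """
    for atom in structure:
        if atom.lj_sigma is None or atom.lj_epsilon is None:
            raise ValueError(f"atom {atom.name}: LJ parameters missing")
        if atom.lj_epsilon <= 0:
            atom.radius = hydrogen_radius
        else:
            atom.radius = derive_atomic_radius(
                atom.lj_sigma, atom.lj_epsilon, probe_sigma, probe_epsilon,
                temperature, combine_rule, subtract_probe)
    return structure


# --------------------------------------------------------------------------
# site states and libraries
# --------------------------------------------------------------------------

CHARGE_SUM_TOL = 1e-6


@dataclass
class SiteState:
    """One protonation/tautomer state of a site."""

    label: str
    protonation_count: int          # x: 1 protonated, 0 deprotonated
    tautomer_index: int
    atom_charges: dict[str, float]  # atom name -> partial charge, e
    pkmod: float
    is_reference: bool = False

    def __post_init__(self):
        if self.protonation_count not in (0, 1):
            raise SiteDefinitionError(
                f"state {self.label}: protonation_count must be 0 or 1")
        if self.tautomer_index < 0:
            raise SiteDefinitionError(
                f"state {self.label}: negative tautomer index")

    @property
    def total_charge(self) -> float:
        return float(sum(self.atom_charges.values()))


@dataclass
class TitratableSite:
    """A titratable group: member atoms, model-compound fragment, states."""

    site_id: int
    residue_type: str
    member_atoms: list[str]
    model_compound_atoms: list[str]
    states: list[SiteState]
    #: structure atom indices, resolved by :func:`instantiate_sites`
    atom_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        sid = f"site {self.site_id} ({self.residue_type})"
        if len(self.states) < 2:
            raise SiteDefinitionError(f"{sid}: needs at least 2 states")
        if not set(self.model_compound_atoms) <= set(self.member_atoms):
            raise SiteDefinitionError(
                f"{sid}: model-compound atoms not a subset of member atoms")
        prot = [s for s in self.states if s.protonation_count == 1]
        deprot = [s for s in self.states if s.protonation_count == 0]
        if not prot or not deprot:
            raise SiteDefinitionError(
                f"{sid}: needs >=1 protonated and >=1 deprotonated state")
        refs = [s for s in self.states if s.is_reference]
        if len(refs) != 1:
            raise SiteDefinitionError(
                f"{sid}: exactly one reference state required, got {len(refs)}")
        member = set(self.member_atoms)
        for s in self.states:
            extra = set(s.atom_charges) - member
            if extra:
                raise SiteDefinitionError(
                    f"{sid}, state {s.label}: charges for non-member atoms {sorted(extra)}")
        # every protonated/deprotonated pair must differ by exactly +1 e
        for p in prot:
            for d in deprot:
                dq = p.total_charge - d.total_charge
                if abs(dq - 1.0) > CHARGE_SUM_TOL:
                    raise SiteDefinitionError(
                        f"{sid}: states {p.label}/{d.label} charge sums differ "
                        f"by {dq:+.4f} e, expected +1 e")

    @property
    def reference_state(self) -> SiteState:
        return next(s for s in self.states if s.is_reference)

    def state(self, label: str) -> SiteState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(f"site {self.site_id}: no state {label!r}")

    def copy(self) -> "TitratableSite":
        states = [SiteState(s.label, s.protonation_count, s.tautomer_index,
                            dict(s.atom_charges), s.pkmod, s.is_reference)
                  for s in self.states]
        return TitratableSite(self.site_id, self.residue_type,
                              list(self.member_atoms),
                              list(self.model_compound_atoms), states,
                              dict(self.atom_index))


TERMINI_TYPES = ("NTR", "CTR")


@dataclass
class SiteLibrary:
    """Templates for titratable residues plus N-/C-terminus variants."""

    entries: dict[str, TitratableSite]
    termini_variants: dict[str, TitratableSite] = field(default_factory=dict)

    def template(self, residue_type: str) -> TitratableSite:
        key = residue_type.upper()
        if key in self.entries:
            return self.entries[key]
        if key in self.termini_variants:
            return self.termini_variants[key]
        raise KeyError(f"no site template for residue type {residue_type!r}")

    def __contains__(self, residue_type: str) -> bool:
        key = residue_type.upper()
        return key in self.entries or key in self.termini_variants


# --------------------------------------------------------------------------
# .sites file format
# --------------------------------------------------------------------------
#
#   SITE <residue_type>
#   MODEL <name> [<name> ...]          (optional; default: all state atoms)
#   STATE <label> x=<0|1> taut=<k> pkmod=<float> ref=<0|1>
#   ATOM <name> <charge>
#   ...
#   <blank line terminates the SITE block>

def _parse_kv(tokens: list[str], lineno: int) -> dict[str, str]:
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise SiteDefinitionError(f"line {lineno}: expected key=value, got {tok!r}")
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def load_site_library(path) -> SiteLibrary:
    """Parse a plain-text .sites file into a validated :class:`SiteLibrary`."""
    with open(path) as fh:
        lines = fh.read().splitlines()

    entries: dict[str, TitratableSite] = {}
    termini: dict[str, TitratableSite] = {}

    res_type = None
    model_atoms: list[str] | None = None
    states: list[SiteState] = []
    cur: dict | None = None   # accumulating STATE block

    def flush_state():
        nonlocal cur
        if cur is not None:
            states.append(SiteState(cur["label"], cur["x"], cur["taut"],
                                    cur["charges"], cur["pkmod"], cur["ref"]))
            cur = None

    def flush_site(lineno):
        nonlocal res_type, model_atoms, states
        if res_type is None:
            return
        flush_state()
        if not states:
            raise SiteDefinitionError(f"line {lineno}: SITE {res_type} has no states")
        member = sorted({name for s in states for name in s.atom_charges})
        model = model_atoms if model_atoms is not None else list(member)
        try:
            site = TitratableSite(0, res_type, member, model, states)
        except SiteDefinitionError as exc:
            raise SiteDefinitionError(f"SITE {res_type}: {exc}") from exc
        (termini if res_type in TERMINI_TYPES else entries)[res_type] = site
        res_type, model_atoms, states = None, None, []

    for lineno, raw in enumerate(lines + [""], start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            flush_site(lineno)
            continue
        tokens = line.split()
        tag = tokens[0].upper()
        if tag == "SITE":
            flush_site(lineno)
            res_type = tokens[1].upper()
        elif tag == "MODEL":
            model_atoms = tokens[1:]
        elif tag == "STATE":
            if res_type is None:
                raise SiteDefinitionError(f"line {lineno}: STATE outside SITE block")
            flush_state()
            kv = _parse_kv(tokens[2:], lineno)
            cur = {"label": tokens[1], "x": int(kv["x"]), "taut": int(kv.get("taut", 0)),
                   "pkmod": float(kv["pkmod"]), "ref": bool(int(kv.get("ref", 0))),
                   "charges": {}}
        elif tag == "ATOM":
            if cur is None:
                raise SiteDefinitionError(f"line {lineno}: ATOM outside STATE block")
            cur["charges"][tokens[1]] = float(tokens[2])
        else:
            raise SiteDefinitionError(f"line {lineno}: unknown record {tag!r}")

    return SiteLibrary(entries, termini)


def save_site_library(library: SiteLibrary, path) -> None:
    """Write a SiteLibrary back to the .sites text format."""
    with open(path, "w") as fh:
        for group in (library.entries, library.termini_variants):
            for res_type, site in group.items():
                fh.write(f"SITE {res_type}\n")
                if sorted(site.model_compound_atoms) != sorted(site.member_atoms):
                    fh.write("MODEL " + " ".join(site.model_compound_atoms) + "\n")
                for s in site.states:
                    fh.write(f"STATE {s.label} x={s.protonation_count} "
                             f"taut={s.tautomer_index} pkmod={s.pkmod:g} "
                             f"ref={int(s.is_reference)}\n")
                    for name, q in s.atom_charges.items():
                        fh.write(f"ATOM {name} {q:.6f}\n")
                fh.write("\n")


# --------------------------------------------------------------------------
# instantiation and state application
# --------------------------------------------------------------------------

def instantiate_sites(structure: Structure, library: SiteLibrary,
                      selection: Sequence[int],
                      titrate_termini: bool = False) -> list[TitratableSite]:
    """Resolve library templates against a structure's selected residues.

    Each selected residue index yields one :class:`TitratableSite` whose
    ``atom_index`` maps member atom names to structure atom indices.  With
    ``titrate_termini``, the first/last residues additionally get the NTR/CTR
    variants (site ids offset by 10000/20000 to stay unique).
    """
    residues = structure.residue_indices()
    sites: list[TitratableSite] = []

    def build(residue_index: int, template: TitratableSite,
              site_id: int) -> TitratableSite:
        atom_idx = {}
        in_res = {structure.atoms[i].name: i
                  for i in structure.atoms_of_residue(residue_index)}
        missing = [n for n in template.member_atoms if n not in in_res]
        if missing:
            raise SiteDefinitionError(
                f"residue {residue_index}: missing atoms {missing} "
                f"required by template {template.residue_type}")
        for name in template.member_atoms:
            atom_idx[name] = in_res[name]
        site = template.copy()
        site.site_id = site_id
        site.atom_index = atom_idx
        return site

    for ridx in selection:
        if ridx not in residues:
            raise SiteDefinitionError(f"residue {ridx} not in structure")
        resname = next(a.residue_name for a in structure.atoms
                       if a.residue_index == ridx).upper()
        if resname not in library:
            raise SiteDefinitionError(
                f"residue {ridx} ({resname}): no template in library")
        sites.append(build(ridx, library.template(resname), ridx))

    if titrate_termini and residues:
        for ttype, ridx, offset in (("NTR", residues[0], 10000),
                                    ("CTR", residues[-1], 20000)):
            if ttype in library.termini_variants:
                sites.append(build(ridx, library.termini_variants[ttype],
                                   offset + ridx))
    return sites


def apply_state(structure: Structure, site: TitratableSite,
                state: SiteState) -> Structure:
    """Set the site's member-atom charges to the given state's (in place).

    Atoms outside the site's member list are never touched; the structure's
    total charge changes by the state's formal-charge difference.
    """
    if state not in site.states:
        raise ValueError(
            f"state {state.label!r} does not belong to site {site.site_id}")
    if not site.atom_index:
        raise ValueError(f"site {site.site_id} has unresolved atom indices")
    for name, q in state.atom_charges.items():
        structure.atoms[site.atom_index[name]].charge = q
    return structure
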