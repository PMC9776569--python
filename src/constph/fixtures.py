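"""Synthetic test systems with attached known-truth metadata.

All fixtures are generated programmatically and deterministically: a Born
sphere (one charged atom with its analytic solvation energy), a two-site rod
(two single-atom titratable sites with the analytic Coulomb coupling), a
bead pentapeptide, and random n-site energy tables whose exact occupancies
follow from enumeration.
"""

from __future__ import annotations

import math

import numpy as np

from constph.calibration import make_pentapeptide_fixture
from constph.constants import COULOMB_KJ_NM, LN10, kt_kj
from constph.pb import SiteEnergyTable
from constph.sites import AtomRecord, SiteState, Structure, TitratableSite


def born_solvation_kt(q: float, radius: float, eps_in: float, eps_out: float,
                      temperature: float) -> float:
    """Analytic Born transfer energy eps_in -> eps_in/eps_out, in kT."""
    kt = kt_kj(temperature)
    return (-0.5 * COULOMB_KJ_NM * q * q / radius
            * (1.0 / eps_in - 1.0 / eps_out) / kt)


def born_sphere(q: float = 1.0, radius: float = 0.2,
                eps_in: float = 2.0, eps_out: float = 80.0,
                temperature: float = 310.0):
    """One charged sphere at the origin plus its analytic solvation energy."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atom = AtomRecord(1, "Q", "ION", 1, [0.0, 0.0, 0.0], charge=q,
                      radius=radius)
    meta = {
        "analytic_solvation_kT": born_solvation_kt(q, radius, eps_in,
                                                   eps_out, temperature),
        "analytic_solvation_kcal": born_solvation_kt(
            q, radius, eps_in, eps_out, temperature)
        * kt_kj(temperature) / 4.184,
    }
    return Structure([atom]), meta


def two_site_rod(separation: float = 1.0, radius: float = 0.05,
                 pkmod: tuple[float, float] = (7.0, 7.0),
                 eps: float = 80.0, temperature: float = 310.0):
    """Two single-atom cationic sites on the x axis.

    Each site has a neutral deprotonated reference state and a +1 protonated
    state, so the analytic coupling between the protonated states in a
    uniform dielectric is W = f / (eps r kT ln10) pK units (attached as
    metadata).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    atoms = [
        AtomRecord(1, "SC", "BAS", 1, [0.0, 0.0, 0.0], 0.0, radius),
        AtomRecord(2, "SC", "BAS", 2, [separation, 0.0, 0.0], 0.0, radius),
    ]
    structure = Structure(atoms)

    def states(pk):
        return [
            SiteState("prot", 1, 0, {"SC": 1.0}, pk),
            SiteState("deprot", 0, 0, {"SC": 0.0}, pk, is_reference=True),
        ]

    sites = [
        TitratableSite(1, "BAS", ["SC"], ["SC"], states(pkmod[0]),
                       atom_index={"SC": 0}),
        TitratableSite(2, "BAS", ["SC"], ["SC"], states(pkmod[1]),
                       atom_index={"SC": 1}),
    ]
    w_pk = COULOMB_KJ_NM / (eps * separation * kt_kj(temperature) * LN10)
    return structure, sites, {"analytic_w_pk": w_pk}


def nsite_random(n: int = 8, seed: int = 0, coupled_fraction: float = 0.3,
                 pkint_range: tuple[float, float] = (3.0, 10.0),
                 w_max: float = 4.0) -> tuple[SiteEnergyTable, dict]:
    """Random n-site two-state energy table (deterministic given seed).

    Sites are acid-like (deprotonated reference); roughly
    ``coupled_fraction`` of the pairs get a coupling between the protonated
    states drawn uniform on [-w_max, w_max].  The table itself is the
    generating truth: exact occupancies follow from enumeration.
    """
    if n < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    site_ids = list(range(1, n + 1))
    pkints = rng.uniform(*pkint_range, size=n)

    labels = {s: ["deprot", "prot"] for s in site_ids}
    x = {}
    pkmod = {}
    pkint = {}
    ref = {s: "deprot" for s in site_ids}
    for sid, pk in zip(site_ids, pkints):
        x[(sid, "deprot")], x[(sid, "prot")] = 0, 1
        pkmod[(sid, "deprot")] = pkmod[(sid, "prot")] = round(float(pk), 3)
        pkint[(sid, "deprot")] = pkmod[(sid, "deprot")]
        pkint[(sid, "prot")] = round(float(pk), 3)

    table = SiteEnergyTable(site_ids, labels, x, pkmod, pkint, ref, {})
    couplings = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < coupled_fraction:
                wij = float(np.round(rng.uniform(-w_max, w_max), 3))
                table.set_w(site_ids[i], "prot", site_ids[j], "prot", wij)
                couplings[(site_ids[i], site_ids[j])] = wij
    meta = {"pkint": {s: pkint[(s, "prot")] for s in site_ids},
            "couplings": couplings}
    return table, meta


def generate_fixtures(kind: str, params: dict | None = None, seed: int = 0):
    """Dispatch to the named fixture generator.

    Returns whatever the generator returns (structure / sites / table plus a
    metadata dict carrying the analytic truth); deterministic given seed.
    """
    params = dict(params or {})
    if kind == "born_sphere":
        return born_sphere(**params)
    if kind == "two_site_rod":
        return two_site_rod(**params)
    if kind == "penta_bead":
        return make_pentapeptide_fixture(**params)
    if kind == "nsite_random":
        params.setdefault("seed", seed)
        return nsite_random(**params)
    raise ValueError(f"unknown fixture kind {kind!r}")
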