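"""Model-compound pKmod calibration against pentapeptide pKa values.

The reference pKa of a model compound (pKmod) anchors the continuum
electrostatics to experiment.  It is calibrated by titrating an Ala2-X-Ala2
pentapeptide-like system with a trial pKmod, fitting the simulated titration
curve, and shifting the trial value by the deviation from the experimental
pKa:

    pKmod <- pKmod + (pKa_exp - pKa_sim(pKmod))

One pass removes a constant bias exactly; the loop iterates (default up to 5
rounds, tolerance 0.05 pK) because stochastic titration noise can leave a
residual.  A single-pass mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from constph.analysis import HillFit, TitrationCurve, fit_hill
from constph.mc import MCConfig, run_mc
from constph.pb import SiteEnergyTable
from constph.sites import AtomRecord, SiteState, Structure, TitratableSite


class CalibrationError(RuntimeError):
    def __init__(self, message, rounds):
        super().__init__(message)
        self.rounds = rounds


@dataclass
class CalibrationTask:
    experimental_pka: float
    initial_guess: float
    ph_offsets: tuple[float, ...] = (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)
    replicates: int = 3
    tolerance: float = 0.05
    max_rounds: int = 5
    single_pass: bool = False

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if max(self.ph_offsets) - min(self.ph_offsets) < 2.0:
            raise ValueError("pH grid must span at least 2 pK units")

    def ph_grid(self, pkmod: float) -> np.ndarray:
        return pkmod + np.asarray(self.ph_offsets, dtype=float)


@dataclass
class CalibrationResult:
    pkmod_final: float
    rounds: list[tuple[float, float, float]]   # (pkmod_in, pka_sim, shift)
    converged: bool


#: an engine maps a trial pKmod to the simulated pKa of the system
Engine = Callable[[float], float]


def calibrate(task: CalibrationTask, engine: Engine) -> CalibrationResult:
    """Iterative shift-and-correct calibration of pKmod.

    ``engine(pkmod)`` must return the simulated pKa for that trial value (or
    a :class:`HillFit`, whose convergence flag is honoured).  Raises
    :class:`CalibrationError` if a round's Hill fit fails; returns an
    unconverged result when ``max_rounds`` is exhausted.
    """
    pkmod = task.initial_guess
    rounds: list[tuple[float, float, float]] = []
    n_rounds = 1 if task.single_pass else task.max_rounds
    for _ in range(n_rounds):
        out = engine(pkmod)
        if isinstance(out, HillFit):
            if not out.converged:
                raise CalibrationError(
                    f"Hill fit failed at pKmod={pkmod:.3f}", rounds)
            pka_sim = out.pka
        else:
            pka_sim = float(out)
        if not math.isfinite(pka_sim):
            raise CalibrationError(
                f"engine returned non-finite pKa at pKmod={pkmod:.3f}", rounds)
        shift = task.experimental_pka - pka_sim
        rounds.append((pkmod, pka_sim, shift))
        pkmod = pkmod + shift
        if abs(shift) <= task.tolerance:
            return CalibrationResult(pkmod, rounds, True)
    return CalibrationResult(pkmod, rounds,
                             task.single_pass and abs(shift) <= task.tolerance)


# --------------------------------------------------------------------------
# pentapeptide bead fixture
# --------------------------------------------------------------------------

ACID_TYPES = {"ASP", "GLU", "CYS", "TYR", "CTR"}
BASE_TYPES = {"LYS", "HIS", "NTR"}

#: water pKa values of the pentapeptide reference compounds used as defaults
DEFAULT_PENTAPEPTIDE_PKA = {
    "ASP": 3.9, "GLU": 4.3, "HIS": 6.5, "CYS": 8.55, "TYR": 9.8,
    "LYS": 10.4, "NTR": 8.0, "CTR": 3.7,
}


def _bead(i, name, resname, resid, pos, charge=0.0, radius=0.2):
    return AtomRecord(i, name, resname, resid, pos, charge, radius)


def make_pentapeptide_fixture(residue_type: str, capped: bool = True,
                              pkmod: float | None = None,
                              spacing: float = 0.38):
    """Coarse bead pentapeptide (Ala2-X-Ala2) with one titratable site.

    One backbone bead per residue on a line, plus a side-chain bead on the
    central residue when X is a side-chain type.  Capped termini do not
    titrate; with ``capped=False`` the requested terminus (NTR/CTR) titrates
    on an all-Ala pentapeptide instead.

    Returns ``(structure, site)``; the site's states are a two-state
    acid (0/-1) or base (+1/0) with the deprotonated (acid) or protonated
    (base) form carrying the net charge.
    """
    rtype = residue_type.upper()
    if rtype not in ACID_TYPES | BASE_TYPES:
        raise ValueError(f"unknown residue type {residue_type!r}")
    if pkmod is None:
        pkmod = DEFAULT_PENTAPEPTIDE_PKA[rtype]
    terminal = rtype in ("NTR", "CTR")
    if terminal and capped:
        raise ValueError(f"{rtype} can only titrate on an uncapped peptide")

    atoms = []
    names = []
    for i in range(5):
        resname = "ALA" if (terminal or i != 2) else rtype
        atoms.append(_bead(i + 1, "BB", resname, i + 1,
                           [i * spacing, 0.0, 0.0]))
        names.append("BB")
    if not terminal:
        atoms.append(_bead(6, "SC", rtype, 3, [2 * spacing, 0.3, 0.0]))

    structure = Structure(atoms)

    acid = rtype in ACID_TYPES
    if acid:
        states = [
            SiteState("prot", 1, 0, {"SC": 0.0}, pkmod, is_reference=False),
            SiteState("deprot", 0, 0, {"SC": -1.0}, pkmod, is_reference=True),
        ]
    else:
        states = [
            SiteState("prot", 1, 0, {"SC": 1.0}, pkmod, is_reference=False),
            SiteState("deprot", 0, 0, {"SC": 0.0}, pkmod, is_reference=True),
        ]

    if terminal:
        # the terminus titrates on the first/last backbone bead
        ridx = 1 if rtype == "NTR" else 5
        aidx = 0 if rtype == "NTR" else 4
        for s in states:
            s.atom_charges = {"BB": s.atom_charges["SC"]}
        site = TitratableSite(ridx, rtype, ["BB"], ["BB"], states,
                              atom_index={"BB": aidx})
    else:
        site = TitratableSite(3, rtype, ["SC"], ["SC"], states,
                              atom_index={"SC": 5})
    return structure, site


@dataclass
class TitrationEngine:
    """Calibration engine running MC titration on a precomputed energy model.

    The electrostatic shift of the site (pKint - pKmod) is independent of the
    trial pKmod, so it is computed once (``ddg_pk``) and each round only
    reruns the MC titration over the pH grid and the Hill fit.
    """

    site_id: int
    state_labels: tuple[str, str]            # (protonated, deprotonated ref)
    task: CalibrationTask
    ddg_pk: float = 0.0                      # pKint = pkmod - ddg_pk
    mc: MCConfig = field(default_factory=lambda: MCConfig(n_cycles=20000))
    noise_sigma: float = 0.0                 # optional extra seeded noise
    _round: int = 0

    def __call__(self, pkmod: float) -> HillFit:
        self._round += 1
        prot, deprot = self.state_labels
        sid = self.site_id
        pkint = pkmod - self.ddg_pk
        table = SiteEnergyTable(
            site_ids=[sid],
            state_labels={sid: [deprot, prot]},
            protonation={(sid, deprot): 0, (sid, prot): 1},
            pkmod={(sid, deprot): pkmod, (sid, prot): pkmod},
            pkint={(sid, deprot): pkmod, (sid, prot): pkint},
            reference={sid: deprot},
            w={},
        )
        ph_grid = self.task.ph_grid(pkmod)
        rows = []
        for rep in range(self.task.replicates):
            row = []
            for k, ph in enumerate(ph_grid):
                seed = (self.mc.seed + 7919 * self._round + 101 * rep
                        + k) % (2 ** 31)
                cfg = MCConfig(self.mc.n_cycles, self.mc.pair_threshold,
                               seed, self.mc.burn_in_cycles)
                res = run_mc(table, float(ph), cfg)
                row.append(res.per_site_protonation[sid])
            rows.append(row)
        curve = TitrationCurve(ph_grid, np.array(rows))
        fit = fit_hill(curve)
        if self.noise_sigma and fit.converged:
            rng = np.random.default_rng((self.mc.seed + self._round) % 2**31)
            fit.pka += rng.normal(0.0, self.noise_sigma)
        return fit
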