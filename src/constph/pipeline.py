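"""The stochastic-titration cycle and pH-dependent counterion bookkeeping.

Each cycle of the stochastic titration scheme (1) computes the PB energy
table on the current conformation, (2) samples a new protonation microstate
by Monte Carlo, (3) applies the new charges, (4) runs a short solvent
relaxation hook, and (5) advances the conformation.  The conformational
sampling stage (an MD engine in production use) is a pluggable
:class:`ConformationProvider`; desk-scale providers are a static structure,
an ensemble cycler over multi-model PDB conformations, and a Gaussian
jitterer.  The cycle interval and relaxation lengths are expressed in
provider steps (they map to tau = 20 ps and 0.2 ps of MD in the production
protocol).

Counterion counts per pH follow the nearest-integer neutralization rule on
the replicate-averaged solute charge, with a restart when the running mean
later drifts by more than 1 protonic unit from the original estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from constph.mc import MCConfig, sample_assignment
from constph.pb import PBConfig, compute_energy_table
from constph.sites import Structure, TitratableSite, apply_state


@dataclass
class CycleConfig:
    ph: float
    n_cycles: int
    tau_steps: int = 10          # provider steps per cycle (MD: 20 ps)
    relax_steps: int = 1         # relaxation hook steps (MD: 0.2 ps)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.tau_steps <= 0:
            raise ValueError("tau_steps must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


class ConformationProvider:
    """Interface of the conformational-sampling stage.

    ``advance`` must preserve atom count and identity; ``relax`` is the
    solvent-relaxation hook and defaults to a no-op (no solvent exists at
    desk scale).
    """

    is_static = False

    def advance(self, structure: Structure, assignment: dict[int, str],
                n_steps: int, rng: np.random.Generator) -> Structure:
        raise NotImplementedError

    def relax(self, structure: Structure, n_steps: int,
              rng: np.random.Generator) -> None:
        return None

    @property
    def conformation_id(self):
        return 0


class StaticProvider(ConformationProvider):
    """Rigid structure: advance returns the input unchanged."""

    is_static = True

    def advance(self, structure, assignment, n_steps, rng):
        return structure


class EnsembleProvider(ConformationProvider):
    """Cycles deterministically through a fixed conformational ensemble
    (e.g. the models of a multi-model PDB); charges are carried over."""

    def __init__(self, models: list[Structure]):
        if not models:
            raise ValueError("ensemble is empty")
        n = len(models[0])
        if any(len(m) != n for m in models):
            raise ValueError("ensemble models differ in atom count")
        self.models = models
        self._index = 0

    @property
    def conformation_id(self):
        return self._index

    def advance(self, structure, assignment, n_steps, rng):
        self._index = (self._index + 1) % len(self.models)
        out = structure.copy()
        out.positions = self.models[self._index].positions
        return out


class JitterProvider(ConformationProvider):
    """Toy thermal motion: adds isotropic Gaussian noise to all positions."""

    def __init__(self, sigma: float = 0.01):
        self.sigma = sigma
        self._moves = 0

    @property
    def conformation_id(self):
        return self._moves

    def advance(self, structure, assignment, n_steps, rng):
        out = structure.copy()
        out.positions = (out.positions
                         + rng.normal(0.0, self.sigma,
                                      size=(len(out), 3)) * math.sqrt(n_steps))
        self._moves += 1
        return out


@dataclass
class CycleRecord:
    cycle: int
    conformation_id: int
    assignment: dict[int, str]
    total_charge: float


def run_cycle(structure: Structure, sites: list[TitratableSite],
              provider: ConformationProvider, cfg: CycleConfig,
              pb: PBConfig | None = None, mc: MCConfig | None = None,
              energy_fn=None) -> list[CycleRecord]:
    """Run the stochastic-titration loop; returns one record per cycle.

    ``energy_fn(structure, sites) -> SiteEnergyTable`` overrides the PB
    energy evaluation (e.g. an analytic toy model); by default
    :func:`constph.pb.compute_energy_table` is used with ``pb``.  For a
    static provider the energy table is computed once and reused.  All
    randomness derives from ``cfg.seed``.
    """
    mc = mc or MCConfig()
    if energy_fn is None:
        if pb is None:
            raise ValueError("need either a PBConfig or an energy_fn")
        energy_fn = lambda st, si: compute_energy_table(st, si, pb)

    ss = np.random.SeedSequence(cfg.seed)
    mc_seeds = ss.generate_state(max(cfg.n_cycles, 1) * 2) % (2 ** 31)
    rng = np.random.default_rng(ss.spawn(1)[0])

    work = structure
    records: list[CycleRecord] = []
    table = None
    for cycle in range(cfg.n_cycles):
        if table is None or not provider.is_static:
            table = energy_fn(work, sites)
        mc_cfg = MCConfig(mc.n_cycles, mc.pair_threshold,
                          int(mc_seeds[cycle]), mc.burn_in_cycles)
        micro = sample_assignment(table, cfg.ph, mc_cfg)
        for site in sites:
            apply_state(work, site, site.state(micro.assignment[site.site_id]))
        provider.relax(work, cfg.relax_steps, rng)
        work = provider.advance(work, micro.assignment, cfg.tau_steps, rng)
        records.append(CycleRecord(cycle, provider.conformation_id,
                                   dict(micro.assignment),
                                   work.total_charge))
    return records


# --------------------------------------------------------------------------
# counterion estimation
# --------------------------------------------------------------------------

@dataclass
class IonPlan:
    per_ph: dict[float, tuple[int, int]]        # pH -> (n_cations, n_anions)
    mean_system_charge: dict[float, float]      # pH -> mean solute charge, e
    restarted: dict[float, bool] = field(default_factory=dict)


def _neutralizing_ions(mean_charge: float) -> tuple[int, int]:
    """Monovalent counterion counts minimizing the residual |Q - n sign|.

    The half-integer tie is broken toward fewer ions (minimal perturbation).
    """
    n = max(0, math.ceil(abs(mean_charge) - 0.5))
    if mean_charge > 0:
        return 0, n     # anions neutralize a positive solute
    if mean_charge < 0:
        return n, 0
    return 0, 0


def estimate_counterions(charge_series: dict[float, list[np.ndarray]],
                         solvent_capacity: int | None = None) -> IonPlan:
    """Counterion counts per pH from replicate solute-charge series.

    ``charge_series[pH]`` holds one charge time series (or scalar mean) per
    replicate; the replicate-averaged mean charge sets the ion counts by the
    nearest-integer rule.
    """
    per_ph, means, restarted = {}, {}, {}
    for ph, reps in charge_series.items():
        if not reps:
            raise ValueError(f"pH {ph}: no replicates")
        mean = float(np.mean([np.mean(np.asarray(r, dtype=float))
                              for r in reps]))
        counts = _neutralizing_ions(mean)
        if solvent_capacity is not None and sum(counts) > solvent_capacity:
            raise ValueError(f"pH {ph}: {sum(counts)} ions exceed solvent "
                             f"capacity {solvent_capacity}")
        per_ph[ph] = counts
        means[ph] = mean
        restarted[ph] = False
    return IonPlan(per_ph, means, restarted)


def check_restart(plan: IonPlan,
                  running_means: dict[float, float]) -> IonPlan:
    """Flag pH values whose running mean charge drifted by more than 1 e.

    The comparison is strict ("more than 1 absolute protonic unit"); flagged
    pH values get counts recomputed from the running mean.
    """
    per_ph = dict(plan.per_ph)
    means = dict(plan.mean_system_charge)
    restarted = dict(plan.restarted)
    for ph, running in running_means.items():
        if ph not in per_ph:
            raise KeyError(f"pH {ph} not covered by the ion plan")
        # strict "more than 1 e", robust to floating-point representation
        if abs(running - plan.mean_system_charge[ph]) > 1.0 + 1e-9:
            per_ph[ph] = _neutralizing_ions(running)
            means[ph] = running
            restarted[ph] = True
    return IonPlan(per_ph, means, restarted)
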