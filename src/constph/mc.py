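"""Metropolis Monte Carlo over protonation/tautomer microstates at fixed pH.

The microstate energy, in pK units (multiply by kT ln10 for kJ/mol), is

    E = sum_i g(i, s_i) + sum_{i<j} W((i, s_i), (j, s_j))

    g(i, s) = x_s (pH - pKint(i,s)) + (1 - x_s)(pKmod(i,s) - pKint(i,s))

so that a site in its reference state contributes nothing, a protonated site
at pH = pKint contributes nothing, and deprotonated non-reference tautomers
carry their continuum-electrostatics shift.  Moves are accepted with
probability min(1, 10^(-dE)).

Each MC cycle attempts one single-site move per site (a uniformly random
alternative state) plus one joint move per *coupled pair* -- pairs whose
maximal |W| over state combinations exceeds the pair threshold (default 2 pK)
-- in randomized order.  An exact enumerator over the full microstate space
serves as the correctness oracle for small systems.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from constph.pb import SiteEnergyTable


@dataclass
class MCConfig:
    n_cycles: int = 100_000
    pair_threshold: float = 2.0   # pK units
    seed: int = 0
    burn_in_cycles: int = 0

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.pair_threshold < 0:
            raise ValueError("pair_threshold must be >= 0")


@dataclass
class Microstate:
    assignment: dict[int, str]
    energy: float  # pK units


@dataclass
class OccupancyResult:
    per_site_protonation: dict[int, float]
    per_state_population: dict[tuple[int, str], float]
    acceptance_single: float
    acceptance_pair: float
    n_samples: int
    seed: int | None = None
    trace: np.ndarray | None = field(default=None, repr=False)


class _Compiled:
    """Array view of a SiteEnergyTable for the sampling kernels."""

    def __init__(self, table: SiteEnergyTable):
        self.site_ids = list(table.site_ids)
        self.labels = [list(table.state_labels[s]) for s in self.site_ids]
        self.nstates = [len(l) for l in self.labels]
        self.x = []
        self.c = []      # pH-independent part of g
        for sid, labs in zip(self.site_ids, self.labels):
            xs, cs = [], []
            for lab in labs:
                x = table.protonation[(sid, lab)]
                pkint = table.pkint[(sid, lab)]
                pkmod = table.pkmod[(sid, lab)]
                if not (math.isfinite(pkint) and math.isfinite(pkmod)):
                    raise ValueError(f"non-finite energy for site {sid}, "
                                     f"state {lab}")
                xs.append(x)
                cs.append(-x * pkint + (1 - x) * (pkmod - pkint))
            self.x.append(xs)
            self.c.append(cs)
        n = len(self.site_ids)
        self.w = [[None] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                wij = [[table.get_w(self.site_ids[i], la,
                                    self.site_ids[j], lb)
                        for lb in self.labels[j]]
                       for la in self.labels[i]]
                self.w[i][j] = wij

    def coupled_pairs(self, threshold: float) -> list[tuple[int, int]]:
        pairs = []
        n = len(self.site_ids)
        for i in range(n):
            for j in range(i + 1, n):
                wmax = max(abs(v) for row in self.w[i][j] for v in row)
                if wmax > threshold:
                    pairs.append((i, j))
        return pairs

    def energy(self, states: list[int], ph: float) -> float:
        e = 0.0
        n = len(states)
        for i, s in enumerate(states):
            e += self.x[i][s] * ph + self.c[i][s]
            for j in range(i + 1, n):
                e += self.w[i][j][s][states[j]]
        return e

    def index_of(self, assignment: dict[int, str]) -> list[int]:
        states = []
        for sid, labs in zip(self.site_ids, self.labels):
            if sid not in assignment:
                raise ValueError(f"assignment missing site {sid}")
            lab = assignment[sid]
            if lab not in labs:
                raise ValueError(f"site {sid}: unknown state {lab!r}")
            states.append(labs.index(lab))
        return states


def microstate_energy(assignment: dict[int, str], ph: float,
                      table: SiteEnergyTable) -> float:
    """Energy of a complete microstate, in pK units."""
    comp = _Compiled(table)
    return comp.energy(comp.index_of(assignment), ph)


def _occupancy_from_counts(comp, counts, acc_s, att_s, acc_p, att_p,
                           n_samples, seed, trace=None) -> OccupancyResult:
    per_state = {}
    per_site = {}
    for i, sid in enumerate(comp.site_ids):
        tot = counts[i].sum()
        frac = counts[i] / tot if tot else counts[i]
        prot = 0.0
        for s, lab in enumerate(comp.labels[i]):
            per_state[(sid, lab)] = float(frac[s])
            if comp.x[i][s]:
                prot += float(frac[s])
        per_site[sid] = prot
    return OccupancyResult(
        per_site, per_state,
        acceptance_single=acc_s / att_s if att_s else 0.0,
        acceptance_pair=acc_p / att_p if att_p else 0.0,
        n_samples=n_samples, seed=seed, trace=trace)


def run_mc(table: SiteEnergyTable, ph: float, mc: MCConfig,
           pair_moves: bool = True, record: bool = False) -> OccupancyResult:
    """Sample state occupancies at the given pH.

    ``pair_moves=False`` disables the coupled-pair moves (diagnostic use:
    strongly coupled sites then mix much more slowly).  ``record=True``
    stores a per-cycle microstate-index trace (mixed-radix encoded).
    """
    comp = _Compiled(table)
    n = len(comp.site_ids)
    if n == 0:
        raise ValueError("energy table has no sites")
    rng = np.random.default_rng(mc.seed)

    pairs = comp.coupled_pairs(mc.pair_threshold) if pair_moves else []
    moves: list[tuple[int, int, int]] = [(0, i, -1) for i in range(n)]
    moves += [(1, i, j) for (i, j) in pairs]

    cur = [0] * n   # start from the first (conventionally reference) state
    x, c, w, ns = comp.x, comp.c, comp.w, comp.nstates
    counts = [np.zeros(k) for k in ns]
    acc_s = att_s = acc_p = att_p = 0
    n_samples = 0
    trace = np.empty(mc.n_cycles - mc.burn_in_cycles, dtype=np.int64) \
        if record else None

    # mixed-radix weights for trace encoding
    radix = np.ones(n, dtype=np.int64)
    for i in range(n - 2, -1, -1):
        radix[i] = radix[i + 1] * ns[i + 1]

    log10e = 1.0 / math.log(10.0)
    nmoves = len(moves)
    for cycle in range(mc.n_cycles):
        order = rng.permutation(nmoves) if nmoves > 1 else (0,)
        u_move = rng.random(nmoves)
        u_pick = rng.random(nmoves * 2)
        for m_i, midx in enumerate(order):
            kind, i, j = moves[midx]
            if kind == 0:
                s = cur[i]
                if ns[i] < 2:
                    continue
                t = int(u_pick[2 * m_i] * (ns[i] - 1))
                if t >= s:
                    t += 1
                de = (x[i][t] - x[i][s]) * ph + (c[i][t] - c[i][s])
                for l in range(n):
                    if l != i:
                        wil = w[i][l]
                        de += wil[t][cur[l]] - wil[s][cur[l]]
                att_s += 1
                if de <= 0.0 or u_move[m_i] < 10.0 ** (-de):
                    cur[i] = t
                    acc_s += 1
            else:
                si, sj = cur[i], cur[j]
                ti = int(u_pick[2 * m_i] * ns[i])
                tj = int(u_pick[2 * m_i + 1] * ns[j])
                if ti == si and tj == sj:
                    continue
                de = ((x[i][ti] - x[i][si]) * ph + (c[i][ti] - c[i][si])
                      + (x[j][tj] - x[j][sj]) * ph + (c[j][tj] - c[j][sj])
                      + w[i][j][ti][tj] - w[i][j][si][sj])
                for l in range(n):
                    if l != i and l != j:
                        de += (w[i][l][ti][cur[l]] - w[i][l][si][cur[l]]
                               + w[j][l][tj][cur[l]] - w[j][l][sj][cur[l]])
                att_p += 1
                if de <= 0.0 or u_move[m_i] < 10.0 ** (-de):
                    cur[i], cur[j] = ti, tj
                    acc_p += 1
        if cycle >= mc.burn_in_cycles:
            for i in range(n):
                counts[i][cur[i]] += 1
            if record:
                code = 0
                for i in range(n):
                    code += cur[i] * radix[i]
                trace[n_samples] = code
            n_samples += 1

    if att_s and acc_s == 0:
        warnings.warn("no single-site move was accepted", stacklevel=2)

    result = _occupancy_from_counts(comp, counts, acc_s, att_s, acc_p, att_p,
                                    n_samples, mc.seed, trace)
    result._final_states = cur  # for sample_assignment
    result._compiled = comp
    return result


def sample_assignment(table: SiteEnergyTable, ph: float,
                      mc: MCConfig) -> Microstate:
    """Final microstate of an MC run (seed-reproducible), for the
    stochastic-titration loop."""
    res = run_mc(table, ph, mc)
    comp = res._compiled
    assignment = {sid: comp.labels[i][res._final_states[i]]
                  for i, sid in enumerate(comp.site_ids)}
    return Microstate(assignment, comp.energy(res._final_states, ph))


def enumerate_exact(table: SiteEnergyTable, ph: float,
                    max_states: int = 10 ** 6) -> OccupancyResult:
    """Exact Boltzmann averages over all microstates (small systems only)."""
    comp = _Compiled(table)
    n = len(comp.site_ids)
    total = 1
    for k in comp.nstates:
        total *= k
    if total > max_states:
        raise ValueError(f"state space too large ({total} microstates); "
                         f"use run_mc instead")

    energies = np.empty(total)
    combos = list(itertools.product(*[range(k) for k in comp.nstates]))
    for idx, states in enumerate(combos):
        energies[idx] = comp.energy(list(states), ph)
    emin = energies.min()
    weights = 10.0 ** (-(energies - emin))
    weights /= weights.sum()

    counts = [np.zeros(k) for k in comp.nstates]
    for states, wgt in zip(combos, weights):
        for i, s in enumerate(states):
            counts[i][s] += wgt
    return _occupancy_from_counts(comp, counts, 0, 0, 0, 0, total,
                                  seed=None)


def partition_function_log10(table: SiteEnergyTable, ph: float) -> float:
    """log10 of the microstate partition sum (for thermodynamic identities)."""
    comp = _Compiled(table)
    energies = []
    for states in itertools.product(*[range(k) for k in comp.nstates]):
        energies.append(-comp.energy(list(states), ph))
    energies = np.array(energies)
    emax = energies.max()
    return float(emax + np.log10(np.sum(10.0 ** (energies - emax))))
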