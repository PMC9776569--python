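"""Finite-difference LPBE solver, focusing, and charging energies.

Analytic oracles: the Coulomb potential of a point charge in a uniform
dielectric, the Born-sphere transfer energy, and the mutual Coulomb energy
of two charges.  Grid anisotropy of the 7-point lattice is handled by
averaging the sampled potential over axis and diagonal directions at each
radius.
"""

import math
import warnings

import numpy as np
import pytest

from constph.constants import COULOMB_KJ_NM, LN10, kt_kj
from constph.fixtures import born_solvation_kt, two_site_rod
from constph.pb import (GridSpec, PBConfig, build_maps, charging_terms,
                        compute_energy_table, coarse_grid_spec,
                        debye_boundary, focus_solve, solve_lpbe)
from constph.sites import AtomRecord, SiteState, Structure, TitratableSite

KT = kt_kj(310.0)


def point_charge(q=1.0, radius=0.0):
    return Structure([AtomRecord(1, "Q", "ION", 1, [0.0, 0.0, 0.0], q,
                                 radius)])


def direction_shell(r):
    """Axis and body-diagonal sample points at radius r."""
    d = r / math.sqrt(3)
    return np.array([[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0],
                     [0, 0, r], [0, 0, -r],
                     [d, d, d], [-d, -d, -d], [d, -d, d], [-d, d, -d]])


def uniform_config(nodes=41, spacing=0.1, **kw):
    kw.setdefault("eps_in", 80.0)
    kw.setdefault("eps_out", 80.0)
    kw.setdefault("ionic_strength", 0.0)
    return PBConfig(nodes_per_side=nodes, coarse_spacing=spacing, **kw)


class TestBuildMaps:
    def test_charge_conservation_exact(self):
        rng = np.random.default_rng(5)
        atoms = [AtomRecord(i, "A", "X", i, rng.uniform(-0.5, 0.5, 3),
                            rng.normal(), 0.1) for i in range(12)]
        st = Structure(atoms)
        spec = GridSpec(33, 0.1, np.zeros(3))
        maps = build_maps(st, spec, uniform_config())
        assert maps.total_charge == pytest.approx(st.total_charge,
                                                  abs=1e-12)

    def test_sphere_interior_node_count(self):
        # geometric oracle: node count ~ sphere volume, within one shell
        radius, h = 0.2, 0.025
        st = point_charge(radius=radius)
        spec = GridSpec(41, h, np.zeros(3))
        maps = build_maps(st, spec, PBConfig(nodes_per_side=41))
        count = int((~maps.ion_accessible).sum())
        expected = 4.0 / 3.0 * math.pi * radius ** 3 / h ** 3
        shell = 4.0 * math.pi * radius ** 2 * h / h ** 3
        assert abs(count - expected) < shell

    def test_empty_structure(self):
        spec = GridSpec(17, 0.1, np.zeros(3))
        cfg = PBConfig(nodes_per_side=17)
        maps = build_maps(Structure([]), spec, cfg)
        assert np.all(maps.eps_x == cfg.eps_out)
        assert np.all(maps.charge == 0.0)
        assert np.all(maps.ion_accessible)

    def test_charged_atom_outside_grid_raises(self):
        st = Structure([AtomRecord(1, "Q", "X", 1, [5.0, 0, 0], 1.0, 0.1)])
        spec = GridSpec(17, 0.1, np.zeros(3))
        with pytest.raises(ValueError, match="outside"):
            build_maps(st, spec, uniform_config(nodes=17))
        maps = build_maps(st, spec, uniform_config(nodes=17),
                          allow_outside=True)
        assert maps.skipped_atoms == [0]


class TestSolveLpbe:
    def test_zero_charge_zero_boundary_gives_zero(self):
        spec = GridSpec(17, 0.1, np.zeros(3))
        cfg = uniform_config(nodes=17)
        maps = build_maps(Structure([]), spec, cfg)
        grid = solve_lpbe(maps, spec, cfg)
        assert np.all(grid.values == 0.0)
        assert grid.residual <= cfg.convergence_tol

    def test_point_charge_matches_coulomb(self):
        cfg = uniform_config(nodes=41, spacing=0.1)
        st = point_charge()
        spec = GridSpec(41, 0.1, np.zeros(3))
        maps = build_maps(st, spec, cfg)
        bound = debye_boundary(spec, st.positions, st.charges, cfg)
        grid = solve_lpbe(maps, spec, cfg, bound)
        half_box = 0.5 * (41 - 1) * 0.1
        for r in np.linspace(3 * 0.1, half_box, 6):
            phi = grid.at(direction_shell(r)).mean()
            analytic = COULOMB_KJ_NM / (80.0 * KT * r)
            assert phi == pytest.approx(analytic, rel=0.03)

    def test_linearity_of_solutions(self):
        # LPBE is linear: the potential of q_A + q_B is the sum of parts
        atoms = [AtomRecord(1, "A", "X", 1, [-0.3, 0, 0], 0.0, 0.15),
                 AtomRecord(2, "B", "X", 2, [0.4, 0.1, 0], 0.0, 0.12)]
        st = Structure(atoms)
        spec = GridSpec(33, 0.1, np.zeros(3))
        cfg = PBConfig(nodes_per_side=33, ionic_strength=0.1,
                       convergence_tol=1e-4)
        sols = {}
        for name, q in (("a", [1.0, 0.0]), ("b", [0.0, -1.0]),
                        ("ab", [1.0, -1.0])):
            qv = np.array(q)
            maps = build_maps(st, spec, cfg, charges=qv)
            bound = debye_boundary(spec, st.positions, qv, cfg)
            sols[name] = solve_lpbe(maps, spec, cfg, bound).values
        diff = np.abs(sols["ab"] - (sols["a"] + sols["b"]))
        assert diff.max() < 5e-3

    def test_born_sphere_energy(self):
        # focused solvation energy vs the analytic Born expression
        st = point_charge(radius=0.2)
        energies = {}
        for eps_out in (80.0, 2.0):
            cfg = PBConfig(eps_in=2.0, eps_out=eps_out, ionic_strength=0.0,
                           nodes_per_side=41, coarse_spacing=0.1,
                           fine_spacing=0.025,
                           dielectric_smoothing="harmonic")
            foc = focus_solve(st, [0, 0, 0], cfg)
            energies[eps_out] = 0.5 * foc.potential_at([[0, 0, 0]])[0]
        solvation = energies[80.0] - energies[2.0]
        analytic = born_solvation_kt(1.0, 0.2, 2.0, 80.0, 310.0)
        assert solvation == pytest.approx(analytic, rel=0.02)


class TestFocusing:
    def test_reproduces_unfocused_coulomb_in_fine_interior(self):
        cfg = uniform_config(nodes=41, fine_spacing=0.025)
        foc = focus_solve(point_charge(), [0, 0, 0], cfg)
        for r in (0.1, 0.2, 0.4):
            phi = foc.potential_at(direction_shell(r)).mean()
            analytic = COULOMB_KJ_NM / (80.0 * KT * r)
            assert phi == pytest.approx(analytic, rel=0.02)

    def test_translation_invariance(self):
        shift = np.array([0.513, -0.207, 0.331])
        st, sites, _ = two_site_rod()
        cfg = uniform_config(nodes=33, fine_spacing=0.05)
        t1 = compute_energy_table(st, sites, cfg)
        st2 = st.copy()
        st2.positions = st.positions + shift
        t2 = compute_energy_table(st2, [s.copy() for s in sites], cfg)
        assert abs(t1.get_w(1, "prot", 2, "prot")
                   - t2.get_w(1, "prot", 2, "prot")) < 1e-6
        assert abs(t1.pkint[(1, "prot")] - t2.pkint[(1, "prot")]) < 1e-6

    def test_fine_grid_escaping_coarse_raises(self):
        st = point_charge(radius=0.1)
        cfg = PBConfig(nodes_per_side=17, coarse_spacing=0.1,
                       fine_spacing=0.2)
        with pytest.raises(ValueError, match="beyond|outside"):
            focus_solve(st, [0, 0, 0], cfg)

    def test_robust_to_half_spacing_coarse_shift(self):
        # production grid geometry: 81 nodes, 0.1 -> 0.025 nm focusing
        st = point_charge(radius=0.15)
        cfg = PBConfig(eps_in=2.0, eps_out=80.0, ionic_strength=0.0,
                       nodes_per_side=81)
        base = coarse_grid_spec(st, cfg)
        f1 = focus_solve(st, [0, 0, 0], cfg)
        shifted = GridSpec(base.nodes_per_side, base.spacing,
                           base.center + np.array([0.05, 0, 0]))
        f2 = focus_solve(st, [0, 0, 0], cfg, coarse_spec=shifted)
        pts = np.array([[0.1, 0, 0], [0, 0.2, 0], [0.05, 0.05, 0.05],
                        [0.2, 0.1, 0], [0.5, 0, 0]])
        assert np.max(np.abs(f1.fine.at(pts) - f2.fine.at(pts))) \
            < cfg.convergence_tol


def _two_atom_site(rotate=False):
    p1, p2 = np.array([0.0, 0, 0]), np.array([0.12, 0, 0])
    if rotate:
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        p1, p2 = rot @ p1, rot @ p2
    atoms = [AtomRecord(1, "A", "X", 1, p1, 0.0, 0.15),
             AtomRecord(2, "B", "X", 1, p2, 0.0, 0.12)]
    states = [SiteState("prot", 1, 0, {"A": 0.6, "B": 0.4}, 7.0),
              SiteState("deprot", 0, 0, {"A": 0.0, "B": 0.0}, 7.0,
                        is_reference=True)]
    site = TitratableSite(1, "X", ["A", "B"], ["A", "B"], states,
                          atom_index={"A": 0, "B": 1})
    return Structure(atoms), site


class TestChargingTerms:
    def test_identical_contexts_cancel_exactly(self):
        # the site alone IS the protein: both contexts identical by code path
        st, site = _two_atom_site()
        cfg = PBConfig(nodes_per_side=33, fine_spacing=0.025)
        prot = charging_terms(st, site, site.states[0], "protein", cfg)
        model = charging_terms(st, site, site.states[0], "model_compound",
                               cfg)
        assert prot[0] == model[0]
        assert prot[1] == model[1]

    def test_background_matches_coulomb_for_rod(self):
        # uniform dielectric: interaction with a background charge is Coulomb
        sep = 1.0
        atoms = [AtomRecord(1, "SC", "A", 1, [0, 0, 0], 1.0, 0.05),
                 AtomRecord(2, "BG", "B", 2, [sep, 0, 0], 1.0, 0.05)]
        st = Structure(atoms)
        states = [SiteState("prot", 1, 0, {"SC": 1.0}, 7.0),
                  SiteState("deprot", 0, 0, {"SC": 0.0}, 7.0,
                            is_reference=True)]
        site = TitratableSite(1, "A", ["SC"], ["SC"], states,
                              atom_index={"SC": 0})
        cfg = uniform_config(nodes=41, fine_spacing=0.05)
        _, back = charging_terms(st, site, site.states[0], "protein", cfg)
        analytic = COULOMB_KJ_NM / (80.0 * KT * sep)
        assert back == pytest.approx(analytic, rel=0.03)

    def test_self_energy_invariant_under_lattice_rotation(self):
        cfg = PBConfig(nodes_per_side=33, ionic_strength=0.1,
                       fine_spacing=0.025)
        st0, site0 = _two_atom_site(rotate=False)
        st1, site1 = _two_atom_site(rotate=True)
        se0, _ = charging_terms(st0, site0, site0.states[0], "protein", cfg)
        se1, _ = charging_terms(st1, site1, site1.states[0], "protein", cfg)
        assert se0 == pytest.approx(se1, abs=1e-6)

    def test_foreign_state_rejected(self):
        st, site = _two_atom_site()
        foreign = SiteState("other", 1, 0, {"A": 1.0, "B": 0.0}, 5.0)
        with pytest.raises(ValueError):
            charging_terms(st, site, foreign, "protein",
                           PBConfig(nodes_per_side=33))


class TestEnergyTable:
    def test_isolated_model_compound_identity(self):
        # sign-convention anchor: pKint == pKmod when the model compound is
        # the entire protein
        st, site = _two_atom_site()
        cfg = PBConfig(nodes_per_side=33, fine_spacing=0.025)
        table = compute_energy_table(st, [site], cfg)
        assert table.pkint[(1, "prot")] == pytest.approx(7.0, abs=1e-3)
        assert table.pkint[(1, "deprot")] == table.pkmod[(1, "deprot")]

    def test_w_matches_coulomb(self):
        st, sites, meta = two_site_rod(separation=1.0)
        cfg = uniform_config(nodes=41, fine_spacing=0.05)
        table = compute_energy_table(st, sites, cfg)
        w = table.get_w(1, "prot", 2, "prot")
        # analytic: 138.935/(80 * 1.0 * kT * ln10) ~ 0.293 pK
        assert meta["analytic_w_pk"] == pytest.approx(
            COULOMB_KJ_NM / (80.0 * KT * LN10), rel=1e-12)
        assert w == pytest.approx(meta["analytic_w_pk"], rel=0.03)

    def test_w_symmetric_and_reference_null(self):
        st, sites, _ = two_site_rod(separation=0.8)
        cfg = uniform_config(nodes=33, fine_spacing=0.05)
        table = compute_energy_table(st, sites, cfg)
        for sa in ("prot", "deprot"):
            for sb in ("prot", "deprot"):
                assert table.get_w(1, sa, 2, sb) == table.get_w(2, sb, 1, sa)
        # any pair involving a reference state couples with zero W
        assert table.get_w(1, "deprot", 2, "prot") == 0.0
        assert table.get_w(1, "prot", 2, "deprot") == 0.0
        table.validate()

    def test_context_cancellation_under_grid_doubling(self):
        # grid self-energies cancel protein-vs-model on identical fine grids
        atoms = [AtomRecord(1, "SC", "TOY", 1, [0.0, 0, 0], 0.0, 0.12),
                 AtomRecord(2, "SH", "HOST", 2, [0.28, 0, 0], 0.0, 0.30),
                 AtomRecord(3, "SH2", "HOST", 3, [-0.28, 0, 0], 0.0, 0.30)]
        states = [SiteState("prot", 1, 0, {"SC": 1.0}, 7.0),
                  SiteState("deprot", 0, 0, {"SC": 0.0}, 7.0,
                            is_reference=True)]

        def pkint(nodes):
            st = Structure([a.copy() for a in atoms])
            site = TitratableSite(1, "TOY", ["SC"], ["SC"],
                                  [SiteState(s.label, s.protonation_count,
                                             s.tautomer_index,
                                             dict(s.atom_charges), s.pkmod,
                                             s.is_reference)
                                   for s in states],
                                  atom_index={"SC": 0})
            cfg = PBConfig(nodes_per_side=nodes, ionic_strength=0.1,
                           fine_spacing=0.025,
                           dielectric_smoothing="harmonic")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return compute_energy_table(st, [site],
                                            cfg).pkint[(1, "prot")]

        p33, p65 = pkint(33), pkint(65)
        assert p33 < 0.0  # strongly buried cation: large downward shift
        assert abs(p65 - p33) < 0.05

    def test_monotone_born_refinement(self):
        # with edge-fraction (harmonic) dielectric smoothing the Born error
        # strictly decreases along the focusing ladder
        st = point_charge(radius=0.2)
        analytic = born_solvation_kt(1.0, 0.2, 2.0, 80.0, 310.0)
        errors = []
        for h in (0.1, 0.05, 0.025):
            energies = {}
            for eps_out in (80.0, 2.0):
                cfg = PBConfig(eps_in=2.0, eps_out=eps_out,
                               ionic_strength=0.0, nodes_per_side=41,
                               coarse_spacing=0.1, fine_spacing=h,
                               dielectric_smoothing="harmonic")
                foc = focus_solve(st, [0, 0, 0], cfg)
                energies[eps_out] = 0.5 * foc.potential_at([[0, 0, 0]])[0]
            errors.append(abs(energies[80.0] - energies[2.0] - analytic))
        assert errors[0] > errors[1] > errors[2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PBConfig(eps_in=80.0, eps_out=2.0)
        with pytest.raises(ValueError):
            PBConfig(convergence_tol=0.0)
        with pytest.raises(ValueError):
            GridSpec(8, 0.1, np.zeros(3))
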