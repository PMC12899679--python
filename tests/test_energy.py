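"""Energy terms: bonded forms, dipole coupling, vdW, hydrogen bonds, totals."""

import copy
import itertools
import math

import numpy as np
import pytest

from conftest import random_rotation
from pbdp.charges import TableChargeProvider, update_induced_dipoles
from pbdp.energy import (
    HydrogenBond,
    bond_energy,
    angle_energy,
    detect_hydrogen_bonds,
    dipole_pair_energy,
    dipole_pair_geometry,
    electrostatic_energy,
    molecular_dipole,
    orbital_energy,
    torsion_energy,
    total_energy,
    vdw_energy,
)
from pbdp.fixtures import (
    gen_alkane_chain,
    gen_dipole_rig,
    gen_water_cluster,
    gen_water_dimer,
)
from pbdp.model import (
    Atom,
    Bond,
    MolecularSystem,
    assign_atom_types,
    assign_bond_dipoles,
    build_topology,
    electrostatic_pair_list,
    vdw_pair_list,
)
from pbdp.params import COULOMB_KCAL, EA_PER_DEBYE, K_DD, combine_vdw


def _two_atom_system(elements, b, params_key=None):
    atoms = [
        Atom(0, elements[0], np.zeros(3)),
        Atom(1, elements[1], np.array([b, 0.0, 0.0])),
    ]
    return MolecularSystem(atoms, [Bond(0, 1)])


class TestBondedTerms:
    def test_zero_at_equilibrium(self, water, params):
        top = build_topology(water)
        assert bond_energy(water, params) == pytest.approx(0.0, abs=1e-20)
        assert angle_energy(water, top, params) == pytest.approx(0.0, abs=1e-12)

    def test_single_bond_hand_value(self, params):
        # Kb=320 (CT-OH), b0=1.41, b=1.51 → 320·0.01 = 3.20; use a direct pair
        sys_ = _two_atom_system(["C", "O"], 1.51)
        sys_.atoms[0].atom_type = "CT"
        sys_.atoms[1].atom_type = "OH"
        ps = copy.deepcopy(params)
        ps.bonded.bonds["CT-OH"] = (300.0, 1.41)
        assert bond_energy(sys_, ps) == pytest.approx(3.00, abs=1e-10)

    def test_angle_hand_value(self, params):
        # Kθ=50, θ0=109.5°, θ=119.5° → 50·(10°)² in rad² = 1.52309
        sys_ = MolecularSystem(
            [
                Atom(0, "H", np.array([1.0, 0.0, 0.0])),
                Atom(1, "C", np.zeros(3)),
                Atom(
                    2,
                    "H",
                    np.array(
                        [math.cos(math.radians(119.5)), math.sin(math.radians(119.5)), 0]
                    ),
                ),
            ],
            [Bond(0, 1), Bond(1, 2)],
        )
        assign_atom_types(sys_)
        top = build_topology(sys_)
        ps = copy.deepcopy(params)
        ps.bonded.angles["X-CT-X"] = (50.0, 109.5)
        expected = 50.0 * math.radians(10.0) ** 2
        assert angle_energy(sys_, top, ps) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.523, abs=5e-4)

    def test_angle_symmetric_under_flank_swap(self, water3, params):
        top = build_topology(water3)
        e1 = angle_energy(water3, top, params)
        swapped = copy.deepcopy(top)
        swapped.angles = [(k, j, i) for i, j, k in top.angles]
        assert angle_energy(water3, swapped, params) == pytest.approx(e1, rel=1e-14)

    def test_torsion_cosine_zero_and_max(self, params):
        # Vn=1.5, n=3, γ=0: φ=60° → 0; φ=0 → 3.0
        def chain_at(phi_deg):
            phi = math.radians(phi_deg)
            pts = [
                np.array([0.0, 1.0, 0.0]),
                np.zeros(3),
                np.array([1.5, 0.0, 0.0]),
                np.array([1.5, math.cos(phi), math.sin(phi)]),
            ]
            sys_ = MolecularSystem(
                [Atom(i, "C", p) for i, p in enumerate(pts)],
                [Bond(0, 1), Bond(1, 2), Bond(2, 3)],
            )
            assign_atom_types(sys_)
            return sys_

        ps = copy.deepcopy(params)
        ps.bonded.dihedrals["X-CT-CT-X"] = [(1.5, 3, 0.0)]
        for phi, expected in [(60.0, 0.0), (0.0, 3.0), (120.0, 3.0)]:
            sys_ = chain_at(phi)
            top = build_topology(sys_)
            # restrict to the backbone dihedral by zeroing hydrogens: pure C chain
            assert torsion_energy(sys_, top, ps) == pytest.approx(expected, abs=1e-9)

    def test_torsion_2pi_periodicity(self, params):
        ps = copy.deepcopy(params)
        ps.bonded.dihedrals["X-CT-CT-X"] = [(0.7, 2, 35.0)]
        butane = gen_alkane_chain(4)
        top = build_topology(butane)
        e1 = torsion_energy(butane, top, ps)
        # rotating the terminal methyl by 2π leaves every dihedral unchanged
        assert e1 == pytest.approx(torsion_energy(butane, top, ps), rel=1e-14)

    def test_untabulated_torsion_warns_and_contributes_zero(self, params):
        ps = copy.deepcopy(params)
        ps.bonded.dihedrals.clear()
        butane = gen_alkane_chain(4)
        top = build_topology(butane)
        with pytest.warns(UserWarning, match="treated as V=0"):
            assert torsion_energy(butane, top, ps, warn_missing=True) == 0.0

    def test_bond_energy_rigid_motion_invariant(self, glucose, params):
        rot = random_rotation(5)
        moved = glucose.copy()
        moved.set_coords(glucose.coords @ rot.T + np.array([3.0, -2.0, 7.0]))
        assert bond_energy(moved, params) == pytest.approx(
            bond_energy(glucose, params), abs=1e-9
        )


class TestDipolePair:
    def test_convention_head_to_tail(self):
        si, sj = gen_dipole_rig(0.0, math.pi, 0.0, 3.0)
        geo = dipole_pair_geometry(si, sj)
        assert geo.alpha == pytest.approx(0.0, abs=1e-12)
        assert geo.alpha_prime == pytest.approx(math.pi, abs=1e-12)
        e, pp, pi_, ii = dipole_pair_energy(si, sj, K_DD)
        assert e == pytest.approx(-2 * K_DD / 27.0, rel=1e-12)
        assert e == pytest.approx(-1.066, abs=5e-4)

    def test_parallel_side_by_side_repulsive(self):
        si, sj = gen_dipole_rig(math.pi / 2, math.pi / 2, 0.0, 3.0)
        geo = dipole_pair_geometry(si, sj)
        assert geo.beta == pytest.approx(0.0, abs=1e-12)
        e, *_ = dipole_pair_energy(si, sj, K_DD)
        assert e == pytest.approx(K_DD / 27.0, rel=1e-12)
        assert e == pytest.approx(0.533, abs=5e-4)

    def test_orthogonal_pair_is_zero(self):
        si, sj = gen_dipole_rig(0.0, math.pi / 2, 0.0, 3.0)
        e, *_ = dipole_pair_energy(si, sj, K_DD)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_coincident_centers_error(self):
        si, sj = gen_dipole_rig(0.3, 0.4, 0.5, 1.0)
        sj.center = si.center.copy()
        with pytest.raises(ValueError, match="coincident"):
            dipole_pair_geometry(si, sj)

    def test_point_charge_oracle(self):
        """Two-point-charge Coulomb limit at d/r ≤ 0.01, ≤1e−3 relative.

        Relative to the pair's natural energy scale k_dd·μμ/r³ so that
        orientations near the angular node do not inflate the ratio.
        """
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(500):
            a, ap, b = rng.uniform(0, math.pi, 3)
            r = rng.uniform(2.0, 10.0)
            mi, mj = rng.uniform(0.3, 2.5, 2)
            si, sj = gen_dipole_rig(a, ap, b, r, mi, mj)
            e, *_ = dipole_pair_energy(si, sj, K_DD)
            d = 0.01 * r
            qi, qj = mi * EA_PER_DEBYE / d, mj * EA_PER_DEBYE / d
            pts_i = [(si.center + 0.5 * d * si.axis, qi), (si.center - 0.5 * d * si.axis, -qi)]
            pts_j = [(sj.center + 0.5 * d * sj.axis, qj), (sj.center - 0.5 * d * sj.axis, -qj)]
            e_pc = sum(
                COULOMB_KCAL * q1 * q2 / np.linalg.norm(p1 - p2)
                for p1, q1 in pts_i
                for p2, q2 in pts_j
            )
            scale = K_DD * mi * mj / r**3
            worst = max(worst, abs(e - e_pc) / max(abs(e_pc), scale))
        assert worst < 1e-3

    def test_split_sums_to_combined_magnitudes(self):
        si, sj = gen_dipole_rig(0.7, 2.1, 0.9, 4.2, 1.3, 0.8, 0.21, -0.13)
        e, pp, pi_, ii = dipole_pair_energy(si, sj, K_DD)
        assert e == pytest.approx(pp + pi_ + ii, rel=1e-14)
        geo = dipole_pair_geometry(si, sj)
        combined = (
            K_DD * si.mu_total * sj.mu_total / geo.r**3 * geo.angular_factor
        )
        assert e == pytest.approx(combined, rel=1e-12)


class TestElectrostaticSums:
    def test_table_provider_zeroes_induced_terms(self, water3, params):
        rep = total_energy(water3, params)
        assert rep.e_es_pi == 0.0
        assert rep.e_es_ii == 0.0

    def test_far_separated_waters_decay(self, params):
        w = gen_water_cluster(1, seed=1)
        far = w.copy()
        atoms = w.atoms + [
            Atom(3 + a.index, a.element, a.position + np.array([50.0, 0, 0]))
            for a in far.atoms
        ]
        bonds = list(w.bonds) + [Bond(3, 4), Bond(3, 5)]
        pair = assign_atom_types(MolecularSystem(atoms, bonds))
        rep = total_energy(pair, params)
        assert abs(rep.e_es) < 1e-3

    def test_three_waters_match_tensor_bruteforce(self, water3, params):
        """Independent naive double loop with the dipole interaction tensor."""
        sites = assign_bond_dipoles(water3, params)
        top = build_topology(water3)
        charges = TableChargeProvider(params)(water3)
        update_induced_dipoles(sites, water3, charges, params)
        pairs = electrostatic_pair_list(sites, top)
        e_pp, e_pi, e_ii = electrostatic_energy(sites, pairs, params.k_dd)
        brute = 0.0
        for a, b in pairs:
            sa, sb = sites[a], sites[b]
            rv = sb.center - sa.center
            r = np.linalg.norm(rv)
            rh = rv / r
            ang = np.dot(sa.axis, sb.axis) - 3 * np.dot(sa.axis, rh) * np.dot(sb.axis, rh)
            brute += params.k_dd * sa.mu_total * sb.mu_total * ang / r**3
        assert e_pp + e_pi + e_ii == pytest.approx(brute, rel=1e-12)


class TestVdw:
    def test_pair_at_minimum(self, params):
        a, b = combine_vdw("OW", "OW", params.vdw)
        rmin = (2 * a / b) ** (1 / 6)
        sys_ = gen_water_cluster(1, seed=1)
        pair = [(0, 0, 1.0)]  # dummy; evaluate directly instead
        # direct evaluation of the pair formula at the analytic minimum
        assert a / rmin**12 - b / rmin**6 == pytest.approx(-(b**2) / (4 * a), rel=1e-12)

    def test_zero_crossing(self, params):
        a, b = combine_vdw("CT", "CT", params.vdw)
        r0 = (a / b) ** (1 / 6)
        assert a / r0**12 - b / r0**6 == pytest.approx(0.0, abs=1e-12)

    def test_butane_14_contributes_half(self, params):
        butane = gen_alkane_chain(4)
        top = build_topology(butane)
        pairs = vdw_pair_list(butane, top)
        full = [(i, j, 1.0) for i, j, s in pairs]
        onlyscaled = [(i, j, s) for i, j, s in pairs]
        e14_full = vdw_energy(butane, [(0, 3, 1.0)], params)
        e14_half = vdw_energy(butane, [(0, 3, 0.5)], params)
        assert e14_half == pytest.approx(0.5 * e14_full, rel=1e-14)
        assert any(s == 0.5 for _, _, s in onlyscaled)
        assert len(full) == len(onlyscaled)

    def test_zero_distance_error(self, params):
        sys_ = gen_water_cluster(1, seed=2)
        sys_.atoms[1].position = sys_.atoms[0].position.copy()
        with pytest.raises(ValueError, match="zero distance"):
            vdw_energy(sys_, [(0, 1, 1.0)], params)


class TestHydrogenBonds:
    def test_ideal_water_dimer(self, water_dimer, params):
        hbs = detect_hydrogen_bonds(water_dimer, params)
        assert len(hbs) == 1
        assert hbs[0].class_key == "OW-HW...OW"
        assert hbs[0].r_hb == pytest.approx(2.9, abs=1e-9)
        assert hbs[0].alpha_deg == pytest.approx(180.0, abs=1e-6)

    def test_intramolecular_sugar_contacts_never_reported(self, glucose, params):
        assert detect_hydrogen_bonds(glucose, params) == []

    def test_only_parameterized_classes(self, glucose, params):
        rng = np.random.default_rng(3)
        cluster = _sugar_with_waters(glucose, n_water=6, seed=4)
        for hb in detect_hydrogen_bonds(cluster, params):
            assert hb.class_key in params.orbital.classes
            assert cluster.molecule_id[hb.donor_o] != cluster.molecule_id[hb.acceptor_o]

    def test_bruteforce_geometric_filter(self, params):
        cluster = gen_water_cluster(12, seed=9)
        got = {
            (hb.donor_o, hb.donor_h, hb.acceptor_o)
            for hb in detect_hydrogen_bonds(cluster, params)
        }
        expected = set()
        mol = cluster.molecule_id
        for b in cluster.bonds:
            for o, h in ((b.i, b.j), (b.j, b.i)):
                if cluster.atoms[o].atom_type != "OW" or cluster.atoms[h].atom_type != "HW":
                    continue
                for acc in cluster.atoms:
                    if acc.atom_type != "OW" or mol[acc.index] == mol[o]:
                        continue
                    r = np.linalg.norm(cluster.atoms[o].position - acc.position)
                    if r > params.orbital.r_cut:
                        continue
                    v1 = cluster.atoms[o].position - cluster.atoms[h].position
                    v2 = acc.position - cluster.atoms[h].position
                    ang = math.degrees(
                        math.acos(
                            np.clip(
                                np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2),
                                -1,
                                1,
                            )
                        )
                    )
                    if ang >= params.orbital.angle_cut:
                        expected.add((o, h, acc.index))
        assert got == expected


def _sugar_with_waters(glucose, n_water, seed):
    from pbdp.fixtures import gen_water

    rng = np.random.default_rng(seed)
    atoms = [Atom(a.index, a.element, a.position.copy()) for a in glucose.atoms]
    bonds = list(glucose.bonds)
    base = len(atoms)
    center = glucose.coords.mean(axis=0)
    for k in range(n_water):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        origin = center + direction * (4.0 + 1.5 * k / max(1, n_water - 1))
        elements, coords = gen_water(origin=origin, rotation=random_rotation(seed + k))
        for el, xyz in zip(elements, coords):
            atoms.append(Atom(len(atoms), el, xyz))
        bonds += [Bond(base, base + 1), Bond(base, base + 2)]
        base += 3
    return assign_atom_types(MolecularSystem(atoms, bonds))


class TestOrbitalTerm:
    def _ideal(self, cls_key, params, r=None, alpha=None, b1=None, b2=None):
        cls = params.orbital.classes[cls_key]
        return HydrogenBond(
            class_key=cls_key,
            donor_o=0,
            donor_h=1,
            acceptor_o=2,
            r_hb=cls.R0 if r is None else r,
            alpha_deg=cls.alpha0 if alpha is None else alpha,
            beta1_deg=cls.beta0 if b1 is None else b1,
            beta2_deg=cls.beta0 if b2 is None else b2,
        )

    def test_minus_d_at_ideal_geometry(self, params):
        for key, cls in params.orbital.classes.items():
            hb = self._ideal(key, params)
            assert orbital_energy(hb, params.orbital) == pytest.approx(-cls.D, rel=1e-12)

    def test_vanishes_at_large_distance(self, params):
        hb = self._ideal("OW-HW...OW", params, r=25.0)
        assert abs(orbital_energy(hb, params.orbital)) < 1e-12

    def test_angle_node_at_90_degrees(self, params):
        cls = params.orbital.classes["OW-HW...OW"]
        hb = self._ideal("OW-HW...OW", params, alpha=cls.alpha0 - 90.0)
        assert orbital_energy(hb, params.orbital) == pytest.approx(0.0, abs=1e-15)

    def test_clamped_beyond_90_degrees(self, params):
        cls = params.orbital.classes["OW-HW...OW"]
        hb = self._ideal("OW-HW...OW", params, b1=cls.beta0 + 135.0)
        assert orbital_energy(hb, params.orbital) == 0.0

    def test_continuity_in_r(self, params):
        cls = params.orbital.classes["OW-HW...OW"]
        rs = np.linspace(cls.R0 - 0.4, cls.R0 + 2.0, 200)
        vals = [
            orbital_energy(self._ideal("OW-HW...OW", params, r=float(r)), params.orbital)
            for r in rs
        ]
        diffs = np.abs(np.diff(vals))
        assert diffs.max() < 0.6  # no jumps on a fine grid
        assert min(vals) == pytest.approx(-cls.D, abs=1e-3)

    def test_p1_recovers_plain_morse(self, params):
        ps = copy.deepcopy(params)
        ps.orbital.classes["OW-HW...OW"].p = 1
        cls = ps.orbital.classes["OW-HW...OW"]
        r = cls.R0 + 0.3
        hb = self._ideal("OW-HW...OW", ps, r=r)
        x = math.exp(-2 * cls.a * (r - cls.R0)) - 2 * math.exp(-cls.a * (r - cls.R0))
        assert orbital_energy(hb, ps.orbital) == pytest.approx(cls.D * x, rel=1e-12)


class TestTotalEnergy:
    def test_isolated_equilibrium_water_is_zero(self, water, params):
        rep = total_energy(water, params)
        assert rep.e_total == pytest.approx(0.0, abs=1e-10)
        assert rep.n_es_pairs == 0  # both sites share the oxygen

    def test_component_sum_identity(self, water3, params):
        rep = total_energy(water3, params)
        total = (
            rep.e_bond + rep.e_angle + rep.e_dihedral
            + rep.e_es_pp + rep.e_es_pi + rep.e_es_ii + rep.e_vdw + rep.e_orb
        )
        assert rep.e_total == pytest.approx(total, rel=1e-14)

    def test_rigid_motion_invariance(self, water3, params):
        rep0 = total_energy(water3, params)
        rot = random_rotation(17)
        moved = water3.copy()
        moved.set_coords(water3.coords @ rot.T + np.array([-4.0, 2.5, 11.0]))
        rep1 = total_energy(moved, params)
        for attr in ("e_bond", "e_angle", "e_dihedral", "e_es_pp", "e_vdw", "e_orb"):
            assert getattr(rep1, attr) == pytest.approx(
                getattr(rep0, attr), abs=1e-9
            ), attr

    def test_extensive_for_far_copies(self, params):
        single = gen_water_cluster(2, seed=21, box=4.0)
        rep_single = total_energy(single, params)
        atoms = [Atom(a.index, a.element, a.position.copy()) for a in single.atoms]
        offset = np.array([1.0e5, 0.0, 0.0])  # dipole coupling decays only as r⁻³
        for a in single.atoms:
            atoms.append(Atom(len(atoms), a.element, a.position + offset))
        bonds = list(single.bonds) + [
            Bond(b.i + single.n_atoms, b.j + single.n_atoms) for b in single.bonds
        ]
        double = assign_atom_types(MolecularSystem(atoms, bonds))
        rep_double = total_energy(double, params)
        assert rep_double.e_total == pytest.approx(2 * rep_single.e_total, abs=1e-9)


class TestMolecularDipole:
    def test_water_hand_value(self, water, params):
        vec = molecular_dipole(water, params)
        mu_oh = params.dipole.mu0["OW-HW"]
        expected = 2 * mu_oh * math.cos(math.radians(104.52 / 2))
        assert vec.magnitude == pytest.approx(expected, rel=1e-10)

    def test_rotation_equivariance(self, glucose, params):
        vec0 = molecular_dipole(glucose, params).as_array()
        rot = random_rotation(23)
        moved = glucose.copy()
        moved.set_coords(glucose.coords @ rot.T + 1.0)
        vec1 = molecular_dipole(moved, params).as_array()
        assert np.allclose(vec1, rot @ vec0, atol=1e-10)
        assert np.linalg.norm(vec1) == pytest.approx(np.linalg.norm(vec0), abs=1e-10)

    def test_multi_molecule_rejected(self, water3, params):
        with pytest.raises(ValueError, match="per-molecule"):
            molecular_dipole(water3, params)
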