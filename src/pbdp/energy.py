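"""Energy terms of the polarizable bond-dipole potential.

Total energy = bonded (harmonic bonds + harmonic angles + Fourier torsions)
+ dipole–dipole electrostatics over permanent and induced bond dipoles
+ 12-6 van der Waals + an orbital-overlap hydrogen-bond correction.

The dipole–dipole coupling between two sites i, j uses the classical
point-dipole form in internal coordinates (r, α, α′, β):

    E_ij = k_dd · μ_i μ_j / r³ · (2 cosα cosα′ + sinα sinα′ cosβ)

with α the angle of site i's axis to the center line directed i→j, α′ the
angle of site j's axis to the center line directed j→i, and β the dihedral
between the two axis planes.  With these conventions a head-to-tail pair
(α=0, α′=π) is attractive, matching the two-point-charge limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .charges import ChargeSet, update_induced_dipoles
from .model import (
    BondDipoleSite,
    MolecularSystem,
    Topology,
    assign_bond_dipoles,
    build_topology,
    electrostatic_pair_list,
    vdw_pair_list,
)
from .params import (
    MissingParameterError,
    OrbitalParams,
    ParameterSet,
    canonical_angle_key,
    canonical_dihedral_key,
    combine_vdw,
)

__all__ = [
    "EnergyReport",
    "DipolePairGeometry",
    "HydrogenBond",
    "DipoleVector",
    "bond_energy",
    "angle_energy",
    "torsion_energy",
    "dipole_pair_geometry",
    "dipole_pair_energy",
    "electrostatic_energy",
    "vdw_energy",
    "detect_hydrogen_bonds",
    "orbital_energy",
    "total_energy",
    "molecular_dipole",
]


@dataclass
class EnergyReport:
    """Component-wise energies (kcal·mol⁻¹) and term counts."""

    e_bond: float = 0.0
    e_angle: float = 0.0
    e_dihedral: float = 0.0
    e_es_pp: float = 0.0
    e_es_pi: float = 0.0
    e_es_ii: float = 0.0
    e_vdw: float = 0.0
    e_orb: float = 0.0
    n_es_pairs: int = 0
    n_vdw_pairs: int = 0
    n_hbonds: int = 0

    @property
    def e_es(self) -> float:
        return self.e_es_pp + self.e_es_pi + self.e_es_ii

    @property
    def e_total(self) -> float:
        return (
            self.e_bond + self.e_angle + self.e_dihedral
            + self.e_es + self.e_vdw + self.e_orb
        )

    def as_dict(self) -> dict:
        return {
            "e_bond": self.e_bond,
            "e_angle": self.e_angle,
            "e_dihedral": self.e_dihedral,
            "e_es_pp": self.e_es_pp,
            "e_es_pi": self.e_es_pi,
            "e_es_ii": self.e_es_ii,
            "e_es": self.e_es,
            "e_vdw": self.e_vdw,
            "e_orb": self.e_orb,
            "e_total": self.e_total,
            "counts": {
                "n_es_pairs": self.n_es_pairs,
                "n_vdw_pairs": self.n_vdw_pairs,
                "n_hbonds": self.n_hbonds,
            },
        }


# ---------------------------------------------------------------------------
# bonded terms


def bond_energy(system: MolecularSystem, params: ParameterSet) -> float:
    """Σ Kb (b − b0)² over all bonds."""
    e = 0.0
    for bond in system.bonds:
        kb, b0 = params.bonded.bond_params(system.bond_key(bond))
        b = system.bond_length(bond)
        e += kb * (b - b0) ** 2
    return e


def _angle_rad(system: MolecularSystem, i: int, j: int, k: int) -> float:
    u = system.atoms[i].position - system.atoms[j].position
    v = system.atoms[k].position - system.atoms[j].position
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(min(1.0, max(-1.0, cosv)))


def angle_energy(
    system: MolecularSystem, topology: Topology, params: ParameterSet
) -> float:
    """Σ Kθ (θ − θ0)², θ in radians internally (θ0 stored in degrees)."""
    e = 0.0
    for i, j, k in topology.angles:
        key = canonical_angle_key(
            system.atoms[i].atom_type,  # type: ignore[arg-type]
            system.atoms[j].atom_type,
            system.atoms[k].atom_type,
        )
        kth, th0_deg = params.bonded.angle_params(key)
        theta = _angle_rad(system, i, j, k)
        e += kth * (theta - math.radians(th0_deg)) ** 2
    return e


def _dihedral_rad(system: MolecularSystem, i: int, j: int, k: int, l: int) -> float:
    p = [system.atoms[a].position for a in (i, j, k, l)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return math.atan2(y, x)


def torsion_energy(
    system: MolecularSystem,
    topology: Topology,
    params: ParameterSet,
    warn_missing: bool = False,
) -> float:
    """Σ over dihedrals of Σ_n Vn[1 + cos(nφ − γn)].

    Untabulated torsion types contribute zero (sparse-table convention);
    set ``warn_missing`` to emit a warning naming them.
    """
    import warnings

    e = 0.0
    for i, j, k, l in topology.dihedrals:
        key = canonical_dihedral_key(
            *(system.atoms[a].atom_type for a in (i, j, k, l))  # type: ignore[misc]
        )
        terms = params.bonded.dihedral_terms(key)
        if terms is None:
            if warn_missing:
                warnings.warn(f"no torsion parameters for {key}; treated as V=0")
            continue
        phi = _dihedral_rad(system, i, j, k, l)
        for vn, n, gamma_deg in terms:
            e += vn * (1.0 + math.cos(n * phi - math.radians(gamma_deg)))
    return e


# ---------------------------------------------------------------------------
# dipole–dipole electrostatics


@dataclass
class DipolePairGeometry:
    r: float
    alpha: float  # rad, axis_i vs center line i→j
    alpha_prime: float  # rad, axis_j vs center line j→i
    beta: float  # rad, dihedral between axis planes, in [0, π]

    @property
    def angular_factor(self) -> float:
        return (
            2.0 * math.cos(self.alpha) * math.cos(self.alpha_prime)
            + math.sin(self.alpha) * math.sin(self.alpha_prime) * math.cos(self.beta)
        )


def dipole_pair_geometry(
    site_i: BondDipoleSite, site_j: BondDipoleSite
) -> DipolePairGeometry:
    rij = site_j.center - site_i.center
    r = float(np.linalg.norm(rij))
    if r == 0.0:
        raise ValueError("coincident dipole centers")
    u = rij / r
    ca = float(np.clip(np.dot(site_i.axis, u), -1.0, 1.0))
    cap = float(np.clip(np.dot(site_j.axis, -u), -1.0, 1.0))
    alpha = math.acos(ca)
    alpha_p = math.acos(cap)
    # azimuthal dihedral between the perpendicular components of the axes
    wi = site_i.axis - ca * u
    wj = site_j.axis - (-cap) * u
    ni, nj = np.linalg.norm(wi), np.linalg.norm(wj)
    if ni < 1e-12 or nj < 1e-12:
        beta = 0.0  # degenerate: the sinα·sinα′ factor vanishes anyway
    else:
        cb = float(np.clip(np.dot(wi, wj) / (ni * nj), -1.0, 1.0))
        beta = math.acos(cb)
    return DipolePairGeometry(r=r, alpha=alpha, alpha_prime=alpha_p, beta=beta)


def dipole_pair_energy(
    site_i: BondDipoleSite,
    site_j: BondDipoleSite,
    k_dd: float,
) -> tuple[float, float, float, float]:
    """(E, E_pp, E_pi, E_ii) in kcal·mol⁻¹ for one site pair.

    E_pp carries μ0·μ0, E_pi the two permanent–induced cross terms and
    E_ii the δμ·δμ term; E is their sum and equals the single-pass value
    with combined magnitudes (μ0+δμ).
    """
    geo = dipole_pair_geometry(site_i, site_j)
    pref = k_dd / geo.r**3 * geo.angular_factor
    e_pp = pref * site_i.mu0 * site_j.mu0
    e_pi = pref * (site_i.mu0 * site_j.delta_mu + site_j.mu0 * site_i.delta_mu)
    e_ii = pref * site_i.delta_mu * site_j.delta_mu
    return e_pp + e_pi + e_ii, e_pp, e_pi, e_ii


def electrostatic_energy(
    sites: list[BondDipoleSite],
    pair_list: list[tuple[int, int]],
    k_dd: float,
) -> tuple[float, float, float]:
    """(e_pp, e_pi, e_ii) summed over the pair list.

    Induced magnitudes must already be loaded on the sites
    (:func:`pbdp.charges.update_induced_dipoles`).
    """
    e_pp = e_pi = e_ii = 0.0
    for a, b in pair_list:
        _, pp, pi, ii = dipole_pair_energy(sites[a], sites[b], k_dd)
        e_pp += pp
        e_pi += pi
        e_ii += ii
    return e_pp, e_pi, e_ii


# ---------------------------------------------------------------------------
# van der Waals


def vdw_energy(
    system: MolecularSystem,
    vdw_pairs: list[tuple[int, int, float]],
    params: ParameterSet,
) -> float:
    """Σ scale · (A_ij/R¹² − B_ij/R⁶) over the pair list."""
    e = 0.0
    coords = system.coords
    for i, j, scale in vdw_pairs:
        rij = coords[i] - coords[j]
        r2 = float(np.dot(rij, rij))
        if r2 == 0.0:
            raise ValueError(f"zero distance between atoms {i} and {j}")
        a, b = combine_vdw(
            system.atoms[i].atom_type, system.atoms[j].atom_type, params.vdw
        )
        r6 = r2**3
        e += scale * (a / (r6 * r6) - b / r6)
    return e


# ---------------------------------------------------------------------------
# hydrogen bonds / orbital term


@dataclass
class HydrogenBond:
    """One detected intermolecular donor–H···acceptor contact."""

    class_key: str  # e.g. "OH-HO...OW"
    donor_o: int
    donor_h: int
    acceptor_o: int
    r_hb: float  # donor-O–acceptor-O distance, Å
    alpha_deg: float  # D–H···A angle at the hydrogen
    beta1_deg: float  # H···A axis vs acceptor's first covalent bond
    beta2_deg: float  # H···A axis vs acceptor's second covalent bond


_DONOR_KEYS = {("OW", "HW"), ("OH", "HO")}
_ACCEPTOR_TYPES = ("OW", "OH", "OS")


def _vec_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(
        np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    )
    return math.degrees(math.acos(c))


def detect_hydrogen_bonds(
    system: MolecularSystem, params: ParameterSet
) -> list[HydrogenBond]:
    """Intermolecular H-bonds of the four parameterized classes only.

    Classes: OW-HW···OW, OH-HO···OW, OW-HW···OH, OW-HW···OS.  A candidate
    qualifies when the donor-O–acceptor-O distance is within ``r_cut``
    (default 3.5 Å) and the D–H···A angle is at least ``angle_cut``
    (default 120°).  Intramolecular contacts and sugar-donor→sugar-acceptor
    pairs are never reported.
    """
    mol = system.molecule_id
    out: list[HydrogenBond] = []
    donors: list[tuple[int, int, str]] = []  # (O, H, donor type pair)
    for bond in system.bonds:
        for o, h in ((bond.i, bond.j), (bond.j, bond.i)):
            to = system.atoms[o].atom_type
            th = system.atoms[h].atom_type
            if (to, th) in _DONOR_KEYS:
                donors.append((o, h, f"{to}-{th}"))

    acceptors = [
        a.index for a in system.atoms if a.atom_type in _ACCEPTOR_TYPES
    ]
    for d_o, d_h, d_key in donors:
        for a_o in acceptors:
            if mol[a_o] == mol[d_o]:
                continue
            class_key = f"{d_key}...{system.atoms[a_o].atom_type}"
            if class_key not in params.orbital.classes:
                continue
            r_hb = float(
                np.linalg.norm(system.atoms[d_o].position - system.atoms[a_o].position)
            )
            if r_hb > params.orbital.r_cut:
                continue
            h_pos = system.atoms[d_h].position
            alpha = _vec_angle_deg(
                system.atoms[d_o].position - h_pos,
                system.atoms[a_o].position - h_pos,
            )
            if alpha < params.orbital.angle_cut:
                continue
            nbrs = system.neighbors(a_o)
            if len(nbrs) != 2:
                continue
            axis = h_pos - system.atoms[a_o].position  # A → H
            betas = [
                _vec_angle_deg(
                    axis, system.atoms[n].position - system.atoms[a_o].position
                )
                for n in nbrs
            ]
            out.append(
                HydrogenBond(
                    class_key=class_key,
                    donor_o=d_o,
                    donor_h=d_h,
                    acceptor_o=a_o,
                    r_hb=r_hb,
                    alpha_deg=alpha,
                    beta1_deg=betas[0],
                    beta2_deg=betas[1],
                )
            )
    return out


def _clamped_cos(delta_deg: float) -> float:
    """cos of an angular deviation, clamped to 0 beyond 90° so the bonding
    correction never changes sign at grossly non-ideal geometry."""
    if abs(delta_deg) > 90.0:
        return 0.0
    return math.cos(math.radians(delta_deg))


def orbital_energy(hbond: HydrogenBond, orbital: OrbitalParams) -> float:
    """Morse-bracket^p × angular-cosine correction for one hydrogen bond."""
    cls = orbital.for_class(hbond.class_key)
    x = math.exp(-2.0 * cls.a * (hbond.r_hb - cls.R0)) - 2.0 * math.exp(
        -cls.a * (hbond.r_hb - cls.R0)
    )
    bracket = x**cls.p  # p odd: sign of x preserved
    return (
        cls.D
        * bracket
        * _clamped_cos(hbond.alpha_deg - cls.alpha0)
        * _clamped_cos(hbond.beta1_deg - cls.beta0)
        * _clamped_cos(hbond.beta2_deg - cls.beta0)
    )


# ---------------------------------------------------------------------------
# total energy and molecular dipole


def total_energy(
    system: MolecularSystem,
    params: ParameterSet,
    charge_provider=None,
    topology: Topology | None = None,
) -> EnergyReport:
    """Full component-wise single-point energy.

    ``charge_provider`` is any callable ``system -> ChargeSet``; when None,
    the q0 table provider is used (all induced dipoles vanish).
    """
    from .charges import TableChargeProvider

    if topology is None:
        topology = build_topology(system)
    if charge_provider is None:
        charge_provider = TableChargeProvider(params)

    report = EnergyReport()
    report.e_bond = bond_energy(system, params)
    report.e_angle = angle_energy(system, topology, params)
    report.e_dihedral = torsion_energy(system, topology, params)

    sites = assign_bond_dipoles(system, params)
    charges = charge_provider(system)
    update_induced_dipoles(sites, system, charges, params)
    pairs = electrostatic_pair_list(
        sites, topology, params.scaling.elec_min_bond_path
    )
    report.e_es_pp, report.e_es_pi, report.e_es_ii = electrostatic_energy(
        sites, pairs, params.k_dd
    )
    report.n_es_pairs = len(pairs)

    vpairs = vdw_pair_list(system, topology, params.scaling.vdw14_scale)
    report.e_vdw = vdw_energy(system, vpairs, params)
    report.n_vdw_pairs = len(vpairs)

    hbonds = detect_hydrogen_bonds(system, params)
    report.e_orb = sum(orbital_energy(hb, params.orbital) for hb in hbonds)
    report.n_hbonds = len(hbonds)
    return report


@dataclass
class DipoleVector:
    mux: float
    muy: float
    muz: float

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.mux**2 + self.muy**2 + self.muz**2)

    def as_array(self) -> np.ndarray:
        return np.array([self.mux, self.muy, self.muz])


def molecular_dipole(
    system: MolecularSystem,
    params: ParameterSet,
    charge_provider=None,
) -> DipoleVector:
    """Vector sum Σ (μ0 + δμ)·axis over one molecule's dipole sites (Debye)."""
    from .charges import TableChargeProvider

    if system.n_molecules != 1:
        raise ValueError(
            "molecular_dipole is a per-molecule quantity; got "
            f"{system.n_molecules} molecules (extract a subsystem first)"
        )
    if charge_provider is None:
        charge_provider = TableChargeProvider(params)
    sites = assign_bond_dipoles(system, params)
    charges = charge_provider(system)
    update_induced_dipoles(sites, system, charges, params)
    vec = np.zeros(3)
    for s in sites:
        vec += s.mu_total * s.axis
    return DipoleVector(*vec)
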