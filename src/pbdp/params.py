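"""Force-field parameter model, JSON serialization and combination rules.

Units follow the file convention throughout: lengths in Å, energies in
kcal·mol⁻¹, angles in **degrees in files** (radians internally where noted),
dipoles in Debye, charges in elementary charges.

The dipole–dipole prefactor ``k_dd`` converts D²·Å⁻³ to kcal·mol⁻¹:
k_dd = 332.0637 kcal·Å·mol⁻¹·e⁻² × (0.20819434 e·Å/D)² ≈ 14.3938.
It is stored in the parameter file so energies are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "ParameterError",
    "MissingParameterError",
    "BondedParams",
    "DipoleParams",
    "VdwParams",
    "OrbitalParams",
    "OrbitalClassParams",
    "ScalingParams",
    "ParameterSet",
    "combine_vdw",
    "canonical_angle_key",
    "canonical_dihedral_key",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "COULOMB_KCAL",
    "EA_PER_DEBYE",
    "K_DD",
]

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻²
COULOMB_KCAL = 332.0637
#: 1 Debye in e·Å
EA_PER_DEBYE = 0.20819434
#: dipole–dipole prefactor, kcal·mol⁻¹·Å³·D⁻²
K_DD = COULOMB_KCAL * EA_PER_DEBYE**2

HB_CLASSES = ("OW-HW...OW", "OH-HO...OW", "OW-HW...OH", "OW-HW...OS")


class ParameterError(ValueError):
    """Schema or invariant violation in a parameter set."""


class MissingParameterError(KeyError):
    """A required parameter entry is absent."""


def _canon_pair(key: str) -> str:
    a, b = key.split("-")
    from .model import canonical_bond_key

    return canonical_bond_key(a, b)


def canonical_angle_key(ti: str, tj: str, tk: str) -> str:
    """Angle type key with the lexicographically smaller flank first."""
    return f"{ti}-{tj}-{tk}" if ti <= tk else f"{tk}-{tj}-{ti}"


def canonical_dihedral_key(ti: str, tj: str, tk: str, tl: str) -> str:
    parts = [ti, tj, tk, tl]
    return "-".join(min(parts, parts[::-1]))


def _canon_triple(key: str) -> str:
    a, b, c = key.split("-")
    return canonical_angle_key(a, b, c)


def _canon_quad(key: str) -> str:
    parts = key.split("-")
    if len(parts) != 4:
        raise ParameterError(f"bad dihedral key {key!r}")
    return canonical_dihedral_key(*parts)


@dataclass
class BondedParams:
    """Harmonic bond/angle constants and Fourier torsion series.

    ``angles`` and ``dihedrals`` support Amber-style ``X`` wildcards in the
    flanking positions (``X-CT-X``, ``X-CT-OS-X``); exact keys win.
    Angle θ0 is stored in degrees; energy routines convert to radians.
    Torsion terms are (Vn kcal·mol⁻¹, n ≥ 1, γn degrees).
    """

    bonds: dict[str, tuple[float, float]] = field(default_factory=dict)
    angles: dict[str, tuple[float, float]] = field(default_factory=dict)
    dihedrals: dict[str, list[tuple[float, int, float]]] = field(default_factory=dict)

    def validate(self) -> None:
        for key, (kb, b0) in self.bonds.items():
            if kb < 0:
                raise ParameterError(f"bonded.bonds.{key}: Kb must be >= 0")
            if b0 <= 0:
                raise ParameterError(f"bonded.bonds.{key}: b0 must be > 0")
        for key, (kth, th0) in self.angles.items():
            if kth < 0:
                raise ParameterError(f"bonded.angles.{key}: Ktheta must be >= 0")
            if not (0.0 < th0 < 180.0):
                raise ParameterError(
                    f"bonded.angles.{key}: theta0 must be in (0, 180) degrees"
                )
        for key, terms in self.dihedrals.items():
            for vn, n, gamma in terms:
                if n < 1 or int(n) != n:
                    raise ParameterError(
                        f"bonded.dihedrals.{key}: periodicity n must be integer >= 1"
                    )

    def bond_params(self, key: str) -> tuple[float, float]:
        try:
            return self.bonds[key]
        except KeyError:
            raise MissingParameterError(f"no bond parameters for {key}") from None

    def angle_params(self, key: str) -> tuple[float, float]:
        if key in self.angles:
            return self.angles[key]
        _, center, _ = key.split("-")
        wild = f"X-{center}-X"
        if wild in self.angles:
            return self.angles[wild]
        raise MissingParameterError(f"no angle parameters for {key}")

    def dihedral_terms(self, key: str) -> list[tuple[float, int, float]] | None:
        """Fourier terms or None when the torsion is untabulated (treated V=0)."""
        if key in self.dihedrals:
            return self.dihedrals[key]
        _, b, c, _ = key.split("-")
        for wild in (f"X-{b}-{c}-X", f"X-{c}-{b}-X"):
            if wild in self.dihedrals:
                return self.dihedrals[wild]
        return None


@dataclass
class DipoleParams:
    """Permanent magnitudes μ0, reference charges q0 and correction factor c.

    ``induced_enabled`` switches the δμ = c(q−q0)d response per bond key;
    the shipped default polarizes O–H and C–H bonds but not C–O.
    ``site_fraction`` places the point dipole along the bond (0 = negative
    end, 1 = positive end, default midpoint).
    """

    mu0: dict[str, float] = field(default_factory=dict)
    axis_sign: dict[str, float] = field(default_factory=dict)
    induced_enabled: dict[str, bool] = field(default_factory=dict)
    q0: dict[str, float] = field(default_factory=dict)
    c: float = 0.0
    site_fraction: float = 0.5

    def validate(self) -> None:
        for key, mu in self.mu0.items():
            if mu < 0:
                raise ParameterError(f"dipole.mu0.{key}: must be >= 0")
        for key, s in self.axis_sign.items():
            if s not in (-1.0, 1.0):
                raise ParameterError(f"dipole.axis_sign.{key}: must be +1 or -1")
        if not (0.0 <= self.site_fraction <= 1.0):
            raise ParameterError("dipole.site_fraction: must be in [0, 1]")

    def q0_for(self, atom_type: str) -> float:
        try:
            return self.q0[atom_type]
        except KeyError:
            raise MissingParameterError(f"no q0 for atom type {atom_type}") from None


@dataclass
class VdwParams:
    """Per-type (ε kcal·mol⁻¹, Rmin Å); combined on demand to A₁₂/B₆."""

    epsilon: dict[str, float] = field(default_factory=dict)
    rmin: dict[str, float] = field(default_factory=dict)
    combining_rule: str = "lorentz-berthelot"

    def validate(self) -> None:
        if self.combining_rule not in ("lorentz-berthelot", "geometric"):
            raise ParameterError(f"vdw.combining_rule: unknown {self.combining_rule!r}")
        for t, eps in self.epsilon.items():
            if eps < 0:
                raise ParameterError(f"vdw.epsilon.{t}: must be >= 0")
        for t, r in self.rmin.items():
            if r <= 0:
                raise ParameterError(f"vdw.rmin.{t}: must be > 0")
        if set(self.epsilon) != set(self.rmin):
            raise ParameterError("vdw: epsilon and rmin must cover the same types")


@dataclass
class OrbitalClassParams:
    """Morse-type hydrogen-bond correction for one donor···acceptor class.

    E = D·[exp(−2a(R−R0)) − 2·exp(−a(R−R0))]^p
        · cos(α−α0)·cos(β1−β0)·cos(β2−β0)
    with p odd so the ideal geometry gives −D.  Angles in degrees.
    """

    D: float
    a: float
    R0: float
    alpha0: float
    beta0: float
    p: int = 5

    def validate(self, key: str) -> None:
        if self.D <= 0 or self.a <= 0:
            raise ParameterError(f"orbital.{key}: D and a must be > 0")
        if self.R0 <= 0:
            raise ParameterError(f"orbital.{key}: R0 must be > 0")
        if self.p < 1 or self.p % 2 == 0:
            raise ParameterError(f"orbital.{key}: exponent p must be odd >= 1")


@dataclass
class OrbitalParams:
    classes: dict[str, OrbitalClassParams] = field(default_factory=dict)
    #: donor-O–acceptor-O detection cutoff, Å
    r_cut: float = 3.5
    #: minimal D–H···A angle, degrees
    angle_cut: float = 120.0

    def validate(self) -> None:
        for key, cls in self.classes.items():
            if key not in HB_CLASSES:
                raise ParameterError(f"orbital: unknown hydrogen-bond class {key!r}")
            cls.validate(key)
        if self.r_cut <= 0:
            raise ParameterError("orbital.r_cut: must be > 0")

    def for_class(self, key: str) -> OrbitalClassParams:
        try:
            return self.classes[key]
        except KeyError:
            raise MissingParameterError(f"no orbital parameters for class {key}") from None


@dataclass
class ScalingParams:
    elec_min_bond_path: int = 3
    vdw14_scale: float = 0.5

    def validate(self) -> None:
        if self.elec_min_bond_path < 1:
            raise ParameterError("scaling.elec_min_bond_path: must be >= 1")


@dataclass
class ParameterSet:
    bonded: BondedParams
    dipole: DipoleParams
    vdw: VdwParams
    orbital: OrbitalParams
    scaling: ScalingParams = field(default_factory=ScalingParams)
    k_dd: float = K_DD
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.k_dd <= 0:
            raise ParameterError("k_dd must be > 0")
        self.bonded.validate()
        self.dipole.validate()
        self.vdw.validate()
        self.orbital.validate()
        self.scaling.validate()


def combine_vdw(type_i: str, type_j: str, vdw: VdwParams) -> tuple[float, float]:
    """(A_ij, B_ij) for the 12-6 pair potential A/R¹² − B/R⁶.

    Lorentz–Berthelot by default: ε_ij = √(ε_i ε_j),
    Rmin_ij = (Rmin_i + Rmin_j)/2; then A = ε·Rmin¹², B = 2ε·Rmin⁶.
    The geometric rule replaces the radius mean by √(Rmin_i·Rmin_j).
    """
    for t in (type_i, type_j):
        if t not in vdw.epsilon:
            raise MissingParameterError(f"no vdW parameters for atom type {t}")
    eps = math.sqrt(vdw.epsilon[type_i] * vdw.epsilon[type_j])
    if vdw.combining_rule == "geometric":
        rmin = math.sqrt(vdw.rmin[type_i] * vdw.rmin[type_j])
    else:
        rmin = 0.5 * (vdw.rmin[type_i] + vdw.rmin[type_j])
    a = eps * rmin**12
    b = 2.0 * eps * rmin**6
    return a, b


# ---------------------------------------------------------------------------
# JSON serialization

_SCHEMA_VERSION = 1
_TOP_KEYS = {"meta", "bonded", "dipole", "vdw", "orbital", "scaling", "k_dd"}


def _to_dict(ps: ParameterSet) -> dict:
    return {
        "meta": {"schema_version": _SCHEMA_VERSION, **ps.meta},
        "bonded": {
            "bonds": {k: list(v) for k, v in ps.bonded.bonds.items()},
            "angles": {k: list(v) for k, v in ps.bonded.angles.items()},
            "dihedrals": {
                k: [list(t) for t in v] for k, v in ps.bonded.dihedrals.items()
            },
        },
        "dipole": {
            "mu0": ps.dipole.mu0,
            "axis_sign": ps.dipole.axis_sign,
            "induced_enabled": ps.dipole.induced_enabled,
            "q0": ps.dipole.q0,
            "c": ps.dipole.c,
            "site_fraction": ps.dipole.site_fraction,
        },
        "vdw": {
            "epsilon": ps.vdw.epsilon,
            "rmin": ps.vdw.rmin,
            "combining_rule": ps.vdw.combining_rule,
        },
        "orbital": {
            "classes": {
                k: {
                    "D": c.D,
                    "a": c.a,
                    "R0": c.R0,
                    "alpha0": c.alpha0,
                    "beta0": c.beta0,
                    "p": c.p,
                }
                for k, c in ps.orbital.classes.items()
            },
            "r_cut": ps.orbital.r_cut,
            "angle_cut": ps.orbital.angle_cut,
        },
        "scaling": {
            "elec_min_bond_path": ps.scaling.elec_min_bond_path,
            "vdw14_scale": ps.scaling.vdw14_scale,
        },
        "k_dd": ps.k_dd,
    }


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ParameterError(f"{where}: missing mandatory block {key!r}")
    return d[key]


def _from_dict(data: dict) -> ParameterSet:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ParameterError(f"unknown top-level keys: {sorted(unknown)}")
    meta = dict(data.get("meta", {}))
    version = meta.pop("schema_version", _SCHEMA_VERSION)
    if version != _SCHEMA_VERSION:
        raise ParameterError(f"unsupported schema_version {version}")

    braw = _require(data, "bonded", "parameters")
    bonded = BondedParams(
        bonds={_canon_pair(k): (float(v[0]), float(v[1]))
               for k, v in braw.get("bonds", {}).items()},
        angles={_canon_triple(k): (float(v[0]), float(v[1]))
                for k, v in braw.get("angles", {}).items()},
        dihedrals={
            _canon_quad(k): [(float(t[0]), int(t[1]), float(t[2])) for t in v]
            for k, v in braw.get("dihedrals", {}).items()
        },
    )
    draw = _require(data, "dipole", "parameters")
    dipole = DipoleParams(
        mu0={_canon_pair(k): float(v) for k, v in draw.get("mu0", {}).items()},
        axis_sign={_canon_pair(k): float(v)
                   for k, v in draw.get("axis_sign", {}).items()},
        induced_enabled={_canon_pair(k): bool(v)
                         for k, v in draw.get("induced_enabled", {}).items()},
        q0={k: float(v) for k, v in draw.get("q0", {}).items()},
        c=float(draw.get("c", 0.0)),
        site_fraction=float(draw.get("site_fraction", 0.5)),
    )
    vraw = _require(data, "vdw", "parameters")
    vdw = VdwParams(
        epsilon={k: float(v) for k, v in vraw.get("epsilon", {}).items()},
        rmin={k: float(v) for k, v in vraw.get("rmin", {}).items()},
        combining_rule=vraw.get("combining_rule", "lorentz-berthelot"),
    )
    oraw = data.get("orbital", {"classes": {}})
    orbital = OrbitalParams(
        classes={
            k: OrbitalClassParams(
                D=float(c["D"]), a=float(c["a"]), R0=float(c["R0"]),
                alpha0=float(c["alpha0"]), beta0=float(c["beta0"]),
                p=int(c.get("p", 5)),
            )
            for k, c in oraw.get("classes", {}).items()
        },
        r_cut=float(oraw.get("r_cut", 3.5)),
        angle_cut=float(oraw.get("angle_cut", 120.0)),
    )
    sraw = data.get("scaling", {})
    scaling = ScalingParams(
        elec_min_bond_path=int(sraw.get("elec_min_bond_path", 3)),
        vdw14_scale=float(sraw.get("vdw14_scale", 0.5)),
    )
    ps = ParameterSet(
        bonded=bonded, dipole=dipole, vdw=vdw, orbital=orbital,
        scaling=scaling, k_dd=float(data.get("k_dd", K_DD)), meta=meta,
    )
    ps.validate()
    return ps


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a JSON parameter file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParameterError(f"{path}: not valid JSON ({exc})") from exc
    return _from_dict(data)


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    ps.validate()
    with open(path, "w") as fh:
        json.dump(_to_dict(ps), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# shipped placeholder set


def default_parameters() -> ParameterSet:
    """Placeholder parameter set for water + pyranose carbohydrates.

    Bonded constants follow GLYCAM06-style magnitudes; the permanent bond
    dipoles are physically plausible bond moments (O–H ≈ 1.5 D, C–O ≈ 0.9 D,
    C–H ≈ 0.35 D); q0(HO) is the published AM1 reference of 0.2142 e, the
    remaining q0 values are representative AM1-scale charges.  The orbital
    well depths/ranges are textbook hydrogen-bond scales.  These values are
    a self-consistent *working* set for development, fixtures and property
    tests — they are not a refit of the published appendix tables, which can
    be imported through the same JSON schema when available.
    """
    bonded = BondedParams(
        bonds={
            "CT-CT": (310.0, 1.520),
            "CT-OS": (285.0, 1.410),
            "CT-OH": (320.0, 1.410),
            "OH-HO": (553.0, 0.960),
            "CT-H1": (340.0, 1.092),
            "CT-H2": (340.0, 1.092),
            "OW-HW": (553.0, 0.9572),
        },
        angles={
            "HW-OW-HW": (100.0, 104.52),
            "CT-OS-CT": (62.0, 113.8),
            "CT-OH-HO": (55.0, 107.3),
            "X-CT-X": (50.0, 109.5),
        },
        dihedrals={
            # representative refit torsions plus a generic sp3-sp3 background
            "CT-CT-CT-OS": [(0.16, 3, 0.0)],
            "OS-CT-CT-OS": [(0.82, 2, 0.0), (0.10, 3, 0.0)],
            "OH-CT-CT-OS": [(0.75, 2, 0.0), (0.14, 3, 0.0)],
            "CT-OS-CT-H2": [(0.0, 3, 0.0)],
            "X-CT-CT-X": [(0.156, 3, 0.0)],
            "X-CT-OS-X": [(0.30, 3, 0.0)],
            "X-CT-OH-X": [(0.18, 3, 0.0)],
        },
    )
    dipole = DipoleParams(
        mu0={
            "CT-OS": 0.90,
            "CT-OH": 0.95,
            "OH-HO": 1.52,
            "CT-H1": 0.30,
            "CT-H2": 0.35,
            "OW-HW": 1.515,
        },
        axis_sign={},
        induced_enabled={
            "OH-HO": True,
            "CT-H1": True,
            "CT-H2": True,
            "OW-HW": True,
            "CT-OS": False,
            "CT-OH": False,
        },
        q0={
            "HO": 0.2142,
            "H1": 0.085,
            "H2": 0.110,
            "HW": 0.191,
            "CT": 0.050,
            "OW": -0.382,
            "OH": -0.330,
            "OS": -0.290,
        },
        c=0.8,
    )
    vdw = VdwParams(
        epsilon={
            "CT": 0.1094,
            "OS": 0.1700,
            "OH": 0.2104,
            "HO": 0.0000,
            "H1": 0.0157,
            "H2": 0.0157,
            "OW": 0.1520,
            "HW": 0.0000,
        },
        rmin={
            "CT": 3.816,
            "OS": 3.367,
            "OH": 3.442,
            "HO": 1.200,
            "H1": 2.774,
            "H2": 2.574,
            "OW": 3.5364,
            "HW": 1.200,
        },
    )
    orbital = OrbitalParams(
        classes={
            "OW-HW...OW": OrbitalClassParams(
                D=1.20, a=2.0, R0=2.90, alpha0=180.0, beta0=109.5, p=5),
            "OH-HO...OW": OrbitalClassParams(
                D=1.30, a=2.0, R0=2.85, alpha0=180.0, beta0=109.5, p=5),
            "OW-HW...OH": OrbitalClassParams(
                D=1.25, a=2.0, R0=2.88, alpha0=180.0, beta0=109.5, p=5),
            "OW-HW...OS": OrbitalClassParams(
                D=1.00, a=2.0, R0=2.95, alpha0=180.0, beta0=109.5, p=5),
        },
    )
    ps = ParameterSet(
        bonded=bonded,
        dipole=dipole,
        vdw=vdw,
        orbital=orbital,
        meta={"name": "pbdp-placeholder", "provenance": "synthetic working set"},
    )
    ps.validate()
    return ps
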