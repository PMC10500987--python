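"""Per-window topology emission in a constrained GROMACS dialect.

An EVB window simulated at fixed lambda needs a topology whose bonded
and charge parameters realize that window's mapping potential.  Two
conventions are combined, both stated in the emitted file headers:

* interactions present in both end states (charges, harmonic bonds,
  angles, periodic dihedrals, shared Morse bonds) are interpolated
  parameter by parameter, ``p(lam) = (1-lam) p_RS + lam p_PS``;
* interactions present in only one state — breaking/forming Morse bonds
  and the soft exponential repulsions that replace their 6-12 terms —
  are emitted as tabulated bonds (GROMACS funct 9) whose per-window
  scale factor is that state's weight, ``1-lam`` for reactant-only and
  ``lam`` for product-only terms, so the bonded part of the mapping
  potential is realized exactly.

Only a single-molecule dialect is supported: harmonic bonds (funct 1),
Morse bonds (funct 3), tabulated bonds (funct 9), harmonic angles,
periodic dihedrals, pairs and exclusions.  Preprocessor macros,
``#include`` lines, virtual sites etc. are rejected loudly.  Files use
GROMACS units (nm, kJ/mol, 1-based indices); in-memory parameters are
Angstrom and kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import KJ_PER_KCAL, MorseParams, SoftRepulsionParams
from .fep import LambdaSchedule

__all__ = [
    "Atom", "HarmonicBond", "MorseBond", "TabulatedBond", "Angle",
    "Dihedral", "SoftPair", "TopologySubset", "TopologyError",
    "write_lambda_topologies", "write_tabulated_bond", "parse_topology",
]

_KJNM2_PER_KCALA2 = KJ_PER_KCAL * 100.0   # kcal/mol/A^2 -> kJ/mol/nm^2
_NM_PER_A = 0.1


class TopologyError(ValueError):
    """Unsupported construct or inconsistent reactant/product inputs."""


@dataclass(frozen=True)
class Atom:
    name: str
    type: str
    charge: float
    residue: str = "MOL"


@dataclass(frozen=True)
class HarmonicBond:
    ai: int
    aj: int
    b0: float    # A
    k: float     # kcal/mol/A^2


@dataclass(frozen=True)
class MorseBond:
    ai: int
    aj: int
    params: MorseParams   # D kcal/mol, a 1/A, r_eq A


@dataclass(frozen=True)
class TabulatedBond:
    ai: int
    aj: int
    table: int
    scale: float


@dataclass(frozen=True)
class Angle:
    ai: int
    aj: int
    ak: int
    theta0: float   # degrees
    k_theta: float  # kcal/mol/rad^2


@dataclass(frozen=True)
class Dihedral:
    ai: int
    aj: int
    ak: int
    al: int
    phase: float    # degrees
    k_phi: float    # kcal/mol
    mult: int


@dataclass(frozen=True)
class SoftPair:
    """Soft exponential repulsion between a reacting atom pair."""

    ai: int
    aj: int
    params: SoftRepulsionParams   # C kcal/mol, beta_rep 1/A


@dataclass
class TopologySubset:
    """One molecule block of the constrained dialect (1-based indices)."""

    name: str = "MOL"
    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)            # HarmonicBond
    morse_bonds: list = field(default_factory=list)      # MorseBond
    tabulated_bonds: list = field(default_factory=list)  # TabulatedBond
    soft_pairs: list = field(default_factory=list)       # SoftPair
    angles: list = field(default_factory=list)
    dihedrals: list = field(default_factory=list)
    pairs: list = field(default_factory=list)            # (ai, aj)
    exclusions: list = field(default_factory=list)       # (ai, [aj, ...])

    def validate(self) -> None:
        n = len(self.atoms)
        def chk(i, what):
            if not 1 <= i <= n:
                raise TopologyError(f"{what}: atom index {i} outside 1..{n}")
        for b in self.bonds + self.morse_bonds + self.tabulated_bonds:
            chk(b.ai, "bond"); chk(b.aj, "bond")
        for a in self.angles:
            chk(a.ai, "angle"); chk(a.aj, "angle"); chk(a.ak, "angle")
        for d in self.dihedrals:
            for i in (d.ai, d.aj, d.ak, d.al):
                chk(i, "dihedral")
        bonded = {frozenset((b.ai, b.aj))
                  for b in self.bonds + self.morse_bonds + self.tabulated_bonds}
        for sp in self.soft_pairs:
            chk(sp.ai, "soft pair"); chk(sp.aj, "soft pair")
        for ai, js in self.exclusions:
            chk(ai, "exclusion")
            for j in js:
                chk(j, "exclusion")
        # every directly bonded pair must be excluded from nonbonded lists
        excl = {(a, j) for a, js in self.exclusions for j in js}
        for pair in bonded:
            i, j = sorted(pair)
            if (i, j) not in excl and (j, i) not in excl:
                warnings.warn(f"bonded pair {i}-{j} missing from exclusions")


def _lerp(a: float, b: float, lam: float) -> float:
    return (1.0 - lam) * a + lam * b


def write_tabulated_bond(potential, grid: tuple, scale: float, path) -> None:
    """Write a GROMACS type-9 bond table for a Morse or soft-repulsion
    potential: columns r (nm), energy (kJ/mol), force -dE/dr (kJ/mol/nm),
    all pre-multiplied by ``scale``.

    ``grid = (r_min, r_max, spacing)`` in nm; Morse requires r_min > 0.
    """
    r_min, r_max, spacing = grid
    if spacing <= 0 or r_max <= r_min:
        raise ValueError("grid must satisfy r_max > r_min and spacing > 0")
    r_nm = np.arange(r_min, r_max + 0.5 * spacing, spacing)
    r_a = r_nm / _NM_PER_A
    if isinstance(potential, MorseParams):
        if r_min <= 0:
            raise ValueError("Morse table requires r_min > 0")
        u = np.exp(-potential.a * (r_a - potential.r_eq))
        e_kcal = potential.D * (1.0 - u) ** 2
        de_dra = 2.0 * potential.D * potential.a * u * (1.0 - u)
    elif isinstance(potential, SoftRepulsionParams):
        e_kcal = potential.C * np.exp(-potential.beta_rep * r_a)
        de_dra = -potential.beta_rep * e_kcal
    else:
        raise TypeError(f"cannot tabulate {type(potential).__name__}")
    e = scale * e_kcal * KJ_PER_KCAL
    f = -scale * de_dra * KJ_PER_KCAL / _NM_PER_A    # -dE/dr in kJ/mol/nm
    lines = ["# evbkit tabulated bond: r(nm) E(kJ/mol) -dE/dr(kJ/mol/nm)"]
    for ri, ei, fi in zip(r_nm, e, f):
        lines.append(f"{ri:.6f} {ei:.10e} {fi:.10e}")
    Path(path).write_text("\n".join(lines) + "\n")


def _keyed(items, key):
    out = {}
    for it in items:
        k = key(it)
        if k in out:
            raise TopologyError(f"duplicate interaction {k}")
        out[k] = it
    return out


def _bond_key(b):
    return tuple(sorted((b.ai, b.aj)))


def _angle_key(a):
    return (a.ai, a.aj, a.ak) if a.ai < a.ak else (a.ak, a.aj, a.ai)


def _dih_key(d):
    fwd = (d.ai, d.aj, d.ak, d.al)
    return min(fwd, fwd[::-1]) + (d.mult,)


def _collect_tables(rs: TopologySubset, ps: TopologySubset):
    """Unique one-state potentials -> table ids (deterministic order)."""
    tables = []
    def tid(pot):
        for i, p in enumerate(tables):
            if p == pot:
                return i + 1
        tables.append(pot)
        return len(tables)
    plan = []   # (ai, aj, table id, state) with state "rs"|"ps"|"both"
    rs_m = _keyed(rs.morse_bonds, _bond_key)
    ps_m = _keyed(ps.morse_bonds, _bond_key)
    rs_h = _keyed(rs.bonds, _bond_key)
    ps_h = _keyed(ps.bonds, _bond_key)
    for k in sorted(set(rs_h) | set(ps_h)):
        if k in rs_m or k in ps_m:
            raise TopologyError(
                f"bond {k} has different functional forms in the two states")
        if (k in rs_h) != (k in ps_h):
            raise TopologyError(
                f"harmonic bond {k} exists in only one state; model the "
                "breaking/forming bond as Morse")
    for k in sorted(set(rs_m) | set(ps_m)):
        if k in rs_m and k in ps_m:
            plan.append((k, None, "both"))
        elif k in rs_m:
            plan.append((k, tid(rs_m[k].params), "rs"))
        else:
            plan.append((k, tid(ps_m[k].params), "ps"))
    rs_s = _keyed(rs.soft_pairs, _bond_key)
    ps_s = _keyed(ps.soft_pairs, _bond_key)
    for k in sorted(set(rs_s) | set(ps_s)):
        if k in rs_s and k in ps_s:
            if rs_s[k].params != ps_s[k].params:
                raise TopologyError(
                    f"soft pair {k} differs between states; not supported")
            plan.append((k, tid(rs_s[k].params), "both-soft"))
        elif k in rs_s:
            plan.append((k, tid(rs_s[k].params), "rs-soft"))
        else:
            plan.append((k, tid(ps_s[k].params), "ps-soft"))
    return tables, plan


def _interpolated_topology(rs: TopologySubset, ps: TopologySubset, lam: float,
                           plan) -> TopologySubset:
    """One window's topology under the stated conventions; zero-weight
    interactions are dropped so the endpoints reproduce rs / ps exactly."""
    atoms = [replace(a, charge=_lerp(a.charge, b.charge, lam))
             for a, b in zip(rs.atoms, ps.atoms)]
    rs_h = _keyed(rs.bonds, _bond_key)
    ps_h = _keyed(ps.bonds, _bond_key)
    bonds = [HarmonicBond(*k, b0=_lerp(rs_h[k].b0, ps_h[k].b0, lam),
                          k=_lerp(rs_h[k].k, ps_h[k].k, lam))
             for k in sorted(rs_h)]

    rs_m = _keyed(rs.morse_bonds, _bond_key)
    ps_m = _keyed(ps.morse_bonds, _bond_key)
    morse, tab = [], []
    for k, table, state in plan:
        if state == "both":
            p1, p2 = rs_m[k].params, ps_m[k].params
            morse.append(MorseBond(*k, params=MorseParams(
                D=_lerp(p1.D, p2.D, lam), a=_lerp(p1.a, p2.a, lam),
                r_eq=_lerp(p1.r_eq, p2.r_eq, lam))))
            continue
        w = {"rs": 1.0 - lam, "ps": lam, "rs-soft": 1.0 - lam,
             "ps-soft": lam, "both-soft": 1.0}[state]
        if w > 0.0:
            tab.append(TabulatedBond(*k, table=table, scale=w))

    def merge(rs_items, ps_items, key, make):
        rs_d, ps_d = _keyed(rs_items, key), _keyed(ps_items, key)
        out = []
        for k in sorted(set(rs_d) | set(ps_d)):
            a, b = rs_d.get(k), ps_d.get(k)
            if a is not None and b is not None:
                out.append(make(k, a, b, lam))
            else:
                one, w = (a, 1.0 - lam) if a is not None else (b, lam)
                scaled = make(k, one, one, 0.0)
                scaled = _scale_force(scaled, w)
                if w > 0.0:
                    out.append(scaled)
        return out

    angles = merge(rs.angles, ps.angles, _angle_key,
                   lambda k, a, b, t: Angle(a.ai, a.aj, a.ak,
                                            theta0=_lerp(a.theta0, b.theta0, t),
                                            k_theta=_lerp(a.k_theta, b.k_theta, t)))
    dihedrals = merge(rs.dihedrals, ps.dihedrals, _dih_key,
                      lambda k, a, b, t: Dihedral(a.ai, a.aj, a.ak, a.al,
                                                  phase=a.phase, mult=a.mult,
                                                  k_phi=_lerp(a.k_phi, b.k_phi, t)))
    pairs = sorted({tuple(sorted(p)) for p in rs.pairs} |
                   {tuple(sorted(p)) for p in ps.pairs})
    excl = {}
    for src in (rs.exclusions, ps.exclusions):
        for ai, js in src:
            excl.setdefault(ai, set()).update(js)
    exclusions = [(ai, sorted(js)) for ai, js in sorted(excl.items())]
    return TopologySubset(name=rs.name, atoms=atoms, bonds=bonds,
                          morse_bonds=morse, tabulated_bonds=tab,
                          soft_pairs=[], angles=angles, dihedrals=dihedrals,
                          pairs=pairs, exclusions=exclusions)


def _scale_force(item, w):
    if isinstance(item, Angle):
        return replace(item, k_theta=item.k_theta * w)
    return replace(item, k_phi=item.k_phi * w)


def write_lambda_topologies(rs: TopologySubset, ps: TopologySubset,
                            schedule: LambdaSchedule, out_dir,
                            table_grid: tuple = (0.002, 1.0, 0.002)) -> dict:
    """Emit one topology per lambda window plus shared bond tables.

    Returns ``{"topologies": [paths...], "tables": [paths...]}``.  The
    reactant and product inputs must share the atom list (names/types);
    interactions are matched by index tuples.  Tables are written once
    at unit scale; per-window weights go on the tabulated-bond lines.
    """
    if len(rs.atoms) != len(ps.atoms) or any(
            (a.name, a.type) != (b.name, b.type)
            for a, b in zip(rs.atoms, ps.atoms)):
        raise TopologyError("reactant/product topologies must share the atom list")
    rs.validate()
    ps.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tables, plan = _collect_tables(rs, ps)
    table_paths = []
    for i, pot in enumerate(tables, start=1):
        path = out_dir / f"table_b{i}.xvg"
        grid = table_grid
        if isinstance(pot, SoftRepulsionParams) and grid[0] > 0:
            grid = (0.0, grid[1], grid[2])   # repulsion is finite at contact
        write_tabulated_bond(pot, grid, 1.0, path)
        table_paths.append(str(path))

    topo_paths = []
    for m, lam in enumerate(schedule):
        topo = _interpolated_topology(rs, ps, float(lam), plan)
        path = out_dir / f"topol_w{m:03d}.top"
        _write_topology(topo, float(lam), path)
        topo_paths.append(str(path))
    return {"topologies": topo_paths, "tables": table_paths}


def _write_topology(t: TopologySubset, lam: float, path) -> None:
    w = []
    w.append("; evbkit per-window topology (constrained dialect)")
    w.append(f"; lambda = {lam:.6f}")
    w.append("; shared interactions: parameters linearly interpolated in lambda")
    w.append("; one-state bonds/repulsions: funct-9 tables weighted by state")
    w.append("")
    w.append("[ moleculetype ]")
    w.append("; name  nrexcl")
    w.append(f"{t.name}  3")
    w.append("")
    w.append("[ atoms ]")
    w.append(";   nr  type      resnr residue atom   cgnr       charge")
    for i, a in enumerate(t.atoms, start=1):
        w.append(f"{i:6d}  {a.type:<8s} {1:5d} {a.residue:<7s} {a.name:<6s} "
                 f"{i:4d} {a.charge:12.6f}")
    w.append("")
    w.append("[ bonds ]")
    w.append(";  ai  aj funct  parameters")
    for b in t.bonds:
        w.append(f"{b.ai:5d} {b.aj:5d} {1:5d} {b.b0 * _NM_PER_A:.9f} "
                 f"{b.k * _KJNM2_PER_KCALA2:.6f}")
    for b in t.morse_bonds:
        p = b.params
        w.append(f"{b.ai:5d} {b.aj:5d} {3:5d} {p.r_eq * _NM_PER_A:.9f} "
                 f"{p.D * KJ_PER_KCAL:.6f} {p.a / _NM_PER_A:.6f}")
    for b in t.tabulated_bonds:
        w.append(f"{b.ai:5d} {b.aj:5d} {9:5d} {b.table:d} {b.scale:.9f}")
    w.append("")
    w.append("[ angles ]")
    w.append(";  ai  aj  ak funct  theta0(deg)  k(kJ/mol/rad2)")
    for a in t.angles:
        w.append(f"{a.ai:5d} {a.aj:5d} {a.ak:5d} {1:5d} {a.theta0:.6f} "
                 f"{a.k_theta * KJ_PER_KCAL:.6f}")
    w.append("")
    w.append("[ dihedrals ]")
    w.append(";  ai  aj  ak  al funct  phase(deg)  k(kJ/mol)  mult")
    for d in t.dihedrals:
        w.append(f"{d.ai:5d} {d.aj:5d} {d.ak:5d} {d.al:5d} {9:5d} "
                 f"{d.phase:.6f} {d.k_phi * KJ_PER_KCAL:.6f} {d.mult:d}")
    w.append("")
    w.append("[ pairs ]")
    for i, j in t.pairs:
        w.append(f"{i:5d} {j:5d} {1:5d}")
    w.append("")
    w.append("[ exclusions ]")
    for ai, js in t.exclusions:
        w.append(f"{ai:5d} " + " ".join(f"{j:d}" for j in js))
    Path(path).write_text("\n".join(w) + "\n")


def parse_topology(path) -> TopologySubset:
    """Re-parse a file of the constrained dialect (validation path).

    Anything outside the dialect — preprocessor lines, multiple molecule
    blocks, unknown functs — raises :class:`TopologyError`.
    """
    t = TopologySubset()
    section = None
    seen_moltype = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            raise TopologyError(
                f"{path}:{lineno}: preprocessor directives are not supported")
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        cells = line.split()
        try:
            if section == "moleculetype":
                if seen_moltype:
                    raise TopologyError(
                        f"{path}:{lineno}: only one molecule block supported")
                t.name = cells[0]
                seen_moltype = True
            elif section == "atoms":
                t.atoms.append(Atom(name=cells[4], type=cells[1],
                                    charge=float(cells[6]), residue=cells[3]))
            elif section == "bonds":
                ai, aj, funct = int(cells[0]), int(cells[1]), int(cells[2])
                if funct == 1:
                    t.bonds.append(HarmonicBond(
                        ai, aj, b0=float(cells[3]) / _NM_PER_A,
                        k=float(cells[4]) / _KJNM2_PER_KCALA2))
                elif funct == 3:
                    t.morse_bonds.append(MorseBond(ai, aj, MorseParams(
                        r_eq=float(cells[3]) / _NM_PER_A,
                        D=float(cells[4]) / KJ_PER_KCAL,
                        a=float(cells[5]) * _NM_PER_A)))
                elif funct == 9:
                    t.tabulated_bonds.append(TabulatedBond(
                        ai, aj, table=int(cells[3]), scale=float(cells[4])))
                else:
                    raise TopologyError(
                        f"{path}:{lineno}: bond funct {funct} not in dialect")
            elif section == "angles":
                if int(cells[3]) != 1:
                    raise TopologyError(f"{path}:{lineno}: angle funct must be 1")
                t.angles.append(Angle(int(cells[0]), int(cells[1]), int(cells[2]),
                                      theta0=float(cells[4]),
                                      k_theta=float(cells[5]) / KJ_PER_KCAL))
            elif section == "dihedrals":
                if int(cells[4]) != 9:
                    raise TopologyError(f"{path}:{lineno}: dihedral funct must be 9")
                t.dihedrals.append(Dihedral(
                    int(cells[0]), int(cells[1]), int(cells[2]), int(cells[3]),
                    phase=float(cells[5]), k_phi=float(cells[6]) / KJ_PER_KCAL,
                    mult=int(cells[7])))
            elif section == "pairs":
                t.pairs.append((int(cells[0]), int(cells[1])))
            elif section == "exclusions":
                t.exclusions.append((int(cells[0]), [int(c) for c in cells[1:]]))
            else:
                raise TopologyError(
                    f"{path}:{lineno}: section [{section}] not in dialect")
        except (IndexError, ValueError) as err:
            raise TopologyError(f"{path}:{lineno}: malformed line: {err}") from err
    t.validate()
    return t
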