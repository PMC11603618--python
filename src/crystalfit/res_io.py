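"""SHELX ``.res`` crystal files and the training-set manifest.

A ``.res`` file carries geometry only: cell, symmetry (LATT centering code
and SYMM cards), and fractional atom records.  Charges, force-field atom
types, the rigid-molecule partition, reference intermolecular energies and
merit-function weights are not part of the format, so a training set is a
YAML *manifest* that points at the ``.res`` files and supplies the rest.

Reading a bare ``.res`` yields a :class:`~.crystal.Crystal` whose
asymmetric unit is a single rigid "molecule" containing every atom (zero
charges, atom types equal to the elements); the manifest loader re-applies
the declared molecule partition, charges and types.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml

from .crystal import (
    Crystal,
    CrystalSystem,
    Lattice,
    RigidMolecule,
    SymmetryOp,
    cell_matrix,
)
from .errors import ConsistencyError, NeutralityError, ParseError
from .residuals import ReferenceEntry, asym_fractional_coords

__all__ = [
    "ManifestEntry",
    "read_res",
    "write_res",
    "read_manifest",
    "write_manifest",
    "infer_crystal_system",
    "parse_symm",
    "format_symm",
]

# LATT centering translations (|code|): P, I, R(obverse), F, A, B, C
_CENTERING = {
    1: [(0, 0, 0)],
    2: [(0, 0, 0), (0.5, 0.5, 0.5)],
    3: [(0, 0, 0), (2 / 3, 1 / 3, 1 / 3), (1 / 3, 2 / 3, 2 / 3)],
    4: [(0, 0, 0), (0, 0.5, 0.5), (0.5, 0, 0.5), (0.5, 0.5, 0)],
    5: [(0, 0, 0), (0, 0.5, 0.5)],
    6: [(0, 0, 0), (0.5, 0, 0.5)],
    7: [(0, 0, 0), (0.5, 0.5, 0)],
}

_KEYWORDS = {
    "TITL", "CELL", "ZERR", "LATT", "SYMM", "SFAC", "UNIT", "NEUT",
    "DISP", "L.S.", "PLAN", "TEMP", "WGHT", "FVAR", "BOND", "CONF",
    "ACTA", "LIST", "SIZE", "OMIT", "AFIX", "PART", "MORE", "REM",
    "END", "HKLF", "ABIN", "ANIS", "EQIV",
}

_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG",
    "AL", "SI", "P", "S", "CL", "AR", "K", "CA", "BR", "I", "FE", "ZN",
}


# ---------------------------------------------------------------------------
# symmetry-operator strings
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"\s*([+-]?)\s*(?:(\d+(?:\.\d+)?(?:/\d+)?)\s*\*?\s*)?([XYZ])?", re.I
)


def parse_symm(text: str) -> SymmetryOp:
    """Parse a SYMM card such as ``-X, 1/2+Y, 1/2-Z``."""
    parts = text.upper().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ParseError(f"bad SYMM record: {text!r}")
    R = np.zeros((3, 3), dtype=int)
    t = np.zeros(3)
    axis = {"X": 0, "Y": 1, "Z": 2}
    for row, part in enumerate(parts):
        pos = 0
        matched = False
        while pos < len(part):
            m = _TERM_RE.match(part, pos)
            if not m or m.end() == pos:
                raise ParseError(f"bad SYMM term in {text!r}")
            sign = -1 if m.group(1) == "-" else 1
            num, var = m.group(2), m.group(3)
            if var is not None:
                coeff = sign * (int(float(num)) if num else 1)
                R[row, axis[var]] += coeff
            elif num is not None:
                t[row] += sign * float(Fraction(num))
            pos = m.end()
            matched = True
        if not matched:
            raise ParseError(f"empty SYMM component in {text!r}")
    return SymmetryOp.create(R, t)


def format_symm(op: SymmetryOp) -> str:
    """Inverse of :func:`parse_symm` (canonical form, e.g. ``-X,1/2+Y,-Z``)."""
    names = "XYZ"
    parts = []
    for row in range(3):
        s = ""
        tr = Fraction(op.t[row]).limit_denominator(12)
        if tr:
            s += str(tr)
        for col in range(3):
            c = op.rotation[row][col]
            if c == 0:
                continue
            s += ("+" if c > 0 and s else "-" if c < 0 else "") + (
                "" if abs(c) == 1 else str(abs(c))
            ) + names[col]
        parts.append(s)
    return ",".join(parts)


# ---------------------------------------------------------------------------
# .res reading
# ---------------------------------------------------------------------------


@dataclass
class _RawRes:
    label: str
    cell: np.ndarray  # a b c alpha beta gamma
    ops: list
    names: list
    elements: list
    frac: np.ndarray


def _read_res_raw(path) -> _RawRes:
    lines = Path(path).read_text().splitlines()
    label = Path(path).stem
    cell = None
    latt = 1  # SHELX default: primitive, centrosymmetric
    latt_seen = False
    symm_ops = []
    sfac: list[str] = []
    atoms = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("REM"):
            continue
        word = line.split()[0].upper()
        if word == "TITL":
            label = line.split(maxsplit=1)[1].strip() if " " in line else label
        elif word == "CELL":
            vals = line.split()[1:]
            if len(vals) < 7:
                raise ParseError("CELL record needs wavelength + 6 parameters")
            cell = np.array([float(v) for v in vals[1:7]])
        elif word == "LATT":
            latt = int(line.split()[1])
            latt_seen = True
            if abs(latt) not in _CENTERING:
                raise ParseError(f"unknown LATT code {latt}")
        elif word == "SYMM":
            symm_ops.append(parse_symm(line.split(maxsplit=1)[1]))
        elif word == "SFAC":
            sfac.extend(tok.capitalize() for tok in line.split()[1:])
        elif word in _KEYWORDS:
            if word in ("END", "HKLF"):
                break
        else:
            toks = line.split()
            if len(toks) >= 5:
                name = toks[0]
                try:
                    sfac_idx = int(toks[1])
                    xyz = np.array([float(v) for v in toks[2:5]])
                except ValueError:
                    continue  # not an atom record
                if np.any(np.abs(xyz) >= 5.0):
                    raise ParseError(
                        f"atom {name}: coordinates {xyz} look non-fractional "
                        "(fixed-coordinate SHELX dialect not supported)"
                    )
                if 1 <= sfac_idx <= len(sfac):
                    element = sfac[sfac_idx - 1]
                else:
                    m = re.match(r"([A-Za-z]+)", name)
                    element = (m.group(1) if m else name).capitalize()
                    if element.upper() not in _ELEMENTS:
                        element = element[:1]
                atoms.append((name, element, xyz))
    if cell is None:
        raise ParseError(f"{path}: missing CELL record")
    if not atoms:
        raise ParseError(f"{path}: no atom records found")
    if not latt_seen and not symm_ops:
        latt = -1  # bare file: treat as P1
    ops = _expand_latt(latt, symm_ops)
    return _RawRes(
        label=label,
        cell=cell,
        ops=ops,
        names=[a[0] for a in atoms],
        elements=[a[1] for a in atoms],
        frac=np.array([a[2] for a in atoms]),
    )


def _expand_latt(latt: int, symm_ops: list) -> list:
    """Expand LATT centering and centrosymmetry into explicit operators."""
    base = [SymmetryOp.identity()] + list(symm_ops)
    if latt > 0:  # centrosymmetric: add inversion-related operators
        base = base + [
            SymmetryOp.create(-np.asarray(op.rotation), -op.t) for op in base
        ]
    out, seen = [], set()
    for shift in _CENTERING[abs(latt)]:
        for op in base:
            cand = SymmetryOp.create(op.rotation, op.t + np.asarray(shift))
            key = (cand.rotation, tuple(np.round(cand.t, 9)))
            if key not in seen:
                seen.add(key)
                out.append(cand)
    # identity first
    out.sort(key=lambda o: 0 if o.is_identity else 1)
    return out


def infer_crystal_system(cell: np.ndarray, tol: float = 1e-6) -> CrystalSystem:
    """Heuristic assignment from the cell parameters alone."""
    a, b, c, al, be, ga = cell

    def eq(x, y):
        return abs(x - y) <= tol * max(1.0, abs(y))

    right = eq(al, 90) and eq(be, 90) and eq(ga, 90)
    if right and eq(a, b) and eq(b, c):
        return CrystalSystem.CUBIC
    if right and eq(a, b):
        return CrystalSystem.TETRAGONAL
    if eq(al, 90) and eq(be, 90) and eq(ga, 120) and eq(a, b):
        return CrystalSystem.HEXAGONAL
    if right:
        return CrystalSystem.ORTHORHOMBIC
    if eq(al, 90) and eq(ga, 90):
        return CrystalSystem.MONOCLINIC
    return CrystalSystem.TRICLINIC


def read_res(path, crystal_system: CrystalSystem | None = None) -> Crystal:
    """Read a SHELX ``.res`` file (geometry only).

    The returned crystal has one rigid unit containing every asymmetric
    atom, zero charges and element names as atom types; use
    :func:`read_manifest` to attach training-set information.
    """
    raw = _read_res_raw(path)
    system = crystal_system or infer_crystal_system(raw.cell)
    lattice = Lattice(*raw.cell, crystal_system=system)
    mol = _molecule_from_frac(
        lattice, raw.elements, raw.elements, np.zeros(len(raw.elements)), raw.frac
    )
    return Crystal.create(lattice, raw.ops, [mol], label=raw.label)


def _molecule_from_frac(lattice, elements, types, charges, frac) -> RigidMolecule:
    L = cell_matrix(lattice)
    cart = np.asarray(frac) @ L.T
    centroid = cart.mean(axis=0)
    center_frac = np.linalg.inv(L) @ centroid
    return RigidMolecule.create(
        elements, types, cart - centroid, charges, center=center_frac
    )


# ---------------------------------------------------------------------------
# .res writing
# ---------------------------------------------------------------------------


def write_res(crystal: Crystal, path) -> None:
    """Write the asymmetric unit as a SHELX ``.res`` file.

    Symmetry is written explicitly (LATT -1 plus one SYMM card per
    non-identity operator), which survives round trips for any operator
    set regardless of the original centering code.
    """
    lat = crystal.lattice
    lines = [f"TITL {crystal.label or 'crystal'}"]
    lines.append(
        "CELL 0.71073 {:.6f} {:.6f} {:.6f} {:.6f} {:.6f} {:.6f}".format(
            lat.a, lat.b, lat.c, lat.alpha, lat.beta, lat.gamma
        )
    )
    lines.append(f"ZERR {crystal.Z} 0 0 0 0 0 0")
    lines.append("LATT -1")
    for op in crystal.ops:
        if not op.is_identity:
            lines.append(f"SYMM {format_symm(op)}")
    elements = []
    for mol in crystal.asym_unit:
        for el in mol.elements:
            if el not in elements:
                elements.append(el)
    lines.append("SFAC " + " ".join(elements))
    counts = {el: 0 for el in elements}
    for mol in crystal.asym_unit:
        for el in mol.elements:
            counts[el] += 1
    lines.append(
        "UNIT " + " ".join(str(counts[el] * len(crystal.ops)) for el in elements)
    )
    frac = asym_fractional_coords(crystal)
    k = 0
    for mol in crystal.asym_unit:
        for a, el in enumerate(mol.elements):
            lines.append(
                "{:<5s} {:d} {: .6f} {: .6f} {: .6f}".format(
                    f"{el}{k + 1}", elements.index(el) + 1, *frac[k]
                )
            )
            k += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManifestEntry:
    """One training structure as declared in the manifest."""

    label: str
    res_path: str
    charges: tuple
    atom_types: tuple
    molecules: tuple  # tuple of tuples of atom indices (file order)
    u_inter_ref: float
    w_G: float
    w_E: float
    crystal_system: CrystalSystem | None = None


def _entry_from_dict(d: dict, base: Path) -> ManifestEntry:
    try:
        label = str(d["label"])
        res_path = str(d["res"])
        charges = tuple(float(q) for q in d["charges"])
        types = tuple(str(t) for t in d["atom_types"])
        u_ref = float(d["u_inter_ref"])
    except KeyError as exc:
        raise ParseError(f"manifest entry missing key {exc}") from exc
    mols = d.get("molecules")
    mols = (
        tuple(tuple(int(i) for i in m) for m in mols)
        if mols
        else (tuple(range(len(charges))),)
    )
    w_G = float(d.get("w_G", 1.0))
    # polarized hydrogens: energy weight defaults to zero
    w_E = float(d.get("w_E", 0.0 if "Hp" in types else 1.0))
    system = d.get("crystal_system")
    return ManifestEntry(
        label=label,
        res_path=str((base / res_path)),
        charges=charges,
        atom_types=types,
        molecules=mols,
        u_inter_ref=u_ref,
        w_G=w_G,
        w_E=w_E,
        crystal_system=CrystalSystem(system) if system else None,
    )


def read_manifest(path) -> list[tuple[Crystal, ReferenceEntry]]:
    """Load a training set: each entry yields the reference crystal (with
    charges, atom types and molecule partition attached) and its
    :class:`~.residuals.ReferenceEntry`."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "structures" not in doc:
        raise ParseError("manifest must contain a 'structures' list")
    out = []
    for d in doc["structures"]:
        me = _entry_from_dict(d, path.parent)
        raw = _read_res_raw(me.res_path)
        n_at = len(raw.elements)
        if len(me.charges) != n_at or len(me.atom_types) != n_at:
            raise ConsistencyError(
                f"{me.label}: manifest lists {len(me.charges)} charges / "
                f"{len(me.atom_types)} types but {me.res_path} has {n_at} atoms"
            )
        declared = sorted(i for m in me.molecules for i in m)
        if declared != list(range(n_at)):
            raise ConsistencyError(
                f"{me.label}: molecule partition must cover every atom once"
            )
        system = me.crystal_system or infer_crystal_system(raw.cell)
        lattice = Lattice(*raw.cell, crystal_system=system)
        mols = []
        for idxs in me.molecules:
            idxs = list(idxs)
            mols.append(
                _molecule_from_frac(
                    lattice,
                    [raw.elements[i] for i in idxs],
                    [me.atom_types[i] for i in idxs],
                    np.array([me.charges[i] for i in idxs]),
                    raw.frac[idxs],
                )
            )
        crystal = Crystal.create(lattice, raw.ops, mols, label=me.label)
        total_q = sum(float(m.charges.sum()) for m in mols) * len(raw.ops)
        if abs(total_q) > 1e-8:
            raise NeutralityError(
                f"{me.label}: net unit-cell charge {total_q:.3e} e"
            )
        if me.w_G < 0 or me.w_E < 0:
            raise ConsistencyError(f"{me.label}: negative weight")
        out.append(
            (
                crystal,
                ReferenceEntry(
                    crystal_ref=crystal,
                    u_inter_ref=me.u_inter_ref,
                    w_G=me.w_G,
                    w_E=me.w_E,
                    label=me.label,
                ),
            )
        )
    return out


def write_manifest(
    entries: list[ReferenceEntry], directory, name: str = "manifest.yaml"
) -> Path:
    """Write reference entries as ``.res`` files plus a manifest document."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {"structures": []}
    for k, e in enumerate(entries):
        fname = f"{e.label or f'structure{k}'}.res"
        write_res(e.crystal_ref, directory / fname)
        charges, types, mols = [], [], []
        at = 0
        for mol in e.crystal_ref.asym_unit:
            charges.extend(float(q) for q in mol.charges)
            types.extend(mol.atom_types)
            mols.append(list(range(at, at + mol.n_atoms)))
            at += mol.n_atoms
        doc["structures"].append(
            {
                "label": e.label or f"structure{k}",
                "res": fname,
                "charges": charges,
                "atom_types": types,
                "molecules": mols,
                "u_inter_ref": float(e.u_inter_ref),
                "w_G": float(e.w_G),
                "w_E": float(e.w_E),
                "crystal_system": e.crystal_ref.lattice.crystal_system.value,
            }
        )
    out = directory / name
    out.write_text(yaml.safe_dump(doc, sort_keys=False))
    return out
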