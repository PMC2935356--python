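"""Read, validate and measure protein backbones from PDB coordinate files.

Only the four backbone heavy atoms (N, CA, C, O) are retained: the whole
downstream pipeline is conditioned on backbone geometry alone. Residues
missing any backbone atom are dropped at parse time (they cannot be measured
or designed on), alternate locations collapse to the highest-occupancy copy,
and selenomethionine is mapped to methionine. Author residue numbering is
preserved for cross-structure correspondence; internal indices are 0-based.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from ._tables import THREE_TO_ONE

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: CA-CA distance above which consecutive residues are flagged as a chain
#: break (trans peptide geometry gives ~3.8 A).
CHAIN_BREAK_CA_CA = 4.3

STANDARD_RESIDUES = frozenset(THREE_TO_ONE)


class EmptyStructureError(ValueError):
    """No residue survived backbone-completeness filtering."""


class CorrespondenceError(ValueError):
    """Two structures share no residues under author numbering."""


class InsufficientResiduesError(ValueError):
    """Too few residues for the requested measurement."""


@dataclass
class Residue:
    """One residue with its backbone atoms.

    Coordinates are in Angstrom; ``res_seq`` is the author (1-based) number
    from the PDB file.
    """

    chain_id: str
    res_seq: int
    res_name: str
    coords: dict[str, np.ndarray]
    b_factors: dict[str, float] = field(default_factory=dict)
    had_altloc: bool = False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def is_complete(self) -> bool:
        return all(
            name in self.coords and np.all(np.isfinite(self.coords[name]))
            for name in BACKBONE_ATOMS
        )


@dataclass
class ValidationIssue:
    index: int
    code: str  # MISSING_ATOM | ZERO_BFACTOR | NONSTANDARD | ALTLOC | CHAIN_BREAK
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.issues

    def to_tsv(self) -> str:
        lines = ["index\tcode\tmessage"]
        lines += [f"{i.index}\t{i.code}\t{i.message}" for i in self.issues]
        return "\n".join(lines) + "\n"


class BackboneStructure:
    """An ordered protein backbone with derived torsion angles.

    Residue ``i`` has dihedrals (phi_i, psi_i, omega_i) where phi is the
    C(i-1)-N-CA-C torsion (undefined at the first residue), psi the
    N-CA-C-N(i+1) torsion and omega the CA-C-N(i+1)-CA(i+1) peptide torsion
    (both undefined at the last residue). Angles are degrees in [-180, 180).
    """

    def __init__(self, residues: list[Residue]):
        self.residues = list(residues)
        self._dihedrals: list[tuple[float | None, float | None, float | None]] | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atom_coords(self, atom: str) -> np.ndarray:
        return np.array([r.coords[atom] for r in self.residues])

    @property
    def ca_coords(self) -> np.ndarray:
        return self.atom_coords("CA")

    def ca_distances(self) -> np.ndarray:
        """Consecutive CA-CA distances (length L-1), for break detection."""
        ca = self.ca_coords
        return np.linalg.norm(np.diff(ca, axis=0), axis=1)

    def dihedrals(self) -> list[tuple[float | None, float | None, float | None]]:
        if self._dihedrals is None:
            self._dihedrals = _compute_dihedrals(self)
        return self._dihedrals


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion of four points in degrees, range [-180, 180).

    Standard convention: looking down the p1->p2 bond, the angle from the
    p0-p1-p2 plane to the p1-p2-p3 plane, positive clockwise.
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = -float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang >= 180.0:
        ang -= 360.0
    return ang


def _compute_dihedrals(structure: BackboneStructure) -> list[tuple]:
    if len(structure) < 3:
        raise InsufficientResiduesError(
            f"need at least 3 residues for dihedrals, got {len(structure)}"
        )
    res = structure.residues
    out = []
    for i, r in enumerate(res):
        phi = psi = omega = None
        if i > 0:
            phi = dihedral_angle(
                res[i - 1].coords["C"], r.coords["N"], r.coords["CA"], r.coords["C"]
            )
        if i < len(res) - 1:
            nxt = res[i + 1]
            psi = dihedral_angle(
                r.coords["N"], r.coords["CA"], r.coords["C"], nxt.coords["N"]
            )
            omega = dihedral_angle(
                r.coords["CA"], r.coords["C"], nxt.coords["N"], nxt.coords["CA"]
            )
        out.append((phi, psi, omega))
    return out


def dihedrals(structure: BackboneStructure) -> list[tuple]:
    """Per-residue (phi, psi, omega) in degrees; ``None`` where undefined."""
    return structure.dihedrals()


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_pdb(
    source: str,
    chain: str | None = None,
    model_index: int = 1,
) -> BackboneStructure:
    """Parse a PDB file (path or text) into a backbone.

    ``model_index`` is 1-based and selects the n-th MODEL block of a
    multi-model (e.g. NMR) file. ``chain=None`` takes the first chain.
    Residues lacking any of N/CA/C/O are dropped with a logged warning;
    for alternate locations the highest-occupancy copy is kept; HETATM
    records are ignored except MSE, which is mapped to MET.
    """
    if "\n" in source or source.lstrip().startswith(("ATOM", "HEADER", "MODEL", "REMARK")):
        st = gemmi.read_pdb_string(source)
    else:
        st = gemmi.read_pdb(source)

    if not (1 <= model_index <= len(st)):
        raise KeyError(f"model {model_index} not in file with {len(st)} model(s)")
    model = st[model_index - 1]

    chain_names = [ch.name for ch in model]
    if chain is None:
        if not chain_names:
            raise EmptyStructureError("file contains no chains")
        chain = chain_names[0]
    if chain not in chain_names:
        raise KeyError(f"chain {chain!r} not found (have {chain_names})")

    residues: list[Residue] = []
    for res in model[chain]:
        name = res.name
        if res.het_flag == "H":
            if name == "MSE":
                name = "MET"  # selenomethionine: standard counterpart
            else:
                continue
        elif name == "MSE":
            name = "MET"
        if name not in STANDARD_RESIDUES:
            logger.warning(
                "dropping nonstandard residue %s %s%d", res.name, chain, res.seqid.num
            )
            continue
        coords: dict[str, np.ndarray] = {}
        bfacs: dict[str, float] = {}
        had_altloc = False
        for atom_name in BACKBONE_ATOMS:
            best = None
            for atom in res:
                if atom.name != atom_name:
                    continue
                if atom.altloc:
                    had_altloc = True
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is not None:
                coords[atom_name] = np.array([best.pos.x, best.pos.y, best.pos.z])
                bfacs[atom_name] = float(best.b_iso)
        r = Residue(
            chain_id=chain,
            res_seq=res.seqid.num,
            res_name=name,
            coords=coords,
            b_factors=bfacs,
            had_altloc=had_altloc,
        )
        if not r.is_complete():
            missing = [a for a in BACKBONE_ATOMS if a not in coords]
            logger.warning(
                "dropping residue %s%d (%s): missing backbone atom(s) %s",
                chain, res.seqid.num, res.name, ",".join(missing),
            )
            continue
        residues.append(r)

    if not residues:
        raise EmptyStructureError(
            f"no residue with a complete backbone in chain {chain!r}"
        )
    return BackboneStructure(residues)


def write_pdb(structure: BackboneStructure, path: str | None = None) -> str:
    """Serialize backbone atoms as fixed-column PDB ATOM records."""
    buf = io.StringIO()
    serial = 1
    for res in structure.residues:
        for atom in BACKBONE_ATOMS:
            x, y, z = res.coords[atom]
            b = res.b_factors.get(atom, 1.0)
            element = atom[0]
            atom_field = atom if len(atom) == 4 else f" {atom:<3s}"
            buf.write(
                f"ATOM  {serial:5d} {atom_field} {res.res_name:>3s} "
                f"{res.chain_id:1s}{res.res_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
                f"          {element:>2s}\n"
            )
            serial += 1
    buf.write("TER\nEND\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(structure: BackboneStructure) -> ValidationReport:
    """Report-only checks: zero B-factors, nonstandard names, chain breaks,
    retained alternate locations. An empty report means the structure is
    clean input for the design stage."""
    report = ValidationReport()
    for i, res in enumerate(structure.residues):
        missing = [a for a in BACKBONE_ATOMS if a not in res.coords]
        if missing:
            report.issues.append(
                ValidationIssue(i, "MISSING_ATOM", f"missing {','.join(missing)}")
            )
        for atom, b in res.b_factors.items():
            if b == 0.0:
                report.issues.append(
                    ValidationIssue(i, "ZERO_BFACTOR", f"atom {atom} has B=0.0")
                )
        if res.res_name not in STANDARD_RESIDUES:
            report.issues.append(
                ValidationIssue(i, "NONSTANDARD", f"residue name {res.res_name}")
            )
        if res.had_altloc:
            report.issues.append(
                ValidationIssue(i, "ALTLOC", "alternate locations collapsed")
            )
    if len(structure) >= 2:
        for i, d in enumerate(structure.ca_distances()):
            if d > CHAIN_BREAK_CA_CA:
                report.issues.append(
                    ValidationIssue(
                        i + 1, "CHAIN_BREAK", f"CA-CA distance {d:.2f} A to previous"
                    )
                )
    return report


# ---------------------------------------------------------------------------
# Superposition RMSD
# ---------------------------------------------------------------------------

def backbone_rmsd(
    a: BackboneStructure,
    b: BackboneStructure,
    atoms: tuple[str, ...] = BACKBONE_ATOMS,
) -> float:
    """Least-squares superposition (Kabsch) RMSD in Angstrom.

    Residue correspondence is the intersection of author residue numbers;
    the rigid transform minimizing the RMSD over the chosen atom set is
    applied before measuring.
    """
    map_a = {r.res_seq: r for r in a.residues}
    map_b = {r.res_seq: r for r in b.residues}
    common = sorted(set(map_a) & set(map_b))
    pa, pb = [], []
    for num in common:
        ra, rb = map_a[num], map_b[num]
        for atom in atoms:
            if atom in ra.coords and atom in rb.coords:
                pa.append(ra.coords[atom])
                pb.append(rb.coords[atom])
    if not pa:
        raise CorrespondenceError("no common residues under author numbering")
    pa = np.asarray(pa)
    pb = np.asarray(pb)
    pa_c = pa - pa.mean(axis=0)
    pb_c = pb - pb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa_c, pb_c)
    return float(rssd / math.sqrt(len(pa)))
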