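"""Synthetic backbones and sequence databases for desk-scale pipelines.

Backbones are built in internal coordinates (NeRF-style placement) with
fixed ideal bond lengths and angles; only the torsions vary. This gives
exact control over the Ramachandran content of a fold — idealized helices,
strands and strained positive-phi turns — and lets dihedral noise of known
magnitude be injected and rebuilt into Cartesian coordinates. Decoy
databases are i.i.d. draws from a background composition; "homolog"
databases are column-wise samples from a profile's match emissions,
sharpened or flattened by a temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._tables import ALPHABET, ONE_TO_THREE, uniform_background
from .structure_io import BackboneStructure, Residue, backbone_rmsd

# Ideal backbone geometry (A, degrees): trans peptide.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

#: Default (phi, psi) per segment kind.
SEGMENT_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
    "turnL": (60.0, 40.0),
}

#: Residue name used when building each segment kind (backbone-only, so this
#: is cosmetic; turnL gets GLY as the residue most tolerant of positive phi).
_SEGMENT_RESNAME = {"helix": "ALA", "strand": "ALA", "turnL": "GLY"}


@dataclass
class FoldSpec:
    """Sequence of idealized secondary-structure segments."""

    segments: list[tuple[str, int]]
    seed: int = 0

    def __post_init__(self):
        for kind, n in self.segments:
            if kind not in SEGMENT_DIHEDRALS:
                raise ValueError(f"unknown segment kind {kind!r}")
            if n < 1:
                raise ValueError("segment length must be >= 1")
        if self.total_length < 10:
            raise ValueError("fold must have at least 10 residues")

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.segments)


@dataclass
class PerturbSpec:
    """Gaussian phi/psi noise, degrees."""

    sigma_deg: float
    seed: int = 0

    def __post_init__(self):
        if self.sigma_deg < 0:
            raise ValueError("sigma_deg must be >= 0")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D so that |C-D| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion."""
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n_hat = np.cross(ab, bc_hat)
    n_hat /= np.linalg.norm(n_hat)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(tau),
        bond * math.sin(theta) * math.sin(tau),
    ])
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def build_backbone(
    phi: list[float],
    psi: list[float],
    omega: list[float] | None = None,
    res_names: list[str] | None = None,
    chain_id: str = "A",
) -> BackboneStructure:
    """Build Cartesian coordinates from per-residue torsions.

    ``phi[0]`` and ``psi[-1]``/``omega[-1]`` are geometrically unused (chain
    termini). Omega defaults to 180 (trans) everywhere.
    """
    L = len(phi)
    if len(psi) != L:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = [180.0] * L
    if res_names is None:
        res_names = ["ALA"] * L

    n = np.zeros((L, 3))
    ca = np.zeros((L, 3))
    c = np.zeros((L, 3))
    o = np.zeros((L, 3))

    # First residue fixes the global frame.
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (BOND_N_CA, 0.0, 0.0)
    th = math.radians(ANGLE_N_CA_C)
    c[0] = ca[0] + BOND_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])

    for i in range(L):
        if i + 1 < L:
            n[i + 1] = _nerf(n[i], ca[i], c[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
            ca[i + 1] = _nerf(ca[i], c[i], n[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega[i])
            c[i + 1] = _nerf(c[i], n[i + 1], ca[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])
        # Carbonyl O: anti to the following N (torsion psi + 180).
        tau_o = (psi[i] + 180.0) if i + 1 < L else 180.0
        o[i] = _nerf(n[i], ca[i], c[i], BOND_C_O, ANGLE_CA_C_O, tau_o)

    residues = [
        Residue(
            chain_id=chain_id,
            res_seq=i + 1,
            res_name=res_names[i],
            coords={"N": n[i], "CA": ca[i], "C": c[i], "O": o[i]},
            b_factors={a: 1.0 for a in ("N", "CA", "C", "O")},
        )
        for i in range(L)
    ]
    return BackboneStructure(residues)


def make_backbone(spec: FoldSpec) -> BackboneStructure:
    """Idealized backbone realizing the fold's segment dihedrals exactly."""
    phi, psi, names = [], [], []
    for kind, count in spec.segments:
        p, s = SEGMENT_DIHEDRALS[kind]
        phi += [p] * count
        psi += [s] * count
        names += [_SEGMENT_RESNAME[kind]] * count
    return build_backbone(phi, psi, res_names=names)


def default_mixed_fold(seed: int = 0) -> FoldSpec:
    """An 80-residue mixed alpha/beta fold with two strained
    positive-phi turns — the standard desk-scale test subject."""
    return FoldSpec(
        segments=[
            ("helix", 20), ("turnL", 3), ("strand", 12), ("helix", 15),
            ("turnL", 3), ("strand", 12), ("helix", 15),
        ],
        seed=seed,
    )


def perturb_backbone(
    structure: BackboneStructure, spec: PerturbSpec
) -> tuple[BackboneStructure, float]:
    """Add i.i.d. Gaussian noise to phi/psi and rebuild with ideal geometry.

    Returns the rebuilt backbone and the achieved superposition RMSD (A)
    against the input. With ``sigma_deg=0`` a backbone that was itself built
    from ideal internal coordinates is reproduced exactly.
    """
    rng = np.random.default_rng(spec.seed)
    dihs = structure.dihedrals()
    L = len(structure)
    phi = [d[0] if d[0] is not None else -57.0 for d in dihs]
    psi = [d[1] if d[1] is not None else -47.0 for d in dihs]
    omega = [d[2] if d[2] is not None else 180.0 for d in dihs]
    noise_phi = rng.normal(0.0, spec.sigma_deg, L)
    noise_psi = rng.normal(0.0, spec.sigma_deg, L)
    phi = [p + e for p, e in zip(phi, noise_phi)]
    psi = [p + e for p, e in zip(psi, noise_psi)]
    names = [r.res_name for r in structure.residues]
    rebuilt = build_backbone(phi, psi, omega, res_names=names,
                             chain_id=structure.residues[0].chain_id)
    for r_new, r_old in zip(rebuilt.residues, structure.residues):
        r_new.res_seq = r_old.res_seq
    rmsd = backbone_rmsd(structure, rebuilt)
    return rebuilt, rmsd


# ---------------------------------------------------------------------------
# Sequence databases
# ---------------------------------------------------------------------------

#: Default decoy length law (mean, sd): typical globular-protein lengths.
DEFAULT_LENGTH_LAW = (250.0, 100.0)
_MIN_SEQ_LEN = 20


def make_decoy_db(
    n: int,
    length_law: tuple[float, float] = DEFAULT_LENGTH_LAW,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> list[SeqRecord]:
    """``n`` i.i.d. background sequences with 'decoy' headers."""
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be a 20-vector summing to 1")
    rng = np.random.default_rng(seed)
    mean, sd = length_law
    records = []
    for i in range(n):
        length = max(_MIN_SEQ_LEN, int(round(rng.normal(mean, sd))))
        seq = "".join(ALPHABET[j] for j in rng.choice(20, size=length, p=background))
        records.append(
            SeqRecord(Seq(seq), id=f"decoy_{i:05d}",
                      description=f"decoy_{i:05d} decoy random background sequence")
        )
    return records


def make_homolog_db(
    hmm,
    n: int,
    temperature: float = 1.0,
    seed: int = 0,
) -> list[SeqRecord]:
    """Sample ``n`` gapless sequences from a profile's match emissions.

    Emissions are raised to 1/temperature and renormalized: temperature
    below ~1e-3 collapses to the per-column argmax consensus, larger values
    flatten toward background-like diversity.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    rng = np.random.default_rng(seed)
    em = np.asarray(hmm.match_emissions, dtype=float)
    if temperature < 1e-3:
        p = np.zeros_like(em)
        p[np.arange(em.shape[0]), em.argmax(axis=1)] = 1.0
    else:
        logp = np.log(np.clip(em, 1e-300, None)) / temperature
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
    records = []
    for i in range(n):
        seq = "".join(
            ALPHABET[rng.choice(20, p=p[k])] for k in range(em.shape[0])
        )
        records.append(
            SeqRecord(Seq(seq), id=f"homolog_{i:04d}",
                      description=f"homolog_{i:04d} homolog profile sample T={temperature:g}")
        )
    return records


def consensus_sequence(hmm) -> str:
    """Per-column argmax of the match emissions."""
    em = np.asarray(hmm.match_emissions)
    return "".join(ALPHABET[j] for j in em.argmax(axis=1))


def write_fasta(records: list[SeqRecord], path: str) -> None:
    """60-column-wrapped FASTA."""
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def backbone_residue_names(sequence: str) -> list[str]:
    return [ONE_TO_THREE[a] for a in sequence]
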