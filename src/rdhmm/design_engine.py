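"""Fixed-backbone sequence design by Metropolis simulated annealing.

A deliberately lightweight stand-in for full-atom design: the backbone is
rigid, side chains are summarized by per-residue scalar properties
(hydropathy, charge, volume), and the energy couples the sequence to the
structure through (i) Ramachandran-class propensities, (ii) a burial term
rewarding hydrophobics at positions with many spatial neighbors, (iii)
pairwise hydrophobic attraction and like-charge repulsion across CA-CA
contacts, and (iv) a steric crowding penalty on large residues in dense
neighborhoods:

    E = w_rama * sum_i -ln P(aa_i | class_i)
      + w_burial * sum_i b_i (1 - h_i)
      + sum_{contacts (i,j)} [ -w_pair h_i h_j + w_chg q_i q_j ]
      + w_steric * sum_i v_i * crowd_i

Annealing from a random start with geometric cooling gives one designed
sequence per seed; independent runs form the ensemble whose per-column
statistics feed the profile HMM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from ._tables import (
    ALPHABET,
    AA_INDEX,
    N_AA,
    RAMA_CLASSES,
    charge_vector,
    default_propensity_table,
    hydropathy_vector,
    volume_vector,
)
from .structure_io import BackboneStructure

# ---------------------------------------------------------------------------
# Ramachandran classification
# ---------------------------------------------------------------------------

def classify_rama(phi: float | None, psi: float | None) -> str:
    """Coarse Ramachandran class of a (phi, psi) pair in degrees.

    alphaR: phi < 0 and psi in (-120, 50]; beta: phi < 0 otherwise;
    alphaL: phi >= 0 and psi in (-90, 90]; other: the remainder and any
    undefined (terminal) dihedral.
    """
    if phi is None or psi is None:
        return "other"
    if phi < 0:
        return "alphaR" if -120.0 < psi <= 50.0 else "beta"
    return "alphaL" if -90.0 < psi <= 90.0 else "other"


@dataclass
class EnergyParams:
    """Weights, property tables and annealing schedule for the design energy."""

    propensity_table: np.ndarray = field(default_factory=default_propensity_table)
    hydropathy: np.ndarray = field(default_factory=hydropathy_vector)
    charge: np.ndarray = field(default_factory=charge_vector)
    volume: np.ndarray = field(default_factory=volume_vector)
    w_rama: float = 1.0
    w_burial: float = 1.0
    w_pair: float = 1.0
    w_chg: float = 0.5
    w_steric: float = 0.5
    burial_radius: float = 8.0
    burial_count_threshold: int = 6
    contact_radius: float = 8.0
    t_init: float = 5.0
    t_final: float = 0.05
    moves_per_residue: int = 200
    seed: int = 0

    def __post_init__(self):
        for w in (self.w_rama, self.w_burial, self.w_pair, self.w_chg, self.w_steric):
            if w < 0:
                raise ValueError("energy weights must be >= 0")
        if not (self.t_init > self.t_final > 0):
            raise ValueError("need t_init > t_final > 0")
        cols = np.asarray(self.propensity_table).sum(axis=0)
        if not np.allclose(cols, 1.0, atol=1e-6):
            raise ValueError("propensity columns must sum to 1")


@dataclass
class DesignedSequence:
    sequence: str
    initial_energy: float
    final_energy: float
    seed: int
    accepted_moves: int


@dataclass
class DesignEnsemble:
    """Independent designed sequences on one backbone."""

    sequences: list[str]
    designs: list[DesignedSequence]
    length: int
    seed: int

    @property
    def n(self) -> int:
        return len(self.sequences)

    def column_frequencies(self) -> np.ndarray:
        """(L, 20) per-column residue frequencies."""
        counts = np.zeros((self.length, N_AA))
        for seq in self.sequences:
            for i, a in enumerate(seq):
                counts[i, AA_INDEX[a]] += 1
        return counts / max(1, self.n)

    def mean_pairwise_identity(self) -> float:
        """Closed form under exchangeability: sum_c sum_a f_ca^2 / L,
        corrected for self-pairs."""
        f = self.column_frequencies()
        n = self.n
        # unbiased pairwise identity between distinct rows
        return float((((f**2).sum(axis=1) * n * n - n) / (n * (n - 1))).sum() / self.length)


# ---------------------------------------------------------------------------
# Structure-dependent precomputation
# ---------------------------------------------------------------------------

class _SiteModel:
    """Precomputed per-position and pairwise cost tables for one backbone."""

    def __init__(self, structure: BackboneStructure, params: EnergyParams):
        L = len(structure)
        dih = structure.dihedrals() if L >= 3 else [(None, None, None)] * L
        self.classes = [classify_rama(d[0], d[1]) for d in dih]
        class_idx = [RAMA_CLASSES.index(c) for c in self.classes]

        ca = structure.ca_coords
        tree = cKDTree(ca)
        # neighbor counts excluding self and i+-1
        def counts(radius):
            out = np.zeros(L, dtype=int)
            for i, nbrs in enumerate(tree.query_ball_point(ca, radius)):
                out[i] = sum(1 for j in nbrs if abs(j - i) > 1)
            return out

        n_burial = counts(params.burial_radius)
        n_crowd = counts(6.0)
        buried = (n_burial >= params.burial_count_threshold).astype(float)
        crowd = np.maximum(0, n_crowd - 3).astype(float)

        # contacts: CA-CA < contact_radius, |i-j| >= 3
        pairs = tree.query_pairs(params.contact_radius)
        self.contacts = sorted((i, j) for i, j in pairs if abs(i - j) >= 3)
        self.neighbors: list[list[int]] = [[] for _ in range(L)]
        for i, j in self.contacts:
            self.neighbors[i].append(j)
            self.neighbors[j].append(i)

        prop = np.asarray(params.propensity_table)
        h = params.hydropathy
        q = params.charge
        v = params.volume
        # (L, 20) single-site cost
        rama_cost = -np.log(np.clip(prop[:, class_idx].T, 1e-12, None))
        self.site_cost = (
            params.w_rama * rama_cost
            + params.w_burial * buried[:, None] * (1.0 - h)[None, :]
            + params.w_steric * crowd[:, None] * v[None, :]
        )
        # (20, 20) pairwise cost per contact
        self.pair_cost = -params.w_pair * np.outer(h, h) + params.w_chg * np.outer(q, q)

    def total_energy(self, seq_idx: list[int]) -> float:
        e = sum(self.site_cost[i, a] for i, a in enumerate(seq_idx))
        e += sum(self.pair_cost[seq_idx[i], seq_idx[j]] for i, j in self.contacts)
        return float(e)

    def delta(self, seq_idx: list[int], pos: int, new_aa: int) -> float:
        old = seq_idx[pos]
        d = self.site_cost[pos, new_aa] - self.site_cost[pos, old]
        pc = self.pair_cost
        for j in self.neighbors[pos]:
            b = seq_idx[j]
            d += pc[new_aa, b] - pc[old, b]
        return float(d)


def energy(structure: BackboneStructure, sequence: str, params: EnergyParams) -> float:
    """Full design energy of a sequence on a backbone (deterministic)."""
    if len(sequence) != len(structure):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    model = _SiteModel(structure, params)
    return model.total_energy([AA_INDEX[a] for a in sequence])


def random_sequence(length: int, seed: int) -> str:
    """I.i.d. uniform sequence over the 20 standard residues."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(ALPHABET[i] for i in rng.integers(0, N_AA, length))


def redesign(
    structure: BackboneStructure,
    params: EnergyParams,
    _model: _SiteModel | None = None,
) -> DesignedSequence:
    """One annealing run: random start, single-position Metropolis moves,
    geometric cooling from t_init to t_final over moves_per_residue * L
    proposals. Fully reproducible from ``params.seed``."""
    L = len(structure)
    model = _model if _model is not None else _SiteModel(structure, params)
    rng = np.random.default_rng(params.seed)

    seq = list(rng.integers(0, N_AA, L))
    e0 = model.total_energy(seq)

    n_moves = params.moves_per_residue * L
    if n_moves < 1:
        raise ValueError("moves_per_residue must be >= 1")
    cool = (params.t_final / params.t_init) ** (1.0 / max(1, n_moves - 1))
    temps = params.t_init * cool ** np.arange(n_moves)

    positions = rng.integers(0, L, n_moves).tolist()
    # propose a residue distinct from the current one: draw 0..18 and shift
    offsets = rng.integers(0, N_AA - 1, n_moves).tolist()
    unif = rng.random(n_moves).tolist()
    temps = temps.tolist()

    e = e0
    accepted = 0
    delta = model.delta
    for k in range(n_moves):
        pos = positions[k]
        new_aa = offsets[k]
        if new_aa >= seq[pos]:
            new_aa += 1
        d = delta(seq, pos, new_aa)
        if d <= 0 or unif[k] < math.exp(-d / temps[k]):
            seq[pos] = new_aa
            e += d
            accepted += 1

    final = model.total_energy(seq)  # re-sum to avoid drift
    return DesignedSequence(
        sequence="".join(ALPHABET[a] for a in seq),
        initial_energy=e0,
        final_energy=final,
        seed=params.seed,
        accepted_moves=accepted,
    )


def derive_seed(seed: int, i: int) -> int:
    """Deterministic per-run seed below 2**31."""
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))


def generate_ensemble(
    structure: BackboneStructure,
    n: int,
    params: EnergyParams,
) -> DesignEnsemble:
    """``n`` independent annealing runs with per-run derived seeds."""
    if n < 2:
        raise ValueError("ensemble needs n >= 2 designs")
    model = _SiteModel(structure, params)
    designs = []
    for i in range(n):
        p = replace(params, seed=derive_seed(params.seed, i))
        designs.append(redesign(structure, p, _model=model))
    return DesignEnsemble(
        sequences=[d.sequence for d in designs],
        designs=designs,
        length=len(structure),
        seed=params.seed,
    )
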