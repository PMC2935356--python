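"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from rdhmm.design_engine import EnergyParams, generate_ensemble
from rdhmm.ensemble_msa import trivial_align
from rdhmm.profile_hmm import ProfileHMM, build
from rdhmm.synthetic_fixtures import default_mixed_fold, make_backbone

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def torsion_oracle(p0, p1, p2, p3) -> float:
    """Torsion from plane normals with an explicit sign from the scalar
    triple product — independent of the atan2 formulation under test."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    if ang >= 180.0:
        ang -= 360.0
    return ang


def brute_force_bits(hmm: ProfileHMM, seq: str) -> float:
    """Enumerate every glocal path (global across model nodes, free
    sequence flanks) and return the best log2-odds score."""
    M, n = hmm.M, len(seq)
    lod = np.log2(hmm.match_emissions / hmm.background)
    aa = {a: i for i, a in enumerate(hmm.alphabet)}
    lg = lambda arr, k: math.log2(arr[k])
    best = [-1e30]

    def rec(state, k, j, sc):
        if k == M and state in ("M", "D"):
            best[0] = max(best[0], sc)
            return
        if state == "M":
            if j < n:
                rec("M", k + 1, j + 1, sc + lg(hmm.t_mm, k) + lod[k, aa[seq[j]]])
            rec("D", k + 1, j, sc + lg(hmm.t_md, k))
            if j < n and k < M:
                rec("I", k, j + 1, sc + lg(hmm.t_mi, k))
        elif state == "I":
            if j < n:
                rec("M", k + 1, j + 1, sc + lg(hmm.t_im, k) + lod[k, aa[seq[j]]])
                rec("I", k, j + 1, sc + lg(hmm.t_ii, k))
        else:
            if j < n:
                rec("M", k + 1, j + 1, sc + lg(hmm.t_dm, k) + lod[k, aa[seq[j]]])
            rec("D", k + 1, j, sc + lg(hmm.t_dd, k))

    for j0 in range(n + 1):
        rec("M", 0, j0, 0.0)
    return best[0]


def random_toy_hmm(m: int, k_alpha: int = 4, seed: int = 0) -> ProfileHMM:
    """Random well-formed profile over a reduced alphabet."""
    r = np.random.default_rng(seed)
    em = r.dirichlet(np.ones(k_alpha), size=m)
    t = np.zeros((m, 7))
    for i in range(m):
        t[i, 0:3] = r.dirichlet(np.ones(3))
        t[i, 3:5] = r.dirichlet(np.ones(2))
        t[i, 5:7] = r.dirichlet(np.ones(2))
    return ProfileHMM(
        match_emissions=em, background=np.full(k_alpha, 1.0 / k_alpha),
        t_mm=t[:, 0], t_mi=t[:, 1], t_md=t[:, 2],
        t_im=t[:, 3], t_ii=t[:, 4], t_dm=t[:, 5], t_dd=t[:, 6],
        alphabet="ABCD"[:k_alpha],
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def mixed_structure():
    """The 80-residue mixed alpha/beta fold with two positive-phi turns."""
    return make_backbone(default_mixed_fold())


@pytest.fixture(scope="session")
def helix_structure():
    from rdhmm.synthetic_fixtures import FoldSpec

    return make_backbone(FoldSpec([("helix", 20)]))


@pytest.fixture(scope="session")
def small_ensemble(mixed_structure):
    """40 designs — enough column statistics for unit tests, fast."""
    return generate_ensemble(mixed_structure, 40, EnergyParams(seed=101))


@pytest.fixture(scope="session")
def small_hmm(small_ensemble):
    return build(trivial_align(small_ensemble))


def turn_columns():
    """0-based indices of the positive-phi (turnL) residues in the default
    mixed fold: segments helix20 turnL3 strand12 helix15 turnL3 strand12
    helix15."""
    return list(range(20, 23)) + list(range(50, 53))


def helix_columns():
    """Interior helix residues of the default mixed fold (segments at
    0-19, 35-49 and 65-79), avoiding segment boundaries."""
    return list(range(2, 18)) + list(range(37, 48)) + list(range(67, 78))
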