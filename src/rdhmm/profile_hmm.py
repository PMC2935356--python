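"""Profile hidden Markov models over designed-sequence alignments.

A left-to-right profile with match/insert/delete states is estimated from
the alignment (columns with gap fraction < 0.5 become match states), scored
against target sequences by Viterbi dynamic programming in log2-odds
("bits") against an i.i.d. background null, and calibrated by fitting a
Gumbel extreme-value law to the scores of random background sequences.

Alignment mode is glocal: the model is traversed from its first to its last
node (deletions allowed), while any prefix and suffix of the target
sequence are free. Scores therefore grow roughly linearly with model length
for sequences the model describes well, and are strongly negative for
unrelated sequences — a random sequence must pay the log-odds of every
column. This is the score scale on which "positive bits" is a meaningful
acceptance requirement and on which zero false positives at E <= 1 is an
achievable operating point. Everything is computed in log space; no
probability is multiplied in linear space along a DP path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._tables import ALPHABET, uniform_background

_NEG = -1e30  # effective -infinity in log2 space
_MASK_CHAR = "X"  # un-matchable residue used for greedy domain masking


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with per-node transition probabilities.

    Transition arrays are indexed by the *from* node k (0 = begin):
    ``t_mm[k]`` is P(M_k -> M_{k+1}), etc. Node M exits freely. Insert
    emissions equal the background, so inserted residues cost only their
    transition probabilities.
    """

    match_emissions: np.ndarray  # (M, K)
    background: np.ndarray  # (K,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    alphabet: str = ALPHABET
    n_rows: int = 0
    source: str = ""

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[0] < 1:
            raise ValueError("match_emissions must be (M, K) with M >= 1")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        for t in (self.t_mm, self.t_mi, self.t_md, self.t_im, self.t_ii,
                  self.t_dm, self.t_dd):
            if len(t) != self.M:
                raise ValueError("transition arrays must have length M")
        if not np.allclose(self.t_mm + self.t_mi + self.t_md, 1.0, atol=1e-9):
            raise ValueError("M-state transitions must sum to 1")
        if not np.allclose(self.t_im + self.t_ii, 1.0, atol=1e-9):
            raise ValueError("I-state transitions must sum to 1")
        if not np.allclose((self.t_dm + self.t_dd)[1:], 1.0, atol=1e-9):
            raise ValueError("D-state transitions must sum to 1")

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    # -- serialization (versioned plain text) --------------------------------

    def to_text(self, path: str | None = None) -> str:
        lines = [f"RDHMM 1", f"ALPH {self.alphabet}", f"M {self.M}",
                 f"NROWS {self.n_rows}", f"SOURCE {self.source}"]
        lines.append("BG " + " ".join(f"{x:.8g}" for x in self.background))
        for k in range(self.M):
            lines.append(
                f"NODE {k + 1} EM " +
                " ".join(f"{x:.8g}" for x in self.match_emissions[k])
            )
            lines.append(
                f"NODE {k + 1} TR " + " ".join(
                    f"{x:.8g}" for x in (
                        self.t_mm[k], self.t_mi[k], self.t_md[k],
                        self.t_im[k], self.t_ii[k], self.t_dm[k], self.t_dd[k],
                    )
                )
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_text(cls, text: str) -> "ProfileHMM":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines[0].startswith("RDHMM 1"):
            raise ValueError("not a version-1 profile file")
        alph = lines[1].split(maxsplit=1)[1]
        m = int(lines[2].split()[1])
        n_rows = int(lines[3].split()[1])
        source = lines[4].split(maxsplit=1)[1] if len(lines[4].split()) > 1 else ""
        bg = np.array([float(x) for x in lines[5].split()[1:]])
        em = np.zeros((m, len(alph)))
        tr = np.zeros((m, 7))
        for ln in lines[6:]:
            parts = ln.split()
            k = int(parts[1]) - 1
            vals = [float(x) for x in parts[3:]]
            if parts[2] == "EM":
                em[k] = vals
            else:
                tr[k] = vals
        return cls(
            match_emissions=em, background=bg,
            t_mm=tr[:, 0], t_mi=tr[:, 1], t_md=tr[:, 2],
            t_im=tr[:, 3], t_ii=tr[:, 4], t_dm=tr[:, 5], t_dd=tr[:, 6],
            alphabet=alph, n_rows=n_rows, source=source,
        )


@dataclass
class EVDParams:
    """Gumbel location/scale fitted to random-sequence bit scores."""

    mu: float
    lam: float
    n_samples: int = 0
    length_law: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass
class AlignmentPath:
    """Viterbi path: ops are ('M', node, seq_idx), ('I', node, seq_idx) or
    ('D', node, None); seq indices are 0-based."""

    ops: list[tuple[str, int, int | None]] = field(default_factory=list)

    @property
    def n_insertions(self) -> int:
        return sum(1 for op in self.ops if op[0] == "I")

    @property
    def n_deletions(self) -> int:
        return sum(1 for op in self.ops if op[0] == "D")

    @property
    def n_gaps(self) -> int:
        return self.n_insertions + self.n_deletions

    @property
    def matched_positions(self) -> list[int]:
        return [op[2] for op in self.ops if op[0] == "M"]


@dataclass
class LogoData:
    relative_entropy: np.ndarray  # (M,) bits
    letter_heights: np.ndarray  # (M, K)

    def to_tsv(self) -> str:
        header = "column\trelent\t" + "\t".join(ALPHABET)
        lines = [header]
        for k in range(len(self.relative_entropy)):
            hs = "\t".join(f"{h:.6f}" for h in self.letter_heights[k])
            lines.append(f"{k + 1}\t{self.relative_entropy[k]:.6f}\t{hs}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build(
    alignment,
    pseudocount_alpha: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile from an Alignment.

    Columns with gap fraction < 0.5 become match states. Emissions use
    background-weighted pseudocounts, p_a = (n_a + alpha*bg_a)/(n + alpha);
    transitions come from per-row state paths with Laplace (+1) smoothing.
    """
    rows = [seq for _, seq in alignment.rows]
    if not rows:
        raise ValueError("empty alignment")
    bg = uniform_background() if background is None else np.asarray(background, float)
    n_col = len(rows[0])
    n_rows = len(rows)
    aa_index = {a: i for i, a in enumerate(ALPHABET)}

    gap_frac = [sum(1 for r in rows if r[c] == "-") / n_rows for c in range(n_col)]
    match_cols = [c for c in range(n_col) if gap_frac[c] < 0.5]
    if not match_cols:
        raise ValueError("alignment has zero match columns")
    M = len(match_cols)
    is_match = set(match_cols)

    em = np.zeros((M, len(ALPHABET)))
    for k, c in enumerate(match_cols):
        count = np.zeros(len(ALPHABET))
        n_res = 0
        for r in rows:
            a = r[c]
            if a != "-":
                count[aa_index[a]] += 1
                n_res += 1
        em[k] = (count + pseudocount_alpha * bg) / (n_res + pseudocount_alpha)
        em[k] /= em[k].sum()

    # Transition counts per from-node: [MM, MI, MD, IM, II, DM, DD]
    cnt = np.zeros((M + 1, 7))
    col_node = {}
    node = 0
    for c in range(n_col):
        if c in is_match:
            node += 1
            col_node[c] = ("M", node)
        else:
            col_node[c] = ("I", node)
    for r in rows:
        state, k = "M", 0  # begin
        for c in range(n_col):
            kind, nd = col_node[c]
            if kind == "M":
                new = "M" if r[c] != "-" else "D"
                idx = {"MM": 0, "MD": 2, "IM": 3, "DM": 5, "DD": 6}.get(state + new)
                if state + new == "ID":  # I -> D not in the state set; route I->M->D
                    cnt[k, 3] += 1  # I_k -> M_{k+1} surrogate
                    idx = None
                if idx is not None:
                    cnt[k, idx] += 1
                state, k = new, nd
            else:
                if r[c] != "-":
                    if state == "M":
                        cnt[k, 1] += 1  # M -> I
                    elif state == "I":
                        cnt[k, 4] += 1  # I -> I
                    else:  # D -> I not in the state set; route D->M surrogate
                        cnt[k, 5] += 1
                    state = "I"

    c = cnt[:M] + 1.0  # Laplace smoothing; node M exits freely
    m_tot = c[:, 0] + c[:, 1] + c[:, 2]
    i_tot = c[:, 3] + c[:, 4]
    d_tot = c[:, 5] + c[:, 6]
    return ProfileHMM(
        match_emissions=em, background=bg,
        t_mm=c[:, 0] / m_tot, t_mi=c[:, 1] / m_tot, t_md=c[:, 2] / m_tot,
        t_im=c[:, 3] / i_tot, t_ii=c[:, 4] / i_tot,
        t_dm=c[:, 5] / d_tot, t_dd=c[:, 6] / d_tot,
        n_rows=n_rows,
    )


# ---------------------------------------------------------------------------
# Viterbi scoring
# ---------------------------------------------------------------------------

def _log_odds_emissions(hmm: ProfileHMM) -> dict[str, np.ndarray]:
    """Per-letter log2-odds columns; the mask character can never match."""
    lod = np.log2(np.clip(hmm.match_emissions, 1e-300, None) / hmm.background)
    table = {a: lod[:, i].copy() for i, a in enumerate(hmm.alphabet)}
    table[_MASK_CHAR] = np.full(hmm.M, _NEG)
    return table


def _log2(x: np.ndarray) -> np.ndarray:
    return np.log2(np.clip(x, 1e-300, None))


def score_only(hmm: ProfileHMM, sequence: str) -> float:
    """Glocal Viterbi bit score (no path). Vectorized over model nodes."""
    if not sequence:
        raise ValueError("empty sequence")
    lod = _log_odds_emissions(hmm)
    for a in sequence:
        if a not in lod:
            raise ValueError(f"residue {a!r} not in model alphabet")
    M = hmm.M
    lmm, lmi, lmd = _log2(hmm.t_mm), _log2(hmm.t_mi), _log2(hmm.t_md)
    lim, lii = _log2(hmm.t_im), _log2(hmm.t_ii)
    ldm, ldd = _log2(hmm.t_dm), _log2(hmm.t_dd)

    # cumulative D->D costs for the within-column delete scan
    # c[k] = sum_{t=1}^{k} ldd[t] over from-nodes t (ldd[0] unused)
    c = np.concatenate([[0.0], np.cumsum(ldd[1:])])  # length M, for k=1..M

    def delete_scan(m_vec: np.ndarray) -> np.ndarray:
        # m_vec: nodes 0..M ; returns D over nodes 0..M (node 0 = -inf)
        g = m_vec[:M] + lmd - c  # entry into D_{k} from M_{k-1}, k=1..M
        run = np.maximum.accumulate(g)
        d = np.full(M + 1, _NEG)
        d[1:] = run + c
        return d

    prev_m = np.full(M + 1, _NEG)
    prev_m[0] = 0.0
    prev_i = np.full(M, _NEG)
    prev_d = delete_scan(prev_m)
    best = max(prev_m[M], prev_d[M])

    for a in sequence:
        e = lod[a]
        stay = np.maximum(prev_m[:M] + lmm, prev_i + lim)
        enter = np.maximum(stay, prev_d[:M] + ldm)
        new_m = np.full(M + 1, _NEG)
        new_m[0] = 0.0
        new_m[1:] = e + enter
        new_i = np.maximum(prev_m[:M] + lmi, prev_i + lii)
        new_d = delete_scan(new_m)
        best = max(best, new_m[M], new_d[M])
        prev_m, prev_i, prev_d = new_m, new_i, new_d
    return float(best)


def score(hmm: ProfileHMM, sequence: str) -> tuple[float, AlignmentPath]:
    """Glocal Viterbi bit score with the optimal state path."""
    if not sequence:
        raise ValueError("empty sequence")
    lod = _log_odds_emissions(hmm)
    for a in sequence:
        if a not in lod:
            raise ValueError(f"residue {a!r} not in model alphabet")
    M, n = hmm.M, len(sequence)
    lmm, lmi, lmd = _log2(hmm.t_mm), _log2(hmm.t_mi), _log2(hmm.t_md)
    lim, lii = _log2(hmm.t_im), _log2(hmm.t_ii)
    ldm, ldd = _log2(hmm.t_dm), _log2(hmm.t_dd)

    vm = np.full((M + 1, n + 1), _NEG)
    vi = np.full((M, n + 1), _NEG)
    vd = np.full((M + 1, n + 1), _NEG)
    bm = np.zeros((M + 1, n + 1), dtype=np.int8)  # 0=B/M,1=I,2=D
    bd = np.zeros((M + 1, n + 1), dtype=np.int8)  # 0=from M, 1=from D
    bi = np.zeros((M, n + 1), dtype=np.int8)  # 0=from M, 1=from I

    vm[0, :] = 0.0
    for j in range(n + 1):
        for k in range(1, M + 1):
            from_m = vm[k - 1, j] + lmd[k - 1]
            from_d = vd[k - 1, j] + ldd[k - 1] if k > 1 else _NEG
            if from_d > from_m:
                vd[k, j], bd[k, j] = from_d, 1
            else:
                vd[k, j], bd[k, j] = from_m, 0
        if j == n:
            break
        a = sequence[j]
        e = lod[a]
        nj = j + 1
        for k in range(M):
            from_m = vm[k, j] + lmi[k]
            from_i = vi[k, j] + lii[k]
            if from_i > from_m:
                vi[k, nj], bi[k, nj] = from_i, 1
            else:
                vi[k, nj], bi[k, nj] = from_m, 0
        for k in range(1, M + 1):
            cand = (vm[k - 1, j] + lmm[k - 1],
                    vi[k - 1, j] + lim[k - 1] if k - 1 < M else _NEG,
                    vd[k - 1, j] + ldm[k - 1])
            w = int(np.argmax(cand))
            vm[k, nj] = e[k - 1] + cand[w]
            bm[k, nj] = w

    # choose end cell: node M, any j, M or D state
    ends = [(vm[M, j], "M", j) for j in range(n + 1)]
    ends += [(vd[M, j], "D", j) for j in range(n + 1)]
    bits, state, j = max(ends, key=lambda t: t[0])

    # traceback: stop on reaching the begin state (node 0, "M")
    ops: list[tuple[str, int, int | None]] = []
    k = M
    while not (k == 0 and state == "M"):
        if state == "M":
            ops.append(("M", k, j - 1))
            state = ("M", "I", "D")[bm[k, j]]
            k -= 1
            j -= 1
        elif state == "D":
            ops.append(("D", k, None))
            state = "D" if bd[k, j] else "M"
            k -= 1
        else:  # insert at node k (node unchanged while tracing inserts)
            ops.append(("I", k, j - 1))
            state = "I" if bi[k, j] else "M"
            j -= 1
    ops.reverse()
    return float(bits), AlignmentPath(ops=ops)


# ---------------------------------------------------------------------------
# Calibration and E-values
# ---------------------------------------------------------------------------

def calibrate(
    hmm: ProfileHMM,
    n_samples: int = 1000,
    length_law: tuple[float, float] | None = None,
    seed: int = 0,
) -> EVDParams:
    """Fit a Gumbel law to scores of random background sequences.

    Sample lengths follow Normal(mean, sd) truncated at 10; the default law
    is (M, 0.2*M). The fit is maximum likelihood (scipy's gumbel_r).
    """
    if n_samples < 100:
        raise ValueError("need n_samples >= 100 for a stable fit")
    if length_law is None:
        length_law = (float(hmm.M), 0.2 * hmm.M)
    rng = np.random.default_rng(seed)
    bg = hmm.background
    scores = np.empty(n_samples)
    for i in range(n_samples):
        length = max(10, int(round(rng.normal(*length_law))))
        seq = "".join(hmm.alphabet[j] for j in rng.choice(len(bg), length, p=bg))
        scores[i] = score_only(hmm, seq)
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate (zero-variance) score distribution")
    mu, lam = fit_gumbel(scores)
    return EVDParams(mu=mu, lam=lam, n_samples=n_samples,
                     length_law=length_law, seed=seed)


def fit_gumbel(samples: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda=1/scale)."""
    loc, scale = stats.gumbel_r.fit(np.asarray(samples, dtype=float))
    return float(loc), float(1.0 / scale)


def evalue(evd: EVDParams, score_bits: float, n_db: int) -> float:
    """Expected count of >= score hits among n_db random sequences:
    E = n_db * (1 - exp(-exp(-lambda (s - mu))))."""
    if evd.lam <= 0:
        raise ValueError("lambda must be > 0")
    if n_db < 1:
        raise ValueError("n_db must be >= 1")
    x = evd.lam * (score_bits - evd.mu)
    # survival of the Gumbel max; -expm1 keeps precision for large scores
    surv = -math.expm1(-math.exp(-x)) if x > -30 else 1.0
    return float(n_db * surv)


# ---------------------------------------------------------------------------
# Logo
# ---------------------------------------------------------------------------

def logo(hmm: ProfileHMM) -> LogoData:
    """Per-column relative entropy vs background and letter heights."""
    p = hmm.match_emissions
    bg = hmm.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / bg), 0.0)
    rel = terms.sum(axis=1)
    rel = np.maximum(rel, 0.0)
    heights = p * rel[:, None]
    return LogoData(relative_entropy=rel, letter_heights=heights)


def consensus(hmm: ProfileHMM) -> str:
    """Per-column argmax residue of the match emissions."""
    return "".join(hmm.alphabet[i] for i in hmm.match_emissions.argmax(axis=1))
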