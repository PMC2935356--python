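"""Scan FASTA databases with a calibrated profile and report ranked hits.

The scan scores every database sequence, keeps those with E-value at or
below the acceptance threshold (default 10, matching the search protocol's
default), sorts by bit score, counts domains by greedy iterative alignment
masking, and renders HMMER-style three-line alignment blocks. Hits can be
binned by score interval and mutually exclusive annotation keyword groups
for survey plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .profile_hmm import (
    AlignmentPath,
    EVDParams,
    ProfileHMM,
    _MASK_CHAR,
    consensus,
    evalue,
    score,
    score_only,
)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class Hit:
    seq_id: str
    description: str
    bits: float
    evalue: float
    sequence: str
    path: AlignmentPath
    n_domains: int = 1

    @property
    def n_gaps(self) -> int:
        return self.path.n_gaps


@dataclass
class BinTable:
    bin_edges: list[float]
    keyword_groups: list[str]
    counts: np.ndarray  # (n_bins, n_groups)

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"[{self.bin_edges[i]:g},{self.bin_edges[i + 1]:g})"
            for i in range(len(self.bin_edges) - 1)
        ]
        return pd.DataFrame(self.counts, index=labels, columns=self.keyword_groups)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t")


def _read_db(db) -> list:
    if isinstance(db, (str,)):
        return list(SeqIO.parse(db, "fasta"))
    return list(db)


def search_fasta(
    hmm: ProfileHMM,
    evd: EVDParams,
    db,
    e_max: float = 10.0,
    domain_floor: float | None = None,
) -> list[Hit]:
    """Score every sequence of a FASTA database (path or records).

    Hits with E <= e_max are retained, sorted by bits descending with
    seq_id as the tie-break; ``n_db`` for the E-value is the number of
    sequences in the scanned file. ``domain_floor`` is the bit score used
    for greedy domain counting; by default the score corresponding to
    E = e_max, so every retained hit has at least one domain.
    """
    records = _read_db(db)
    n_db = len(records)
    if n_db == 0:
        return []
    hits: list[Hit] = []
    for rec in records:
        seq = str(rec.seq).upper()
        bits = score_only(hmm, seq)
        e = evalue(evd, bits, n_db)
        if e <= e_max:
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            hits.append(Hit(rec.id, desc, bits, e, seq, AlignmentPath()))
    hits.sort(key=lambda h: (-h.bits, h.seq_id))
    if domain_floor is None:
        # score at which E(score) == e_max (capped for tiny databases)
        import math
        p = min(0.99, e_max / n_db)
        domain_floor = evd.mu - math.log(-math.log1p(-p)) / evd.lam
    for h in hits:
        h.bits, h.path = score(hmm, h.sequence)
        # a retained hit contributed at least the domain that scored it
        h.n_domains = max(1, count_domains(hmm, h.sequence, domain_floor))
    return hits


def count_domains(hmm: ProfileHMM, sequence: str, bits_floor: float) -> int:
    """Greedy iterative alignment: score, mask the matched residues, repeat
    while the pass scores at least ``bits_floor``."""
    seq = list(sequence.upper())
    n = 0
    for _ in range(64):  # safety bound
        bits, path = score(hmm, "".join(seq))
        if bits < bits_floor:
            break
        matched = path.matched_positions
        if not matched:
            break
        n += 1
        for i in matched:
            seq[i] = _MASK_CHAR
    return n


def bin_hits(
    hits: list[Hit],
    bin_width: float,
    keyword_groups: list[str],
) -> BinTable:
    """Cross-tabulate hits by score bin and first-matching keyword group.

    Keyword matching is case-insensitive substring; the last group is the
    catch-all (conventionally "*"). Bin edges cover the observed score
    range in steps of ``bin_width``.
    """
    if not keyword_groups:
        raise ValueError("need at least one keyword group")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not hits:
        return BinTable([0.0, bin_width], list(keyword_groups),
                        np.zeros((1, len(keyword_groups)), dtype=int))
    lo = np.floor(min(h.bits for h in hits) / bin_width) * bin_width
    hi = np.ceil((max(h.bits for h in hits) + 1e-9) / bin_width) * bin_width
    edges = list(np.arange(lo, hi + bin_width / 2, bin_width))
    if len(edges) < 2:
        edges = [lo, lo + bin_width]
    counts = np.zeros((len(edges) - 1, len(keyword_groups)), dtype=int)
    for h in hits:
        b = min(int((h.bits - lo) // bin_width), len(edges) - 2)
        g = len(keyword_groups) - 1  # catch-all
        desc = h.description.lower()
        for gi, kw in enumerate(keyword_groups[:-1]):
            if kw.lower() in desc:
                g = gi
                break
        counts[b, g] += 1
    return BinTable(edges, list(keyword_groups), counts)


def render_alignment(hmm: ProfileHMM, hit: Hit, width: int = 60) -> str:
    """Three-line alignment block: consensus (dots at target insertions),
    match mask (identity letter / '+' similarity / blank), target (dashes
    at deletions). Wrapped in fixed-width blocks."""
    cons = consensus(hmm)
    top, mid, bot = [], [], []
    for op, node, pos in hit.path.ops:
        if op == "M":
            c = cons[node - 1]
            t = hit.sequence[pos]
            top.append(c)
            bot.append(t)
            if c == t:
                mid.append(c)
            elif _blosum_positive(c, t):
                mid.append("+")
            else:
                mid.append(" ")
        elif op == "I":
            top.append(".")
            mid.append(" ")
            bot.append(hit.sequence[pos])
        else:  # deletion
            top.append(cons[node - 1])
            mid.append(" ")
            bot.append("-")
    blocks = []
    for i in range(0, len(top), width):
        blocks.append(
            "".join(top[i:i + width]) + "\n"
            + "".join(mid[i:i + width]) + "\n"
            + "".join(bot[i:i + width])
        )
    return "\n\n".join(blocks) + "\n"


def _blosum_positive(a: str, b: str) -> bool:
    try:
        return _BLOSUM62[a, b] > 0
    except (KeyError, IndexError):
        return False


def hits_to_tsv(hits: list[Hit]) -> str:
    lines = ["rank\tid\tbits\tevalue\tn_domains\tn_gaps\tdescription"]
    for i, h in enumerate(hits, start=1):
        lines.append(
            f"{i}\t{h.seq_id}\t{h.bits:.2f}\t{h.evalue:.3g}\t{h.n_domains}"
            f"\t{h.n_gaps}\t{h.description}"
        )
    return "\n".join(lines) + "\n"
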