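"""Assemble designed sequences into alignments.

Because every designed sequence shares the backbone's length and a
one-to-one column/residue correspondence, alignment of a single ensemble is
trivial. Multi-structure combined models consume a precomputed structural
alignment (aligned FASTA) as a per-structure master gap pattern, which is
slid onto every designed row of the matching ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


@dataclass
class Alignment:
    """Rows of equal column count; design rows map columns to residues."""

    rows: list[tuple[str, str]]
    #: per design row column -> (structure id, residue index) or None at gaps
    column_map: dict[str, list[tuple[str, int] | None]] = field(default_factory=dict)

    def __post_init__(self):
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: column counts {sorted(widths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def degap(self, row_id: str) -> str:
        seq = dict(self.rows)[row_id]
        return seq.replace(GAP, "")

    def to_fasta(self, path: str | None = None) -> str:
        text = "".join(
            f">{rid}\n" + "\n".join(seq[i:i + 60] for i in range(0, len(seq), 60)) + "\n"
            for rid, seq in self.rows
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_stockholm(self, path: str) -> None:
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in self.rows]
        )
        AlignIO.write(msa, path, "stockholm")


@dataclass
class GapPattern:
    """Master gapped row from an external structural alignment."""

    structure_id: str
    master_row: str

    @property
    def n_columns(self) -> int:
        return len(self.master_row)

    @property
    def ungapped_length(self) -> int:
        return len(self.master_row) - self.master_row.count(GAP)


def read_gap_patterns(path: str) -> list[GapPattern]:
    """Each row of an aligned FASTA becomes one structure's gap pattern."""
    return [
        GapPattern(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def trivial_align(
    ensemble,
    include_native: bool = False,
    native_sequence: str | None = None,
    prefix: str = "design",
) -> Alignment:
    """Ungapped alignment of an ensemble (all rows are length L).

    The native sequence is excluded by default — the core protocol builds
    the model from designed sequences only; ``include_native=True`` adds it
    as an extra row for the score-inflation experiment.
    """
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    rows = [(f"{prefix}_{i:04d}", seq) for i, seq in enumerate(ensemble.sequences)]
    cmap = {
        rid: [(prefix, j) for j in range(ensemble.length)] for rid, _ in rows
    }
    if include_native:
        if native_sequence is None:
            raise ValueError("include_native=True requires native_sequence")
        if len(native_sequence) != ensemble.length:
            raise ValueError("native sequence length != ensemble length")
        rows.append(("native", native_sequence))
        cmap["native"] = [("native", j) for j in range(ensemble.length)]
    return Alignment(rows=rows, column_map=cmap)


def apply_gap_pattern(pattern: GapPattern, sequence: str) -> str:
    """Slide one ungapped sequence into the master's gapping pattern."""
    if pattern.ungapped_length != len(sequence):
        raise ValueError(
            f"master ungapped length {pattern.ungapped_length} != sequence "
            f"length {len(sequence)}"
        )
    it = iter(sequence)
    return "".join(GAP if c == GAP else next(it) for c in pattern.master_row)


def propagate_gaps(pattern: GapPattern, ensemble, prefix: str | None = None) -> Alignment:
    """Replicate the master gap pattern onto every designed row."""
    prefix = prefix or pattern.structure_id
    rows = []
    cmap = {}
    for i, seq in enumerate(ensemble.sequences):
        rid = f"{prefix}_{i:04d}"
        rows.append((rid, apply_gap_pattern(pattern, seq)))
        col_map: list[tuple[str, int] | None] = []
        j = 0
        for c in pattern.master_row:
            if c == GAP:
                col_map.append(None)
            else:
                col_map.append((pattern.structure_id, j))
                j += 1
        cmap[rid] = col_map
    return Alignment(rows=rows, column_map=cmap)


def merge(alignments: list[Alignment]) -> Alignment:
    """Row concatenation of alignments sharing a common master; columns
    gapped in every row are dropped."""
    if not alignments:
        raise ValueError("nothing to merge")
    widths = {a.n_columns for a in alignments}
    if len(widths) > 1:
        raise ValueError(f"column mismatch: {sorted(widths)}")
    rows = [row for a in alignments for row in a.rows]
    cmap = {k: v for a in alignments for k, v in a.column_map.items()}
    n_col = len(rows[0][1])
    keep = [c for c in range(n_col) if any(seq[c] != GAP for _, seq in rows)]
    if len(keep) != n_col:
        rows = [(rid, "".join(seq[c] for c in keep)) for rid, seq in rows]
        cmap = {rid: [m[c] for c in keep] for rid, m in cmap.items()}
    return Alignment(rows=rows, column_map=cmap)
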