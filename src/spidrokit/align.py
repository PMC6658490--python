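"""Pairwise and small progressive multiple alignment primitives.

Pairwise affine-gap dynamic programming is delegated to
:class:`Bio.Align.PairwiseAligner`; this module fixes the parameterisations
the pipeline uses and adds the quantities the downstream stages need:

* percent identity with end-gap columns excluded from the denominator, so a
  shorter full-length terminal domain is not penalised for length (the
  CD-HIT-like reading of identity "across the terminal domain");
* a deterministic progressive multiple alignment for near-identical repeat
  units, built by aligning each sequence to the growing profile's consensus
  and propagating gaps ("once a gap, always a gap").

Two scoring schemes are exposed: BLOSUM62 with gap open -10 / extend -1 for
domain detection, and a plain identity matrix (match 1, mismatch 0, gaps
-5 / -1) for identity-threshold clustering, where the score should not
depend on a similarity matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length plus the optimal affine-gap score.

    ``span_a``/``span_b`` are the 0-based half-open coordinates of the
    aligned region in the ungapped inputs (the full sequence for global
    mode, the matched substring for local mode).
    """

    aligned_a: str
    aligned_b: str
    score: float
    mode: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("gapped rows differ in length")


@dataclass(frozen=True)
class MultipleAlignment:
    """>= 2 gapped rows of equal length with no all-gap column."""

    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentError("multiple alignment needs >= 2 rows")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise AlignmentError("rows differ in length")
        for j in range(ncol):
            if all(r[j] == GAP for r in self.rows):
                raise AlignmentError(f"all-gap column {j}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def _make_aligner(
    mode: str, matrix: str, gap_open: float, gap_extend: float, free_end_gaps: bool
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if matrix == "identity":
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if mode == "global" and free_end_gaps:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def pairwise_align(
    a: str,
    b: str,
    mode: str = "global",
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    free_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two protein sequences.

    A gap run of length ``g`` costs ``gap_open + (g - 1) * gap_extend``.
    ``matrix`` is a :mod:`Bio.Align.substitution_matrices` name or
    ``"identity"`` (match 1, mismatch 0). The traceback is deterministic
    (the engine's first optimal alignment).
    """
    if not a or not b:
        raise AlignmentError("empty input sequence")
    if mode not in ("global", "local"):
        raise AlignmentError(f"unknown mode {mode!r}")
    aligner = _make_aligner(mode, matrix, gap_open, gap_extend, free_end_gaps)
    alignments = aligner.align(a, b)
    try:
        aln = alignments[0]
    except IndexError:
        # local mode with no positive-scoring pair: the empty alignment
        return PairwiseAlignment("", "", 0.0, mode, (0, 0), (0, 0))
    # Alignment.__getitem__ gives the gapped rows directly.
    ga, gb = aln[0], aln[1]
    if mode == "local":
        blocks_a, blocks_b = aln.aligned
        span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
        span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    else:
        span_a, span_b = (0, len(a)), (0, len(b))
    return PairwiseAlignment(ga, gb, float(aln.score), mode, span_a, span_b)


def _end_gap_columns(al: PairwiseAlignment) -> tuple[int, int]:
    """Number of leading/trailing columns that are end-gaps in either row."""
    n = len(al.aligned_a)
    lead = 0
    while lead < n and (al.aligned_a[lead] == GAP or al.aligned_b[lead] == GAP):
        # leading run of columns gapped in one row
        if al.aligned_a[lead] != GAP and al.aligned_b[lead] != GAP:
            break
        lead += 1
    trail = 0
    while trail < n - lead and (
        al.aligned_a[n - 1 - trail] == GAP or al.aligned_b[n - 1 - trail] == GAP
    ):
        trail += 1
    return lead, trail


def percent_identity(al: PairwiseAlignment) -> float:
    """100 x matches / columns, end-gap columns excluded from the
    denominator; internal gap columns count as mismatches."""
    lead, trail = _end_gap_columns(al)
    core_a = al.aligned_a[lead : len(al.aligned_a) - trail]
    core_b = al.aligned_b[lead : len(al.aligned_b) - trail]
    if not core_a:
        raise AlignmentError("undefined identity: alignment is fully end-gapped")
    matches = sum(
        1 for x, y in zip(core_a, core_b) if x == y and x != GAP
    )
    return 100.0 * matches / len(core_a)


def global_identity(
    a: str, b: str, gap_open: float = -5.0, gap_extend: float = -1.0
) -> float:
    """Identity-matrix semi-global alignment identity of two sequences.

    This is the clustering metric: plain identity fraction under an
    alignment that does not charge for end gaps.
    """
    al = pairwise_align(
        a, b, mode="global", matrix="identity",
        gap_open=gap_open, gap_extend=gap_extend, free_end_gaps=True,
    )
    return percent_identity(al)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


def _column_consensus(rows: list[str], j: int) -> str:
    residues = [r[j] for r in rows if r[j] != GAP]
    if not residues:
        return GAP
    counts = Counter(residues)
    top = max(counts.values())
    return min(r for r, c in counts.items() if c == top)


def _consensus_of_rows(rows: list[str]) -> str:
    return "".join(_column_consensus(rows, j) for j in range(len(rows[0])))


def _merge_into_profile(rows: list[str], seq: str) -> list[str]:
    """Align ``seq`` to the profile consensus and propagate gaps."""
    cons = _consensus_of_rows(rows).replace(GAP, "X")  # placeholder for rare all-gap
    al = pairwise_align(
        cons, seq, mode="global", matrix="identity", gap_open=-5.0, gap_extend=-1.0
    )
    new_rows = []
    for row in rows:
        out = []
        k = 0  # cursor in the ungapped consensus == profile columns
        for ca, cb in zip(al.aligned_a, al.aligned_b):
            if ca == GAP:
                out.append(GAP)  # insertion relative to profile
            else:
                out.append(row[k])
                k += 1
        new_rows.append("".join(out))
    new_rows.append(al.aligned_b)
    return new_rows


def progressive_msa(seqs: list[str]) -> MultipleAlignment:
    """Deterministic progressive alignment of near-identical sequences.

    The longest sequence (ties: first) seeds the profile; the remaining
    sequences join in descending order of identity to the seed (ties: input
    order). Each joiner is aligned to the profile consensus under the
    identity scheme and gaps are propagated to all existing rows.
    """
    if len(seqs) < 2:
        raise AlignmentError("progressive_msa needs >= 2 sequences")
    if any(not s for s in seqs):
        raise AlignmentError("empty input sequence")
    seed_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    order = sorted(
        (i for i in range(len(seqs)) if i != seed_idx),
        key=lambda i: (-global_identity(seqs[seed_idx], seqs[i]), i),
    )
    rows = [seqs[seed_idx]]
    pos = {seed_idx: 0}
    for i in order:
        rows = _merge_into_profile(rows, seqs[i])
        pos[i] = len(rows) - 1
    # restore input order
    ordered = [rows[pos[i]] for i in range(len(seqs))]
    # drop all-gap columns (cannot arise from merging, but keep the invariant)
    ncol = len(ordered[0])
    keep = [j for j in range(ncol) if any(r[j] != GAP for r in ordered)]
    ordered = ["".join(r[j] for j in keep) for r in ordered]
    return MultipleAlignment(tuple(ordered))
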