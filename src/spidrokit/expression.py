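"""TPM computation and C-terminus-anchored spidroin aggregation.

Spidroin transcripts assemble badly: the repetitive core fragments, so one
gene surfaces as many contigs differing only in how much repeat they carry.
The aggregation scheme implemented here sidesteps that: collapse transcripts
with identical C-terminal domains to one representative trimmed to a 500-
base window containing the CTD coding region, then sum TPM across
representatives whose CTDs share >= 95% amino-acid identity. Spidroin
expression shares are then percentages over spidroin clusters only.

TPM (transcripts per million) for transcript i with read count c_i and
effective length l_i is ``10^6 * (c_i / l_i) / sum_j (c_j / l_j)``; a
library's TPMs sum to 10^6 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import SequenceRecord
from .termini import TerminalDomainHit, TerminiCluster

TRIM_WINDOW = 500  # bases, CTD-anchored representative length


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    effective_length: float
    count: float
    tpm: float
    replicate: str = "rep1"


@dataclass
class AggregatedExpression:
    cluster_id: str
    member_ids: list[str]
    tpm_by_replicate: dict[str, float]
    share_percent: dict[str, float] = field(default_factory=dict)

    @property
    def mean_tpm(self) -> float:
        return float(np.mean(list(self.tpm_by_replicate.values())))


def compute_tpm(counts: pd.DataFrame) -> list[ExpressionRecord]:
    """Compute TPM per replicate from a counts table.

    Expects columns ``transcript_id``, ``length``, ``count`` and optional
    ``replicate`` (default "rep1"). Counts must be >= 0, lengths > 0, and
    each replicate needs at least one positive count.
    """
    df = counts.copy()
    if "replicate" not in df.columns:
        df["replicate"] = "rep1"
    for col in ("transcript_id", "length", "count"):
        if col not in df.columns:
            raise ExpressionError(f"counts table missing column {col!r}")
    if (df["length"] <= 0).any():
        raise ExpressionError("non-positive effective length")
    if (df["count"] < 0).any():
        raise ExpressionError("negative count")
    records: list[ExpressionRecord] = []
    for rep, sub in df.groupby("replicate", sort=True):
        rate = sub["count"].to_numpy(float) / sub["length"].to_numpy(float)
        denom = rate.sum()
        if denom == 0:
            raise ExpressionError(f"replicate {rep!r}: all counts are zero")
        tpm = 1e6 * rate / denom
        records.extend(
            ExpressionRecord(t, float(l), float(c), float(x), str(rep))
            for t, l, c, x in zip(
                sub["transcript_id"], sub["length"], sub["count"], tpm
            )
        )
    return records


@dataclass(frozen=True)
class TrimmedRepresentative:
    transcript_id: str
    member_ids: tuple[str, ...]
    residues: str
    trim_span: tuple[int, int]  # window in the original transcript, bases
    trim_error: bool = False  # CTD coding region wider than the window


def make_ctd_representatives(
    transcripts: list[SequenceRecord],
    ctd_hits: dict[str, TerminalDomainHit],
    window: int = TRIM_WINDOW,
) -> list[TrimmedRepresentative]:
    """Collapse identical-CTD transcripts and trim to a CTD-anchored window.

    ``ctd_hits`` are protein-coordinate CTD hits for the translations; they
    are back-mapped x3 to nucleotide coordinates. The representative of an
    identical-CTD group (first by id) keeps the 3'-most ``window`` bases
    that still contain the full CTD coding region; transcripts shorter than
    the window are kept whole. A CTD coding region wider than the window is
    reported (``trim_error``) and the full CTD span kept instead.
    """
    groups: dict[str, list[SequenceRecord]] = {}
    for t in transcripts:
        if t.id not in ctd_hits:
            raise ExpressionError(f"transcript {t.id!r} has no CTD hit")
        hit = ctd_hits[t.id]
        ctd_nt = t.residues[hit.span[0] * 3 : hit.span[1] * 3]
        groups.setdefault(ctd_nt, []).append(t)
    reps: list[TrimmedRepresentative] = []
    for ctd_nt, members in sorted(groups.items(), key=lambda kv: kv[1][0].id):
        members = sorted(members, key=lambda t: t.id)
        rep = members[0]
        hit = ctd_hits[rep.id]
        nt_start, nt_end = hit.span[0] * 3, hit.span[1] * 3
        n = len(rep.residues)
        if n <= window:
            span, error = (0, n), False
        elif nt_end - nt_start > window:
            span, error = (nt_start, nt_end), True
        else:
            start = min(n - window, nt_start)
            span, error = (start, start + window), False
        reps.append(
            TrimmedRepresentative(
                transcript_id=rep.id,
                member_ids=tuple(t.id for t in members),
                residues=rep.residues[span[0] : span[1]],
                trim_span=span,
                trim_error=error,
            )
        )
    return reps


def aggregate_by_ctd(
    records: list[ExpressionRecord],
    clusters: list[TerminiCluster],
) -> list[AggregatedExpression]:
    """Sum TPM per >= threshold-identity CTD cluster and compute shares.

    Transcripts not in any cluster are treated as non-spidroin and excluded
    from the share denominator; a transcript claimed by two clusters is an
    assignment error. Shares per replicate sum to 100 over clusters.
    """
    assignment: dict[str, str] = {}
    for cl in clusters:
        for m in cl.member_ids:
            if m in assignment:
                raise ExpressionError(
                    f"transcript {m!r} assigned to both {assignment[m]!r} "
                    f"and {cl.cluster_id!r}"
                )
            assignment[m] = cl.cluster_id
    replicates = sorted({r.replicate for r in records})
    out: list[AggregatedExpression] = []
    for cl in clusters:
        tpm_by_rep = {rep: 0.0 for rep in replicates}
        for r in records:
            if assignment.get(r.transcript_id) == cl.cluster_id:
                tpm_by_rep[r.replicate] += r.tpm
        out.append(AggregatedExpression(cl.cluster_id, list(cl.member_ids), tpm_by_rep))
    for rep in replicates:
        total = sum(a.tpm_by_replicate[rep] for a in out)
        for a in out:
            a.share_percent[rep] = (
                100.0 * a.tpm_by_replicate[rep] / total if total > 0 else 0.0
            )
    return out


def rank_spidroins(agg: list[AggregatedExpression]) -> list[AggregatedExpression]:
    """Clusters in descending mean-TPM order (ties: cluster id)."""
    if not agg:
        raise ExpressionError("no aggregated clusters")
    return sorted(agg, key=lambda a: (-a.mean_tpm, a.cluster_id))


def expression_table(agg: list[AggregatedExpression]) -> pd.DataFrame:
    rows = []
    for a in rank_spidroins(agg):
        row = {"cluster_id": a.cluster_id, "members": ",".join(a.member_ids),
               "mean_tpm": a.mean_tpm}
        for rep, tpm in sorted(a.tpm_by_replicate.items()):
            row[f"tpm_{rep}"] = tpm
            row[f"share_{rep}"] = a.share_percent[rep]
        rows.append(row)
    return pd.DataFrame(rows)
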