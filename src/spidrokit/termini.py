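"""Terminal-domain detection and greedy C-terminal identity clustering.

Spidroin N- and C-terminal domains are the conserved, non-repetitive
anchors of otherwise highly repetitive proteins, so they are the reliable
handles both for delimiting the repetitive region and for grouping
transcript variants of the same gene. Detection is local alignment of each
query against a labelled NTD/CTD reference library (BLOSUM62); clustering
of C-termini is greedy longest-first centroid clustering at a plain-identity
threshold (CD-HIT-style: a sequence joins the first cluster whose centroid
CTD it matches at >= threshold, else founds a new one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import global_identity, pairwise_align, percent_identity
from .seqio import SequenceRecord

#: A CTD hit must end within this many residues of the sequence end.
CTD_END_SLACK = 5


class TerminiError(ValueError):
    pass


@dataclass(frozen=True)
class TerminalDomainHit:
    """Best local-alignment hit of a reference terminal domain in a query."""

    query_id: str
    kind: str  # "NTD" | "CTD"
    span: tuple[int, int]  # 0-based half-open, in query coordinates
    reference_id: str
    identity: float
    score: float


@dataclass
class TerminiCluster:
    """One >= threshold-identity C-terminal group."""

    cluster_id: str
    centroid_ctd: str
    member_ids: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)
    representative_id: str = ""


def _reference_kind(rec: SequenceRecord) -> str:
    if rec.id.startswith("NTD"):
        return "NTD"
    if rec.id.startswith("CTD"):
        return "CTD"
    # fall back to a kind=... tag in the description
    for token in rec.description.split():
        if token.startswith("kind="):
            return token.split("=", 1)[1]
    raise TerminiError(f"reference {rec.id!r}: cannot determine NTD/CTD kind")


def find_termini(
    query: SequenceRecord,
    reference: list[SequenceRecord],
    min_identity: float = 40.0,
    min_length: int = 60,
) -> list[TerminalDomainHit]:
    """Best NTD and CTD hits of the reference library in ``query``.

    A candidate counts when its local alignment covers >= ``min_length``
    columns at >= ``min_identity`` percent identity (the conservation level
    of spidroin termini across genera). At most one hit per domain kind is
    returned; CTD hits must end within :data:`CTD_END_SLACK` residues of
    the sequence end, NTD hits must start within the same slack of the
    sequence start.
    """
    if query.alphabet != "protein":
        raise TerminiError(f"query {query.id!r}: protein sequence required")
    if not reference:
        raise TerminiError("empty reference library")
    best: dict[str, TerminalDomainHit] = {}
    for ref in reference:
        kind = _reference_kind(ref)
        al = pairwise_align(query.residues, ref.residues, mode="local")
        if len(al.aligned_a) < min_length:
            continue
        ident = percent_identity(al)
        if ident < min_identity:
            continue
        span = al.span_a
        if kind == "CTD" and span[1] < len(query.residues) - CTD_END_SLACK:
            continue
        if kind == "NTD" and span[0] > CTD_END_SLACK:
            continue
        hit = TerminalDomainHit(query.id, kind, span, ref.id, ident, al.score)
        if kind not in best or hit.score > best[kind].score:
            best[kind] = hit
    return [best[k] for k in ("NTD", "CTD") if k in best]


def extract_ctd(seq: SequenceRecord, hit: TerminalDomainHit) -> str:
    if hit.kind != "CTD" or hit.query_id != seq.id:
        raise TerminiError("hit is not a CTD hit for this sequence")
    return seq.residues[hit.span[0] : hit.span[1]]


def cluster_ctermini(
    sequences: list[SequenceRecord],
    ctd_hits: dict[str, TerminalDomainHit],
    threshold: float = 95.0,
) -> list[TerminiCluster]:
    """Greedy longest-first centroid clustering of C-terminal domains.

    Sequences are processed by descending full length (ties: id); each
    joins the first existing cluster whose centroid CTD identity is >=
    ``threshold`` (inclusive), else founds a new cluster with its own CTD
    as centroid. The representative is the longest member (ties:
    lexicographically smallest id).
    """
    if not 0.0 < threshold <= 100.0:
        raise TerminiError(f"threshold {threshold} outside (0, 100]")
    missing = [s.id for s in sequences if s.id not in ctd_hits]
    if missing:
        raise TerminiError(f"sequences without CTD hit: {missing}")
    order = sorted(sequences, key=lambda s: (-len(s.residues), s.id))
    clusters: list[TerminiCluster] = []
    for seq in order:
        ctd = extract_ctd(seq, ctd_hits[seq.id])
        placed = False
        for cl in clusters:
            ident = global_identity(cl.centroid_ctd, ctd)
            if ident >= threshold:
                cl.member_ids.append(seq.id)
                cl.identities[seq.id] = ident
                placed = True
                break
        if not placed:
            cl = TerminiCluster(
                cluster_id=f"cluster{len(clusters)}",
                centroid_ctd=ctd,
                member_ids=[seq.id],
                identities={seq.id: 100.0},
            )
            clusters.append(cl)
    by_id = {s.id: s for s in sequences}
    for cl in clusters:
        cl.representative_id = min(
            cl.member_ids, key=lambda m: (-len(by_id[m].residues), m)
        )
    return clusters


def select_representatives(
    clusters: list[TerminiCluster], sequences: list[SequenceRecord]
) -> list[SequenceRecord]:
    """Longest member of each cluster (the per-group analysis sequence)."""
    if not clusters:
        raise TerminiError("no clusters")
    by_id = {s.id: s for s in sequences}
    return [by_id[cl.representative_id] for cl in clusters]
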