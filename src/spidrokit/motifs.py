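"""Silk-motif scanning, occupancy, and MaSp classification.

The short motifs of dragline silk map onto mechanics: poly-alanine runs
(A_n) form the beta-sheet nanocrystals behind tensile strength, GPGX and
the MaSp4-specific GPGPQ form the beta-turn-rich amorphous matrix behind
extensibility, and GGX is the glycine-rich spacer. Scanning is a greedy
left-to-right tiling under a fixed precedence (longer / more specific
first), so occurrences never overlap and occupancy — the percent of region
residues covered per motif class — is well defined and reproducible.

Classification into MaSp subfamilies follows the motif-combination rules of
the silk literature: poly-alanine with GPGX reads as MaSp2, poly-alanine
without GPGX as MaSp1, GPGPQ-dominated repeats without poly-alanine as
MaSp4, GGX-dominated repeats without poly-alanine as MaSp5 — gated on the
C-terminal domain family being a MaSp at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GPGX_ALPHABET = frozenset("GSAQ")
POLYA_MIN_RUN = 4
MASP4_GPGPQ_MIN_OCCUPANCY = 20.0

#: Tiling precedence: longer / more specific motifs claim residues first.
MOTIF_PRECEDENCE = ("VSVVSTTVS", "GPGPQ", "GPGG", "GPGX", "polyA", "GGX")


@dataclass(frozen=True)
class MotifGrammar:
    """The silk-motif token set and its tiling precedence."""

    gpgx_alphabet: frozenset = GPGX_ALPHABET
    polya_min_run: int = POLYA_MIN_RUN
    precedence: tuple[str, ...] = MOTIF_PRECEDENCE

    def __post_init__(self) -> None:
        if self.polya_min_run < 2:
            raise ValueError("polya_min_run must be >= 2")


DEFAULT_GRAMMAR = MotifGrammar()


@dataclass(frozen=True)
class MotifOccurrence:
    motif_class: str
    span: tuple[int, int]


@dataclass
class MotifAnnotation:
    """Non-overlapping motif occurrences over a region plus occupancies."""

    region_id: str
    region_length: int
    occurrences: list[MotifOccurrence] = field(default_factory=list)

    def occupancy(self, motif_class: str) -> float:
        covered = sum(
            o.span[1] - o.span[0]
            for o in self.occurrences
            if o.motif_class == motif_class
        )
        return 100.0 * covered / self.region_length

    @property
    def occupancies(self) -> dict[str, float]:
        classes = {o.motif_class for o in self.occurrences}
        return {c: self.occupancy(c) for c in sorted(classes)}

    @property
    def total_occupancy(self) -> float:
        return sum(self.occupancy(c) for c in {o.motif_class for o in self.occurrences})

    def gpgx_like_occupancy(self) -> float:
        """Combined occupancy of the GPGX-family motifs (GPGX + GPGG)."""
        return self.occupancy("GPGX") + self.occupancy("GPGG")


def _match_at(region: str, pos: int, motif: str, grammar: MotifGrammar) -> int:
    """Length of ``motif`` matched at ``pos``, or 0."""
    n = len(region)
    if motif == "VSVVSTTVS":
        return 9 if region.startswith("VSVVSTTVS", pos) else 0
    if motif == "GPGPQ":
        return 5 if region.startswith("GPGPQ", pos) else 0
    if motif == "GPGG":
        return 4 if region.startswith("GPGG", pos) else 0
    if motif == "GPGX":
        if (
            pos + 4 <= n
            and region.startswith("GPG", pos)
            and region[pos + 3] in grammar.gpgx_alphabet
        ):
            return 4
        return 0
    if motif == "polyA":
        run = 0
        while pos + run < n and region[pos + run] == "A":
            run += 1
        return run if run >= grammar.polya_min_run else 0
    if motif == "GGX":
        return 3 if pos + 3 <= n and region.startswith("GG", pos) else 0
    raise ValueError(f"unknown motif class {motif!r}")


def scan_motifs(
    region: str, region_id: str = "region", grammar: MotifGrammar = DEFAULT_GRAMMAR
) -> MotifAnnotation:
    """Greedy left-to-right tiling of the motif grammar over ``region``.

    At each position the highest-precedence matching motif claims its span
    and scanning resumes after it; unclaimed residues stay uncovered, so
    per-class occupancies and their total are percentages of the region.
    """
    if not region:
        raise ValueError("empty region")
    ann = MotifAnnotation(region_id=region_id, region_length=len(region))
    pos = 0
    n = len(region)
    while pos < n:
        for motif in grammar.precedence:
            length = _match_at(region, pos, motif, grammar)
            if length:
                ann.occurrences.append(MotifOccurrence(motif, (pos, pos + length)))
                pos += length
                break
        else:
            pos += 1
    return ann


@dataclass(frozen=True)
class SpidroinClassCall:
    label: str  # MaSp1 | MaSp2 | MaSp4 | MaSp5 | other-MaSp | non-MaSp
    rule_trace: tuple[str, ...]


def classify_spidroin(
    annotation: MotifAnnotation,
    ctd_family: str,
    masp4_gpgpq_min: float = MASP4_GPGPQ_MIN_OCCUPANCY,
) -> SpidroinClassCall:
    """Motif-combination classification gated on the CTD family.

    For MaSp-family termini: GPGPQ occupancy >= ``masp4_gpgpq_min`` with no
    poly-alanine reads as MaSp4; poly-alanine with GPGX-family motifs as
    MaSp2; poly-alanine without them as MaSp1; no poly-alanine with GGX as
    the dominant class as MaSp5; anything else as other-MaSp. Non-MaSp
    termini short-circuit to non-MaSp.
    """
    if annotation is None:
        raise ValueError("missing motif annotation")
    if not ctd_family.startswith("MaSp"):
        return SpidroinClassCall(
            "non-MaSp", (f"CTD family {ctd_family} is not MaSp",)
        )
    trace = [f"CTD family {ctd_family} is MaSp"]
    occ = annotation.occupancies
    polya = occ.get("polyA", 0.0)
    gpgpq = occ.get("GPGPQ", 0.0)
    gpgx = annotation.gpgx_like_occupancy()
    ggx = occ.get("GGX", 0.0)
    if gpgpq >= masp4_gpgpq_min and polya == 0.0:
        trace.append(
            f"GPGPQ occupancy {gpgpq:.1f}% >= {masp4_gpgpq_min}% and no poly-A"
        )
        return SpidroinClassCall("MaSp4", tuple(trace))
    if polya > 0.0 and gpgx > 0.0:
        trace.append(f"poly-A present ({polya:.1f}%) with GPGX ({gpgx:.1f}%)")
        return SpidroinClassCall("MaSp2", tuple(trace))
    if polya > 0.0:
        trace.append(f"poly-A present ({polya:.1f}%) without GPGX")
        return SpidroinClassCall("MaSp1", tuple(trace))
    others = [v for c, v in occ.items() if c != "GGX"]
    if ggx > 0.0 and ggx > max(others, default=0.0):
        trace.append(f"no poly-A; GGX dominant ({ggx:.1f}%)")
        return SpidroinClassCall("MaSp5", tuple(trace))
    trace.append("no MaSp1/2/4/5 motif combination matched")
    return SpidroinClassCall("other-MaSp", tuple(trace))
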