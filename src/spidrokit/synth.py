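"""Synthetic spidroins, transcriptomes and count tables with known truth.

Spider silk proteins (spidroins) are long tandem arrays of "ensemble
repeats" — units themselves composed of short motifs (poly-alanine runs,
GGX, GPGX, and in the MaSp4 family the proline-rich GPGPQ) — flanked by
conserved non-repetitive N- and C-terminal domains (NTD/CTD). This module
builds such architectures from an explicit motif grammar so that every
downstream stage (terminal detection, clustering, repeat decomposition,
motif occupancy, TPM aggregation, composition prediction) can be tested
against exact ground truth without any external download.

What is emulated: NTD + k noisy tandem unit copies + CTD proteins;
family-specific CTDs with controlled within- and between-family divergence;
codon back-translated transcripts; multinomial read counts for a known
abundance vector (probability proportional to abundance x effective
length, so TPM computed downstream recovers the abundances). What is not:
indels, codon-usage realism, read-level sequencing error.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import PROTEIN_ALPHABET, SequenceRecord, write_fasta, write_table

AA = "".join(sorted(PROTEIN_ALPHABET))

# ---------------------------------------------------------------------------
# Motif grammar: unit templates per spidroin class (zero-noise ground truth)
# ---------------------------------------------------------------------------

#: Ensemble-repeat unit templates, written as concatenations of grammar
#: tokens. masp4 follows the MaSp4 architecture: GPGPQ-dominated 63-residue
#: units with one GPGG and one VSVVSTTVS, no poly-alanine.
UNIT_TEMPLATES: dict[str, str] = {
    "masp1": "GGA" "GGQ" "GGA" "GGY" "GGL" "GGQ" + "A" * 8,
    "masp2": "GPGG" "GPGQ" "GPGS" + "GGY" "GGQ" + "A" * 8,
    "masp4": "GPGPQ" * 3 + "GPGG" + "GPGPQ" * 2 + "VSVVSTTVS" + "GPGPQ"
    + "SQYSPISYQTSPSQYSPVSQ",
    "masp5": "GGQ" "GGY" "GGL" "GGQ" "GGA" "GGQ" "GGY" "GGL",
    "other": "SQSASAFAQSSSLASSFASQSTIV",
}

SPIDROIN_CLASSES = tuple(UNIT_TEMPLATES)

#: CTD reference family used for each synthetic class.
CLASS_CTD_FAMILY: dict[str, str] = {
    "masp1": "MaSp1",
    "masp2": "MaSp2",
    "masp4": "MaSp4",
    "masp5": "MaSp5",
    "other": "TuSp",
}

MASP_FAMILIES = frozenset({"MaSp1", "MaSp2", "MaSp4", "MaSp5"})

# Hand-composed spidroin-flavoured terminal domains (synthetic stand-ins for
# published termini: alanine/serine/glutamine-rich, ~150 aa NTD, ~100 aa CTD).
BASE_NTD_MASP = (
    "MNWSTRLALSILAVLCTQSLA"
    "AQANTPWSSKANADAFINSFISAASNTGSFSQDQMEDMSLIGNTLMAAMDNMGGRITPSKLQALDMAFASSV"
    "AEIAASEGGDLGVTTNAIADALTSAFYQTTGVVNSRFISEIRSLIGMFAQASANDV"
)
BASE_NTD_OTHER = (
    "MNWTARFTLSLLVVLCAQSVS"
    "GQAKTPWENPAHAEAFIQNFLQNVSSSGAFTADQLDDMSVISNTIMSSMDQMSSSVKTASQLQALNMAFASSM"
    "AELVIAENADLSSTTRAVADSLSSAFLQTTGSVNQQFVNEISSLINMFAQVSSSSV"
)
BASE_CTD_MASP = (
    "SRLSSPSASSRVSSAVSSLVSSGPTNPASLSNAISSVVSQVSASNPGSSGCDVLVQALLEVITALIHVLGSA"
    "SIGQVNSSSVGQSASIVGQSVYRALS"
)
BASE_CTD_OTHER = (
    "ARLASPDSSARISSHASTLLSSGPTKHDSLADAIESSFSTAMSQSGASSPGYLNELLHTLTGLLQVFSQT"
    "SGFNDQDLLNQVNELITMFSHHMNDS"
)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue independently with probability ``rate``,
    replacing it with a uniform draw over the other 19 residues."""
    if rate == 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [c for c in AA if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def build_reference_library(family_divergence: float = 0.25, seed: int = 7070) -> list[SequenceRecord]:
    """Regenerate the bundled terminal-domain reference library.

    Each MaSp family CTD is the shared MaSp base CTD with seeded divergence
    (default 25%: families are clearly distinct, well below any clustering
    threshold, yet detectable by local alignment). Non-MaSp entries derive
    from a separate base.
    """
    rng = np.random.default_rng(seed)
    records = [
        SequenceRecord("NTD_MaSp", BASE_NTD_MASP, "protein", "kind=NTD family=MaSp"),
        SequenceRecord("NTD_TuSp", BASE_NTD_OTHER, "protein", "kind=NTD family=TuSp"),
    ]
    for fam in ("MaSp1", "MaSp2", "MaSp4", "MaSp5"):
        ctd = mutate(BASE_CTD_MASP, family_divergence, rng)
        records.append(
            SequenceRecord(f"CTD_{fam}", ctd, "protein", f"kind=CTD family={fam}")
        )
    for fam in ("TuSp", "Flag"):
        ctd = mutate(BASE_CTD_OTHER, family_divergence, rng)
        records.append(
            SequenceRecord(f"CTD_{fam}", ctd, "protein", f"kind=CTD family={fam}")
        )
    return records


def reference_library() -> list[SequenceRecord]:
    """Load the bundled synthetic terminal-domain reference library."""
    from .seqio import read_fasta

    path = resources.files("spidrokit") / "data" / "terminal_reference_synthetic.fasta"
    with resources.as_file(path) as p:
        return read_fasta(p, "protein")


def reference_family(ref_id: str) -> str:
    """Family label encoded in a reference id like ``CTD_MaSp1``."""
    return ref_id.split("_", 1)[1]


# ---------------------------------------------------------------------------
# Spidroin generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchitectureSpec:
    """Blueprint for one synthetic spidroin: NTD + k noisy unit copies + CTD."""

    ntd: str
    ctd: str
    unit: str
    copies: int
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.unit) < 10:
            raise ValueError("unit length must be >= 10")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not 0.0 <= self.substitution_rate <= 0.2:
            raise ValueError("substitution_rate must be in [0, 0.2]")


@dataclass
class TruthEntry:
    """Ground truth for one generated spidroin."""

    id: str
    unit: str
    unit_spans: list[tuple[int, int]]
    repetitive_span: tuple[int, int]
    class_label: str
    ctd_family: str


@dataclass
class TruthManifest:
    """Ground truth for a generated transcriptome."""

    proteins: dict[str, TruthEntry] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)  # sum to 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, e in self.proteins.items():
            rows.append(
                {
                    "id": tid,
                    "class": e.class_label,
                    "ctd_family": e.ctd_family,
                    "unit": e.unit,
                    "copies": len(e.unit_spans),
                    "weight": self.weights.get(tid, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def gen_spidroin(
    spec: ArchitectureSpec, id: str = "synth", class_label: str = "masp1"
) -> tuple[SequenceRecord, TruthEntry]:
    """Generate one spidroin protein and its truth entry.

    Substitution noise is applied i.i.d. per repetitive residue; the
    terminal domains are kept as given (divergence of termini is controlled
    by the caller, e.g. :func:`gen_transcriptome`).
    """
    rng = np.random.default_rng(spec.seed)
    repeats = mutate(spec.unit * spec.copies, spec.substitution_rate, rng)
    protein = spec.ntd + repeats + spec.ctd
    start = len(spec.ntd)
    L = len(spec.unit)
    spans = [(start + i * L, start + (i + 1) * L) for i in range(spec.copies)]
    entry = TruthEntry(
        id=id,
        unit=spec.unit,
        unit_spans=spans,
        repetitive_span=(start, start + spec.copies * L),
        class_label=class_label,
        ctd_family=CLASS_CTD_FAMILY.get(class_label, "TuSp"),
    )
    return SequenceRecord(id, protein, "protein"), entry


#: One fixed codon per amino acid (back-translation is a right inverse of
#: translation; codon-usage realism is deliberately out of scope).
CODON: dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}


def back_translate(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein)


def translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


#: Relative abundance scale per class, mirroring major-ampullate gland
#: expression structure (MaSp2 > MaSp1 > MaSp4 >> MaSp5 > non-MaSp).
CLASS_ABUNDANCE_SCALE: dict[str, float] = {
    "masp2": 4.0,
    "masp1": 2.0,
    "masp4": 1.0,
    "masp5": 0.2,
    "other": 0.05,
}


def gen_transcriptome(
    class_mix: dict[str, int],
    seed: int = 0,
    copies_range: tuple[int, int] = (4, 10),
    substitution_rate: float = 0.01,
    ctd_divergence: float = 0.01,
    weight_jitter_sd: float = 0.5,
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthManifest]:
    """Generate a synthetic gland transcriptome with known truth.

    Returns ``(nucleotide_records, protein_records, manifest)``. Each
    protein is NTD + k unit copies (k uniform in ``copies_range``) + a
    family CTD carrying ``ctd_divergence`` within-family noise. Abundance
    weights are class-scaled log-normal draws normalised to sum 1.
    """
    if not class_mix or any(n < 0 for n in class_mix.values()):
        raise ValueError("class_mix must map classes to non-negative counts")
    unknown = set(class_mix) - set(SPIDROIN_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lib = {r.id: r.residues for r in reference_library()}
    proteins: list[SequenceRecord] = []
    manifest = TruthManifest()
    raw_weights: dict[str, float] = {}
    for cls in SPIDROIN_CLASSES:
        for j in range(class_mix.get(cls, 0)):
            tid = f"{cls}_{j}"
            fam = CLASS_CTD_FAMILY[cls]
            ntd = lib["NTD_MaSp"] if fam in MASP_FAMILIES else lib["NTD_TuSp"]
            ctd = mutate(lib[f"CTD_{fam}"], ctd_divergence, rng)
            copies = int(rng.integers(copies_range[0], copies_range[1] + 1))
            spec = ArchitectureSpec(
                ntd=ntd,
                ctd=ctd,
                unit=UNIT_TEMPLATES[cls],
                copies=copies,
                substitution_rate=substitution_rate,
                seed=int(rng.integers(2**31)),
            )
            rec, entry = gen_spidroin(spec, id=tid, class_label=cls)
            proteins.append(rec)
            manifest.proteins[tid] = entry
            scale = CLASS_ABUNDANCE_SCALE[cls]
            raw_weights[tid] = scale * float(
                np.exp(rng.normal(0.0, weight_jitter_sd))
            )
    total = sum(raw_weights.values())
    manifest.weights = {tid: w / total for tid, w in raw_weights.items()}
    nts = [
        SequenceRecord(p.id, back_translate(p.residues), "nucleotide", p.description)
        for p in proteins
    ]
    return nts, proteins, manifest


def gen_counts(
    manifest: TruthManifest,
    lengths: dict[str, int],
    library_size: int = 1_000_000,
    seed: int = 0,
    replicate: str = "rep1",
) -> pd.DataFrame:
    """Draw a multinomial count table for the manifest's abundance vector.

    Per-transcript probability is proportional to weight x effective
    length (``lengths``, in bases), which is how read counts relate to
    molar abundance; the TPM formula downstream then recovers the weights
    (x 10^6) in expectation. Columns: transcript_id, length, count,
    replicate.
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    rng = np.random.default_rng(seed)
    tids = list(manifest.weights)
    w = np.array([manifest.weights[t] for t in tids], dtype=float)
    ln = np.array([lengths[t] for t in tids], dtype=float)
    p = w * ln
    p = p / p.sum()
    counts = rng.multinomial(library_size, p)
    return pd.DataFrame(
        {
            "transcript_id": tids,
            "length": ln.astype(int),
            "count": counts,
            "replicate": replicate,
        }
    )


def prediction_sampling_sd(
    weights: np.ndarray,
    lengths: np.ndarray,
    library_size: int,
    membership: np.ndarray,
    profiles: np.ndarray,
) -> np.ndarray:
    """Delta-method SD of an expression-weighted composition prediction.

    Counts are multinomial with p_t proportional to weight_t x length_t;
    the TPM share of transcript t is s_t = (c_t / l_t) / sum_j (c_j / l_j),
    cluster shares are sums of member s_t, and the predicted percent of
    residue r is the cluster-share-weighted average of cluster profiles.
    This propagates the multinomial covariance of the count draw through
    that chain, evaluated at the expected counts; the result is the
    per-residue SD of the predicted percents, i.e. the sampling error a
    recovery test should tolerate.

    ``membership`` is (n_clusters, n_transcripts) 0/1; ``profiles`` is
    (n_clusters, n_residues) percent compositions.
    """
    w = np.asarray(weights, float)
    l = np.asarray(lengths, float)
    p = w * l
    p = p / p.sum()
    c = library_size * p  # expected counts
    u = c / l
    U = u.sum()
    s = u / U
    # J[t, j] = d s_t / d c_j = (delta_tj - s_t) / (l_j * U)
    n = len(w)
    J = (np.eye(n) - s[:, None]) / (l[None, :] * U)
    cov_c = library_size * (np.diag(p) - np.outer(p, p))
    cov_s = J @ cov_c @ J.T
    cov_S = membership @ cov_s @ membership.T
    var_pred = np.einsum("kr,kl,lr->r", profiles, cov_S, profiles)
    return np.sqrt(np.maximum(var_pred, 0.0))


def write_synthetic_dataset(
    out_dir: str | Path,
    class_mix: dict[str, int],
    seed: int = 0,
    library_size: int = 1_000_000,
    n_replicates: int = 2,
    **kwargs,
) -> dict[str, Path]:
    """Generate and write a full synthetic dataset (FASTA + counts + truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nts, prots, manifest = gen_transcriptome(class_mix, seed=seed, **kwargs)
    lengths = {r.id: len(r.residues) for r in nts}
    tables = [
        gen_counts(
            manifest, lengths, library_size,
            seed=seed + 1 + i, replicate=f"rep{i + 1}",
        )
        for i in range(n_replicates)
    ]
    paths = {
        "proteins": out / "proteins.fasta",
        "transcripts": out / "transcripts.fasta",
        "counts": out / "counts.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(prots, paths["proteins"])
    write_fasta(nts, paths["transcripts"])
    write_table(pd.concat(tables, ignore_index=True), paths["counts"])
    write_table(manifest.to_frame(), paths["truth"])
    return paths
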