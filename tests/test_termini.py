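import numpy as np
import pytest

from spidrokit.seqio import SequenceRecord
from spidrokit.synth import (
    BASE_CTD_MASP,
    UNIT_TEMPLATES,
    mutate,
    reference_library,
)
from spidrokit.termini import (
    TerminiError,
    cluster_ctermini,
    find_termini,
    select_representatives,
)


def _lib_map(ref_library):
    return {r.id: r.residues for r in ref_library}


def test_find_termini_recovers_true_spans(ref_library):
    lib = _lib_map(ref_library)
    repeats = UNIT_TEMPLATES["masp4"] * 5
    seq = SequenceRecord("q", lib["NTD_MaSp"] + repeats + lib["CTD_MaSp4"], "protein")
    hits = {h.kind: h for h in find_termini(seq, ref_library)}
    assert set(hits) == {"NTD", "CTD"}
    assert hits["NTD"].span == (0, len(lib["NTD_MaSp"]))
    assert hits["CTD"].span == (len(seq.residues) - len(lib["CTD_MaSp4"]), len(seq.residues))
    assert hits["NTD"].reference_id == "NTD_MaSp"
    assert hits["CTD"].reference_id == "CTD_MaSp4"
    assert hits["CTD"].identity == pytest.approx(100.0)


def test_pure_repeats_have_no_termini(ref_library):
    seq = SequenceRecord("r", UNIT_TEMPLATES["masp1"] * 8, "protein")
    assert find_termini(seq, ref_library) == []


def test_diverged_ctd_identity_tracks_divergence(ref_library):
    lib = _lib_map(ref_library)
    rng = np.random.default_rng(42)
    ctd = mutate(lib["CTD_MaSp1"], 0.10, rng)
    seq = SequenceRecord("d", UNIT_TEMPLATES["masp1"] * 6 + ctd, "protein")
    hits = {h.kind: h for h in find_termini(seq, ref_library)}
    assert hits["CTD"].reference_id == "CTD_MaSp1"
    assert hits["CTD"].identity == pytest.approx(90.0, abs=3.0)


def test_nucleotide_query_rejected(ref_library):
    seq = SequenceRecord("n", "ACGT" * 30, "nucleotide")
    with pytest.raises(TerminiError):
        find_termini(seq, ref_library)


def _ctd_sequences(ctds, lengths=None):
    """Build records ending in the given CTDs plus their CTD hits."""
    from spidrokit.termini import TerminalDomainHit

    seqs, hits = [], {}
    for i, ctd in enumerate(ctds):
        pad = "GPGGQGPGQQ" * ((lengths[i] if lengths else 100) // 10)
        sid = f"s{i}"
        seq = pad + ctd
        seqs.append(SequenceRecord(sid, seq, "protein"))
        hits[sid] = TerminalDomainHit(
            sid, "CTD", (len(pad), len(seq)), "CTD_MaSp1", 100.0, 500.0
        )
    return seqs, hits


def test_identical_ctds_form_one_cluster():
    seqs, hits = _ctd_sequences([BASE_CTD_MASP, BASE_CTD_MASP])
    clusters = cluster_ctermini(seqs, hits)
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == ["s0", "s1"]


def test_threshold_boundary_is_inclusive():
    """CTDs of length 100 differing at exactly 5 positions sit at 95.0%
    identity and must co-cluster."""
    ctd = ("ACDEFGHIKLMNPQRSTVWY" * 5)[:100]
    mutated = list(ctd)
    for pos in (10, 30, 50, 70, 90):  # internal, so no end-gap ambiguity
        mutated[pos] = "W" if ctd[pos] != "W" else "Y"
    mutated = "".join(mutated)
    assert sum(1 for x, y in zip(ctd, mutated) if x != y) == 5
    seqs, hits = _ctd_sequences([ctd, mutated], lengths=[200, 100])
    clusters = cluster_ctermini(seqs, hits, threshold=95.0)
    assert len(clusters) == 1


def test_three_families_make_three_clusters(ref_library):
    """3 CTD families, pairwise within-family divergence ~2% (each member
    1% from the family base), between-family ~50%."""
    lib = _lib_map(ref_library)
    rng = np.random.default_rng(8)
    ctds = []
    for fam in ("CTD_MaSp1", "CTD_MaSp2", "CTD_MaSp4"):
        for _ in range(3):
            ctds.append(mutate(lib[fam], 0.01, rng))
    seqs, hits = _ctd_sequences(ctds)
    clusters = cluster_ctermini(seqs, hits)
    assert len(clusters) == 3
    for cl in clusters:
        assert all(v >= 95.0 for v in cl.identities.values())


def test_every_sequence_in_exactly_one_cluster(ref_library):
    lib = _lib_map(ref_library)
    rng = np.random.default_rng(9)
    ctds = [mutate(lib["CTD_MaSp2"], 0.02, rng) for _ in range(6)]
    ctds += [mutate(lib["CTD_TuSp"], 0.02, rng) for _ in range(4)]
    seqs, hits = _ctd_sequences(ctds)
    clusters = cluster_ctermini(seqs, hits)
    members = [m for cl in clusters for m in cl.member_ids]
    assert sorted(members) == sorted(s.id for s in seqs)


def test_representative_is_longest_with_id_tiebreak():
    from spidrokit.termini import TerminalDomainHit

    ctd = BASE_CTD_MASP
    seqs = [
        SequenceRecord("b", "GPGGQGPGQQ" * 10 + ctd, "protein"),
        SequenceRecord("a", "GPGGQGPGQQ" * 10 + ctd, "protein"),
        SequenceRecord("c", "GPGGQGPGQQ" * 25 + ctd, "protein"),
    ]
    hits = {
        s.id: TerminalDomainHit(
            s.id, "CTD", (len(s.residues) - len(ctd), len(s.residues)),
            "CTD_MaSp1", 100.0, 500.0,
        )
        for s in seqs
    }
    clusters = cluster_ctermini(seqs, hits)
    assert len(clusters) == 1
    assert clusters[0].representative_id == "c"
    reps = select_representatives(clusters, seqs)
    assert [r.id for r in reps] == ["c"]
    # drop the long one: tie between a and b resolves lexicographically
    short = [s for s in seqs if s.id != "c"]
    clusters = cluster_ctermini(short, hits)
    assert clusters[0].representative_id == "a"


def test_fourteen_families_give_fourteen_representatives():
    """A fixture with 14 distinct CTD groups yields 14 clusters, the
    group-count scale of a real silk-gland transcriptome survey."""
    rng = np.random.default_rng(14)
    base = BASE_CTD_MASP
    ctds = []
    for _ in range(14):
        fam = mutate(base, 0.30, rng)  # families far apart
        ctds.append(fam)
        ctds.append(mutate(fam, 0.01, rng))  # one close variant each
    seqs, hits = _ctd_sequences(ctds)
    clusters = cluster_ctermini(seqs, hits)
    reps = select_representatives(clusters, seqs)
    assert len(reps) == 14


def test_threshold_validation():
    seqs, hits = _ctd_sequences([BASE_CTD_MASP])
    with pytest.raises(TerminiError):
        cluster_ctermini(seqs, hits, threshold=0.0)
    with pytest.raises(TerminiError):
        cluster_ctermini(seqs, hits, threshold=101.0)
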