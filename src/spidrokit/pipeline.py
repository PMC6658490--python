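"""End-to-end analysis: termini -> clustering -> repeats -> motifs -> GOR,
with expression-weighted composition prediction and optional morphometry.

Given protein sequences, a terminal-domain reference library, and a counts
table, :func:`run_pipeline` reproduces the analysis chain: detect and
cluster C-terminal domains, decompose each cluster representative into its
ensemble repeats, score motif occupancy and call the MaSp class, compute
per-replicate TPM and aggregate it over clusters, predict the fiber
composition as the TPM-share-weighted mixture of repetitive-region
compositions, and predict secondary-structure fractions for each consensus
repeat. All outputs are tab-separated text plus a YAML config snapshot; a
rerun under the same inputs and config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import composition as comp
from . import expression as expr
from . import gor as gormod
from . import motifs as motifmod
from . import repeats as repeatmod
from . import termini as terminimod
from .config import PipelineConfig
from .seqio import SequenceRecord, write_fasta, write_table
from .synth import reference_family

log = logging.getLogger("spidrokit")


@dataclass
class PipelineResult:
    clusters: list[terminimod.TerminiCluster]
    decompositions: dict[str, repeatmod.RepeatDecomposition]
    annotations: dict[str, motifmod.MotifAnnotation]
    class_calls: dict[str, motifmod.SpidroinClassCall]
    aggregated: list[expr.AggregatedExpression] = field(default_factory=list)
    prediction: comp.WeightedPrediction | None = None
    gor_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    ctd_families: dict[str, str] = field(default_factory=dict)


def run_pipeline(
    proteins: list[SequenceRecord],
    reference: list[SequenceRecord],
    counts: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full chain; write per-stage tables when ``out_dir`` is set."""
    cfg = config or PipelineConfig()
    grammar = motifmod.MotifGrammar(
        gpgx_alphabet=frozenset(cfg.gpgx_alphabet), polya_min_run=cfg.polya_min_run
    )
    gor_model = gormod.GorModel.load(decision_constants=cfg.gor_decision_constants)

    # stage 1: terminal domains
    hits: dict[str, list[terminimod.TerminalDomainHit]] = {}
    ctd_hits: dict[str, terminimod.TerminalDomainHit] = {}
    for p in proteins:
        found = terminimod.find_termini(
            p, reference, cfg.min_hit_identity, cfg.min_hit_length
        )
        hits[p.id] = found
        for h in found:
            if h.kind == "CTD":
                ctd_hits[p.id] = h
    with_ctd = [p for p in proteins if p.id in ctd_hits]
    dropped = [p.id for p in proteins if p.id not in ctd_hits]
    if dropped:
        log.info("no CTD hit, excluded from clustering: %s", dropped)
    if not with_ctd:
        raise terminimod.TerminiError("no sequence has a detectable CTD")

    # stage 2: clustering and representatives
    clusters = terminimod.cluster_ctermini(with_ctd, ctd_hits, cfg.identity_threshold)
    reps = terminimod.select_representatives(clusters, with_ctd)
    families = {
        cl.cluster_id: reference_family(ctd_hits[cl.representative_id].reference_id)
        for cl in clusters
    }

    # stage 3-5: repeats, motifs, classification, GOR per representative
    decomps: dict[str, repeatmod.RepeatDecomposition] = {}
    annotations: dict[str, motifmod.MotifAnnotation] = {}
    calls: dict[str, motifmod.SpidroinClassCall] = {}
    gor_fracs: dict[str, dict[str, float]] = {}
    for cl, rep in zip(clusters, reps):
        dec = repeatmod.decompose(
            rep, hits[rep.id], cfg.min_period, cfg.max_period, cfg.harmonic_window
        )
        decomps[cl.cluster_id] = dec
        ann = motifmod.scan_motifs(dec.consensus, region_id=cl.cluster_id, grammar=grammar)
        annotations[cl.cluster_id] = ann
        calls[cl.cluster_id] = motifmod.classify_spidroin(
            ann, families[cl.cluster_id], cfg.masp4_gpgpq_min
        )
        pred = gormod.predict(dec.consensus, gor_model, sequence_id=cl.cluster_id)
        gor_fracs[cl.cluster_id] = gormod.state_fractions(pred)

    result = PipelineResult(
        clusters=clusters,
        decompositions=decomps,
        annotations=annotations,
        class_calls=calls,
        gor_fractions=gor_fracs,
        ctd_families=families,
    )

    # stage 6-7: expression aggregation and weighted composition prediction
    if counts is not None:
        records = expr.compute_tpm(counts)
        agg = expr.aggregate_by_ctd(records, clusters)
        result.aggregated = expr.rank_spidroins(agg)
        profiles = [
            comp.aa_composition(
                rep, span=decomps[cl.cluster_id].repetitive_span,
                region_kind="repetitive",
            )
            for cl, rep in zip(clusters, reps)
        ]
        order = {cl.cluster_id: i for i, cl in enumerate(clusters)}
        weights = [0.0] * len(clusters)
        for a in result.aggregated:
            weights[order[a.cluster_id]] = a.mean_tpm
        result.prediction = comp.weighted_prediction(profiles, weights)
    else:
        log.info("no counts table: composition prediction skipped")

    if out_dir is not None:
        _write_outputs(Path(out_dir), cfg, result, reps)
    return result


def _write_outputs(
    out: Path,
    cfg: PipelineConfig,
    result: PipelineResult,
    reps: list[SequenceRecord],
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    cluster_rows = []
    for cl in result.clusters:
        for m in sorted(cl.member_ids):
            cluster_rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "member_id": m,
                    "is_representative": int(m == cl.representative_id),
                    "identity_to_centroid": round(cl.identities[m], 3),
                    "ctd_family": result.ctd_families[cl.cluster_id],
                }
            )
    write_table(pd.DataFrame(cluster_rows), out / "clusters.tsv")

    repeat_rows = []
    for cid, dec in result.decompositions.items():
        ann = result.annotations[cid]
        repeat_rows.append(
            {
                "cluster_id": cid,
                "representative": dec.sequence_id,
                "unit_length": dec.unit_length,
                "n_units": dec.n_units,
                "mean_identity": round(dec.mean_identity, 2),
                "class_call": result.class_calls[cid].label,
                "gpgpq_occupancy": round(ann.occupancy("GPGPQ"), 2),
                "polya_occupancy": round(ann.occupancy("polyA"), 2),
                "ggx_occupancy": round(ann.occupancy("GGX"), 2),
                "gpgx_occupancy": round(ann.gpgx_like_occupancy(), 2),
                "turn_percent": round(result.gor_fractions[cid]["turn"], 2),
            }
        )
    write_table(pd.DataFrame(repeat_rows), out / "repeats.tsv")

    write_fasta(
        [
            SequenceRecord(cid, dec.consensus, "protein", "consensus repeat")
            for cid, dec in result.decompositions.items()
        ],
        out / "consensus.fasta",
    )

    if result.aggregated:
        write_table(expr.expression_table(result.aggregated), out / "expression.tsv")
    if result.prediction is not None:
        pred = result.prediction.predicted
        write_table(
            pd.DataFrame(
                {"residue": list(pred.percents), "percent": list(pred.percents.values())}
            ),
            out / "predicted_composition.tsv",
        )
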