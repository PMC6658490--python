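"""Amino-acid composition profiling and expression-weighted fiber prediction.

Dragline fiber is a mixture of the spidroins its gland expresses, so the
fiber's amino-acid composition should be predictable as the abundance-
weighted average of the component proteins' compositions. This module
computes percent-molarity profiles (direct residue counting, ambiguous X
excluded from numerator and denominator), convex TPM-share-weighted
mixture predictions, and comparisons against measured hydrolysis profiles
(which cannot distinguish Q from E or N from D, hence the pooled Glx and
Asx accessors).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seqio import PROTEIN_ALPHABET, SequenceRecord

AMINO_ACIDS = tuple(sorted(PROTEIN_ALPHABET))


class CompositionError(ValueError):
    pass


@dataclass
class CompositionProfile:
    """Percent molarity per amino acid for a sequence region or a sample."""

    source_id: str
    region_kind: str  # whole | repetitive | terminal | fiber-measured | gland-measured
    percents: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aa, v in self.percents.items():
            if v < 0:
                raise CompositionError(f"{self.source_id}: negative percent for {aa}")
        total = sum(self.percents.values())
        if abs(total - 100.0) > 1e-6:
            raise CompositionError(
                f"{self.source_id}: percents sum to {total!r}, expected 100"
            )

    def __getitem__(self, aa: str) -> float:
        return self.percents.get(aa, 0.0)

    @property
    def glx(self) -> float:
        """Q + E pooled (hydrolysis cannot distinguish them)."""
        return self["Q"] + self["E"]

    @property
    def asx(self) -> float:
        """N + D pooled."""
        return self["N"] + self["D"]

    def top_residues(self, n: int = 5) -> list[str]:
        return sorted(self.percents, key=lambda a: (-self[a], a))[:n]

    def as_vector(self) -> np.ndarray:
        return np.array([self[aa] for aa in AMINO_ACIDS])


def aa_composition(
    seq: SequenceRecord | str,
    span: tuple[int, int] | None = None,
    source_id: str | None = None,
    region_kind: str = "whole",
) -> CompositionProfile:
    """Percent molarity per residue over ``span`` (default: whole sequence).

    Ambiguous ``X`` residues are excluded from both numerator and
    denominator.
    """
    if isinstance(seq, SequenceRecord):
        residues, sid = seq.residues, seq.id
    else:
        residues, sid = seq, source_id or "seq"
    if span is not None:
        residues = residues[span[0] : span[1]]
        region_kind = region_kind if region_kind != "whole" else "repetitive"
    counts = Counter(c for c in residues if c != "X")
    total = sum(counts.values())
    if total == 0:
        raise CompositionError(f"{sid}: empty (or all-ambiguous) span")
    percents = {aa: 100.0 * counts.get(aa, 0) / total for aa in AMINO_ACIDS}
    return CompositionProfile(source_id=sid, region_kind=region_kind, percents=percents)


def profile_from_percents(
    source_id: str, percents: dict[str, float], region_kind: str = "fiber-measured"
) -> CompositionProfile:
    """Build a measured profile, renormalising minor rounding in the input."""
    total = sum(percents.values())
    if total <= 0:
        raise CompositionError(f"{source_id}: non-positive total")
    scaled = {aa: 100.0 * v / total for aa, v in percents.items() if v != 0}
    return CompositionProfile(source_id, region_kind, scaled)


@dataclass
class WeightedPrediction:
    """Convex combination of component profiles under normalised weights."""

    component_ids: list[str]
    weights: list[float]
    predicted: CompositionProfile

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise CompositionError("weights must sum to 1")


def weighted_prediction(
    profiles: list[CompositionProfile],
    weights: list[float],
    prediction_id: str = "predicted_fiber",
) -> WeightedPrediction:
    """Predicted mixture composition: sum_i weight_i x percent_i per residue.

    ``weights`` are raw abundances (e.g. aggregated TPM) and are normalised
    to sum 1. Every predicted percent is convex, i.e. lies within the
    componentwise [min, max].
    """
    if not profiles:
        raise CompositionError("no component profiles")
    if len(profiles) != len(weights):
        raise CompositionError("profiles and weights differ in length")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise CompositionError("weights must be >= 0 and not all zero")
    w = w / w.sum()
    percents = {
        aa: float(sum(wi * p[aa] for wi, p in zip(w, profiles)))
        for aa in AMINO_ACIDS
    }
    pred = CompositionProfile(prediction_id, "whole", percents)
    return WeightedPrediction([p.source_id for p in profiles], list(w), pred)


@dataclass
class ProfileComparison:
    differences: dict[str, float]  # signed, predicted - measured
    max_abs_difference: float
    top5_concordance: float  # Kendall tau over the measured top-5 residues


def compare_profiles(
    pred: CompositionProfile, measured: CompositionProfile, pool_ambiguous: bool = True
) -> ProfileComparison:
    """Signed per-residue differences plus a rank-concordance summary.

    With ``pool_ambiguous`` (the default for hydrolysis data) Q+E are
    compared as Glx and N+D as Asx. Concordance is the Kendall tau between
    predicted and measured values over the measured top-5 residues.
    """
    def keyed(profile: CompositionProfile) -> dict[str, float]:
        if not pool_ambiguous:
            return {aa: profile[aa] for aa in AMINO_ACIDS}
        out = {aa: profile[aa] for aa in AMINO_ACIDS if aa not in "QEND"}
        out["Glx"] = profile.glx
        out["Asx"] = profile.asx
        return out

    p, m = keyed(pred), keyed(measured)
    diffs = {k: p[k] - m[k] for k in m}
    top5 = sorted(m, key=lambda k: (-m[k], k))[:5]
    tau = stats.kendalltau([p[k] for k in top5], [m[k] for k in top5]).statistic
    return ProfileComparison(
        differences=diffs,
        max_abs_difference=max(abs(d) for d in diffs.values()),
        top5_concordance=float(tau),
    )
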