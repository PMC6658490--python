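"""Silk-gland morphometry statistics.

Major ampullate glands split into tail, ampullate sac, and the S-shaped
spinning duct where the fiber assembles; duct length is the comparative
quantity of interest across species. Inputs are measurement tables
(species, individual, duct_mm, sac_mm). Statistics are mean +/- sample SD
summaries, Student (pooled-variance) two-tailed unpaired t-tests between
species, and per-individual duct/sac length ratios. The pooled-variance
form is used because it reproduces the reference duct-length t statistics
exactly from summary data, where the Welch form does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import TableSchema

MORPHO_SCHEMA = TableSchema(
    columns={
        "species": "text",
        "individual": "text",
        "duct_mm": "length_mm",
        "sac_mm": "length_mm",
    },
    optional=("sac_mm",),
)


class MorphoError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSummary:
    """n, mean and sample SD (n - 1 denominator) of one group, in mm."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise MorphoError("empty group")
        if self.sd < 0:
            raise MorphoError("negative SD")

    @property
    def testable(self) -> bool:
        return self.n >= 2


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    pooled_sd: float


def summarize(values: list[float] | np.ndarray, group: str = "group") -> SampleSummary:
    """Mean +/- sample SD summary; a single value gets sd = 0 and is
    flagged untestable via ``n = 1``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise MorphoError(f"group {group!r}: no measurements")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return SampleSummary(group, int(v.size), float(np.mean(v)), sd)


def summarize_table(
    measurements: pd.DataFrame, column: str = "duct_mm"
) -> dict[str, SampleSummary]:
    """Per-species summaries of one length column."""
    return {
        sp: summarize(sub[column].to_numpy(), group=sp)
        for sp, sub in measurements.groupby("species", sort=True)
    }


def pooled_ttest(a: SampleSummary, b: SampleSummary) -> TTestResult:
    """Student's pooled-variance two-tailed unpaired t-test from summaries.

    t = (mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b)) with
    s_p^2 = ((n_a - 1) sd_a^2 + (n_b - 1) sd_b^2) / (n_a + n_b - 2);
    the two-tailed p comes from the t distribution with n_a + n_b - 2 df.
    """
    if not (a.testable and b.testable):
        raise MorphoError("both groups need n >= 2")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        if a.mean == b.mean:
            raise MorphoError("zero pooled variance with equal means: t undefined")
        return TTestResult(float(np.inf) * np.sign(a.mean - b.mean), df, 0.0, 0.0)
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return TTestResult(float(res.statistic), df, float(res.pvalue), float(np.sqrt(sp2)))


def duct_sac_ratio(measurements: pd.DataFrame, species: str) -> SampleSummary:
    """Per-individual duct/sac length ratio, summarised as mean +/- SD."""
    sub = measurements[measurements["species"] == species]
    if sub.empty:
        raise MorphoError(f"no measurements for species {species!r}")
    if "sac_mm" not in sub.columns or sub["sac_mm"].isna().any():
        raise MorphoError(f"species {species!r}: sac lengths missing")
    if (sub["duct_mm"] <= 0).any() or (sub["sac_mm"] <= 0).any():
        raise MorphoError("non-positive length")
    ratios = (sub["duct_mm"] / sub["sac_mm"]).to_numpy()
    return summarize(ratios, group=f"{species} duct/sac")
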