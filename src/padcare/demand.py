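"""Demand-category assessment from indicator means and dispersions.

Each indicator's demand for improvement is classified against its system
part's pooled benchmark. With ``m_i, s_i`` the indicator's mean and SD and
``m_b, s_b`` the part benchmark (mean and SD of all pooled scores of the
part's indicators):

* ``s_i < s_b`` and ``m_i > m_b``  → **positive** demand — respondents use
  the touchpoint and clearly endorse it;
* ``s_i < s_b`` and ``m_i ≤ m_b``  → **unactivated** demand — consistent
  responses without clear endorsement;
* ``s_i ≥ s_b``                    → **potential** demand — dispersed,
  conflicted responses regardless of the mean.

The SD gate deciding *potential* before the mean is consulted is the single
rule consistent with every published classification, including the potential
rows whose means fall below the benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd

from .codebook import Codebook, SystemPart

__all__ = [
    "CATEGORIES",
    "GroupBenchmark",
    "DemandAssessment",
    "group_benchmark",
    "indicator_stats",
    "classify_demand",
    "assess_all",
    "assess_from_stats",
    "summarize",
]

CATEGORIES = ("positive", "unactivated", "potential")


@dataclass(frozen=True)
class GroupBenchmark:
    """Pooled mean/SD benchmark of one system part."""

    part: SystemPart
    mean_b: float
    sd_b: float

    def __post_init__(self):
        if self.sd_b < 0:
            raise ValueError("benchmark SD must be non-negative")


@dataclass(frozen=True)
class DemandAssessment:
    """One indicator's demand classification against its part benchmark."""

    indicator: str
    mean_i: float
    sd_i: float
    gt_mean: bool
    lt_sd: bool
    category: str


def _scores_for(scores: pd.DataFrame, codes: Iterable[str]) -> np.ndarray:
    sub = scores[scores["indicator_code"].isin(set(codes))]
    return pd.to_numeric(sub["score"]).to_numpy(dtype=float)


def group_benchmark(
    scores: pd.DataFrame,
    codebook: Codebook,
    part: SystemPart | str,
    ddof: int = 1,
) -> GroupBenchmark:
    """Benchmark mean/SD of all pooled scores of a part's indicators.

    ``ddof=1`` (sample SD) is the default convention; ``ddof=0`` selects the
    population SD.
    """
    part = SystemPart(part)
    codes = [ind.code for ind in codebook.in_part(part)]
    pooled = _scores_for(scores, codes)
    if pooled.size < 2:
        raise ValueError(f"insufficient data: <2 pooled scores for {part.value}")
    return GroupBenchmark(
        part=part,
        mean_b=float(pooled.mean()),
        sd_b=float(pooled.std(ddof=ddof)),
    )


def indicator_stats(
    scores: pd.DataFrame, indicator: str, ddof: int = 1
) -> tuple[float, float]:
    """Mean and SD of one indicator's scores (same SD convention as the benchmark)."""
    vals = _scores_for(scores, [indicator])
    if vals.size < 2:
        raise ValueError(f"insufficient data: <2 scores for {indicator}")
    return float(vals.mean()), float(vals.std(ddof=ddof))


def classify_demand(
    mean_i: float,
    sd_i: float,
    bench: GroupBenchmark,
    tie_policy: str = "strict",
) -> DemandAssessment:
    """Apply the mean/SD rule for one indicator.

    ``tie_policy`` resolves exact equality with the benchmark: ``'strict'``
    (default) treats equality as "not greater" / "not less", so an indicator
    exactly at the benchmark SD is *potential*; ``'inclusive'`` counts
    equality as exceeding.
    """
    if tie_policy not in ("strict", "inclusive"):
        raise ValueError(f"tie_policy must be 'strict' or 'inclusive', got {tie_policy!r}")
    if not all(np.isfinite([mean_i, sd_i, bench.mean_b, bench.sd_b])):
        raise ValueError("non-finite inputs to demand classification")
    if tie_policy == "strict":
        gt_mean = mean_i > bench.mean_b
        lt_sd = sd_i < bench.sd_b
    else:
        gt_mean = mean_i >= bench.mean_b
        lt_sd = sd_i <= bench.sd_b
    if not lt_sd:
        category = "potential"
    elif gt_mean:
        category = "positive"
    else:
        category = "unactivated"
    return DemandAssessment(
        indicator="", mean_i=mean_i, sd_i=sd_i,
        gt_mean=gt_mean, lt_sd=lt_sd, category=category,
    )


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), ROUND_HALF_UP))


def summarize(assessments: pd.DataFrame) -> dict:
    """Category counts and half-up percentages over the assessed indicators."""
    n = len(assessments)
    counts = {c: int((assessments["category"] == c).sum()) for c in CATEGORIES}
    pct = {c: _round_half_up(100.0 * counts[c] / n) for c in CATEGORIES}
    return {"n_indicators": n, "counts": counts, "percentages": pct}


def _assemble(
    records: list[DemandAssessment],
    benches: dict[SystemPart, GroupBenchmark],
    codebook: Codebook,
) -> pd.DataFrame:
    rows = []
    for a in records:
        part = codebook.part_of(a.indicator)
        b = benches[part]
        rows.append(
            {
                "indicator_code": a.indicator,
                "system_part": part.value,
                "mean": a.mean_i,
                "sd": a.sd_i,
                "benchmark_mean": b.mean_b,
                "benchmark_sd": b.sd_b,
                "gt_mean": a.gt_mean,
                "lt_sd": a.lt_sd,
                "category": a.category,
            }
        )
    return pd.DataFrame(rows)


def assess_all(
    scores: pd.DataFrame,
    codebook: Codebook,
    ddof: int = 1,
    tie_policy: str = "strict",
) -> tuple[pd.DataFrame, dict]:
    """Assess every indicator present in ``scores`` from raw demand scores.

    Returns the per-indicator assessment table and the category summary.
    """
    present = set(scores["indicator_code"])
    codebook.check_codes(present)
    benches: dict[SystemPart, GroupBenchmark] = {}
    records = []
    for ind in codebook:
        if ind.code not in present:
            continue
        if ind.part not in benches:
            benches[ind.part] = group_benchmark(scores, codebook, ind.part, ddof=ddof)
        m, s = indicator_stats(scores, ind.code, ddof=ddof)
        a = classify_demand(m, s, benches[ind.part], tie_policy=tie_policy)
        records.append(DemandAssessment(ind.code, m, s, a.gt_mean, a.lt_sd, a.category))
    table = _assemble(records, benches, codebook)
    return table, summarize(table)


def assess_from_stats(
    stats: pd.DataFrame,
    codebook: Codebook,
    tie_policy: str = "strict",
) -> tuple[pd.DataFrame, dict]:
    """Assess indicators from a pre-aggregated mean/SD table.

    ``stats`` has columns ``indicator_code, mean, sd``; rows whose code is a
    system-part name supply that part's benchmark, all other rows are
    indicators. Every assessed indicator's part must have a benchmark row.
    """
    part_names = {p.value for p in SystemPart}
    is_bench = stats["indicator_code"].isin(part_names)
    benches = {
        SystemPart(r.indicator_code): GroupBenchmark(
            SystemPart(r.indicator_code), float(r.mean), float(r.sd)
        )
        for r in stats[is_bench].itertuples()
    }
    ind_rows = stats[~is_bench]
    codebook.check_codes(ind_rows["indicator_code"])
    records = []
    for r in ind_rows.itertuples():
        part = codebook.part_of(r.indicator_code)
        if part not in benches:
            raise ValueError(f"no benchmark row for part {part.value}")
        a = classify_demand(float(r.mean), float(r.sd), benches[part], tie_policy)
        records.append(
            DemandAssessment(r.indicator_code, float(r.mean), float(r.sd),
                             a.gt_mean, a.lt_sd, a.category)
        )
    table = _assemble(records, benches, codebook)
    return table, summarize(table)
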