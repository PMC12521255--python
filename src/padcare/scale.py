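"""PAD scoring and nearest-benchmark emotion classification.

The emotional experience of a service touchpoint is measured with a
12-item semantic-differential questionnaire: bipolar adjective pairs scored
on a nine-point grid from −4 to +4. Four items load on each PAD dimension
(pleasure, arousal, dominance), half of them with reversed orientation, and
the dimension score is the signed mean of its four items:

    P = (C1 − C4 + C7 − C10) / 4
    A = (−C2 + C5 − C8 + C11) / 4
    D = (C3 − C6 + C9 − C12) / 4

A measured ``(P, A, D)`` point is then classified by Euclidean proximity to
eight benchmark emotions with normative PAD coordinates (Joy, Relaxation,
Surprise, Reliance — positive polarity; Boredom, Fear, Anxiety, Anger —
negative). The nearest benchmark is the indicator's emotional tendency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import Codebook

__all__ = [
    "ITEM_CODES",
    "ITEM_SIGNS",
    "DIMENSION_ITEMS",
    "PADScore",
    "EmotionBenchmark",
    "EmotionTendencyResult",
    "ValidatedResponses",
    "validate_responses",
    "aggregate_items",
    "aggregate_all",
    "compute_pad",
    "proximity",
    "classify_emotion",
    "evaluate_all",
]

SCALE_MIN, SCALE_MAX = -4, 4

ITEM_CODES: tuple[str, ...] = tuple(f"C{k}" for k in range(1, 13))

#: signed loading of each item on its PAD dimension
DIMENSION_ITEMS: dict[str, tuple[tuple[str, int], ...]] = {
    "P": (("C1", +1), ("C4", -1), ("C7", +1), ("C10", -1)),
    "A": (("C2", -1), ("C5", +1), ("C8", -1), ("C11", +1)),
    "D": (("C3", +1), ("C6", -1), ("C9", +1), ("C12", -1)),
}

ITEM_SIGNS: dict[str, tuple[str, int]] = {
    item: (dim, sign)
    for dim, items in DIMENSION_ITEMS.items()
    for item, sign in items
}


@dataclass(frozen=True)
class PADScore:
    """A measured pleasure/arousal/dominance point for one indicator."""

    P: float
    A: float
    D: float
    indicator: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.A, self.D], dtype=float)


@dataclass(frozen=True)
class EmotionBenchmark:
    """A named benchmark emotion with normative PAD coordinates.

    Codes 01–04 carry positive polarity, 05–08 negative.
    """

    no: str
    name: str
    P: float
    A: float
    D: float
    polarity: str

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        expected = "positive" if self.no in ("01", "02", "03", "04") else "negative"
        if self.polarity != expected:
            raise ValueError(
                f"benchmark {self.no} ({self.name}): polarity {self.polarity!r} "
                f"inconsistent with code group"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.A, self.D], dtype=float)


@dataclass(frozen=True)
class EmotionTendencyResult:
    """Distances of one indicator's PAD point to all benchmarks and the argmin."""

    indicator: str | None
    pad: PADScore
    distances: dict[str, float]
    tendency: str
    polarity: str
    tie: bool = False
    tied_with: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class ValidatedResponses:
    """Respondent-level item scores partitioned into accepted and rejected rows."""

    accepted: pd.DataFrame
    rejected: pd.DataFrame

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


RESPONSE_COLUMNS = ("respondent_id", "indicator_code", "item_code", "score")


def _check_benchmarks(benchmarks: Sequence[EmotionBenchmark]) -> tuple[EmotionBenchmark, ...]:
    benchmarks = tuple(benchmarks)
    names = [b.name for b in benchmarks]
    if len(benchmarks) != 8 or len(set(names)) != 8:
        raise ValueError(
            f"benchmark set must contain exactly 8 distinct emotions, got {names}"
        )
    return benchmarks


def validate_responses(
    responses: pd.DataFrame, codebook: Codebook
) -> ValidatedResponses:
    """Partition raw item responses into accepted rows and rejected rows.

    Rejection reasons: ``out_of_range`` (score not an integer in [−4, +4]),
    ``unknown_indicator``, ``unknown_item``, and ``duplicate`` (a repeated
    (respondent, indicator, item) triple; the first occurrence is kept).

    Raises
    ------
    ValueError
        If ``responses`` is empty ("no responses") or columns are missing.
    """
    missing = set(RESPONSE_COLUMNS) - set(responses.columns)
    if missing:
        raise ValueError(f"responses table missing columns: {sorted(missing)}")
    if len(responses) == 0:
        raise ValueError("no responses")

    df = responses.loc[:, list(RESPONSE_COLUMNS)].copy()
    score = pd.to_numeric(df["score"], errors="coerce")
    integral = score.notna() & (score == np.round(score))
    in_range = integral & (score >= SCALE_MIN) & (score <= SCALE_MAX)

    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    reason[~in_range] = "out_of_range"
    known_ind = df["indicator_code"].isin(codebook.codes)
    reason[reason.isna() & ~known_ind] = "unknown_indicator"
    known_item = df["item_code"].isin(ITEM_CODES)
    reason[reason.isna() & ~known_item] = "unknown_item"
    dup = df.duplicated(subset=["respondent_id", "indicator_code", "item_code"])
    reason[reason.isna() & dup] = "duplicate"

    rejected = df[reason.notna()].assign(reason=reason[reason.notna()])
    accepted = df[reason.isna()].copy()
    accepted["score"] = score[reason.isna()].astype(int)
    return ValidatedResponses(accepted=accepted, rejected=rejected)


def _complete_wide(
    responses: pd.DataFrame, indicator: str, missing: str
) -> pd.DataFrame:
    sub = responses[responses["indicator_code"] == indicator]
    if len(sub) == 0:
        raise ValueError(f"insufficient data: no responses for {indicator}")
    wide = sub.pivot_table(
        index="respondent_id", columns="item_code", values="score", aggfunc="first"
    ).reindex(columns=list(ITEM_CODES))
    complete = wide.dropna()
    if missing == "error" and len(complete) < len(wide):
        bad = sorted(wide.index.difference(complete.index))
        raise ValueError(
            f"incomplete item sets for {indicator}: respondents {bad}"
        )
    if len(complete) == 0:
        raise ValueError(f"insufficient data: no complete respondent for {indicator}")
    return complete


def aggregate_items(
    responses: pd.DataFrame, indicator: str, missing: str = "drop"
) -> pd.Series:
    """Mean item scores C1…C12 for one indicator over complete respondents.

    ``missing='drop'`` (default) excludes respondents lacking any of the 12
    items for this indicator; ``missing='error'`` raises instead.
    """
    if missing not in ("drop", "error"):
        raise ValueError(f"missing policy must be 'drop' or 'error', got {missing!r}")
    complete = _complete_wide(responses, indicator, missing)
    means = complete.mean(axis=0)
    means.name = indicator
    return means


def aggregate_all(
    responses: pd.DataFrame, codebook: Codebook, missing: str = "drop"
) -> pd.DataFrame:
    """Item-means table (one row per indicator present in ``responses``)."""
    codes = [c for c in codebook.codes if c in set(responses["indicator_code"])]
    rows = [aggregate_items(responses, c, missing=missing) for c in codes]
    out = pd.DataFrame(rows)
    out.insert(0, "indicator_code", codes)
    return out.reset_index(drop=True)


def compute_pad(
    items: Mapping[str, float] | pd.Series, indicator: str | None = None
) -> PADScore:
    """Score the three PAD dimensions from the 12 item values.

    ``items`` maps item codes C1…C12 to (mean) scores; each dimension is the
    signed mean of its four items, so in-range items yield P, A, D in [−4, +4].
    """
    vals = {}
    for code in ITEM_CODES:
        try:
            vals[code] = float(items[code])
        except KeyError:
            raise ValueError(f"item {code} missing from input") from None
    dims = {
        dim: sum(sign * vals[code] for code, sign in loadings) / 4.0
        for dim, loadings in DIMENSION_ITEMS.items()
    }
    if indicator is None and isinstance(items, pd.Series):
        indicator = items.name if isinstance(items.name, str) else None
    return PADScore(P=dims["P"], A=dims["A"], D=dims["D"], indicator=indicator)


def proximity(pad: PADScore, bench: EmotionBenchmark) -> float:
    """Euclidean distance between a measured PAD point and a benchmark emotion."""
    d = pad.as_array() - bench.as_array()
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite PAD coordinates")
    return float(math.sqrt(float(d @ d)))


def classify_emotion(
    pad: PADScore, benchmarks: Sequence[EmotionBenchmark]
) -> EmotionTendencyResult:
    """Assign the benchmark emotion nearest to ``pad``.

    Requires the complete set of 8 benchmarks. Exact ties are broken toward
    the lowest benchmark code and flagged in the result.
    """
    benchmarks = _check_benchmarks(benchmarks)
    ordered = sorted(benchmarks, key=lambda b: b.no)
    distances = {b.name: proximity(pad, b) for b in ordered}
    dmin = min(distances.values())
    minimal = [b for b in ordered if distances[b.name] == dmin]
    winner = minimal[0]
    return EmotionTendencyResult(
        indicator=pad.indicator,
        pad=pad,
        distances=distances,
        tendency=winner.name,
        polarity=winner.polarity,
        tie=len(minimal) > 1,
        tied_with=tuple(b.name for b in minimal[1:]),
    )


def _is_item_means(df: pd.DataFrame) -> bool:
    return set(ITEM_CODES) <= set(df.columns)


def evaluate_all(
    data: pd.DataFrame,
    codebook: Codebook,
    benchmarks: Sequence[EmotionBenchmark],
    *,
    require_complete: bool = False,
    missing: str = "drop",
) -> pd.DataFrame:
    """Score and classify every indicator in ``data``.

    ``data`` is either an item-means table (``indicator_code`` plus C1…C12,
    one row per indicator) or a long respondent-level response table, which
    is validated and aggregated first. Returns one row per indicator with
    columns ``indicator_code, P, A, D, dist_<emotion>×8, tendency, polarity,
    tie``. With ``require_complete=True`` every codebook indicator must be
    present.
    """
    benchmarks = _check_benchmarks(benchmarks)
    if _is_item_means(data):
        means = data
    elif set(RESPONSE_COLUMNS) <= set(data.columns):
        validated = validate_responses(data, codebook)
        means = aggregate_all(validated.accepted, codebook, missing=missing)
    else:
        raise ValueError(
            "input must be an item-means table (indicator_code, C1..C12) or a "
            "response table (respondent_id, indicator_code, item_code, score)"
        )

    codebook.check_codes(means["indicator_code"])
    if require_complete:
        absent = sorted(set(codebook.codes) - set(means["indicator_code"]))
        if absent:
            raise ValueError(f"indicators missing from input: {absent}")

    order = {c: i for i, c in enumerate(codebook.codes)}
    means = means.sort_values("indicator_code", key=lambda s: s.map(order))

    bench_order = sorted(benchmarks, key=lambda b: b.no)
    rows = []
    for _, r in means.iterrows():
        pad = compute_pad(r[list(ITEM_CODES)], indicator=str(r["indicator_code"]))
        res = classify_emotion(pad, benchmarks)
        rows.append(
            {
                "indicator_code": r["indicator_code"],
                "P": pad.P,
                "A": pad.A,
                "D": pad.D,
                **{f"dist_{b.name}": res.distances[b.name] for b in bench_order},
                "tendency": res.tendency,
                "polarity": res.polarity,
                "tie": res.tie,
            }
        )
    return pd.DataFrame(rows)
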