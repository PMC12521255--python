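"""CSV readers and writers for the pipeline's external interfaces.

All readers normalize U+2212 (the typographic minus common in typeset
tables) to the ASCII hyphen-minus before parsing numbers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from .codebook import Codebook
from .scale import ITEM_CODES, RESPONSE_COLUMNS, EmotionBenchmark

__all__ = [
    "read_responses",
    "read_item_means",
    "read_benchmarks",
    "read_codebook",
    "read_demand_scores",
    "read_demand_stats",
    "write_table",
]

MINUS_SIGN = "−"


def _normalized(source: str | Path | IO[str]) -> _io.StringIO:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    return _io.StringIO(text.replace(MINUS_SIGN, "-"))


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns: {sorted(missing)}")


def read_responses(source: str | Path | IO[str]) -> pd.DataFrame:
    """Long respondent-level item scores: respondent_id, indicator_code, item_code, score."""
    df = pd.read_csv(_normalized(source), dtype={"respondent_id": str})
    _require(df, RESPONSE_COLUMNS, "responses")
    return df


def read_item_means(source: str | Path | IO[str]) -> pd.DataFrame:
    """Per-indicator item means: indicator_code plus C1…C12."""
    df = pd.read_csv(_normalized(source))
    _require(df, ("indicator_code", *ITEM_CODES), "item-means")
    return df


def read_benchmarks(source: str | Path | IO[str]) -> tuple[EmotionBenchmark, ...]:
    """Benchmark-emotion table: no, name, P, A, D, polarity."""
    df = pd.read_csv(_normalized(source), dtype={"no": str})
    _require(df, ("no", "name", "P", "A", "D", "polarity"), "benchmark")
    return tuple(
        EmotionBenchmark(
            no=str(row["no"]).zfill(2),
            name=str(row["name"]),
            P=float(row["P"]),
            A=float(row["A"]),
            D=float(row["D"]),
            polarity=str(row["polarity"]),
        )
        for _, row in df.iterrows()
    )


def read_codebook(source: str | Path | IO[str]) -> Codebook:
    return Codebook.from_frame(pd.read_csv(_normalized(source)))


def read_demand_scores(source: str | Path | IO[str]) -> pd.DataFrame:
    """Initial-questionnaire demand scores: respondent_id, indicator_code, score."""
    df = pd.read_csv(_normalized(source), dtype={"respondent_id": str})
    _require(df, ("respondent_id", "indicator_code", "score"), "demand-scores")
    return df


def read_demand_stats(source: str | Path | IO[str]) -> pd.DataFrame:
    """Pre-aggregated demand stats: indicator_code, mean, sd.

    Rows whose ``indicator_code`` is a system-part name carry the part's
    benchmark mean/SD.
    """
    df = pd.read_csv(_normalized(source))
    _require(df, ("indicator_code", "mean", "sd"), "demand-stats")
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, round_digits: int | None = None
) -> None:
    """Write a result table as UTF-8 CSV, optionally rounding float columns."""
    out = df.copy()
    if round_digits is not None:
        for c in out.columns:
            if pd.api.types.is_float_dtype(out[c]):
                out[c] = out[c].round(round_digits)
    out.to_csv(path, index=False)
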