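"""Bundled reference tables of the evaluated smart care service system.

The package ships, as plain CSV data, the published aggregate inputs of the
study it reanalyses: the 18×12 item-mean matrix from the 28-respondent PAD
questionnaire, the 8-emotion benchmark coordinates, and the per-indicator
demand means/SDs with their three part benchmarks. They are the default
inputs of the pipeline and of the examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as _io
from .codebook import Codebook, default_codebook
from .scale import EmotionBenchmark

__all__ = [
    "default_codebook",
    "default_benchmarks",
    "published_item_means",
    "published_demand_stats",
]


def _open(name: str):
    return resources.files("padcare.data").joinpath(name).open("r", encoding="utf-8")


def default_benchmarks() -> tuple[EmotionBenchmark, ...]:
    """The 8 benchmark emotions with normative PAD coordinates."""
    with _open("benchmarks.csv") as fh:
        return _io.read_benchmarks(fh)


def published_item_means() -> pd.DataFrame:
    """The published 18-indicator × 12-item mean score matrix."""
    with _open("item_means.csv") as fh:
        return _io.read_item_means(fh)


def published_demand_stats() -> pd.DataFrame:
    """Published per-indicator demand means/SDs plus part-benchmark rows."""
    with _open("demand_stats.csv") as fh:
        return _io.read_demand_stats(fh)
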