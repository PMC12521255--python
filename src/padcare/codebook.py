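"""Indicator codebook: service touchpoints and their system parts.

A smart older-adult care service system is evaluated through 18 clustered
service touchpoints ("indicators", coded ``S_1`` … ``S_18``) grouped into
three structural parts: smart devices (S_1–S_5), online software (S_6–S_11)
and offline services (S_12–S_18). The codebook maps indicator codes to
human-readable labels and parts; all pipeline stages validate indicator
codes against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["SystemPart", "Indicator", "Codebook", "default_codebook"]


class SystemPart(str, Enum):
    """The three structural parts of the care service system."""

    SMART_DEVICES = "smart_devices"
    ONLINE_SOFTWARE = "online_software"
    OFFLINE_SERVICES = "offline_services"


@dataclass(frozen=True)
class Indicator:
    """One evaluation indicator (a clustered service touchpoint)."""

    code: str
    label: str
    part: SystemPart


class Codebook:
    """An ordered, unique collection of indicators.

    Parameters
    ----------
    indicators
        Iterable of :class:`Indicator`. Codes must be unique.
    """

    def __init__(self, indicators: Iterable[Indicator]):
        self.indicators = tuple(indicators)
        codes = [ind.code for ind in self.indicators]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate indicator codes: {dupes}")
        if not self.indicators:
            raise ValueError("codebook is empty")
        self._by_code = {ind.code: ind for ind in self.indicators}

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(ind.code for ind in self.indicators)

    def __len__(self) -> int:
        return len(self.indicators)

    def __iter__(self) -> Iterator[Indicator]:
        return iter(self.indicators)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Indicator:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown indicator code: {code!r}") from None

    def part_of(self, code: str) -> SystemPart:
        return self[code].part

    def in_part(self, part: SystemPart | str) -> tuple[Indicator, ...]:
        part = SystemPart(part)
        return tuple(ind for ind in self.indicators if ind.part is part)

    def check_codes(self, codes: Iterable[str]) -> None:
        """Raise ``ValueError`` listing any codes absent from the codebook."""
        unknown = sorted({c for c in codes if c not in self._by_code})
        if unknown:
            raise ValueError(f"unknown indicator codes: {unknown}")

    def subset(self, codes: Iterable[str]) -> "Codebook":
        codes = list(codes)
        self.check_codes(codes)
        keep = set(codes)
        return Codebook(ind for ind in self.indicators if ind.code in keep)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Codebook":
        required = {"code", "label", "system_part"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"codebook table missing columns: {sorted(missing)}")
        return cls(
            Indicator(str(r.code), str(r.label), SystemPart(r.system_part))
            for r in df.itertuples()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [i.code for i in self.indicators],
                "label": [i.label for i in self.indicators],
                "system_part": [i.part.value for i in self.indicators],
            }
        )


def default_codebook() -> Codebook:
    """The bundled 18-indicator codebook of the evaluated care system."""
    with resources.files("padcare.data").joinpath("codebook.csv").open("r") as fh:
        return Codebook.from_frame(pd.read_csv(fh))
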