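"""Standardization of measured parameters against normative references.

A Z-score (reported in clinical tables as "difference in SD") is
``z = (measured - reference mean) / reference SD`` against age- and
sex-matched normative data. Entries with |z| > 2 are conventionally flagged
as abnormal. This module holds the shared result container used by both the
mineralization (BMDD) and histomorphometry pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import math

import pandas as pd

from ._rounding import round_half_away
from .errors import MissingReferenceError

#: Default |z| threshold above which a parameter is flagged as abnormal.
FLAG_THRESHOLD: float = 2.0


@dataclass(frozen=True)
class ReferenceStat:
    """Normative mean and SD for one parameter."""

    parameter: str
    mean: float
    sd: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"reference SD for {self.parameter!r} must be > 0")


@dataclass(frozen=True)
class ZScoreRow:
    """One standardized parameter: measured value, reference, z and flag."""

    parameter: str
    value: float
    ref_mean: float
    ref_sd: float
    z: float  # unrounded; use z2 for the 2-decimal presentation value
    flagged: bool

    @property
    def z2(self) -> float:
        return round_half_away(self.z, 2)


@dataclass
class ZScoreSet:
    """Ordered collection of standardized parameters."""

    rows: list[ZScoreRow] = field(default_factory=list)
    flag_threshold: float = FLAG_THRESHOLD
    label: str = ""

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, parameter: str) -> ZScoreRow:
        for row in self.rows:
            if row.parameter == parameter:
                return row
        raise KeyError(parameter)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": [r.parameter for r in self.rows],
                "value": [r.value for r in self.rows],
                "ref_mean": [r.ref_mean for r in self.rows],
                "ref_sd": [r.ref_sd for r in self.rows],
                "z": [r.z2 for r in self.rows],
                "flagged": [r.flagged for r in self.rows],
            }
        )


def zscore(value: float, mean: float, sd: float) -> float:
    """Standardized deviation of ``value`` from a normative (mean, sd)."""
    if not sd > 0:
        raise ValueError("reference SD must be > 0")
    return (value - mean) / sd


def standardize(
    values: Mapping[str, float],
    reference: Iterable[ReferenceStat] | Mapping[str, ReferenceStat],
    *,
    flag_threshold: float = FLAG_THRESHOLD,
    require_all: bool = True,
    label: str = "",
) -> ZScoreSet:
    """Standardize a dict of measured parameters against reference stats.

    Parameters without a reference row raise :class:`MissingReferenceError`
    when ``require_all`` is true, and are silently skipped otherwise (used
    for parameters the reference tables leave blank).
    """
    if not isinstance(reference, Mapping):
        reference = {r.parameter: r for r in reference}
    rows: list[ZScoreRow] = []
    for name, value in values.items():
        ref = reference.get(name)
        if ref is None:
            if require_all:
                raise MissingReferenceError(
                    f"no reference row for parameter {name!r}"
                )
            continue
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        z = zscore(value, ref.mean, ref.sd)
        rows.append(
            ZScoreRow(
                parameter=name,
                value=float(value),
                ref_mean=ref.mean,
                ref_sd=ref.sd,
                z=z,
                flagged=abs(z) > flag_threshold,
            )
        )
    return ZScoreSet(rows=rows, flag_threshold=flag_threshold, label=label)
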