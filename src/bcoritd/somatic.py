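"""Tumour/normal somatic variant filtering.

Implements the depth-based somatic filter applied to merged tumour+normal
variant tables: a variant is retained as somatic iff

    variant ratio > 0.05  AND  tumour depth > 50  AND
    tumour alt depth > 6  AND  normal alt depth < 4

with all four inequalities strict (boundary values reject); the thresholds
are configurable.  The "variant ratio" is the tumour variant allele
fraction (alt/total); the normal-side threshold counts reads, matching the
units of the other coverage filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

REQUIRED_FIELDS = ("tumour_depth", "tumour_alt", "normal_alt")


@dataclass(frozen=True)
class SomaticThresholds:
    min_ratio: float = 0.05
    min_depth: int = 50
    min_alt: int = 6
    max_normal_alt: int = 4


@dataclass(frozen=True)
class VariantRecord:
    """One merged tumour/normal variant observation."""

    contig: str
    pos: int
    ref: str
    alt: str
    tumour_depth: int
    tumour_alt: int
    normal_alt: int

    def __post_init__(self) -> None:
        if self.tumour_alt > self.tumour_depth:
            raise ValueError("alt depth exceeds total depth")

    @property
    def ratio(self) -> float:
        return self.tumour_alt / self.tumour_depth if self.tumour_depth else 0.0


def is_somatic(
    ratio: float, tumour_depth: int, tumour_alt: int, normal_alt: int,
    thresholds: SomaticThresholds = SomaticThresholds(),
) -> bool:
    """The four-way somatic predicate (strict inequalities)."""
    t = thresholds
    return (
        ratio > t.min_ratio
        and tumour_depth > t.min_depth
        and tumour_alt > t.min_alt
        and normal_alt < t.max_normal_alt
    )


def call_somatic(
    records: pd.DataFrame,
    thresholds: SomaticThresholds = SomaticThresholds(),
    *,
    with_reasons: bool = False,
):
    """Filter a merged variant table down to somatic calls.

    ``records`` needs columns ``tumour_depth``, ``tumour_alt`` and
    ``normal_alt`` (a ``ratio`` column is used if present, else computed).
    Returns the retained rows in input order; with ``with_reasons`` also a
    per-rejected-row reason series.  Rows with missing depth fields are
    rejected with reason ``missing-field`` rather than failing the run.
    """
    for col in REQUIRED_FIELDS:
        if col not in records.columns:
            raise KeyError(f"variant table lacks required column {col!r}")
    df = records.copy()
    missing = df[list(REQUIRED_FIELDS)].isna().any(axis=1)
    if "ratio" in df.columns:
        ratio = df["ratio"].where(~df["ratio"].isna(),
                                  df["tumour_alt"] / df["tumour_depth"])
    else:
        ratio = df["tumour_alt"] / df["tumour_depth"]
    t = thresholds
    ok = (
        (ratio > t.min_ratio)
        & (df["tumour_depth"] > t.min_depth)
        & (df["tumour_alt"] > t.min_alt)
        & (df["normal_alt"] < t.max_normal_alt)
        & ~missing
    )
    retained = df[ok.fillna(False)]
    if not with_reasons:
        return retained
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[missing] = "missing-field"
    free = ~missing
    reasons[free & ~(ratio > t.min_ratio)] = "low-ratio"
    reasons[free & (ratio > t.min_ratio) & ~(df["tumour_depth"] > t.min_depth)] = "low-depth"
    reasons[
        free
        & (ratio > t.min_ratio)
        & (df["tumour_depth"] > t.min_depth)
        & ~(df["tumour_alt"] > t.min_alt)
    ] = "low-alt"
    reasons[
        free
        & (ratio > t.min_ratio)
        & (df["tumour_depth"] > t.min_depth)
        & (df["tumour_alt"] > t.min_alt)
        & ~(df["normal_alt"] < t.max_normal_alt)
    ] = "normal-contaminated"
    return retained, reasons[~ok.fillna(False)]


def read_variant_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_somatic_calls(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
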