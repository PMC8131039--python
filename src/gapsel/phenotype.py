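"""Storage-trajectory phenotyping: retainability scoring, softening-type
classification, broad-sense heritability and trait correlation.

Retainability is the maximum month (on the measured monthly grid) up to
which a trait value stays at or above its acceptability threshold; firmness
uses 7.0 kg/cm2 and crispness 0.7 kg/cm2 by default.  Trajectories are
classed into three extremity dynamics: type I (acceptability already lost
at harvest), type II (kept through month 6 after a rapid first-month drop)
and type III (kept through month 6 with constant slow softening).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: acceptability thresholds, kg/cm2
DEFAULT_THRESHOLDS = {"firmness": 7.0, "crispness": 0.7}

#: first-month drop (kg/cm2) separating rapid from slow initial softening;
#: the crispness value mirrors the 10x smaller measurement scale
DEFAULT_RAPID_DROP = {"firmness": 1.0, "crispness": 0.1}

#: last month of the measurement grid
LAST_MONTH = 6

TYPE_I = "I"
TYPE_II = "II"
TYPE_III = "III"
UNCLASSIFIED = "unclassified"


@dataclass
class StorageSeries:
    """One hybrid's monthly trait measurements during cold storage."""

    hybrid_id: str
    trait: str
    months: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.months.size == 0:
            raise ValueError(f"empty storage series for hybrid {self.hybrid_id!r}")
        if self.months.size != self.values.size:
            raise ValueError("months and values differ in length")
        if not np.all(np.diff(self.months) > 0):
            raise ValueError("months must be strictly increasing")
        if self.months[0] != 0:
            raise ValueError("series must start at month 0")
        if np.any(self.values < 0):
            raise ValueError("negative trait value")

    def value_at(self, month: int) -> Optional[float]:
        idx = np.flatnonzero(self.months == month)
        return float(self.values[idx[0]]) if idx.size else None


@dataclass
class RetainabilityRecord:
    hybrid_id: str
    trait: str
    retainability: int
    censored: bool
    ptype: str = UNCLASSIFIED


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    var_g: float
    var_e: float
    n_hybrids: int
    n_years: int


def default_threshold(trait: str) -> float:
    try:
        return DEFAULT_THRESHOLDS[trait]
    except KeyError:
        raise KeyError(f"no default threshold for trait {trait!r}") from None


def compute_retainability(series: StorageSeries,
                          threshold: Optional[float] = None) -> RetainabilityRecord:
    """Score one storage series to an integer retainability in months.

    The score is the month immediately before the first measured month whose
    value falls below ``threshold``; 0 if acceptability is already lost at
    month 0; the last measured month with ``censored=True`` if the value
    never drops below threshold.  A dip followed by recovery still ends the
    score at the first crossing (acceptability must be held continuously).
    """
    if threshold is None:
        threshold = default_threshold(series.trait)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    below = np.flatnonzero(series.values < threshold)
    if below.size == 0:
        retain = int(series.months[-1])
        censored = True
    else:
        first = below[0]
        retain = 0 if first == 0 else int(series.months[first - 1])
        censored = False
    record = RetainabilityRecord(
        hybrid_id=series.hybrid_id,
        trait=series.trait,
        retainability=retain,
        censored=censored,
    )
    record.ptype = TYPE_I if retain == 0 else UNCLASSIFIED
    return record


def classify_type(record: RetainabilityRecord, series: StorageSeries,
                  rapid_drop: Optional[float] = None) -> str:
    """Assign the softening-dynamics type for a scored series.

    Type I: retainability 0.  Types II/III require acceptability through
    month 6; they are split by whether the month 0 -> 1 drop reaches
    ``rapid_drop``.  Intermediate retainabilities stay unclassified.
    """
    if rapid_drop is None:
        rapid_drop = DEFAULT_RAPID_DROP.get(series.trait, 1.0)
    if record.retainability == 0:
        record.ptype = TYPE_I
        return TYPE_I
    if record.retainability >= LAST_MONTH:
        v0 = series.value_at(0)
        v1 = series.value_at(1)
        if v1 is None:
            logger.warning(
                "hybrid %s: no month-1 measurement; type II/III undecidable",
                series.hybrid_id,
            )
            record.ptype = UNCLASSIFIED
            return UNCLASSIFIED
        record.ptype = TYPE_II if (v0 - v1) >= rapid_drop else TYPE_III
        return record.ptype
    record.ptype = UNCLASSIFIED
    return UNCLASSIFIED


def score_storage_series(series_list: Sequence[StorageSeries],
                         threshold: Optional[float] = None,
                         rapid_drop: Optional[float] = None) -> pd.DataFrame:
    """Score and classify a batch of series into a retainability table."""
    rows = []
    for series in series_list:
        record = compute_retainability(series, threshold)
        classify_type(record, series, rapid_drop)
        rows.append(
            (record.hybrid_id, record.trait, record.retainability,
             record.censored, record.ptype)
        )
    return pd.DataFrame(
        rows, columns=["hybrid_id", "trait", "retainability", "censored", "ptype"]
    )


def estimate_h2(phenotypes: pd.DataFrame, trait: Optional[str] = None,
                entry_mean: bool = False) -> HeritabilityEstimate:
    """Broad-sense heritability from multi-year records by one-way ANOVA.

    Hybrids are the groups and years the replicates.  Hybrids lacking a
    record in any observed year are dropped so the design is balanced with
    r = number of years.  var_g = (MS_hybrid - MS_error) / r clamped at 0,
    var_e = MS_error, and h2 = var_g / (var_g + var_e) on a per-plot basis;
    ``entry_mean=True`` uses var_g / (var_g + var_e / r) instead.
    """
    frame = phenotypes
    if trait is not None:
        frame = frame[frame["trait"] == trait]
    if "year" not in frame.columns:
        raise ValueError("heritability estimation needs a 'year' column")
    years = sorted(frame["year"].unique())
    if len(years) < 2:
        raise ValueError("need records from >=2 years")
    wide = frame.pivot_table(index="hybrid_id", columns="year", values="opv",
                             aggfunc="mean")
    wide = wide.dropna(axis=0, how="any")
    n, r = wide.shape
    if n < 2:
        raise ValueError("need >=2 hybrids with complete multi-year records")
    data = wide.to_numpy(float)
    grand = data.mean()
    group_means = data.mean(axis=1)
    ss_between = r * float(np.sum((group_means - grand) ** 2))
    ss_within = float(np.sum((data - group_means[:, None]) ** 2))
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (r - 1))
    var_g = max(0.0, (ms_between - ms_within) / r)
    var_e = ms_within
    denom = var_g + (var_e / r if entry_mean else var_e)
    h2 = var_g / denom if denom > 0 else 0.0
    return HeritabilityEstimate(
        trait=trait if trait is not None else "all",
        h2=h2, var_g=var_g, var_e=var_e, n_hybrids=n, n_years=r,
    )


def correlate(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, int]:
    """Pearson correlation on complete pairs; returns (r, n used)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("trait vectors differ in length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need >=3 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(stats.pearsonr(a, b).statistic)
    return r, int(a.size)


def correlate_traits(phenotypes: pd.DataFrame, trait_a: str,
                     trait_b: str) -> tuple[float, int]:
    """Pearson correlation between two traits across hybrids (paired on id)."""
    wide = phenotypes.pivot_table(index="hybrid_id", columns="trait",
                                  values="opv", aggfunc="mean")
    for t in (trait_a, trait_b):
        if t not in wide.columns:
            raise KeyError(f"trait {t!r} absent from phenotype table")
    return correlate(wide[trait_a].to_numpy(), wide[trait_b].to_numpy())
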