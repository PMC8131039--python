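"""Per-marker genotype-class effect estimation and allelic-action classing.

A marker's genotype-class effect is the deviation of the mean observed
phenotype of hybrids sharing that genotype class from the overall mean of
all phenotyped training hybrids.  For three-class markers the heterozygote
position relative to the homozygote midpoint (the |d/a| ratio) classifies
the allelic action as additive, partial dominant, complete dominant or
overdominant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_tables import GenotypeTable, call_alleles

logger = logging.getLogger(__name__)

ACTION_ADDITIVE = "additive"
ACTION_PARTIAL = "partial_dominant"
ACTION_COMPLETE = "complete_dominant"
ACTION_OVERDOMINANT = "overdominant"
ACTION_UNDETERMINED = "undetermined"

#: |d/a| bin edges: <=0.2 additive, (0.2, 0.8) partial, [0.8, 1.2] complete,
#: >1.2 overdominant.  Conventional quantitative-genetics bins.
DEFAULT_RATIO_BINS = (0.2, 0.8, 1.2)

DEFAULT_MIN_CLASS_N = 3


@dataclass
class MarkerEffect:
    """Genotype-class means, deviations and allelic action for one marker."""

    marker_id: str
    classes: list[str]
    class_means: list[float]
    class_counts: list[int]
    effects: list[float]
    retained: list[bool]
    effect_span: float
    action: str = ACTION_UNDETERMINED

    def effect_of(self, class_label: str) -> Optional[float]:
        try:
            idx = self.classes.index(class_label)
        except ValueError:
            return None
        return self.effects[idx]

    @property
    def is_empty(self) -> bool:
        return not self.classes

    def to_dict(self) -> dict:
        return {
            "marker_id": self.marker_id,
            "classes": self.classes,
            "class_means": self.class_means,
            "class_counts": self.class_counts,
            "effects": self.effects,
            "retained": self.retained,
            "effect_span": self.effect_span,
            "action": self.action,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "MarkerEffect":
        return cls(
            marker_id=payload["marker_id"],
            classes=list(payload["classes"]),
            class_means=[float(x) for x in payload["class_means"]],
            class_counts=[int(x) for x in payload["class_counts"]],
            effects=[float(x) for x in payload["effects"]],
            retained=[bool(x) for x in payload["retained"]],
            effect_span=float(payload["effect_span"]),
            action=payload["action"],
        )


def _opv_by_hybrid(phenotypes: pd.DataFrame, trait: Optional[str]) -> pd.Series:
    frame = phenotypes
    if trait is not None and "trait" in frame.columns:
        frame = frame[frame["trait"] == trait]
    if frame.empty:
        raise ValueError(f"no phenotype records for trait {trait!r}")
    # multi-year records average to one OPV per hybrid
    return frame.groupby("hybrid_id")["opv"].mean()


def estimate_genotype_effects(genotypes: GenotypeTable,
                              phenotypes: pd.DataFrame,
                              trait: Optional[str] = None,
                              min_class_n: int = DEFAULT_MIN_CLASS_N,
                              ratio_bins: Sequence[float] = DEFAULT_RATIO_BINS,
                              ) -> list[MarkerEffect]:
    """Estimate genotype-class effects for every marker in the table.

    The overall mean is computed once over all phenotyped hybrids present
    in the genotype table (pooled across populations).  A hybrid missing a
    call at a marker is excluded from that marker's class means but still
    contributes to the overall mean.  Classes with fewer than
    ``min_class_n`` members keep their mean but get effect 0 and
    ``retained=False``.
    """
    opv = _opv_by_hybrid(phenotypes, trait)
    opv = opv.loc[opv.index.intersection(genotypes.calls.index)]
    if opv.empty:
        raise ValueError("no phenotyped hybrids found in the genotype table")
    overall_mean = float(opv.mean())
    calls = genotypes.calls.loc[opv.index]

    results: list[MarkerEffect] = []
    for marker in calls.columns:
        column = calls[marker]
        observed = column[column.notna()]
        if observed.empty:
            logger.warning("marker %s: all calls missing; empty effect entry", marker)
            results.append(
                MarkerEffect(marker, [], [], [], [], [], 0.0, ACTION_UNDETERMINED)
            )
            continue
        grouped = opv.loc[observed.index].groupby(observed.astype(str))
        means = grouped.mean()
        counts = grouped.size()
        classes = sorted(means.index)
        class_means = [float(means[c]) for c in classes]
        class_counts = [int(counts[c]) for c in classes]
        retained = [n >= min_class_n for n in class_counts]
        effects = [
            (m - overall_mean) if keep else 0.0
            for m, keep in zip(class_means, retained)
        ]
        kept_means = [m for m, keep in zip(class_means, retained) if keep]
        span = (max(kept_means) - min(kept_means)) if kept_means else 0.0
        effect = MarkerEffect(
            marker_id=marker,
            classes=classes,
            class_means=class_means,
            class_counts=class_counts,
            effects=effects,
            retained=retained,
            effect_span=span,
        )
        effect.action = classify_allelic_action(effect, ratio_bins=ratio_bins)
        results.append(effect)
    return results


def dominance_components(effect: MarkerEffect,
                         min_class_n: int = DEFAULT_MIN_CLASS_N,
                         ) -> Optional[tuple[float, float]]:
    """(a, d) from a three-class marker: half-difference of homozygote means
    and heterozygote deviation from their midpoint.  None when the marker
    does not present two homozygote classes and one heterozygote class with
    adequate counts."""
    if len(effect.classes) != 3:
        return None
    if any(n < min_class_n for n in effect.class_counts):
        return None
    homs: list[float] = []
    het: Optional[float] = None
    for label, mean in zip(effect.classes, effect.class_means):
        a1, a2 = call_alleles(label)
        if a1 == a2:
            homs.append(mean)
        else:
            het = mean
    if len(homs) != 2 or het is None:
        return None
    a = (max(homs) - min(homs)) / 2.0
    d = het - (homs[0] + homs[1]) / 2.0
    return a, d


def classify_allelic_action(effect: MarkerEffect,
                            ratio_bins: Sequence[float] = DEFAULT_RATIO_BINS,
                            a_tol: float = 1e-8,
                            min_class_n: int = DEFAULT_MIN_CLASS_N) -> str:
    """Classify a marker's allelic action from its |d/a| ratio.

    Two-class (backcross-type) markers and markers with undersized classes
    are undetermined, as are markers with |a| below ``a_tol``.
    """
    components = dominance_components(effect, min_class_n=min_class_n)
    if components is None:
        return ACTION_UNDETERMINED
    a, d = components
    if abs(a) < a_tol:
        return ACTION_UNDETERMINED
    return classify_ratio(abs(d / a), ratio_bins)


def classify_ratio(ratio: float,
                   ratio_bins: Sequence[float] = DEFAULT_RATIO_BINS) -> str:
    """Map a |d/a| ratio to its allelic-action label."""
    add_max, partial_max, over_min = ratio_bins
    if ratio <= add_max:
        return ACTION_ADDITIVE
    if ratio < partial_max:
        return ACTION_PARTIAL
    if ratio <= over_min:
        return ACTION_COMPLETE
    return ACTION_OVERDOMINANT


def effects_to_frame(effects: Sequence[MarkerEffect]) -> pd.DataFrame:
    """Long-format table: one row per (marker, genotype class)."""
    rows = []
    for eff in effects:
        if eff.is_empty:
            rows.append((eff.marker_id, "NA", 0, float("nan"), 0.0, False,
                         eff.effect_span, eff.action))
            continue
        for label, mean, count, value, keep in zip(
            eff.classes, eff.class_means, eff.class_counts, eff.effects, eff.retained
        ):
            rows.append((eff.marker_id, label, count, mean, value, keep,
                         eff.effect_span, eff.action))
    return pd.DataFrame(
        rows,
        columns=["marker_id", "genotype", "count", "class_mean", "effect",
                 "retained", "effect_span", "action"],
    )
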