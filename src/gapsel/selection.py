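"""Simulative selection on genomics-predicted values.

Hybrids whose GPV meets the criterion are selected; the selection rate is
the selected fraction of all hybrids with a GPV, and the efficiency is the
fraction of selected hybrids whose observed value also meets the criterion.
Ties at the criterion are selected (>=).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd


@dataclass
class SelectionResult:
    trait: Optional[str]
    criterion: float
    selected_ids: list[str]
    n_total: int
    selection_rate: float
    efficiency: Optional[float]  # None when nothing selected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hybrid_id": self.selected_ids})


def simulate_selection(predictions: pd.DataFrame, criterion: float,
                       trait: Optional[str] = None) -> SelectionResult:
    """Apply a GPV >= criterion truncation selection to a prediction set."""
    if not math.isfinite(criterion):
        raise ValueError("criterion must be finite")
    frame = predictions
    if "complete" in frame.columns:
        frame = frame[frame["complete"]]
    frame = frame[frame["gpv"].notna()]
    n_total = len(frame)
    if n_total == 0:
        raise ValueError("no hybrids with a GPV to select from")
    selected = frame[frame["gpv"] >= criterion]
    rate = len(selected) / n_total
    if len(selected) == 0:
        efficiency = None
    else:
        if selected["opv"].isna().any():
            raise ValueError("selected hybrids lack OPV; efficiency undefined")
        efficiency = float((selected["opv"] >= criterion).mean())
    return SelectionResult(
        trait=trait,
        criterion=criterion,
        selected_ids=list(selected["hybrid_id"]),
        n_total=n_total,
        selection_rate=rate,
        efficiency=efficiency,
    )
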