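"""Gastric-state labels from the trial event timeline, and class balancing.

For an emetic-infusion trial the timeline defines three states: everything
before the infusion is *baseline*; the infusion-to-first-retch interval is
split in half into *early* and *late*.  The halves are equal by construction,
which is the premise for the 33% (3-class) and 50% (2-class) chance levels
after balancing.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd

from .io import Event

__all__ = ["GastricState", "assign_state_labels", "balance_classes", "LabelingError"]


class GastricState(str, Enum):
    BASELINE = "baseline"
    EARLY = "early"
    LATE = "late"


class LabelingError(ValueError):
    """The event timeline cannot support state labeling."""


def assign_state_labels(
    table: pd.DataFrame,
    events: list[Event],
    window_length_s: float = 60.0,
    late_onset_fraction: float = 0.5,
) -> pd.DataFrame:
    """Attach a ``label`` column; unlabeled (boundary/post-retch) rows dropped.

    A segment must be fully contained in a state interval to receive its
    label: segments straddling the infusion, the early/late midpoint, or the
    first retch are dropped rather than assigned by majority overlap, which
    keeps the early and late durations exactly equal.

    ``late_onset_fraction`` moves the early/late boundary (default 0.5, the
    halfway point of the infusion-to-retch interval).
    """
    t_inf = next((e.time_s for e in events if e.kind == "infusion_start"), None)
    t_retch = next((e.time_s for e in events if e.kind == "first_retch"), None)
    if t_inf is None or t_retch is None:
        raise LabelingError("need infusion_start and first_retch events to label")
    if t_retch <= t_inf:
        raise LabelingError("first_retch precedes infusion_start")
    if not 0.0 < late_onset_fraction < 1.0:
        raise ValueError("late_onset_fraction must be in (0, 1)")
    t_mid = t_inf + late_onset_fraction * (t_retch - t_inf)

    labels = []
    for t0 in table["t_start_s"].to_numpy(dtype=float):
        t1 = t0 + window_length_s
        if t1 <= t_inf:
            labels.append(GastricState.BASELINE.value)
        elif t0 >= t_inf and t1 <= t_mid:
            labels.append(GastricState.EARLY.value)
        elif t0 >= t_mid and t1 <= t_retch:
            labels.append(GastricState.LATE.value)
        else:
            labels.append(None)
    out = table.copy()
    out["label"] = labels
    return out[out["label"].notna()].reset_index(drop=True)


def balance_classes(
    table: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
    label_col: str = "label",
    group_col: str | None = "source_id",
) -> pd.DataFrame:
    """Randomly undersample every class to the smallest class count.

    The usable windows per class are limited by the shortest recorded gastric
    state, so majority classes are downsampled without replacement.  Classes
    with zero rows are dropped from the problem (the class set shrinks, e.g.
    a session with <1 min of baseline runs in 2-state mode).  Sampling is
    performed independently within each ``group_col`` group (signal source);
    the result row order is shuffled deterministically under ``seed``.
    """
    rng = np.random.default_rng(seed)
    counts = table[label_col].value_counts()
    present = counts[counts > 0]
    if len(present) < 2:
        raise ValueError("need >= 2 labeled classes to balance")
    groups = [g for _, g in table.groupby(group_col, sort=False)] if group_col else [table]
    picked = []
    for g in groups:
        gcounts = g[label_col].value_counts()
        if (gcounts == 0).any() or len(gcounts) < len(present):
            warnings.warn(
                "a class is empty for some source; it is dropped there",
                stacklevel=2,
            )
        n_min = int(gcounts.min())
        for _, cls_rows in g.groupby(label_col, sort=False):
            idx = rng.choice(len(cls_rows), size=n_min, replace=False)
            picked.append(cls_rows.iloc[np.sort(idx)])
    out = pd.concat(picked, ignore_index=True)
    perm = rng.permutation(len(out))
    return out.iloc[perm].reset_index(drop=True)
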