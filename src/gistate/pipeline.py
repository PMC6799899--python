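"""End-to-end convenience: session -> labeled, normalized feature table."""

from __future__ import annotations

import pandas as pd

from .config import PipelineConfig
from .features import extract_features, median_normalize
from .io import SessionRecording
from .labeling import assign_state_labels
from .preprocess import preprocess_session

__all__ = ["session_feature_table"]


def session_feature_table(
    rec: SessionRecording,
    cfg: PipelineConfig | None = None,
    include_bipolar: bool = False,
    label: bool = True,
) -> pd.DataFrame:
    """Run preprocessing, feature extraction, per-source median normalization
    and (optionally) gastric-state labeling for one session."""
    cfg = cfg or PipelineConfig()
    traces = preprocess_session(rec, cfg, include_bipolar=include_bipolar)
    table = pd.concat(
        [extract_features(tr, cfg) for tr in traces], ignore_index=True
    )
    table = median_normalize(table, mode=cfg.normalize_mode)
    if label:
        table = assign_state_labels(table, rec.events, cfg.window_length_s)
    return table
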