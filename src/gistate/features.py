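"""Per-segment feature vectors for gastric-state classification.

Seven features per 1-min window, mirroring the published feature set:

==========  ================================================================
P_brady     % of 6-15 cpm power in the bradygastric band (DF-3 to DF-1 cpm)
P_norm      % in the normogastric band (DF +/- 1 cpm)
P_tachy     % in the tachygastric band (DF+1 to DF+3 cpm)
DF          dominant frequency, cpm
DP          power in the single 0.3 cpm bin containing the DF
LL          line length: sum of absolute successive sample differences, mV
ZX          zero crossings of the mean-removed window (sign changes)
==========  ================================================================

Features are normalized to their median per signal source, so each column of
a source has median 1; classifiers then see ratio-scale deviations from that
source's typical window rather than absolute amplitudes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .config import PipelineConfig
from .io import ProcessedTrace, Segment
from .preprocess import segment_trace
from .spectral import SegmentSpectrum, band_edges, band_powers, power_spectrum

__all__ = [
    "FEATURE_COLUMNS",
    "line_length",
    "zero_crossings",
    "dominant_power",
    "extract_features",
    "median_normalize",
    "MedianNormalizer",
]

FEATURE_COLUMNS = ["P_brady", "P_norm", "P_tachy", "DF", "DP", "LL", "ZX"]


def line_length(x: np.ndarray) -> float:
    """Sum of the magnitude of the first difference over the window."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 samples for line length")
    return float(np.abs(np.diff(x)).sum())


def zero_crossings(x: np.ndarray, remove_mean: bool = True) -> int:
    """Number of algebraic sign changes of the (mean-removed) window.

    Zeros carry the previous nonzero sign, so a touch of zero without a
    polarity reversal is not a crossing.  An all-zero window has none.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 samples for zero crossings")
    if remove_mean:
        x = x - x.mean()
    s = np.sign(x)
    nz = s != 0
    if not nz.any():
        return 0
    # propagate last nonzero sign forward through exact zeros
    idx = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = s[idx]
    filled[: np.argmax(nz)] = 0  # leading zeros carry no sign
    valid = filled != 0
    f = filled[valid]
    return int(np.count_nonzero(f[1:] * f[:-1] < 0))


def dominant_power(spec: SegmentSpectrum, cfg: PipelineConfig | None = None) -> float:
    """Power within the 0.3 cpm band around the DF (the DF bin itself)."""
    cfg = cfg or PipelineConfig()
    if not np.isfinite(spec.df_cpm):
        return float("nan")
    half = cfg.bin_cpm / 2
    sel = np.abs(spec.freqs_cpm - spec.df_cpm) <= half - 1e-9
    sel |= np.abs(spec.freqs_cpm - spec.df_cpm) < 1e-9
    return float(spec.power[sel].sum())


def extract_features(
    trace: ProcessedTrace,
    cfg: PipelineConfig | None = None,
    session_df_cpm: float | None = None,
) -> pd.DataFrame:
    """One feature row per non-excluded 1-min segment of a processed trace.

    Band edges are DF-relative; by default each window uses its own DF
    (``band_edge_mode='per_segment'``).  Passing ``session_df_cpm`` with
    ``band_edge_mode='session'`` pins the edges to a validated session-level
    DF instead, as used for figure-style band summaries.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    segments = segment_trace(trace, cfg.window_length_s)
    for seg in segments:
        if seg.excluded:
            continue
        spec = power_spectrum(seg, cfg)
        if cfg.band_edge_mode == "session" and session_df_cpm is not None:
            edges = band_edges(session_df_cpm, cfg)
            p_b, p_n, p_t, total = band_powers(spec, edges, cfg)
        else:
            p_b, p_n, p_t, total = (
                spec.p_brady,
                spec.p_norm,
                spec.p_tachy,
                spec.total_power_6_15,
            )
        rows.append(
            {
                "source_id": seg.source_id,
                "segment_index": seg.index,
                "t_start_s": seg.start_s,
                "P_brady": p_b,
                "P_norm": p_n,
                "P_tachy": p_t,
                "DF": spec.df_cpm,
                "DP": dominant_power(spec, cfg),
                "LL": line_length(seg.samples),
                "ZX": zero_crossings(seg.samples),
            }
        )
    if not rows:
        warnings.warn(
            f"no usable segments in trace {trace.source_id!r}", stacklevel=2
        )
        return pd.DataFrame(
            columns=["source_id", "segment_index", "t_start_s", *FEATURE_COLUMNS]
        )
    return pd.DataFrame(rows)


class MedianNormalizer(TransformerMixin, BaseEstimator):
    """Scale each feature column by its median.

    With ``mode='median'`` (default) values are divided by the fitted column
    median, so the transformed column has median 1 -- the ratio-scale reading
    of "normalized to the median".  ``mode='center'`` subtracts the median
    instead (median 0).  A zero median falls back to the median absolute
    value for that column (logged via warning) to keep the division defined.
    """

    def __init__(self, mode: str = "median"):
        self.mode = mode

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan")
        if self.mode not in ("median", "center"):
            raise ValueError(f"unknown mode {self.mode!r}")
        med = np.nanmedian(X, axis=0)
        if self.mode == "median":
            zero = med == 0
            if np.any(zero):
                warnings.warn(
                    f"{int(zero.sum())} feature column(s) have zero median; "
                    "normalizing by median absolute value instead",
                    stacklevel=2,
                )
                alt = np.nanmedian(np.abs(X), axis=0)
                med = np.where(zero, np.where(alt == 0, 1.0, alt), med)
        self.median_ = med
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "median_")
        X = check_array(X, ensure_all_finite="allow-nan")
        if self.mode == "center":
            return X - self.median_
        return X / self.median_


def median_normalize(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    mode: str = "median",
) -> pd.DataFrame:
    """Normalize feature columns to their per-source median.

    The median is computed within each ``source_id`` group over all of that
    source's segments, so two sources with different absolute scales each end
    at column median 1.
    """
    columns = columns or FEATURE_COLUMNS
    out = table.copy()
    out[columns] = out[columns].astype(float)
    for _, idx in table.groupby("source_id", sort=False).groups.items():
        block = table.loc[idx, columns].to_numpy(dtype=float)
        norm = MedianNormalizer(mode=mode).fit(block)
        out.loc[idx, columns] = norm.transform(block)
    return out
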