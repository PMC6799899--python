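"""Per-segment power spectra, dominant frequency, and DF-relative band power.

Each 60 s window at 10 Hz (600 samples) is mean-removed and zero-padded to
2000 samples so that the DFT bin spacing is 10/2000 Hz = 0.005 Hz = 0.3
cycles/min -- the minimal construction giving the published 0.3 cpm bin size.
Power is the squared magnitude of the one-sided DFT with a rectangular window.

The dominant frequency (DF) of a window is the bin with the highest power in
0-15 cpm.  A session-level DF is *validated* by a one-way ANOVA of power
across frequency bins (segments as replicates) followed by simultaneous
contrasts of the global peak of the mean spectrum against each rival local
peak; the DF peak exists iff the ANOVA and every contrast are significant.

Band power is expressed relative to the DF: bradygastria is 1-3 cpm below,
normogastria within +/-1 cpm, tachygastria 1-3 cpm above, each as a
percentage of the total 6-15 cpm power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .io import Segment

__all__ = [
    "SegmentSpectrum",
    "BandEdges",
    "DFValidation",
    "power_spectrum",
    "band_edges",
    "band_powers",
    "validate_df",
]


@dataclass
class SegmentSpectrum:
    """One window's power spectrum on the 0.3 cpm grid, plus derived scalars."""

    source_id: str
    segment_index: int
    freqs_cpm: np.ndarray
    power: np.ndarray
    df_cpm: float = float("nan")
    total_power_6_15: float = float("nan")
    p_brady: float = float("nan")
    p_norm: float = float("nan")
    p_tachy: float = float("nan")


@dataclass(frozen=True)
class BandEdges:
    """DF-relative gastric bands; each is a 2 cpm half-open interval [lo, hi)."""

    brady: tuple[float, float]
    normo: tuple[float, float]
    tachy: tuple[float, float]


@dataclass
class DFValidation:
    """Statistical decision on whether a session has a dominant-frequency peak."""

    source_id: str
    mean_power: np.ndarray
    freqs_cpm: np.ndarray
    global_peak_cpm: float
    local_peaks_cpm: list[float]
    anova_p: float
    contrast_p: list[float]
    alpha: float = 0.05
    validated: bool = False


def power_spectrum(
    seg: Segment, cfg: PipelineConfig | None = None
) -> SegmentSpectrum:
    """One-sided power spectrum of a 1-min segment on the 0.3 cpm grid."""
    cfg = cfg or PipelineConfig()
    n_expected = int(round(cfg.window_length_s * seg.fs))
    x = np.asarray(seg.samples, dtype=float)
    if len(x) != n_expected:
        raise ValueError(f"segment has {len(x)} samples, expected {n_expected}")
    # pad length chosen so fs / n_fft equals the configured bin width
    n_fft = int(round(seg.fs * 60.0 / cfg.bin_cpm))
    x = x - x.mean()
    spec = np.fft.rfft(x, n=n_fft)
    power = np.abs(spec) ** 2
    freqs_cpm = np.fft.rfftfreq(n_fft, d=1.0 / seg.fs) * 60.0
    out = SegmentSpectrum(
        source_id=seg.source_id,
        segment_index=seg.index,
        freqs_cpm=freqs_cpm,
        power=power,
    )
    lo, hi = cfg.df_range_cpm
    search = (freqs_cpm >= lo - 1e-9) & (freqs_cpm <= hi + 1e-9)
    out.df_cpm = float(freqs_cpm[search][np.argmax(power[search])])
    edges = band_edges(out.df_cpm, cfg) if out.df_cpm > cfg.band_outer_cpm else None
    if edges is not None:
        out.p_brady, out.p_norm, out.p_tachy, out.total_power_6_15 = band_powers(
            out, edges, cfg
        )
    return out


def band_edges(df_cpm: float, cfg: PipelineConfig | None = None) -> BandEdges:
    """DF-relative band edges: brady (DF-3, DF-1), normo (DF-1, DF+1),
    tachy (DF+1, DF+3), all in cpm."""
    cfg = cfg or PipelineConfig()
    inner, outer = cfg.band_inner_cpm, cfg.band_outer_cpm
    if df_cpm <= outer:
        raise ValueError(
            f"DF {df_cpm} cpm <= {outer} cpm: bradygastric band undefined"
        )
    return BandEdges(
        brady=(df_cpm - outer, df_cpm - inner),
        normo=(df_cpm - inner, df_cpm + inner),
        tachy=(df_cpm + inner, df_cpm + outer),
    )


def band_powers(
    spec: SegmentSpectrum,
    edges: BandEdges,
    cfg: PipelineConfig | None = None,
) -> tuple[float, float, float, float]:
    """(P_brady, P_norm, P_tachy, total) with P in percent of 6-15 cpm power.

    Bins are attributed by centre frequency to half-open [lo, hi) intervals so
    a shared band edge is never double-counted; band portions outside the
    6-15 cpm range contribute only their in-range bins.  A zero total yields
    NaN percentages (the caller flags the segment).
    """
    cfg = cfg or PipelineConfig()
    f = spec.freqs_cpm
    lo_t, hi_t = cfg.total_band_cpm
    in_total = (f >= lo_t - 1e-9) & (f < hi_t - 1e-9)
    total = float(spec.power[in_total].sum())
    if total == 0.0:
        return float("nan"), float("nan"), float("nan"), 0.0

    def pct(band: tuple[float, float]) -> float:
        lo, hi = band
        sel = in_total & (f >= lo - 1e-9) & (f < hi - 1e-9)
        return 100.0 * float(spec.power[sel].sum()) / total

    return pct(edges.brady), pct(edges.normo), pct(edges.tachy), total


def _local_peaks(mean_power: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (greater than both grid neighbours)."""
    interior = (mean_power[1:-1] > mean_power[:-2]) & (
        mean_power[1:-1] > mean_power[2:]
    )
    return np.flatnonzero(interior) + 1


def _maxt_adjust(diffs: np.ndarray) -> list[float] | None:
    """Single-step max-t adjusted one-sided p-values for contrast columns.

    ``diffs`` is (n_segments, m): per-segment differences peak-minus-rival.
    The joint distribution of the m t-statistics under H0 is approximated by
    a multivariate t with the empirical contrast correlation; p_j is
    P(max_k T_k >= t_j).  Returns None if the correlation matrix is unusable
    (the caller then falls back to Bonferroni).
    """
    n, m = diffs.shape
    t_obs = diffs.mean(axis=0) / (diffs.std(axis=0, ddof=1) / np.sqrt(n))
    if m == 1:
        return [float(stats.t.sf(t_obs[0], df=n - 1))]
    cov = np.cov(diffs, rowvar=False)
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0) or not np.all(np.isfinite(t_obs)):
        return None
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2 + 1e-10 * np.eye(m)
    try:
        mvt = stats.multivariate_t(loc=np.zeros(m), shape=corr, df=n - 1)
        out = []
        for tj in t_obs:
            # P(all T_k < tj): one-sided box probability
            p_all_below = float(mvt.cdf(np.full(m, tj)))
            out.append(min(1.0, max(0.0, 1.0 - p_all_below)))
        return out
    except Exception:
        return None


def validate_df(
    spectra: list[SegmentSpectrum],
    alpha: float = 0.05,
    cfg: PipelineConfig | None = None,
) -> DFValidation:
    """Decide whether the session's mean spectrum has a statistically
    dominant peak.

    One-way ANOVA with frequency bin (on the 0-15 cpm grid) as the factor and
    segments as replicates asks whether any bins differ; simultaneous
    one-sided contrasts then compare the global peak of the mean spectrum
    against each rival local peak (single-step max-t adjustment, Bonferroni
    fallback).  The DF is validated iff the ANOVA and all contrasts reject at
    ``alpha``.  With no rival local peaks the ANOVA alone decides.
    """
    cfg = cfg or PipelineConfig()
    if len(spectra) < 5:
        raise ValueError(f"need >= 5 segments for DF validation, got {len(spectra)}")
    f = spectra[0].freqs_cpm
    lo, hi = cfg.df_range_cpm
    sel = np.flatnonzero((f >= lo - 1e-9) & (f <= hi + 1e-9))
    mat = np.stack([s.power[sel] for s in spectra])  # (n_segments, n_bins)
    freqs = f[sel]
    mean_power = mat.mean(axis=0)
    gi = int(np.argmax(mean_power))
    local = [int(i) for i in _local_peaks(mean_power) if i != gi]

    anova_p = float(stats.f_oneway(*(mat[:, j] for j in range(mat.shape[1]))).pvalue)

    contrast_p: list[float] = []
    if local:
        diffs = mat[:, [gi]] - mat[:, local]  # (n_segments, m)
        adjusted = _maxt_adjust(diffs)
        if adjusted is None:  # Bonferroni fallback
            m = len(local)
            adjusted = []
            for j in range(m):
                t_res = stats.ttest_rel(mat[:, gi], mat[:, local[j]])
                p_one = t_res.pvalue / 2 if t_res.statistic > 0 else 1 - t_res.pvalue / 2
                adjusted.append(min(1.0, float(p_one) * m))
        contrast_p = [float(p) for p in adjusted]

    validated = anova_p < alpha and all(p < alpha for p in contrast_p)
    return DFValidation(
        source_id=spectra[0].source_id,
        mean_power=mean_power,
        freqs_cpm=freqs,
        global_peak_cpm=float(freqs[gi]),
        local_peaks_cpm=[float(freqs[i]) for i in local],
        anova_p=anova_p,
        contrast_p=contrast_p,
        alpha=alpha,
        validated=validated,
    )
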