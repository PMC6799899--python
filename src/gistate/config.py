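"""Pipeline configuration.

Defaults reproduce the published analysis settings: 2.5 Hz 4th-order and
0.3 Hz 2nd-order low-pass Butterworth stages around a 10 Hz downsample, 60 s
windows, 0.3 cpm spectral bins, DF search over 0-15 cpm, DF-relative bands at
+/-1 and +/-3 cpm, and the kNN / RBF-SVM hyperparameter grids.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # filter cascade
    lowpass1_hz: float = 2.5
    lowpass1_order: int = 4
    target_fs: float = 10.0
    lowpass2_hz: float = 0.3
    lowpass2_order: int = 2
    # segmentation / spectra
    window_length_s: float = 60.0
    bin_cpm: float = 0.3
    df_range_cpm: tuple[float, float] = (0.0, 15.0)
    total_band_cpm: tuple[float, float] = (6.0, 15.0)
    band_inner_cpm: float = 1.0   # normo half-width around DF
    band_outer_cpm: float = 3.0   # brady/tachy outer offset from DF
    alpha: float = 0.05
    # artifact blanking
    artifact_threshold_k: float = 8.0
    blank_halfwidth_s: float = 30.0
    # feature options
    normalize_mode: str = "median"        # "median" (ratio) or "center" (subtract)
    band_edge_mode: str = "per_segment"   # or "session" (validated session DF)
    # classifier grids
    knn_neighbors: tuple[int, ...] = tuple(range(1, 11))
    svm_gamma: tuple[float, ...] = (0.001, 0.0001)
    svm_regularization: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    cv_folds: int = 5
    test_fraction: float = 0.2
    # repeat counts
    n_scrambles: int = 100
    ci_repeats: int = 20
    seed: int = 0

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing keys fall back to the defaults above."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = asdict(cfg)
    unknown = set(data) - set(known)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        if isinstance(known[key], tuple):
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = asdict(cfg)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
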