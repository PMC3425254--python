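"""Per-sample array quality metrics and exclusion rules.

Four whole-array summaries are computed per sample, mirroring the standard
pre-calling exclusions for Illumina-style CNV analysis: the standard
deviation of the LRR over all probes, the median BAF in the heterozygote
band, the BAF drift (mean squared departure of BAF from the canonical
diploid values 0 / 0.5 / 1), and the wave factor (variability of windowed
LRR means along the genome).  A sample is excluded if any criterion fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QCMetrics", "QCThresholds", "qc_metrics", "qc_table", "apply_qc"]


@dataclass(frozen=True)
class QCMetrics:
    lrr_sd: float
    baf_median: float
    baf_drift: float
    wave_factor: float


@dataclass(frozen=True)
class QCThresholds:
    """Default thresholds are the standard published exclusion criteria."""

    max_lrr_sd: float = 0.28
    baf_median_range: tuple = (0.45, 0.55)
    max_baf_drift: float = 0.002
    wave_factor_range: tuple = (-0.04, 0.04)

    def __post_init__(self) -> None:
        if self.baf_median_range[0] > self.baf_median_range[1]:
            raise ValueError("baf_median_range out of order")
        if self.wave_factor_range[0] > self.wave_factor_range[1]:
            raise ValueError("wave_factor_range out of order")


def qc_metrics(lrr_row, baf_row, window: int = 50) -> QCMetrics:
    """QC metrics for one sample.

    * ``lrr_sd``: sample SD (ddof=1) of the LRR over all probes.
    * ``baf_median``: median BAF over probes in the heterozygote band
      (BAF in (0.25, 0.75)); 0.5 if no probe falls in the band.
    * ``baf_drift``: mean squared distance from BAF to the nearest of
      {0, 0.5, 1}.
    * ``wave_factor``: population SD (ddof=0) of mean LRR over
      non-overlapping windows of ``window`` probes, trailing remainder
      dropped.
    """
    lrr = np.asarray(lrr_row, dtype=float)
    baf = np.asarray(baf_row, dtype=float)
    if lrr.ndim != 1 or lrr.shape != baf.shape:
        raise ValueError("lrr_row and baf_row must be equal-length vectors")
    if len(lrr) < max(2, window):
        raise ValueError(
            f"need at least max(2, window={window}) probes, got {len(lrr)}"
        )
    lrr_sd = float(np.std(lrr, ddof=1))
    het = (baf > 0.25) & (baf < 0.75)
    baf_median = float(np.median(baf[het])) if het.any() else 0.5
    dist = np.minimum.reduce(
        [np.abs(baf - 0.0), np.abs(baf - 0.5), np.abs(baf - 1.0)]
    )
    baf_drift = float(np.mean(dist**2))
    n_win = len(lrr) // window
    win_means = lrr[: n_win * window].reshape(n_win, window).mean(axis=1)
    wave_factor = float(np.std(win_means, ddof=0))
    return QCMetrics(lrr_sd, baf_median, baf_drift, wave_factor)


def qc_table(lrr, baf, sample_ids=None, window: int = 50) -> pd.DataFrame:
    """QC metrics for every sample of an LRR/BAF matrix pair."""
    lrr = np.atleast_2d(lrr)
    baf = np.atleast_2d(baf)
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(lrr.shape[0])]
    rows = [qc_metrics(lrr[i], baf[i], window) for i in range(lrr.shape[0])]
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "lrr_sd": [r.lrr_sd for r in rows],
            "baf_median": [r.baf_median for r in rows],
            "baf_drift": [r.baf_drift for r in rows],
            "wave_factor": [r.wave_factor for r in rows],
        }
    )


def apply_qc(
    metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> pd.DataFrame:
    """Pass/fail flag plus the list of violated criteria per sample."""
    out = metrics.copy()
    reasons = []
    for _, row in metrics.iterrows():
        r = []
        if row["lrr_sd"] > thresholds.max_lrr_sd:
            r.append("max_lrr_sd")
        lo, hi = thresholds.baf_median_range
        if not (lo <= row["baf_median"] <= hi):
            r.append("baf_median_range")
        if row["baf_drift"] > thresholds.max_baf_drift:
            r.append("max_baf_drift")
        lo, hi = thresholds.wave_factor_range
        if not (lo <= row["wave_factor"] <= hi):
            r.append("wave_factor_range")
        reasons.append(",".join(r))
    out["qc_pass"] = [not r for r in reasons]
    out["reasons"] = reasons
    return out
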