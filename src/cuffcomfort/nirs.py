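"""Near-infrared spectroscopy (NIRS) processing.

Tissue oxygen saturation is the oxygenated fraction of total hemoglobin,

    StO2 = 100 * oxyHb / (oxyHb + deoxyHb)   [%]

computed per sample from the instrument's concentration exports (arbitrary
units; the ratio is scale invariant).  The per-epoch discomfort statistic is
the *decrease in StO2*: the mean over a 30-s pre-onset baseline block minus
the mean of the last full 30-s block of the epoch, in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eda import _check_uniform


class NIRSError(ValueError):
    """Raised for invalid NIRS inputs."""


@dataclass
class NIRSRecording:
    """Paired oxy/deoxy-hemoglobin traces at a uniform sampling rate."""

    time_s: np.ndarray
    oxyHb_au: np.ndarray
    deoxyHb_au: np.ndarray
    fs_hz: float = 5.0
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.oxyHb_au = np.asarray(self.oxyHb_au, dtype=float)
        self.deoxyHb_au = np.asarray(self.deoxyHb_au, dtype=float)
        if not (self.time_s.shape == self.oxyHb_au.shape == self.deoxyHb_au.shape):
            raise NIRSError("time_s, oxyHb_au, deoxyHb_au must share a shape")
        if self.fs_hz <= 0:
            raise NIRSError("fs_hz must be positive")
        _check_uniform(self.time_s)
        if not (np.all(np.isfinite(self.oxyHb_au)) and np.all(np.isfinite(self.deoxyHb_au))):
            raise NIRSError("non-finite hemoglobin samples")


@dataclass
class StO2Series:
    time_s: np.ndarray
    sto2_pct: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class StO2Decrease:
    baseline_pct: float
    block_means_pct: tuple[float, ...]
    decrease_pct: float


def compute_sto2(recording: NIRSRecording) -> StO2Series:
    """Per-sample tissue oxygen saturation in percent.

    Samples with non-positive total hemoglobin, or a ratio outside
    [0, 100] (possible under measurement noise near zero concentrations),
    are flagged invalid rather than raising.
    """
    total = recording.oxyHb_au + recording.deoxyHb_au
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = 100.0 * recording.oxyHb_au / total
    valid = (total > 0) & np.isfinite(sto2) & (sto2 >= 0.0) & (sto2 <= 100.0)
    sto2 = np.where(valid, sto2, np.nan)
    return StO2Series(time_s=recording.time_s, sto2_pct=sto2, valid_mask=valid)


def compute_sto2_decrease(
    series: StO2Series,
    epoch: tuple[float, float],
    block_s: float = 30.0,
    baseline_s: float = 30.0,
    block_stat: str = "last",
) -> StO2Decrease:
    """Block-averaged StO2 drop for one pressure epoch.

    The epoch is tiled with half-open ``block_s`` blocks from its onset;
    partial trailing blocks are discarded.  ``block_stat`` selects whether
    the decrease is referenced to the last full block (default) or to the
    minimum block mean.  Invalid samples are excluded from every mean.
    """
    onset, offset = epoch
    if offset <= onset:
        raise NIRSError(f"empty epoch [{onset}, {offset})")
    n_blocks = int(np.floor((offset - onset) / block_s))
    if n_blocks < 1:
        raise NIRSError(
            f"epoch of {offset - onset:.1f} s holds no full {block_s:.0f}-s block"
        )
    if block_stat not in ("last", "min"):
        raise NIRSError(f"unknown block_stat {block_stat!r}")

    t = series.time_s

    def _mean(t0: float, t1: float, what: str) -> float:
        m = (t >= t0) & (t < t1) & series.valid_mask
        if not m.any():
            raise NIRSError(f"no valid samples in {what} window [{t0}, {t1})")
        return float(series.sto2_pct[m].mean())

    baseline = _mean(onset - baseline_s, onset, "baseline")
    blocks = tuple(
        _mean(onset + k * block_s, onset + (k + 1) * block_s, f"block {k}")
        for k in range(n_blocks)
    )
    ref = blocks[-1] if block_stat == "last" else min(blocks)
    return StO2Decrease(baseline_pct=baseline, block_means_pct=blocks,
                        decrease_pct=baseline - ref)


__all__ = ["NIRSError", "NIRSRecording", "StO2Series", "StO2Decrease",
           "compute_sto2", "compute_sto2_decrease"]
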