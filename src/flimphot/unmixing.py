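"""Red/green spectral bleed-through estimation and correction.

With two emission channels, a green-emitting fluorophore (Peredox or
SBFI) contaminates the red channel by a fixed fraction of its green
photon count.  The correction is linear: measure the red:green ratio in
control ROIs containing only the green fluorophore, then subtract
``ratio * green`` from each red measurement.  The value measured for
SBFI bleed-through into the red channel in the source preparation is
0.053 (red counts were 5.3 +/- 1.2 % of green counts, n = 42 control
cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tcspc import TCSPCHistogram

__all__ = ["UnmixingRatio", "estimate_bleedthrough", "unmix_red", "mix_red"]

logger = logging.getLogger(__name__)

SBFI_RED_BLEEDTHROUGH = 0.053


@dataclass(frozen=True)
class UnmixingRatio:
    """Red counts per green count for the contaminating fluorophore."""

    ratio: float
    n_control_rois: int = 0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.ratio < 1:
            raise ValueError(f"ratio must be in [0, 1), got {self.ratio}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def estimate_bleedthrough(
    control_pairs: Sequence[tuple[float, float]],
) -> UnmixingRatio:
    """Estimate the bleed-through ratio from (red, green) control counts.

    The ratio is the mean of per-ROI red/green ratios and the spread is
    their sample standard deviation, following the per-cell percentage
    convention used to report the 5.3 +/- 1.2 % SBFI value.
    """
    if len(control_pairs) < 1:
        raise ValueError("need at least one control (red, green) pair")
    ratios = []
    for i, (red, green) in enumerate(control_pairs):
        if green <= 0:
            raise ValueError(
                f"control pair {i} has green_counts={green}; must be > 0"
            )
        ratios.append(red / green)
    ratios = np.asarray(ratios, dtype=float)
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return UnmixingRatio(
        ratio=float(ratios.mean()), n_control_rois=ratios.size, sd=sd
    )


def _unmix_arrays(
    red: np.ndarray, green: np.ndarray, ratio: float
) -> tuple[np.ndarray, int]:
    corrected = red - ratio * green
    clamped = int(np.count_nonzero(corrected < 0))
    return np.maximum(corrected, 0.0), clamped


def unmix_red(
    red: TCSPCHistogram | np.ndarray | float,
    green: TCSPCHistogram | np.ndarray | float,
    ratio: UnmixingRatio | float,
):
    """Subtract green bleed-through from the red channel.

    Accepts per-bin histograms (returns a corrected
    :class:`TCSPCHistogram`) or scalar/array intensities (returns the
    same shape).  Negative results from over-subtraction are clamped to
    zero; the number of clamped entries is logged.
    """
    r = ratio.ratio if isinstance(ratio, UnmixingRatio) else float(ratio)
    if isinstance(red, TCSPCHistogram) != isinstance(green, TCSPCHistogram):
        raise ValueError("red and green must both be histograms or both counts")
    if isinstance(red, TCSPCHistogram):
        if red.n_bins != green.n_bins or not np.allclose(
            red.bin_edges, green.bin_edges
        ):
            raise ValueError("red and green histograms have mismatched bins")
        corrected, clamped = _unmix_arrays(
            red.counts.astype(float), green.counts.astype(float), r
        )
        if clamped:
            logger.info("unmix_red clamped %d negative bins to 0", clamped)
        return TCSPCHistogram(
            bin_edges=red.bin_edges,
            counts=np.round(corrected).astype(int),
            channel=red.channel,
            laser_period_ns=red.laser_period_ns,
            frame_time_s=red.frame_time_s,
        )
    red_arr = np.asarray(red, dtype=float)
    green_arr = np.asarray(green, dtype=float)
    if red_arr.shape != green_arr.shape:
        raise ValueError(
            f"shape mismatch: red {red_arr.shape} vs green {green_arr.shape}"
        )
    corrected, clamped = _unmix_arrays(red_arr, green_arr, r)
    if clamped:
        logger.info("unmix_red clamped %d negative values to 0", clamped)
    if np.isscalar(red) or red_arr.ndim == 0:
        return float(corrected)
    return corrected


def mix_red(
    pure_red: np.ndarray, green: np.ndarray, ratio: UnmixingRatio | float
) -> np.ndarray:
    """Forward model of contamination: red + ratio * green (for tests
    and synthetic rendering)."""
    r = ratio.ratio if isinstance(ratio, UnmixingRatio) else float(ratio)
    return np.asarray(pure_red, dtype=float) + r * np.asarray(green, dtype=float)
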