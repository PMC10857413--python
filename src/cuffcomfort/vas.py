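"""Visual analog scale (VAS) normalization.

Raw discomfort ratings (0 = no pain, 10 = worst possible pain) are
normalized against each subject's anchor rating, collected at a fixed
60 kPa reference pressure, to remove individual differences in discomfort
threshold:

    normalized VAS = 100 * VAS(condition) / VAS(60 kPa)   [%]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)


class VASError(ValueError):
    """Raised when a rating cannot be normalized."""


def normalize_vas(vas_raw: float, anchor_raw: float) -> float:
    """Normalize a raw rating to percent of the subject's 60 kPa anchor.

    Values above 100% are legitimate (a condition rated above the anchor)
    and logged as a warning.  A non-positive anchor leaves the ratio
    undefined and raises rather than returning NaN.
    """
    if anchor_raw <= 0:
        raise VASError(f"anchor rating must be positive, got {anchor_raw}")
    if not 0 <= vas_raw <= 10:
        raise VASError(f"raw VAS must lie in [0, 10], got {vas_raw}")
    pct = 100.0 * vas_raw / anchor_raw
    if pct > 100.0:
        logger.warning("normalized VAS %.1f%% exceeds the 60 kPa anchor", pct)
    return pct


@dataclass(frozen=True)
class VASRecord:
    """One subject x pressure rating with its normalization."""

    subject_id: str
    pressure_kPa: float
    vas_raw: float
    anchor_raw: float

    @property
    def vas_norm_pct(self) -> float:
        return normalize_vas(self.vas_raw, self.anchor_raw)


__all__ = ["VASError", "VASRecord", "normalize_vas"]
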