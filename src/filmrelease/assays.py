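"""Summary arithmetic for film characterization assays.

Small, exactly-specified helpers: the gravimetric swelling ratio of a film
after immersion, and percent-decrease / fold-change summaries used when
comparing antioxidant readouts (TPC, DPPH, FRAP) between formulations.
Internal values are kept at full precision; round only at display time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["WeighingPair", "swelling_ratio", "percent_decrease", "fold_change"]


@dataclass(frozen=True)
class WeighingPair:
    """Initial and final film weights from a swelling test (grams)."""

    W_i: float
    W_f: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.W_i) or self.W_i <= 0.0:
            raise ValueError(f"initial weight W_i must be positive, got {self.W_i!r}")
        if not math.isfinite(self.W_f) or self.W_f < 0.0:
            raise ValueError(f"final weight W_f must be >= 0, got {self.W_f!r}")


def swelling_ratio(pair: WeighingPair) -> float:
    """Percent weight gain after immersion: ``(W_f - W_i) / W_i * 100``."""
    return (pair.W_f - pair.W_i) / pair.W_i * 100.0


def percent_decrease(reference: float, value: float) -> float:
    """Percent decrease of ``value`` relative to ``reference``.

    ``(reference - value) / reference * 100``; negative if the value
    increased.
    """
    if not math.isfinite(reference) or reference <= 0.0:
        raise ValueError(f"reference must be positive, got {reference!r}")
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"value must be >= 0, got {value!r}")
    return (reference - value) / reference * 100.0


def fold_change(treated: float, control: float) -> float:
    """Ratio ``treated / control`` of two positive readouts."""
    if not math.isfinite(treated) or treated <= 0.0:
        raise ValueError(f"treated must be positive, got {treated!r}")
    if not math.isfinite(control) or control <= 0.0:
        raise ValueError(f"control must be positive, got {control!r}")
    return treated / control
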