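"""Growth-rate arithmetic and the EVOLVING vs STABLE classification.

Doubling time comes from passage counts: DT = t / n for n splits over t days
(every division exponential with fixed pre-confluence plate size, so
N(t)/N(0) = 2^n).  Growth rate is GR = ln(2) / DT.  A model is called
EVOLVING when it acquires at least 10 alterations per day of culture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

__all__ = [
    "GrowthRecord",
    "EvolvabilityCall",
    "EvolvabilityError",
    "doubling_time",
    "growth_rate",
    "mutation_rate",
    "classify",
    "round_half_up",
    "EVOLVING_THRESHOLD",
]

#: Alterations per day at or above which a model is called EVOLVING.
EVOLVING_THRESHOLD = 10.0


class EvolvabilityError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for table-facing output."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def doubling_time(n: int, t: float) -> float:
    """Doubling time in days from n passages over t days of culture (t / n)."""
    if n < 1:
        raise EvolvabilityError(f"number of passages must be >= 1, got {n}")
    if t <= 0:
        raise EvolvabilityError(f"days of culture must be positive, got {t}")
    return t / n


def growth_rate(dt: float) -> float:
    """Growth rate per day: ln(2) / DT."""
    if dt <= 0:
        raise EvolvabilityError(f"doubling time must be positive, got {dt}")
    return math.log(2) / dt


@dataclass
class GrowthRecord:
    """In-vitro growth bookkeeping for one cell model.

    ``k`` (cells per plate at confluence) and ``split_ratio`` are carried for
    documentation only; both cancel out of the DT/GR formulas.
    """

    sample_id: str
    n: int
    t: float
    k: Optional[float] = None
    split_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.t <= 0:
            raise EvolvabilityError(
                f"{self.sample_id}: need n >= 1 and t > 0 (got n={self.n}, t={self.t})"
            )

    @property
    def dt(self) -> float:
        return doubling_time(self.n, self.t)

    @property
    def gr(self) -> float:
        return growth_rate(self.dt)


def mutation_rate(n_gained: int, elapsed_days: float) -> float:
    """Alterations acquired per day of culture."""
    if elapsed_days <= 0:
        raise EvolvabilityError(f"elapsed_days must be positive, got {elapsed_days}")
    if n_gained < 0:
        raise EvolvabilityError("gained count cannot be negative")
    return n_gained / elapsed_days


def classify(rate: float, threshold: float = EVOLVING_THRESHOLD) -> str:
    """EVOLVING iff the per-day alteration rate reaches the threshold."""
    if rate < 0:
        raise EvolvabilityError("rate cannot be negative")
    return "EVOLVING" if rate >= threshold else "STABLE"


@dataclass
class EvolvabilityCall:
    """Classification of one sample from its gained-variant count."""

    sample_id: str
    gained_count: int
    elapsed_days: float
    threshold: float = EVOLVING_THRESHOLD
    n_doublings: Optional[int] = None

    @property
    def rate(self) -> float:
        return mutation_rate(self.gained_count, self.elapsed_days)

    @property
    def rate_per_doubling(self) -> Optional[float]:
        if not self.n_doublings:
            return None
        return self.gained_count / self.n_doublings

    @property
    def label(self) -> str:
        return classify(self.rate, self.threshold)
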