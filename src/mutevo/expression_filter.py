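"""Significance filter for an externally fitted differential-expression table.

The model fitting (e.g., DESeq2) happens upstream; this module applies the
compound significance rule to its output: adjusted p below 0.05, and either
log2 fold change <= -1 with the reference group's median FPKM >= 10 (down),
or log2 fold change >= 1 with the target group's median FPKM >= 10 (up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = ["DEGRecord", "DEGError", "filter_deg", "deg_direction"]


class DEGError(ValueError):
    pass


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression summary (target vs reference)."""

    gene: str
    log2fc: float
    padj: float
    median_fpkm_ref: float
    median_fpkm_target: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise DEGError(f"{self.gene}: padj {self.padj} outside [0,1]")
        if self.median_fpkm_ref < 0 or self.median_fpkm_target < 0:
            raise DEGError(f"{self.gene}: negative FPKM")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def deg_direction(rec: DEGRecord) -> Optional[str]:
    """"down"/"up" when the record passes the significance rule, else None."""
    if rec.padj >= 0.05:
        return None
    if rec.log2fc <= -1.0 and rec.median_fpkm_ref >= 10.0:
        return "down"
    if rec.log2fc >= 1.0 and rec.median_fpkm_target >= 10.0:
        return "up"
    return None


def filter_deg(
    records: Iterable[DEGRecord],
) -> tuple[list[tuple[DEGRecord, str]], int]:
    """Keep significant records with their direction; tally malformed ones.

    Records with missing fields are rejected (counted, not raised) so one bad
    table row cannot abort a run.
    """
    kept: list[tuple[DEGRecord, str]] = []
    n_rejected = 0
    for rec in records:
        if any(
            _is_missing(x)
            for x in (rec.log2fc, rec.padj, rec.median_fpkm_ref, rec.median_fpkm_target)
        ):
            n_rejected += 1
            continue
        direction = deg_direction(rec)
        if direction is not None:
            kept.append((rec, direction))
    return kept, n_rejected
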