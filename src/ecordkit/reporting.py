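"""Summary arithmetic for DEG tables and ECORD sets.

Small, exact helpers so every printed percentage and per-cluster mean is the
product of one audited code path rather than ad hoc rounding at call sites.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .ecord_detection import GeneCluster
from .genome_model import DEGRecord, GeneClass


def fraction_percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to ``digits``."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round(100.0 * numerator / denominator, digits)


def mean_per(total: int, n: int, digits: int = 1) -> float:
    """Mean ``total / n`` rounded to ``digits`` (e.g. DEGs per cluster)."""
    if n == 0:
        raise ZeroDivisionError("n is zero")
    return round(total / n, digits)


def deg_direction_summary(degs: Mapping[str, DEGRecord]) -> dict[str, float]:
    """Counts of up/down DEGs and the up percentage."""
    up = sum(1 for r in degs.values() if r.klass == GeneClass.DEG_UP)
    down = sum(1 for r in degs.values() if r.klass == GeneClass.DEG_DOWN)
    total = up + down
    return {"n_up": up, "n_down": down, "n_deg": total,
            "percent_up": fraction_percent(up, total) if total else float("nan")}


def ecord_summary(ecords: Sequence[GeneCluster],
                  degs: Mapping[str, DEGRecord] | None = None,
                  direction: str = "UP") -> dict[str, float]:
    """Headline ECORD statistics: count, member DEGs, mean size, and the
    fraction of all same-direction DEGs that fall inside ECORDs."""
    n = len(ecords)
    member_total = sum(e.deg_count for e in ecords)
    out: dict[str, float] = {"n_ecords": n, "n_member_degs": member_total}
    if n:
        out["mean_degs_per_ecord"] = mean_per(member_total, n)
    if degs is not None:
        klass = GeneClass.DEG_UP if direction == "UP" else GeneClass.DEG_DOWN
        n_dir = sum(1 for r in degs.values() if r.klass == klass)
        if n_dir:
            out["percent_degs_in_ecords"] = fraction_percent(member_total, n_dir)
    return out
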