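"""Summary layer: per-order BIN counts, primer efficiencies and the
sorted-versus-combined comparison.

All printed percentages use round-half-up to the nearest integer, the
convention that reproduces every count ratio reported for this kind of
survey (e.g. 268/390 -> 69, 31/35 -> 89).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .score import BinScoreCard, ScoringMatrix, DEFAULT_MATRIX


def percent(numerator: int, denominator: int) -> int:
    """Round-half-up integer percentage of a count ratio."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (200 * numerator + denominator) // (2 * denominator)


@dataclass(frozen=True)
class OrderSummary:
    order_name: str
    total_bins: int
    high_score_bins: int
    high_score_pct: int


@dataclass(frozen=True)
class ComparisonSummary:
    bins_sorted: int
    bins_combined_shared: int
    high_score_sorted: int
    high_score_shared: int
    shared_pct: int
    high_score_shared_pct: int


def summarize_orders(
    cards: list[BinScoreCard], order_of_bin: dict[str, str]
) -> list[OrderSummary]:
    """Per-order BIN counts and high-score fractions.

    ``order_of_bin`` maps BIN -> order name (from the reference taxonomy);
    orders with no detected BIN are omitted.
    """
    per_order: dict[str, list[BinScoreCard]] = {}
    for c in cards:
        order = order_of_bin.get(c.bin_id, "")
        per_order.setdefault(order, []).append(c)
    out = []
    for order in sorted(per_order):
        group = per_order[order]
        total = len({c.bin_id for c in group})
        high = len({c.bin_id for c in group if c.high_score})
        out.append(OrderSummary(order, total, high, percent(high, total)))
    return out


def primer_efficiency(
    cards: list[BinScoreCard],
    order_of_bin: dict[str, str],
    amplicon_names: list[str],
    denominator: str = "detections",
) -> pd.DataFrame:
    """Order x amplicon table of integer percentages.

    A BIN detected by amplicon *a* contributes one BIN-amplicon detection to
    *a* in its order. With ``denominator="detections"`` (default) each cell
    is the share of the order's detections carried by that amplicon, so rows
    sum to ~100; with ``denominator="bins"`` each cell is the percentage of
    the order's BINs that amplicon detected. A pooled "total" row is added.
    """
    if denominator not in ("detections", "bins"):
        raise ValueError("denominator must be 'detections' or 'bins'")
    counts: dict[str, dict[str, int]] = {}
    bins_per_order: dict[str, set[str]] = {}
    for c in cards:
        order = order_of_bin.get(c.bin_id, "")
        row = counts.setdefault(order, {a: 0 for a in amplicon_names})
        bins_per_order.setdefault(order, set()).add(c.bin_id)
        for amp in c.scores:
            if amp in row:
                row[amp] += 1
    orders = sorted(counts)
    rows = []
    for order in orders + ["total"]:
        if order == "total":
            row_counts = {
                a: sum(counts[o][a] for o in orders) for a in amplicon_names
            }
            n_bins = len(set().union(*bins_per_order.values())) if bins_per_order else 0
        else:
            row_counts = counts[order]
            n_bins = len(bins_per_order[order])
        denom = sum(row_counts.values()) if denominator == "detections" else n_bins
        rows.append(
            {
                "order_name": order,
                **{
                    a: (percent(row_counts[a], denom) if denom else 0)
                    for a in amplicon_names
                },
            }
        )
    return pd.DataFrame(rows).set_index("order_name")


def compare_sorted_vs_combined(
    cards_sorted: list[BinScoreCard],
    cards_combined: list[BinScoreCard],
    matrix: ScoringMatrix = DEFAULT_MATRIX,
) -> ComparisonSummary:
    """How much of the pre-sorted result the combined (unsorted) sample recovers.

    Shared = BINs detected in both; high-score shared = BINs that are high
    score in the sorted samples AND reach the threshold in the combined one.
    """
    sorted_bins = {c.bin_id for c in cards_sorted}
    combined_bins = {c.bin_id for c in cards_combined}
    shared = sorted_bins & combined_bins
    hs_sorted = {c.bin_id for c in cards_sorted if c.high_score}
    hs_combined = {
        c.bin_id
        for c in cards_combined
        if c.total_score >= matrix.high_score_threshold
    }
    hs_shared = hs_sorted & hs_combined
    return ComparisonSummary(
        bins_sorted=len(sorted_bins),
        bins_combined_shared=len(shared),
        high_score_sorted=len(hs_sorted),
        high_score_shared=len(hs_shared),
        shared_pct=percent(len(shared), len(sorted_bins)) if sorted_bins else 0,
        high_score_shared_pct=(
            percent(len(hs_shared), len(hs_sorted)) if hs_sorted else 0
        ),
    )
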