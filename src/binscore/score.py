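"""The four-amplicon BIN confidence scoring matrix.

Each amplicon's best-hit identity for a BIN is mapped to a band score:

    97.00-97.99%  ->  70
    98.00-98.99%  -> 150
    99.00-99.99%  -> 240
    100%          -> 340

identities below 97% contribute nothing (they absorb sequencing error and
within-species variation). The four per-amplicon scores are summed into an
overall confidence index per BIN: the maximum is 1360 (100% on all four
amplicons), the minimum non-zero total is 70 (one amplicon below 98%), and a
BIN detected at 97% by every amplicon totals only 280. BINs totalling at
least 300 points are classified "high score"; the threshold is deliberately
above 280 so that single-band evidence on all amplicons is not enough, and a
sub-100% detection needs at least two amplicons to qualify.

Bands are half-open on two-decimal identities, with exactly 100.00 in the top
band, so any identity in [97, 100] lands in exactly one band (99.995 -> 240).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class ScoringMatrix:
    """Identity-band scores, minimum identity and the high-score threshold."""

    # (band lower bound in percent, score); upper bound is the next band's
    # lower bound, the last band is the exact top identity
    bands: tuple[tuple[float, int], ...] = (
        (97.0, 70),
        (98.0, 150),
        (99.0, 240),
        (100.0, 340),
    )
    high_score_threshold: int = 300

    @property
    def min_identity(self) -> float:
        return self.bands[0][0]

    @property
    def max_single(self) -> int:
        return self.bands[-1][1]


DEFAULT_MATRIX = ScoringMatrix()


@dataclass
class BinScoreCard:
    """Per-BIN evidence across amplicons: identities, band scores, total."""

    bin_id: str
    sample: str = ""
    identities: dict[str, float] = field(default_factory=dict)
    scores: dict[str, int] = field(default_factory=dict)
    total_score: int = 0
    high_score: bool = False
    n_amplicons_detected: int = 0


def score_identity(identity_pct: float, matrix: ScoringMatrix = DEFAULT_MATRIX):
    """Band score for one identity percentage, or None below the 97% floor."""
    if not 0.0 <= identity_pct <= 100.0:
        raise ValueError(f"identity must be in [0, 100], got {identity_pct}")
    if identity_pct < matrix.min_identity:
        return None
    score = None
    for lower, band_score in matrix.bands:
        if identity_pct >= lower:
            score = band_score
    return score


def best_identity_per_bin(hits: pd.DataFrame) -> dict[str, float]:
    """Best (maximum) identity per BIN over all clusters of one sample/amplicon
    hit table. Identities below the scoring floor are retained here; the
    filtering happens at scoring time."""
    with_hits = hits[hits["bin_id"].astype(bool) & hits["identity_pct"].notna()]
    if with_hits.empty:
        return {}
    return with_hits.groupby("bin_id")["identity_pct"].max().to_dict()


def aggregate_bin_scores(
    per_amplicon: dict[str, dict[str, float]],
    matrix: ScoringMatrix = DEFAULT_MATRIX,
    sample: str = "",
) -> list[BinScoreCard]:
    """Sum per-amplicon band scores into an overall confidence index per BIN.

    ``per_amplicon`` maps amplicon name -> {bin_id -> best identity}. BINs
    with no amplicon at or above the identity floor are omitted entirely.
    """
    bins: set[str] = set()
    for mapping in per_amplicon.values():
        bins.update(mapping)
    cards = []
    for bin_id in sorted(bins):
        card = BinScoreCard(bin_id=bin_id, sample=sample)
        for amp, mapping in per_amplicon.items():
            if bin_id not in mapping:
                continue
            ident = mapping[bin_id]
            card.identities[amp] = ident
            s = score_identity(ident, matrix)
            if s is not None:
                card.scores[amp] = s
        if not card.scores:
            continue
        card.total_score = sum(card.scores.values())
        card.n_amplicons_detected = len(card.scores)
        card.high_score = classify_high_score(card, matrix)
        cards.append(card)
    return cards


def classify_high_score(
    card: BinScoreCard, matrix: ScoringMatrix = DEFAULT_MATRIX
) -> bool:
    """True iff the summed confidence index reaches the threshold (>= 300)."""
    return card.total_score >= matrix.high_score_threshold


def cards_to_frame(
    cards: list[BinScoreCard],
    amplicon_names: list[str] | None = None,
    taxonomy: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Tabulate score cards; optionally joins per-BIN taxonomy columns."""
    if amplicon_names is None:
        amplicon_names = sorted({a for c in cards for a in c.identities})
    rows = []
    for c in cards:
        row: dict = {"bin_id": c.bin_id, "sample": c.sample}
        if taxonomy is not None:
            row.update(taxonomy.get(c.bin_id, {}))
        for amp in amplicon_names:
            row[f"identity_{amp}"] = c.identities.get(amp)
            row[f"score_{amp}"] = c.scores.get(amp, 0)
        row["total_score"] = c.total_score
        row["n_amplicons_detected"] = c.n_amplicons_detected
        row["high_score"] = c.high_score
        rows.append(row)
    return pd.DataFrame(rows)
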