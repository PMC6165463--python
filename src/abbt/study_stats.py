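"""Reliability and counting-performance statistics of the pilot study.

The package ships CSV transcriptions of the pilot-study outcome tables
(nine participants with Parkinson's disease, three assessment sessions,
both hands: 54 trials).  The per-trial measurement error is

    epsilon = (manual count - automatic count) / manual count,

i.e. the fraction of cubes the automatic counter lost.  Epsilon is always
recomputed from the counts: three printed epsilon cells in the source table
are typographic errors (0.038, 0.003, 0.008 where the counts give 0.138,
0.103, 0.108), and only the recomputed values reproduce the published
summary statistics.  A hand's success percentage is the mean of per-trial
success ratios (1 - epsilon) x 100 over its 27 trials, not the pooled-count
ratio -- again, only this definition reproduces the published 93.45 / 94.42.

Agreement between automatic and manual scores is summarised by Spearman's
rank correlation (Pearson correlation of mid-ranked data).
"""

from __future__ import annotations

import hashlib
import json
import statistics
from collections import Counter
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

HANDS = ("dominant", "non_dominant")

_FIXTURE_SHA256 = {
    "table1_participants.csv":
        "3ca9cb19ef4c02c1a7fa055300a3f79fcd68fba757551a3755f3eb169de68240",
    "table2_outcomes.csv":
        "a6510e9598252c31a8de7f0fc7a09b5056a69fdd2127ec9d4684cbddf2a1d3e1",
    "table3_counts.csv":
        "636725b7a497e5a7feae5a4b3a096108b49e6db06d298b80afb37d67f67438c9",
}


class FixtureError(RuntimeError):
    """A packaged fixture table is missing or corrupted."""


@dataclass(frozen=True)
class TrialRecord:
    """One trial: automatic (abbt) vs manual (bbt) count and its error."""

    participant: str
    session: int
    hand: str
    abbt_count: int
    bbt_count: int

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise ValueError(f"unknown hand {self.hand!r}")
        if not (0 <= self.abbt_count <= self.bbt_count):
            raise ValueError("require 0 <= automatic count <= manual count")

    @property
    def epsilon(self) -> float:
        """Fraction of cubes lost by the automatic counter."""
        return (self.bbt_count - self.abbt_count) / self.bbt_count

    @property
    def lost(self) -> int:
        return self.bbt_count - self.abbt_count


def _fixture_path(name: str) -> Path:
    path = resources.files("abbt.data") / name
    with resources.as_file(path) as p:
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        if digest != _FIXTURE_SHA256[name]:
            raise FixtureError(f"fixture checksum mismatch for {name}")
        return Path(p)


def load_fixture_tables(table2_path: str | Path | None = None,
                        table3_path: str | Path | None = None
                        ) -> tuple[pd.DataFrame, list[TrialRecord]]:
    """Load the packaged outcome tables (or user-supplied replacements).

    Returns the stage-outcome table (NC, Vavg, PT per trial) as a DataFrame
    and the 54 count-comparison trials as :class:`TrialRecord` objects with
    epsilon recomputed from the counts.
    """
    t2 = pd.read_csv(table2_path or _fixture_path("table2_outcomes.csv"))
    t3 = pd.read_csv(table3_path or _fixture_path("table3_counts.csv"))
    required2 = {"participant", "session", "hand", "nc", "vavg"}
    if not required2 <= set(t2.columns):
        raise FixtureError(f"outcome table needs columns {sorted(required2)}")
    trials = [
        TrialRecord(participant=row.participant, session=int(row.session),
                    hand=row.hand, abbt_count=int(row.abbt),
                    bbt_count=int(row.bbt))
        for row in t3.itertuples()
    ]
    if table3_path is None and len(trials) != 54:
        raise FixtureError("packaged trial table must contain 54 records")
    return t2, trials


def load_participants() -> pd.DataFrame:
    """Demographics of the nine study participants."""
    return pd.read_csv(_fixture_path("table1_participants.csv"))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (ties receive mid-ranks)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equally long vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(_scipy_stats.spearmanr(x, y).statistic)


def spearman_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided p-value of the Spearman coefficient (t approximation)."""
    return float(_scipy_stats.spearmanr(x, y).pvalue)


@dataclass(frozen=True)
class ReliabilityReport:
    """Counting performance and rank-correlation summary of the 54 trials."""

    rs_global: float
    rs_dominant: float
    rs_non_dominant: float
    rs_bbt_vs_vavg: float
    p_global: float
    success_dh_pct: float
    success_ndh_pct: float
    max_error_pct: float
    lost_histogram: dict[int, int]
    lost_median: float
    mean_cubes: float
    n_trials: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["lost_histogram"] = {str(k): v
                                     for k, v in self.lost_histogram.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [
            f"trials analysed:                 {self.n_trials}",
            f"mean manual count:               {self.mean_cubes:.1f} cubes",
            f"success, dominant hand:          {self.success_dh_pct:.2f} %",
            f"success, non-dominant hand:      {self.success_ndh_pct:.2f} %",
            f"maximum per-trial error:         {self.max_error_pct:.1f} %",
            f"median cubes lost per trial:     {self.lost_median:g}",
            f"Spearman auto vs manual (all):   {self.rs_global:.3f}"
            f"  (p = {self.p_global:.2g})",
            f"Spearman auto vs manual (DH):    {self.rs_dominant:.3f}",
            f"Spearman auto vs manual (NDH):   {self.rs_non_dominant:.3f}",
            f"Spearman manual vs velocity:     {self.rs_bbt_vs_vavg:.3f}",
            "lost-cube histogram (lost: trials): "
            + ", ".join(f"{k}: {v}" for k, v in sorted(self.lost_histogram.items())),
        ]
        return "\n".join(lines)


def success_summary(trials: Sequence[TrialRecord]) -> dict:
    """Counting-performance fields: per-hand mean success, maximum error,
    lost-cube histogram/median and mean manual count."""
    by_hand = {hand: [t for t in trials if t.hand == hand] for hand in HANDS}
    losses = [t.lost for t in trials]
    return {
        "success_dh_pct": 100.0 * float(
            np.mean([1 - t.epsilon for t in by_hand["dominant"]])),
        "success_ndh_pct": 100.0 * float(
            np.mean([1 - t.epsilon for t in by_hand["non_dominant"]])),
        "max_error_pct": 100.0 * max(t.epsilon for t in trials),
        "lost_histogram": dict(sorted(Counter(losses).items())),
        "lost_median": float(statistics.median(losses)),
        "mean_cubes": float(np.mean([t.bbt_count for t in trials])),
    }


def reliability_report(table2: pd.DataFrame,
                       trials: Sequence[TrialRecord]) -> ReliabilityReport:
    """Full reliability analysis: success summary plus Spearman coefficients
    between automatic and manual counts (globally and per hand) and between
    the manual count and the average displacement velocity."""
    abbt = [t.abbt_count for t in trials]
    bbt = [t.bbt_count for t in trials]
    key = table2.set_index(["participant", "session", "hand"])["vavg"]
    vavg = [float(key[(t.participant, t.session, t.hand)]) for t in trials]

    def per_hand(hand: str) -> float:
        sub = [t for t in trials if t.hand == hand]
        return spearman([t.abbt_count for t in sub], [t.bbt_count for t in sub])

    summary = success_summary(trials)
    return ReliabilityReport(
        rs_global=spearman(abbt, bbt),
        rs_dominant=per_hand("dominant"),
        rs_non_dominant=per_hand("non_dominant"),
        rs_bbt_vs_vavg=spearman(bbt, vavg),
        p_global=spearman_pvalue(abbt, bbt),
        n_trials=len(trials),
        **summary)
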