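"""Target-decoy FDR estimation with a single weighted ranking.

For each (database, target adduct) group, target ions and all sampled decoy
ions are merged into one list sorted by descending score.  With S_D decoy
adducts sampled per target formula, decoys carry weight 1/S_D so the decoy
count estimates the number of false targets at any rank.  With cumulative
counts T_i (targets) and D_i (decoys) at rank i, the continuous FDR is

    FDR_i = ((D_i + 1) / S_D) / ((T_i + 1) + (D_i + 1) / S_D)

with a rule-of-succession pseudocount of 1 on both counts, so the FDR is
never exactly zero.  A reverse cumulative minimum (standard q-value style)
makes the estimate non-decreasing down the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "RankEntry",
    "FdrRanking",
    "build_ranking",
    "estimate_fdr",
    "monotonic_adjust",
    "annotations_at",
]


@dataclass
class RankEntry:
    ion: Any  # caller's ion reference (AnnotationRecord, id, ...)
    score: float
    is_decoy: bool
    weight: float
    fdr_raw: float = float("nan")
    fdr_adjusted: float = float("nan")


@dataclass
class FdrRanking:
    group: tuple[str, str]  # (database id, target adduct)
    entries: list[RankEntry]
    S_D: int

    def to_frame(self) -> pd.DataFrame:
        """Audit dump: rank, score, is_decoy, T_i, D_i, fdr_raw, fdr_adjusted."""
        t = d = 0
        rows = []
        for rank, e in enumerate(self.entries, start=1):
            if e.is_decoy:
                d += 1
            else:
                t += 1
            rows.append(
                {
                    "rank": rank,
                    "score": e.score,
                    "is_decoy": e.is_decoy,
                    "T_i": t,
                    "D_i": d,
                    "fdr_raw": e.fdr_raw,
                    "fdr_adjusted": e.fdr_adjusted,
                }
            )
        return pd.DataFrame(rows)


def build_ranking(
    targets: list[tuple[Any, float]],
    decoys: list[tuple[Any, float]],
    S_D: int,
    group: tuple[str, str] = ("default", ""),
) -> FdrRanking:
    """Merge scored targets and decoys into one descending ranking.

    Stable sort by descending score; ties are broken decoy-before-target so
    tied scores never understate the FDR.  Targets have weight 1, decoys
    1/S_D.
    """
    if S_D < 1:
        raise ValueError("S_D must be >= 1")
    entries = [RankEntry(ion, float(s), False, 1.0) for ion, s in targets]
    entries += [RankEntry(ion, float(s), True, 1.0 / S_D) for ion, s in decoys]
    for e in entries:
        if not np.isfinite(e.score):
            raise ValueError("scores must be finite")
    # decoy-first on ties: sort key (score desc, is_decoy desc) via stable sort
    entries.sort(key=lambda e: (-e.score, not e.is_decoy))
    ranking = FdrRanking(group=group, entries=entries, S_D=S_D)
    estimate_fdr(ranking)
    monotonic_adjust(ranking)
    return ranking


def estimate_fdr(ranking: FdrRanking) -> np.ndarray:
    """Assign the raw continuous FDR at every rank (pseudocounted)."""
    S_D = ranking.S_D
    t = d = 0
    raw = np.empty(len(ranking.entries))
    for i, e in enumerate(ranking.entries):
        if e.is_decoy:
            d += 1
        else:
            t += 1
        dw = (d + 1) / S_D
        e.fdr_raw = dw / ((t + 1) + dw)
        raw[i] = e.fdr_raw
    return raw


def monotonic_adjust(ranking: FdrRanking) -> np.ndarray:
    """Reverse cumulative minimum: adjusted[i] = min_{j>=i} raw[j]."""
    raw = np.array([e.fdr_raw for e in ranking.entries])
    if raw.size == 0:
        return raw
    adjusted = np.minimum.accumulate(raw[::-1])[::-1]
    for e, a in zip(ranking.entries, adjusted):
        e.fdr_adjusted = float(a)
    return adjusted


def annotations_at(
    rankings: list[FdrRanking] | FdrRanking, threshold: float
) -> tuple[list[Any], list[Any]]:
    """Target ions with adjusted FDR <= threshold; decoys reported separately.

    Returns ``(targets, decoy_false_positives)``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(rankings, FdrRanking):
        rankings = [rankings]
    accepted: list[Any] = []
    false_pos: list[Any] = []
    for r in rankings:
        for e in r.entries:
            if e.fdr_adjusted <= threshold:
                (false_pos if e.is_decoy else accepted).append(e.ion)
    return accepted, false_pos
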