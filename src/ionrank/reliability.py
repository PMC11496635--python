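"""Reliability scoring for target-decoy annotation results.

Target and decoy ions are treated as positive and negative instances over a
sweep of FDR cutoffs.  At each observed adjusted-FDR cutoff the F-beta
score (beta = 0.5, weighting precision over recall because decoys outnumber
targets S_D-fold) is computed; the reliability of a default FDR threshold
(5/10/20/50%) is

    reliability = b[nearest cutoff to threshold] / max(b) * (1 - optim_fdr)

where ``optim_fdr`` is the cutoff maximizing F-beta.  The optimal default
threshold is the smallest one attaining the maximum reliability score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReliabilityResult",
    "DEFAULT_THRESHOLDS",
    "fbeta",
    "fbeta_curve",
    "reliability_score",
    "optimal_threshold",
    "assess_reliability",
]

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.20, 0.50)


@dataclass
class ReliabilityResult:
    f: np.ndarray  # ascending candidate FDR cutoffs
    b: np.ndarray  # matching F-beta values
    optim_fdr: float
    scores: dict[float, float]
    optimal_threshold: float


def fbeta(precision: float, recall: float, beta: float = 0.5) -> float:
    """F-beta; returns 0 by convention when precision == recall == 0."""
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def fbeta_curve(
    fdrs: np.ndarray,
    is_decoy: np.ndarray,
    beta: float = 0.5,
    decoy_weight: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """F-beta over all observed adjusted-FDR cutoffs.

    ``fdrs`` and ``is_decoy`` are aligned per-ion arrays (targets and
    decoys).  At cutoff c, predicted positives are ions with FDR <= c;
    precision counts targets among them, recall counts accepted targets
    over all targets.  Decoys count unweighted by default; a
    ``decoy_weight`` of 1/S_D is available as a documented alternative
    consistent with the weighted ranking.
    """
    fdrs = np.asarray(fdrs, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    n_targets = int((~is_decoy).sum())
    if n_targets == 0 or fdrs.size == 0:
        raise ValueError("need at least one target ion")
    cutoffs = np.unique(fdrs)
    b = np.empty(cutoffs.size)
    for i, c in enumerate(cutoffs):
        pred = fdrs <= c
        tp = int((pred & ~is_decoy).sum())
        fp = float((pred & is_decoy).sum()) * decoy_weight
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        recall = tp / n_targets
        b[i] = fbeta(precision, recall, beta)
    return cutoffs, b


def reliability_score(
    f: np.ndarray, b: np.ndarray, default_threshold: float
) -> float:
    """Reliability of annotating at a default FDR threshold given the curve.

    The cutoff nearest to the threshold indexes the curve (ties toward the
    smaller cutoff); argmax ties for the optimum also resolve toward the
    smaller cutoff (conservative).
    """
    f = np.asarray(f, dtype=float)
    b = np.asarray(b, dtype=float)
    if f.size == 0:
        raise ValueError("empty curve")
    i_star = int(np.argmin(np.abs(f - default_threshold)))  # first min = smaller f
    i_opt = int(np.argmax(b))  # first max = smaller f
    optim_fdr = f[i_opt]
    bmax = b[i_opt]
    if bmax == 0:
        return 0.0
    return float(b[i_star] / bmax * (1.0 - optim_fdr))


def optimal_threshold(scores: dict[float, float]) -> float:
    """Smallest default threshold attaining the maximum reliability score."""
    best = max(scores.values())
    return min(t for t, s in scores.items() if s == best)


def assess_reliability(
    fdrs: np.ndarray,
    is_decoy: np.ndarray,
    beta: float = 0.5,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    decoy_weight: float = 1.0,
) -> ReliabilityResult:
    """Full curve, per-threshold reliability scores and the selected optimum."""
    f, b = fbeta_curve(fdrs, is_decoy, beta=beta, decoy_weight=decoy_weight)
    i_opt = int(np.argmax(b))
    scores = {t: reliability_score(f, b, t) for t in thresholds}
    return ReliabilityResult(
        f=f,
        b=b,
        optim_fdr=float(f[i_opt]),
        scores=scores,
        optimal_threshold=optimal_threshold(scores),
    )
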