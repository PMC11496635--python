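"""End-to-end annotation of one dataset: candidates -> features -> scores
-> per-adduct target-decoy rankings -> continuous FDR -> reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fdr as fdr_mod
from .io import AnnotationRecord, CentroidedDataset, MoleculeRecord
from .isotopes import IonCandidate, build_candidates
from .ranker import RankerModel, predict_scaled
from .reliability import ReliabilityResult, assess_reliability
from .scoring import compute_features, msm

__all__ = ["AnnotationResult", "annotate_dataset", "annotation_counts"]


@dataclass
class AnnotationResult:
    """Scored, FDR-ranked annotation output for one dataset."""

    records: list[AnnotationRecord]  # targets, one per (formula, adduct)
    decoy_records: list[AnnotationRecord]  # decoys, one per (formula, adduct, group)
    rankings: dict[str, fdr_mod.FdrRanking]  # target adduct -> ranking
    reliability: ReliabilityResult | None
    skipped: list[str] = field(default_factory=list)

    def pooled_fdrs(self) -> tuple[np.ndarray, np.ndarray]:
        """(adjusted FDR, is_decoy) over all ranking entries, pooled."""
        fdrs, dec = [], []
        for r in self.rankings.values():
            for e in r.entries:
                fdrs.append(e.fdr_adjusted)
                dec.append(e.is_decoy)
        return np.asarray(fdrs), np.asarray(dec, dtype=bool)


def annotate_dataset(
    ds: CentroidedDataset,
    db: list[MoleculeRecord],
    target_adducts: tuple[str, ...] | None = None,
    S_D: int = 20,
    tol_ppm: float = 3.0,
    model: RankerModel | None = None,
    seed: int = 0,
    universe: list[str] | None = None,
    T: int = 4,
    database_id: str = "db",
    with_reliability: bool = True,
) -> AnnotationResult:
    """Annotate a dataset against a molecular database.

    Candidates (targets + shared decoys per formula) are scored with the
    five features; the ranking score is the model's scaled prediction when
    a trained model is supplied, otherwise the rule-based MSM.  For each
    target adduct, targets compete against all sampled decoy ions in a
    single weighted ranking; the continuous FDR (pseudocounted,
    monotonized) is assigned per ion.
    """
    candidates, skipped = build_candidates(
        db,
        target_adducts=target_adducts,
        polarity=ds.polarity,
        S_D=S_D,
        seed=seed,
        universe=universe,
        T=T,
    )
    feats = [compute_features(ds, c, tol_ppm=tol_ppm) for c in candidates]
    msm_scores = [msm(f) for f in feats]
    if model is not None:
        X = np.vstack([f.as_array() for f in feats])
        ml_scores = predict_scaled(model, X)
        scores = ml_scores
    else:
        ml_scores = [float("nan")] * len(candidates)
        scores = msm_scores

    def record(i: int) -> AnnotationRecord:
        c = candidates[i]
        return AnnotationRecord(
            formula=c.formula,
            adduct=c.adduct,
            is_decoy=c.is_decoy,
            features=feats[i],
            msm_score=msm_scores[i],
            ml_score=float(ml_scores[i]),
        )

    target_idx = [i for i, c in enumerate(candidates) if not c.is_decoy]
    decoy_idx = [i for i, c in enumerate(candidates) if c.is_decoy]
    adducts = sorted({candidates[i].adduct for i in target_idx})

    records: list[AnnotationRecord] = []
    decoy_records: list[AnnotationRecord] = []
    rankings: dict[str, fdr_mod.FdrRanking] = {}
    for adduct in adducts:
        t_entries = []
        for i in target_idx:
            if candidates[i].adduct != adduct:
                continue
            rec = record(i)
            records.append(rec)
            t_entries.append((rec, float(scores[i])))
        d_entries = []
        for i in decoy_idx:
            rec = record(i)
            decoy_records.append(rec)
            d_entries.append((rec, float(scores[i])))
        if not t_entries:
            continue
        ranking = fdr_mod.build_ranking(
            t_entries, d_entries, S_D=max(S_D, 1), group=(database_id, adduct)
        )
        for e in ranking.entries:
            e.ion.fdr_raw = e.fdr_raw
            e.ion.fdr = e.fdr_adjusted
        rankings[adduct] = ranking

    reliability = None
    if with_reliability and rankings:
        fdrs, dec = _pooled(rankings)
        if (~dec).sum() > 0 and dec.sum() > 0:
            reliability = assess_reliability(fdrs, dec)
    return AnnotationResult(
        records=records,
        decoy_records=decoy_records,
        rankings=rankings,
        reliability=reliability,
        skipped=skipped,
    )


def _pooled(rankings: dict[str, fdr_mod.FdrRanking]) -> tuple[np.ndarray, np.ndarray]:
    fdrs, dec = [], []
    for r in rankings.values():
        for e in r.entries:
            fdrs.append(e.fdr_adjusted)
            dec.append(e.is_decoy)
    return np.asarray(fdrs), np.asarray(dec, dtype=bool)


def annotation_counts(
    result: AnnotationResult, thresholds: tuple[float, ...] = (0.05, 0.10, 0.20, 0.50)
) -> dict[float, int]:
    """Number of accepted target annotations at each FDR threshold."""
    out = {}
    for thr in thresholds:
        accepted, _ = fdr_mod.annotations_at(list(result.rankings.values()), thr)
        out[thr] = len(accepted)
    return out
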