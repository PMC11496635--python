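"""Evaluation metrics: ranking quality, annotation-count deltas, intensity
profiling, molecular-class enrichment, and reference-list validation.

Average precision (AP) scores a target-vs-decoy ranking; MAP averages AP
over groups (dataset, or dataset x adduct).  Annotation deltas compare
annotation counts between two scoring approaches on log scales.  Class
enrichment applies a one-tailed Fisher exact test per molecular subclass
with log2 fold enrichment as the effect size.  Reference matching compares
accepted annotations against an external identification list (formula +
adduct) and reports TPR/FPR/FNR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CentroidedDataset, MoleculeRecord, extract_ion_image

__all__ = [
    "average_precision",
    "map_over_groups",
    "annotation_delta",
    "intensity_profile",
    "bh_adjust",
    "EnrichmentRow",
    "subclass_enrichment",
    "filter_enrichment_terms",
    "match_reference",
]


def average_precision(labels: np.ndarray | list[bool]) -> float:
    """Mean of precision@k over the target positions of a ranked list.

    ``labels`` is ordered best-first; True marks a target.  Raises on lists
    without any target.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0 or labels.sum() == 0:
        raise ValueError("average precision undefined without targets")
    ks = np.flatnonzero(labels) + 1
    precision_at_k = np.cumsum(labels)[ks - 1] / ks
    return float(precision_at_k.mean())


def map_over_groups(groups: dict[object, np.ndarray | list[bool]]) -> float:
    """Unweighted mean AP over groups; zero-target groups skipped with warning."""
    if not groups:
        raise ValueError("need at least one group")
    aps = []
    for key, labels in groups.items():
        arr = np.asarray(labels, dtype=bool)
        if arr.sum() == 0:
            warnings.warn(f"group {key!r} has no targets; skipped")
            continue
        aps.append(average_precision(arr))
    if not aps:
        raise ValueError("all groups lacked targets")
    return float(np.mean(aps))


def annotation_delta(
    counts_ml: int, counts_baseline: int
) -> tuple[float, float]:
    """(signed log10 difference, log2 fold change) of annotation counts.

    The difference transform is sign(ml - base) * log10(|ml - base| + 1);
    the fold change is log2((ml + 1) / (base + 1)).  The +1 pseudocounts
    keep both transforms finite at zero counts and map equal counts to 0.
    """
    ml, base = int(counts_ml), int(counts_baseline)
    if ml < 0 or base < 0:
        raise ValueError("counts must be nonnegative")
    diff = ml - base
    log_diff = math.copysign(math.log10(abs(diff) + 1), diff) if diff else 0.0
    return log_diff, float(np.log2((ml + 1) / (base + 1)))


def intensity_profile(
    ds: CentroidedDataset,
    ion_sets: dict[str, list[float]],
    tol_ppm: float = 3.0,
    q: float = 0.99,
) -> dict:
    """Median log10 per-ion high-quantile intensity per ion set.

    Each set maps a name (e.g. ``all_ml``, ``only_ml``, ``only_baseline``)
    to the principal-isotope m/z values of its ions.  Per ion, the
    q-quantile intensity over acquired pixels is computed from its ion
    image, log10-transformed, and the per-set median taken.  Pairs of sets
    are compared with a two-sided rank-sum test.  (Multiple-testing
    correction across datasets is the caller's concern; see
    :func:`bh_adjust`.)
    """
    per_set: dict[str, np.ndarray] = {}
    for name, mzs in ion_sets.items():
        vals = []
        for mz in mzs:
            img, _ = extract_ion_image(ds, mz, tol_ppm)
            quant = float(np.quantile(img.values[img.mask], q))
            if quant > 0:
                vals.append(np.log10(quant))
        if vals:
            per_set[name] = np.asarray(vals)
    medians = {name: float(np.median(v)) for name, v in per_set.items()}
    tests = {}
    names = sorted(per_set)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            stat, p = stats.ranksums(per_set[a], per_set[b])
            tests[(a, b)] = {"statistic": float(stat), "p_value": float(p)}
    return {"medians": medians, "tests": tests, "per_ion": per_set}


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))


@dataclass
class EnrichmentRow:
    subclass: str
    a: int  # query in subclass
    b: int  # query not in subclass
    c: int  # background-minus-query in subclass
    d: int  # remainder
    p_value: float
    log2_fold_enrichment: float


def subclass_enrichment(
    query_formulas: list[str] | set[str],
    background: list[MoleculeRecord],
    alternative: str = "greater",
) -> list[EnrichmentRow]:
    """Per-subclass Fisher exact enrichment of a query against a database.

    The background universe is the database's subclass-labeled molecules;
    the query is intersected with it.  For each subclass: a/b split the
    query by membership, c/d split the rest of the background.  One-tailed
    ("greater") by default; ``alternative="two-sided"`` is available.
    Log2 fold enrichment compares the query's subclass rate with the
    background rate.
    """
    labeled = [m for m in background if m.subclass]
    if not labeled:
        raise ValueError("no subclass-labeled molecules in background")
    query = {f for f in query_formulas} & {m.formula for m in labeled}
    if not query:
        return []
    rows: list[EnrichmentRow] = []
    n_bg = len(labeled)
    n_q = len(query)
    for subclass in sorted({m.subclass for m in labeled}):
        members = {m.formula for m in labeled if m.subclass == subclass}
        a = len(query & members)
        b = n_q - a
        c = len(members) - a
        d = (n_bg - n_q) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        if a > 0:
            fe = (a / (a + b)) / ((a + c) / (a + b + c + d))
            log2fe = float(np.log2(fe))
        else:
            log2fe = float("-inf")
        rows.append(EnrichmentRow(subclass, a, b, c, d, float(p), log2fe))
    return rows


def filter_enrichment_terms(
    per_dataset: dict[str, list[EnrichmentRow]],
    alpha: float = 0.05,
    min_fraction: float = 0.10,
) -> list[str]:
    """Terms significant (p < alpha) in at least ``min_fraction`` of datasets."""
    n = len(per_dataset)
    if n == 0:
        return []
    hits: dict[str, int] = {}
    for rows in per_dataset.values():
        for r in rows:
            if r.p_value < alpha:
                hits[r.subclass] = hits.get(r.subclass, 0) + 1
    return sorted(t for t, c in hits.items() if c / n >= min_fraction)


def match_reference(
    annotations: set[tuple[str, str]],
    reference: set[tuple[str, str]],
    universe: set[tuple[str, str]],
    allowed_adducts: tuple[str, ...] = ("+H", "+Na", "+K"),
    other_method: set[tuple[str, str]] | None = None,
) -> dict:
    """Contingency of accepted annotations against a reference ion list.

    Ions are (formula, adduct) pairs; the reference is restricted to
    ``allowed_adducts`` first.  ``other_method`` switches to the exclusive
    mode: ions also annotated by the other method are removed from the
    annotation set before matching.  Returns counts and TPR/FPR/FNR.
    """
    reference = {ion for ion in reference if ion[1] in allowed_adducts}
    if not reference:
        raise ValueError("empty reference after adduct restriction")
    if other_method is not None:
        annotations = annotations - other_method
    annotations = annotations & universe
    tp = len(annotations & reference)
    fp = len(annotations - reference)
    fn = len((universe & reference) - annotations)
    tn = len(universe - reference - annotations)
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    fnr = fn / (tp + fn) if (tp + fn) else 0.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "tpr": tpr,
        "fpr": fpr,
        "fnr": fnr,
    }
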