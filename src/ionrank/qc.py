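"""Dataset quality control: profile-mode detection and exclusion rules.

Mistakenly submitted profile-mode (non-centroided) data is detected from
peak-gap statistics: in profile data consecutive m/z samples lie within the
matching tolerance of each other, so decoy isotopes match peak shoulders
and annotation quality collapses.  The overlap score measures, over the
densest pixels, the fraction of consecutive peak gaps narrower than the ppm
tolerance; datasets scoring above 0.5 are flagged for exclusion.

Two further rules exclude low-quality datasets: too few annotations at the
20% FDR threshold across every (adduct, database) combination, and an
implausibly high median per-pixel peak count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CentroidedDataset, CentroidedSpectrum

__all__ = [
    "QcReport",
    "proportion_overlap",
    "dataset_overlap_score",
    "apply_quality_filters",
    "OVERLAP_THRESHOLD",
    "MIN_ANNOTATIONS_AT_FDR20",
    "MAX_MEDIAN_PEAK_COUNT",
]

OVERLAP_THRESHOLD = 0.5
MIN_ANNOTATIONS_AT_FDR20 = 10
MAX_MEDIAN_PEAK_COUNT = 50_000


@dataclass
class QcReport:
    overlap_score: float
    median_peak_count: float
    annotations_at_fdr20: dict
    excluded: bool
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overlap_score": self.overlap_score,
            "median_peak_count": self.median_peak_count,
            "annotations_at_fdr20": {
                f"{k[0]}|{k[1]}": v for k, v in self.annotations_at_fdr20.items()
            },
            "excluded": self.excluded,
            "reasons": self.reasons,
        }


def proportion_overlap(
    spectrum: CentroidedSpectrum, tol_ppm: float = 3.0, literal: bool = False
) -> float:
    """Fraction of consecutive peak gaps inside the ppm tolerance.

    Default: a gap counts as overlap when ``m[i+1] - m[i] <= m[i] * tol_ppm
    / 1e6`` — peaks closer than the matching tolerance, the signature of
    profile-mode data.  ``literal=True`` instead counts gaps with
    ``m[i+1] - m[i] >= tol_ppm / 1e6`` (an absolute-Da comparison retained
    for auditability; it inverts the intended direction and is not used by
    the exclusion rules).  Both are divided by N - 1.
    """
    m = spectrum.mz
    n = m.size
    if n < 2:
        warnings.warn("proportion_overlap undefined for < 2 peaks; returning 0")
        return 0.0
    gaps = np.diff(m)
    if literal:
        hits = gaps >= tol_ppm / 1e6
    else:
        hits = gaps <= m[:-1] * tol_ppm / 1e6
    return float(hits.sum() / (n - 1))


def dataset_overlap_score(
    ds: CentroidedDataset,
    n_pixels: int = 50,
    tol_ppm: float = 3.0,
    literal: bool = False,
) -> float:
    """Mean overlap proportion over the top-n pixels by nonzero peak count.

    Pixels are ranked by the number of nonzero-intensity peaks (ties broken
    by pixel index, descending count first); all pixels are used when the
    dataset has fewer than ``n_pixels``.
    """
    counts = [
        (int(np.count_nonzero(ds.spectra[p].intensity)), p) for p in sorted(ds.spectra)
    ]
    counts.sort(key=lambda t: (-t[0], t[1]))
    top = counts[:n_pixels]
    scores = [
        proportion_overlap(ds.spectra[p], tol_ppm, literal=literal) for _, p in top
    ]
    return float(np.mean(scores)) if scores else 0.0


def apply_quality_filters(
    ds: CentroidedDataset,
    annotations_at_fdr20: dict[tuple[str, str], int],
    n_pixels: int = 50,
    tol_ppm: float = 3.0,
) -> QcReport:
    """Apply the three exclusion rules and report which ones triggered.

    - ``few_annotations``: every (adduct, database) combination has fewer
      than 10 annotations at FDR 20% (any adequate combination rescues the
      dataset);
    - ``excessive_peaks``: median per-pixel nonzero peak count > 50,000;
    - ``profile_mode``: dataset overlap score > 0.5.
    """
    reasons: list[str] = []
    if annotations_at_fdr20 and all(
        v < MIN_ANNOTATIONS_AT_FDR20 for v in annotations_at_fdr20.values()
    ):
        reasons.append("few_annotations")
    median_peaks = float(
        np.median([np.count_nonzero(s.intensity) for s in ds.spectra.values()])
    )
    if median_peaks > MAX_MEDIAN_PEAK_COUNT:
        reasons.append("excessive_peaks")
    overlap = dataset_overlap_score(ds, n_pixels=n_pixels, tol_ppm=tol_ppm)
    if overlap > OVERLAP_THRESHOLD:
        reasons.append("profile_mode")
    return QcReport(
        overlap_score=overlap,
        median_peak_count=median_peaks,
        annotations_at_fdr20=dict(annotations_at_fdr20),
        excluded=bool(reasons),
        reasons=reasons,
    )
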