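"""The five per-ion features and the rule-based MSM score.

For each candidate ion the engine extracts one ion image per theoretical
isotopic peak and derives:

- ``rho_spatial``  — spatial consistency between the principal-isotope image
  and the higher-isotope images (intensity-weighted mean of nonnegative
  Pearson correlations);
- ``rho_spectral`` — agreement between theoretical and observed isotope
  intensity patterns (1 minus half the L1 distance of the normalized
  vectors);
- ``rho_chaos``    — spatial informativeness of the principal image
  (structured signal forms few connected components across intensity
  thresholds; scattered noise forms many);
- ``mz_error_abs`` — 1 - |observed - theoretical| m/z of the first isotope;
- ``mz_error_rel`` — 1 - |weighted mean over higher isotopes of the
  deviation relative to the first isotope's deviation|.

MSM (Metabolite Signal Matching, the rule-based predecessor score) is the
product of the three rho features.  The two m/z error features operate on
native m/z units (Da-scale differences) by default; ``mz_error_in_ppm``
converts deviations to ppm first — monotone rescalings do not affect tree
models, the switch exists for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CentroidedDataset, IonImage, extract_ion_image
from .isotopes import IonCandidate, IsotopePattern

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "observed_isotope_stack",
    "mz_error_abs",
    "mz_error_rel",
    "rho_spectral",
    "rho_spatial",
    "rho_chaos",
    "msm",
    "compute_features",
]

FEATURE_NAMES = (
    "rho_spatial",
    "rho_spectral",
    "rho_chaos",
    "mz_error_abs",
    "mz_error_rel",
)

# 4-connectivity structuring element for component counting
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class FeatureVector:
    rho_spatial: float
    rho_spectral: float
    rho_chaos: float
    mz_error_abs: float
    mz_error_rel: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.rho_spatial,
                self.rho_spectral,
                self.rho_chaos,
                self.mz_error_abs,
                self.mz_error_rel,
            ]
        )


@dataclass
class IsotopeStack:
    """Observed evidence for the T isotopic peaks of one candidate."""

    images: list[IonImage]
    mean_mz: np.ndarray  # per-isotope intensity-weighted mean matched m/z (NaN if missing)
    total_intensity: np.ndarray  # per-isotope total matched intensity
    missing: np.ndarray  # per-isotope bool: no matched peaks anywhere


def observed_isotope_stack(
    ds: CentroidedDataset, pattern: IsotopePattern, tol_ppm: float = 3.0
) -> IsotopeStack:
    """Extract per-isotope ion images and summary statistics.

    For isotope i the observed mean m/z is the intensity-weighted mean of
    per-pixel matched m/z over pixels with nonzero matched intensity.
    Isotopes with no matched peaks anywhere are flagged missing.
    """
    images: list[IonImage] = []
    mean_mz = np.full(pattern.T, np.nan)
    totals = np.zeros(pattern.T)
    missing = np.zeros(pattern.T, dtype=bool)
    for i, mz in enumerate(pattern.mzs):
        img, matched = extract_ion_image(ds, mz, tol_ppm)
        images.append(img)
        pix_int = img.values[img.mask]
        total = float(img.values.sum())
        totals[i] = total
        if total > 0:
            # weighted mean across pixels of per-pixel matched m/z (Eq. over pixels)
            flat_int = np.zeros(ds.n_pixels)
            xs, ys = ds.coords[:, 0], ds.coords[:, 1]
            flat_int = img.values[ys, xs]
            ok = flat_int > 0
            mean_mz[i] = float(
                np.sum(matched[ok] * flat_int[ok]) / np.sum(flat_int[ok])
            )
        else:
            missing[i] = True
        del pix_int
    return IsotopeStack(images=images, mean_mz=mean_mz, total_intensity=totals, missing=missing)


def mz_error_abs(observed_m1: float, theoretical_m1: float) -> float:
    """1 - |observed - theoretical| m/z of the principal isotope."""
    return 1.0 - abs(observed_m1 - theoretical_m1)


def mz_error_rel(
    deviations: np.ndarray, rel_intensities: np.ndarray, observed: np.ndarray
) -> float:
    """Relative m/z error over higher isotopes.

    ``deviations[i] = observed_mz[i] - theoretical_mz[i]``; higher-isotope
    deviations are measured relative to the first isotope's and averaged
    with theoretical relative intensities as weights.  Missing higher
    isotopes (``observed[i]`` False) are excluded from both sums; if none
    are observed the score is 0 (absence of evidence is not agreement).
    """
    if not observed[0]:
        return 0.0
    idx = np.where(observed[1:])[0] + 1
    if idx.size == 0:
        return 0.0
    w = rel_intensities[idx]
    num = np.sum((deviations[idx] - deviations[0]) * w)
    return 1.0 - abs(float(num / np.sum(w)))


def rho_spectral(rel_intensities: np.ndarray, observed_totals: np.ndarray) -> float:
    """1 - 0.5 * L1 distance between normalized theoretical and observed patterns."""
    p = np.asarray(rel_intensities, dtype=float)
    q = np.asarray(observed_totals, dtype=float)
    if q.sum() <= 0:
        return 0.0
    p = p / p.sum()
    q = q / q.sum()
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return 0.0
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def rho_spatial(images: list[IonImage], rel_intensities: np.ndarray) -> float:
    """Weighted mean of clipped correlations between isotope images and image 1.

    Correlations are computed over acquired pixels, clipped at 0 (a
    negatively correlated isotope image is no evidence), and weighted by the
    theoretical relative intensity of each higher isotope.  Missing higher
    isotopes contribute correlation 0.
    """
    if len(images) < 2:
        return 0.0
    base = images[0]
    a = base.values[base.mask]
    if a.size == 0 or np.count_nonzero(a) < 2 or a.std() == 0:
        return 0.0
    num = 0.0
    den = 0.0
    for img, w in zip(images[1:], rel_intensities[1:]):
        b = img.values[img.mask]
        corr = max(0.0, _pearson(a, b)) if b.sum() > 0 else 0.0
        num += w * corr
        den += w
    return float(num / den) if den > 0 else 0.0


def rho_chaos(image: IonImage, n_levels: int = 30) -> float:
    """Spatial informativeness of the principal ion image.

    At each of ``n_levels`` intensity thresholds (quantile-spaced over the
    nonzero intensities) the image is binarized (>= threshold) and the ratio
    of 4-connected components to retained pixels is computed; the score is
    one minus the mean ratio, clipped to [0, 1].  A single solid blob gives
    a ratio near 0 at every level (score near 1); salt-and-pepper noise
    gives ratio 1 (score 0).
    """
    vals = image.values[image.mask]
    nz = vals[vals > 0]
    if nz.size == 0:
        return 0.0
    qs = np.quantile(nz, np.linspace(0.0, 1.0, n_levels))
    ratios = []
    for thr in qs:
        binary = image.values >= thr
        binary &= image.mask
        kept = int(binary.sum())
        if kept == 0:
            continue
        _, n_comp = ndimage.label(binary, structure=_CROSS)
        ratios.append(n_comp / kept)
    if not ratios:
        return 0.0
    return float(np.clip(1.0 - np.mean(ratios), 0.0, 1.0))


def msm(features: FeatureVector) -> float:
    """Metabolite Signal Matching: equal-weight product of the rho features."""
    return features.rho_spatial * features.rho_spectral * features.rho_chaos


def compute_features(
    ds: CentroidedDataset,
    candidate: IonCandidate,
    tol_ppm: float = 3.0,
    mz_error_in_ppm: bool = False,
    n_levels: int = 30,
) -> FeatureVector:
    """Assemble the five features for one candidate ion.

    Never raises on signal absence: a candidate with no matched peaks at all
    scores (0, 0, 0, 0, 0).
    """
    pattern = candidate.pattern
    stack = observed_isotope_stack(ds, pattern, tol_ppm)
    rel = np.asarray(pattern.rel_intensities)
    theo = np.asarray(pattern.mzs)

    observed = ~stack.missing
    if not observed[0]:
        err_abs = 0.0
        err_rel = 0.0
    else:
        dev = stack.mean_mz - theo
        if mz_error_in_ppm:
            dev = dev / theo * 1e6
        err_abs = mz_error_abs(stack.mean_mz[0], theo[0]) if not mz_error_in_ppm else 1.0 - abs(dev[0])
        err_rel = mz_error_rel(np.nan_to_num(dev), rel, observed)

    spec = rho_spectral(rel, stack.total_intensity)
    spat = rho_spatial(stack.images, rel) if observed[0] else 0.0
    chaos = rho_chaos(stack.images[0], n_levels=n_levels) if observed[0] else 0.0
    return FeatureVector(
        rho_spatial=spat,
        rho_spectral=spec,
        rho_chaos=chaos,
        mz_error_abs=err_abs,
        mz_error_rel=err_rel,
    )
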