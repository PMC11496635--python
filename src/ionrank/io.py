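"""Core data types and I/O for centroided imaging mass spectrometry data.

Centroided data reduce each pixel's spectrum to discrete (m/z, intensity)
peak pairs.  The dataset container keeps one spectrum per pixel together
with the pixel grid coordinates and the acquisition metadata needed for
context classification (polarity, ionization source, mass analyzer, m/z
range).  Ion images are extracted by summing centroid intensities inside a
closed symmetric ppm window around a target m/z.
"""

from __future__ import annotations

import json
import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CentroidedSpectrum",
    "CentroidedDataset",
    "MoleculeRecord",
    "IonImage",
    "AnnotationRecord",
    "read_centroided_dataset",
    "write_centroided_dataset",
    "read_molecule_database",
    "extract_ion_image",
    "classify_geometry",
    "write_results_table",
    "read_results_table",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string like ``C6H12O6``.

    Returns a mapping element -> positive count.  Raises ``ValueError`` on
    anything that does not tokenize completely into element/count pairs.
    """
    if not formula or not formula[0].isupper():
        raise ValueError(f"invalid formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos or not m.group(1):
            break
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"invalid formula: {formula!r}")
    if any(v <= 0 for v in counts.values()):
        raise ValueError(f"invalid formula: {formula!r}")
    return counts


@dataclass
class CentroidedSpectrum:
    """One pixel's centroided peak list; m/z strictly increasing."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D and the same length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class CentroidedDataset:
    """Pixel-indexed centroided spectra plus acquisition metadata."""

    spectra: dict[int, CentroidedSpectrum]
    coords: np.ndarray  # (n_pixels, 2) int, 0-based (x, y)
    polarity: str = "positive"
    analyzer: str = "Orbitrap"
    source: str = "MALDI"
    mz_min: float = 0.0
    mz_max: float = 0.0
    metadata: dict = field(default_factory=dict)
    profile_mode_declared: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.coords.shape != (len(self.spectra), 2):
            raise ValueError("coords must have one (x, y) row per spectrum")
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("pixel coordinates must be unique")
        self._peak_index: tuple | None = None

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)

    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding grid (row-major, 0-based)."""
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def peak_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Globally m/z-sorted (mz, intensity, pixel-id) arrays, built lazily.

        Lets ion-image extraction answer each window query with one binary
        search over the whole dataset instead of one per pixel.
        """
        if self._peak_index is None:
            order_keys = []
            for pix in sorted(self.spectra):
                s = self.spectra[pix]
                order_keys.append(
                    (s.mz, s.intensity, np.full(len(s), pix, dtype=np.int64))
                )
            if order_keys:
                mz = np.concatenate([k[0] for k in order_keys])
                inten = np.concatenate([k[1] for k in order_keys])
                pix = np.concatenate([k[2] for k in order_keys])
            else:  # pragma: no cover - empty dataset
                mz = np.empty(0)
                inten = np.empty(0)
                pix = np.empty(0, dtype=np.int64)
            order = np.argsort(mz, kind="stable")
            self._peak_index = (mz[order], inten[order], pix[order])
        return self._peak_index


@dataclass(frozen=True)
class MoleculeRecord:
    """A database molecule: formula, name and optional class labels."""

    formula: str
    name: str
    subclass: str | None = None
    parent_class: str | None = None


@dataclass
class IonImage:
    """2-D nonnegative intensity image over the pixel grid."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share shape")
        self.values = np.where(self.mask, self.values, 0.0)


@dataclass
class AnnotationRecord:
    """One scored (formula, adduct) ion with its FDR estimate."""

    formula: str
    adduct: str
    is_decoy: bool
    features: "object"  # ion_scoring.FeatureVector
    msm_score: float
    ml_score: float = float("nan")
    fdr_raw: float = float("nan")
    fdr: float = float("nan")


# ---------------------------------------------------------------------------
# imzML I/O


def write_centroided_dataset(ds: CentroidedDataset, path: str) -> None:
    """Write a dataset as an imzML/ibd pair plus a JSON metadata sidecar."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(
        path,
        polarity=ds.polarity,
        mode="processed",
        intensity_dtype=np.float64,
    ) as writer:
        for pix in sorted(ds.spectra):
            s = ds.spectra[pix]
            x, y = ds.coords[pix]
            mz, inten = s.mz, s.intensity
            if len(s) == 0:
                # imzML cannot store zero-length spectra; a zero-intensity
                # placeholder peak is stripped again on read
                mz, inten = np.array([1.0]), np.array([0.0])
            # imzML coordinates are 1-based
            writer.addSpectrum(mz, inten, (int(x) + 1, int(y) + 1, 1))
    sidecar = {
        "polarity": ds.polarity,
        "analyzer": ds.analyzer,
        "source": ds.source,
        "mz_min": ds.mz_min,
        "mz_max": ds.mz_max,
        "metadata": ds.metadata,
        "profile_mode_declared": ds.profile_mode_declared,
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".meta.json"


def read_centroided_dataset(path: str) -> CentroidedDataset:
    """Read an imzML/ibd pair into a :class:`CentroidedDataset`.

    Unsorted per-pixel m/z arrays are sorted ascending with intensities
    co-permuted.  A profile-mode declaration in the file sets
    ``profile_mode_declared`` (QC decides exclusion; reading never fails on
    it).  A ``<stem>.meta.json`` sidecar, if present, supplies acquisition
    metadata that imzML itself does not carry.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise IOError(f"missing binary file: {ibd}")
    parser = ImzMLParser(path)
    profile_declared = False
    try:
        # pyimzml records the spectrum representation in the metadata dict
        for key in parser.metadata.file_description:  # type: ignore[union-attr]
            if "profile" in str(key).lower():
                profile_declared = True
    except Exception:
        pass

    spectra: dict[int, CentroidedSpectrum] = {}
    coords = np.zeros((len(parser.coordinates), 2), dtype=np.int64)
    for idx, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(idx)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        nz = inten > 0  # zero-intensity placeholders carry no signal
        spectra[idx] = CentroidedSpectrum(mz[nz], inten[nz])
        coords[idx] = (int(x) - 1, int(y) - 1)

    polarity = getattr(parser, "polarity", None) or "positive"
    meta: dict = {}
    analyzer, source = "unknown", "unknown"
    mz_min = min((s.mz[0] for s in spectra.values() if len(s)), default=0.0)
    mz_max = max((s.mz[-1] for s in spectra.values() if len(s)), default=0.0)
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar, encoding="utf-8") as fh:
            sc = json.load(fh)
        polarity = sc.get("polarity", polarity)
        analyzer = sc.get("analyzer", analyzer)
        source = sc.get("source", source)
        mz_min = sc.get("mz_min", mz_min)
        mz_max = sc.get("mz_max", mz_max)
        meta = sc.get("metadata", {})
        profile_declared = bool(sc.get("profile_mode_declared", profile_declared))
    if profile_declared:
        warnings.warn(f"{path} declares profile-mode spectra", stacklevel=2)
    return CentroidedDataset(
        spectra=spectra,
        coords=coords,
        polarity=polarity,
        analyzer=analyzer,
        source=source,
        mz_min=float(mz_min),
        mz_max=float(mz_max),
        metadata=meta,
        profile_mode_declared=profile_declared,
    )


# ---------------------------------------------------------------------------
# molecular databases


def read_molecule_database(path: str) -> tuple[list[MoleculeRecord], list[str]]:
    """Read a TSV molecular database (columns: formula, name[, subclass, parent_class]).

    Deduplicates on formula (first occurrence wins).  Rows whose formula does
    not parse are collected as error strings, not fatal.
    Returns (records, errors).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "formula" not in df.columns or "name" not in df.columns:
        raise ValueError("database must have 'formula' and 'name' columns")
    records: list[MoleculeRecord] = []
    errors: list[str] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        formula = row["formula"].strip()
        try:
            parse_formula(formula)
        except ValueError as exc:
            errors.append(str(exc))
            continue
        if formula in seen:
            errors.append(f"duplicate formula dropped: {formula}")
            continue
        seen.add(formula)
        records.append(
            MoleculeRecord(
                formula=formula,
                name=row["name"],
                subclass=row.get("subclass") or None,
                parent_class=row.get("parent_class") or None,
            )
        )
    return records, errors


# ---------------------------------------------------------------------------
# ion images


def extract_ion_image(
    ds: CentroidedDataset, mz: float, tol_ppm: float = 3.0
) -> tuple[IonImage, np.ndarray]:
    """Extract the ion image for a target m/z at a ppm tolerance.

    Per pixel, sums the intensities of every centroid peak inside the closed
    symmetric window ``|peak - mz| <= mz * tol_ppm / 1e6`` and records the
    intensity-weighted mean matched m/z (NaN where nothing matched).

    Returns ``(IonImage, matched_mz)`` where ``matched_mz`` is a flat array
    aligned with pixel ids.
    """
    if mz <= 0:
        raise ValueError("target m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = mz * tol_ppm / 1e6
    all_mz, all_int, all_pix = ds.peak_index()
    lo = np.searchsorted(all_mz, mz - half, side="left")
    hi = np.searchsorted(all_mz, mz + half, side="right")
    n = ds.n_pixels
    sums = np.zeros(n)
    wmz = np.zeros(n)
    if hi > lo:
        seg_int = all_int[lo:hi]
        seg_mz = all_mz[lo:hi]
        seg_pix = all_pix[lo:hi]
        sums = np.bincount(seg_pix, weights=seg_int, minlength=n)
        wmz = np.bincount(seg_pix, weights=seg_int * seg_mz, minlength=n)
    matched = np.full(n, np.nan)
    nz = sums > 0
    matched[nz] = wmz[nz] / sums[nz]
    # also treat zero-intensity matches as matched at the target m/z? no:
    # empty window or zero weight -> no matched m/z recorded.
    shape = ds.grid_shape()
    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    xs, ys = ds.coords[:, 0], ds.coords[:, 1]
    values[ys, xs] = sums
    mask[ys, xs] = True
    return IonImage(values=values, mask=mask), matched


def classify_geometry(ds: CentroidedDataset) -> str:
    """``regular`` iff pixel count == (#distinct x) * (#distinct y)."""
    nx = len(np.unique(ds.coords[:, 0]))
    ny = len(np.unique(ds.coords[:, 1]))
    return "regular" if ds.n_pixels == nx * ny else "irregular"


# ---------------------------------------------------------------------------
# results tables

_RESULT_COLUMNS = [
    "formula",
    "adduct",
    "is_decoy",
    "msm",
    "rho_spatial",
    "rho_spectral",
    "rho_chaos",
    "mz_error_abs",
    "mz_error_rel",
    "ml_score",
    "fdr",
]


def write_results_table(
    records: list[AnnotationRecord], path: str, include_decoys: bool = False
) -> None:
    """Write annotation records as TSV, ordered by (formula, adduct).

    Targets only, unless ``include_decoys``.  Floats are written with
    ``repr`` precision so a round-trip read reproduces values to 1e-9.
    """
    rows = []
    for r in sorted(records, key=lambda r: (r.formula, r.adduct)):
        if r.is_decoy and not include_decoys:
            continue
        f = r.features
        rows.append(
            {
                "formula": r.formula,
                "adduct": r.adduct,
                "is_decoy": r.is_decoy,
                "msm": r.msm_score,
                "rho_spatial": f.rho_spatial,
                "rho_spectral": f.rho_spectral,
                "rho_chaos": f.rho_chaos,
                "mz_error_abs": f.mz_error_abs,
                "mz_error_rel": f.mz_error_rel,
                "ml_score": r.ml_score,
                "fdr": r.fdr,
            }
        )
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", encoding="utf-8")


def read_results_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
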